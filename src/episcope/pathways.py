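"""GO-term over-representation, term clustering and subtype grouping.

Per subtype, DE genes are tested against every gene set with a one-sided
hypergeometric over-representation test, BH-adjusted within (subtype,
namespace) at 0.05. Terms whose enriched genes are >20% autopsy-associated
are removed. Terms are then clustered within each subtype on the Jaccard
distance of their enriched gene sets (cut at 0.66), and collapsed across
subtypes using the fraction of subtypes that place a term pair in different
clusters as a distance (average linkage, cut at 0.66). Subtypes are finally
compared as weighted sets of enriched pathways, where a pathway's weight in a
subtype is the inverse of the summed Jaccard similarities of its gene set to
all of that subtype's enriched pathways (so redundant pathways share weight),
and subtype similarity is the weighted Jaccard of those weight vectors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core import ValidationError


@dataclass
class TermEnrichment:
    """Retained enriched terms per subtype.

    ``table`` rows: subtype, term, namespace, p, padj, n_overlap; ``genes``
    maps (subtype, term) -> enriched gene set (DE ∩ term).
    """

    table: pd.DataFrame
    genes: dict[tuple[str, str], frozenset]

    def terms_of(self, subtype: str) -> list[str]:
        sub = self.table[self.table["subtype"] == subtype]
        return sub["term"].tolist()

    @property
    def subtypes(self) -> list[str]:
        return sorted(self.table["subtype"].unique())


def hypergeom_overrep_p(n_universe, n_list, n_draw, n_overlap) -> float:
    """P(X >= n_overlap) for overlap of a draw of n_draw with a list of n_list."""
    return float(
        stats.hypergeom.sf(n_overlap - 1, n_universe, n_list, n_draw)
    )


def go_overrepresentation(
    de_genes_per_subtype: dict[str, set],
    gene_sets: dict[str, list[str]],
    universe,
    alpha: float = 0.05,
    namespaces: dict[str, str] | None = None,
) -> TermEnrichment:
    """One-sided hypergeometric over-representation with BH within
    (subtype, namespace); retains adjusted p <= alpha."""
    universe = set(universe)
    namespaces = namespaces or {}
    rows, genes = [], {}
    for subtype, de in de_genes_per_subtype.items():
        de = set(de) & universe
        cand = []
        for term, members in gene_sets.items():
            members_in = set(members) & universe
            if not members_in:
                warnings.warn(f"term {term!r} lies outside the universe; skipped")
                continue
            overlap = de & members_in
            p = hypergeom_overrep_p(len(universe), len(members_in), len(de), len(overlap))
            cand.append((term, namespaces.get(term, "BP"), p, overlap))
        if not cand:
            continue
        df = pd.DataFrame(cand, columns=["term", "namespace", "p", "overlap"])
        df["padj"] = np.nan
        for ns in df["namespace"].unique():
            m = df["namespace"] == ns
            df.loc[m, "padj"] = multipletests(df.loc[m, "p"], method="fdr_bh")[1]
        kept = df[df["padj"] <= alpha]
        for _, r in kept.iterrows():
            rows.append(
                {
                    "subtype": subtype,
                    "term": r["term"],
                    "namespace": r["namespace"],
                    "p": r["p"],
                    "padj": r["padj"],
                    "n_overlap": len(r["overlap"]),
                }
            )
            genes[(subtype, r["term"])] = frozenset(r["overlap"])
    table = pd.DataFrame(
        rows, columns=["subtype", "term", "namespace", "p", "padj", "n_overlap"]
    )
    return TermEnrichment(table, genes)


def autopsy_filter(terms: TermEnrichment, autopsy_genes) -> TermEnrichment:
    """Drop terms whose enriched genes are more than 20% autopsy-associated."""
    autopsy = set(autopsy_genes)
    keep_rows, genes = [], {}
    for _, r in terms.table.iterrows():
        key = (r["subtype"], r["term"])
        g = terms.genes[key]
        frac = len(g & autopsy) / len(g) if g else 0.0
        if frac > 0.20:
            continue
        keep_rows.append(r)
        genes[key] = g
    table = pd.DataFrame(keep_rows, columns=terms.table.columns).reset_index(drop=True)
    return TermEnrichment(table, genes)


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def cluster_terms_within_subtype(
    terms: TermEnrichment,
    subtype: str,
    h: float = 0.66,
    method: str = "complete",
) -> pd.Series:
    """Agglomerative clustering of a subtype's terms on Jaccard distance of
    enriched gene sets, cut at height h."""
    names = terms.terms_of(subtype)
    if not names:
        raise ValidationError(f"no enriched terms for subtype {subtype!r}")
    if len(names) == 1:
        return pd.Series([1], index=names)
    sets = [terms.genes[(subtype, t)] for t in names]
    dist = np.array(
        [
            1.0 - jaccard(sets[i], sets[j])
            for i, j in itertools.combinations(range(len(sets)), 2)
        ]
    )
    labels = fcluster(linkage(dist, method=method), t=h, criterion="distance")
    return pd.Series(labels, index=names)


@dataclass
class PathwayCluster:
    """Collapsed cross-subtype pathway clusters."""

    within: dict[str, pd.Series]  # subtype -> term cluster ids
    distance: pd.DataFrame  # f(P1, P2) over all terms
    membership: pd.Series  # term -> collapsed cluster id
    representative: pd.Series  # collapsed cluster id -> representative term name


def collapse_terms_across_subtypes(
    terms: TermEnrichment,
    within: dict[str, pd.Series] | None = None,
    h: float = 0.66,
    within_h: float = 0.66,
) -> PathwayCluster:
    """Collapse terms whose gene content co-clusters across subtypes.

    The distance between two terms is the fraction of subtypes, among those
    where both are enriched, that assign them to different within-subtype
    clusters; pairs never co-enriched get distance 1. Average linkage, cut at h.
    """
    if within is None:
        within = {
            t: cluster_terms_within_subtype(terms, t, h=within_h)
            for t in terms.subtypes
        }
    all_terms = sorted(terms.table["term"].unique())
    n = len(all_terms)
    dist = pd.DataFrame(1.0, index=all_terms, columns=all_terms)
    np.fill_diagonal(dist.values, 0.0)
    for p1, p2 in itertools.combinations(all_terms, 2):
        shared = [
            t
            for t, labels in within.items()
            if p1 in labels.index and p2 in labels.index
        ]
        if shared:
            f = np.mean([within[t][p1] != within[t][p2] for t in shared])
            dist.loc[p1, p2] = dist.loc[p2, p1] = float(f)
    if n == 1:
        membership = pd.Series([1], index=all_terms)
    else:
        labels = fcluster(
            linkage(squareform(dist.values, checks=False), method="average"),
            t=h,
            criterion="distance",
        )
        membership = pd.Series(labels, index=all_terms)

    # representative name: member term with the least mean log p across subtypes
    logp = terms.table.assign(logp=np.log10(terms.table["padj"].clip(lower=1e-300)))
    mean_logp = logp.groupby("term", observed=True)["logp"].mean()
    rep = {}
    for cid in sorted(membership.unique()):
        members = sorted(membership.index[membership == cid])
        rep[cid] = min(members, key=lambda t: (mean_logp.get(t, 0.0), t))
    return PathwayCluster(within, dist, membership, pd.Series(rep))


def heatmap_groups(
    clusters: PathwayCluster,
    terms: TermEnrichment,
    h: float = 2.5,
    min_group: int = 5,
    cap: float = 10.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Min-log-p matrix (collapsed cluster × subtype) and its row groups.

    Entries are the largest −log10 adjusted p of any member term in the
    subtype, trimmed at ``cap``; rows are L1-normalized and Ward-clustered on
    L1 distance; groups of at least ``min_group`` rows are retained (group id
    −1 marks discarded rows).
    """
    subtypes = terms.subtypes
    cids = sorted(clusters.membership.unique())
    mat = pd.DataFrame(0.0, index=cids, columns=subtypes)
    neglog = terms.table.assign(
        v=(-np.log10(terms.table["padj"].clip(lower=1e-300))).clip(upper=cap)
    )
    neglog["cid"] = neglog["term"].map(clusters.membership)
    best = neglog.groupby(["cid", "subtype"], observed=True)["v"].max()
    for (cid, st), v in best.items():
        mat.loc[cid, st] = v
    sums = mat.sum(axis=1)
    norm = mat.div(sums.where(sums > 0, 1.0), axis=0)
    if len(norm) > 1:
        dist = np.array(
            [
                np.abs(norm.iloc[i] - norm.iloc[j]).sum()
                for i, j in itertools.combinations(range(len(norm)), 2)
            ]
        )
        labels = fcluster(linkage(dist, method="ward"), t=h, criterion="distance")
    else:
        labels = np.array([1])
    groups = pd.Series(labels, index=norm.index)
    sizes = groups.value_counts()
    small = sizes[sizes < min_group].index
    groups[groups.isin(small)] = -1
    return mat, groups


def pair_embedding(
    terms: TermEnrichment,
    clusters: PathwayCluster,
    k: int = 10,
    spread: float = 1.5,
    min_dist: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """2D embedding of (subtype, collapsed cluster) pairs.

    Each pair is the union of enriched genes of the cluster's terms in that
    subtype; pairs are embedded with UMAP on their pairwise Jaccard distances.
    """
    pairs, sets = [], []
    for st in terms.subtypes:
        by_cid: dict[int, set] = {}
        for term in terms.terms_of(st):
            cid = clusters.membership[term]
            by_cid.setdefault(cid, set()).update(terms.genes[(st, term)])
        for cid, genes in sorted(by_cid.items()):
            pairs.append((st, cid))
            sets.append(frozenset(genes))
    n = len(pairs)
    if n < 3:
        raise ValidationError("need at least 3 (subtype, cluster) pairs to embed")
    if n <= k:
        warnings.warn(f"only {n} pairs; reducing k from {k} to {n - 1}")
        k = n - 1
    dist = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist[i, j] = dist[j, i] = 1.0 - jaccard(sets[i], sets[j])

    import umap

    emb = umap.UMAP(
        n_neighbors=k,
        spread=spread,
        min_dist=min_dist,
        metric="precomputed",
        random_state=int(seed),
        init="spectral" if n > 4 else "random",
    ).fit_transform(dist)
    return pd.DataFrame(
        emb,
        columns=["umap1", "umap2"],
        index=pd.MultiIndex.from_tuples(pairs, names=["subtype", "cluster"]),
    )


@dataclass
class SubtypeSimilarityMatrix:
    weights: pd.DataFrame  # subtype × pathway weights (0 = not enriched)
    similarity: pd.DataFrame  # subtype × subtype weighted Jaccard
    groups: pd.Series = field(default=None)  # type: ignore[assignment]


def pathway_weights(terms: TermEnrichment, subtype: str) -> pd.Series:
    """Inverse summed Jaccard similarity of each enriched pathway's gene set
    to all of the subtype's enriched pathways (including itself)."""
    names = terms.terms_of(subtype)
    sets = {t: terms.genes[(subtype, t)] for t in names}
    w = {}
    for t in names:
        s = sum(jaccard(sets[t], sets[u]) for u in names)
        w[t] = 1.0 / s if s > 0 else 0.0
    return pd.Series(w)


def weighted_jaccard(a: pd.Series, b: pd.Series) -> float:
    idx = a.index.union(b.index)
    av = a.reindex(idx, fill_value=0.0).to_numpy()
    bv = b.reindex(idx, fill_value=0.0).to_numpy()
    denom = np.maximum(av, bv).sum()
    return float(np.minimum(av, bv).sum() / denom) if denom > 0 else 0.0


def subtype_similarity(
    terms: TermEnrichment, h: float = 1.2, method: str = "average"
) -> SubtypeSimilarityMatrix:
    """Weighted-Jaccard similarity of subtypes over their enriched pathways."""
    subtypes = [t for t in terms.subtypes if terms.terms_of(t)]
    if len(subtypes) < 2:
        raise ValidationError("need at least two subtypes with enriched terms")
    weights = {t: pathway_weights(terms, t) for t in subtypes}
    all_terms = sorted(set().union(*[w.index for w in weights.values()]))
    wmat = pd.DataFrame(0.0, index=subtypes, columns=all_terms)
    for t, w in weights.items():
        wmat.loc[t, w.index] = w
    sim = pd.DataFrame(np.eye(len(subtypes)), index=subtypes, columns=subtypes)
    for a, b in itertools.combinations(subtypes, 2):
        s = weighted_jaccard(weights[a], weights[b])
        sim.loc[a, b] = sim.loc[b, a] = s
    dist = 1.0 - sim.values
    labels = fcluster(
        linkage(squareform(dist, checks=False), method=method),
        t=h,
        criterion="distance",
    )
    groups = pd.Series(labels, index=subtypes)
    return SubtypeSimilarityMatrix(wmat, sim, groups)
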