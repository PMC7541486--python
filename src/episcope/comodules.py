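"""Resampled consensus co-expression module detection and filtering.

Networks are built per cell cluster from the top variable-loading genes:
signed-hybrid adjacency (a = cor^β for positive correlations, 0 otherwise)
with β picked for scale-free topology, converted to a topological overlap
matrix (TOM), and made robust by resampling two-thirds of the cells and
taking the element-wise median (consensus quantile 0.5) across resamples.
Modules are average-linkage clusters of 1−TOM (dynamic hybrid cut, minimum
15 genes), refined by intramodular-connectivity (kIM) driven merging
(Pearson ≥ 0.85 of module kIM profiles), iterative reassignment (alternative
kIM > 1.25× current), and pruning of genes whose kIM is not significantly
above the non-member kIM distribution. A four-stage filter cascade follows:
overlap removal, injury/postmortem-signature removal, sample-vs-condition
confounding, and condition-coefficient significance; surviving modules are
tested for curated-gene enrichment with a VIF-corrected rank-sum test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .core import AnnotatedCounts, ValidationError

logger = logging.getLogger(__name__)


# -- gene selection -----------------------------------------------------------


def select_genes(
    data: AnnotatedCounts,
    cluster: str,
    min_cells: int = 20,
    n_pcs: int = 120,
    top_n: int = 5000,
    cluster_level: str = "level2",
) -> pd.Index:
    """Top PCA-loading genes within one cell cluster.

    Genes expressed in fewer than ``min_cells`` cells of the cluster are
    removed; the remainder are centered+scaled, decomposed into ``n_pcs``
    components, ranked by their highest absolute loading on any PC, and the
    top ``top_n`` returned.
    """
    mask = (data.obs[cluster_level] == cluster).to_numpy()
    if mask.sum() < min_cells:
        raise ValidationError(
            f"cluster {cluster!r} has {int(mask.sum())} cells < {min_cells}"
        )
    import scipy.sparse as sp

    X = sp.csr_matrix(data.X)[mask]
    cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = cells_per_gene >= min_cells
    genes = data.genes[keep]
    dense = np.log1p(X[:, keep].toarray())
    dense -= dense.mean(axis=0)
    sd = dense.std(axis=0)
    dense /= np.where(sd > 0, sd, 1.0)
    from sklearn.decomposition import PCA

    k = min(n_pcs, dense.shape[0] - 1, dense.shape[1])
    pca = PCA(n_components=k, random_state=0)
    pca.fit(dense)
    max_loading = np.abs(pca.components_).max(axis=0)
    if top_n >= len(genes):
        warnings.warn(f"top_n={top_n} >= {len(genes)} candidate genes; returning all")
        order = np.argsort(-max_loading)
    else:
        order = np.argsort(-max_loading)[:top_n]
    return genes[np.sort(order)]


# -- adjacency / TOM ----------------------------------------------------------


def signed_hybrid_adjacency(corr: np.ndarray, beta: float) -> np.ndarray:
    """a = cor^beta where cor > 0, else 0; zero diagonal."""
    a = np.where(corr > 0, corr, 0.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap:
    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij), diagonal 1."""
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def scale_free_fit_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """R² of the log-log regression of the connectivity histogram, the
    standard scale-free topology fit index."""
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 5 or np.ptp(k) == 0:
        return 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-9), n_bins + 1)
    which = np.digitize(k, edges) - 1
    freq, centers = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        freq.append(sel.mean())
        centers.append(k[sel].mean())
    if len(freq) < 3:
        return 0.0
    lx, ly = np.log10(centers), np.log10(freq)
    r = stats.pearsonr(lx, ly)[0]
    return float(r**2)


def pick_soft_threshold(
    expr: np.ndarray | pd.DataFrame,
    powers: range = range(1, 31),
    r2_target: float = 0.93,
    connectivity_percentile: float = 95.0,
    min_mean_connectivity: float = 0.05,
) -> int:
    """Lowest power reaching scale-free R² >= target, after discarding powers
    whose mean connectivity sits at or above the given percentile across
    powers; falls back to the surviving power with the highest R².

    Powers whose mean connectivity falls below ``min_mean_connectivity`` are
    also discarded: a power that effectively disconnects the network produces
    a degenerate degree histogram whose fit index is meaningless.
    """
    X = np.asarray(expr, dtype=float)
    if X.shape[1] < 50:
        raise ValidationError("need at least 50 genes to pick a soft threshold")
    corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr)
    rows = []
    for beta in powers:
        a = signed_hybrid_adjacency(corr, beta)
        k = a.sum(axis=1)
        rows.append((beta, k.mean(), scale_free_fit_r2(k)))
    df = pd.DataFrame(rows, columns=["beta", "mean_k", "r2"])
    cutoff = np.percentile(df["mean_k"], connectivity_percentile)
    surviving = df[(df["mean_k"] < cutoff) & (df["mean_k"] >= min_mean_connectivity)]
    if surviving.empty:
        surviving = df[df["mean_k"] < cutoff]
    if surviving.empty:
        surviving = df
    good = surviving[surviving["r2"] >= r2_target]
    if len(good):
        return int(good["beta"].min())
    return int(surviving.loc[surviving["r2"].idxmax(), "beta"])


@dataclass
class TOMStack:
    """Consensus topological overlap across cell resamples."""

    consensus: pd.DataFrame  # gene × gene, symmetric, diag 1
    beta: float
    n_resamples: int
    fraction: float
    quantile: float

    @property
    def genes(self) -> pd.Index:
        return self.consensus.index


def consensus_tom(
    expr: pd.DataFrame,
    beta: float,
    n_resamples: int = 100,
    fraction: float = 2 / 3,
    quantile: float = 0.5,
    seed: int = 0,
) -> TOMStack:
    """Element-wise quantile of TOMs over random cell subsamples.

    ``expr`` is cells × genes. Genes with zero variance in any resample are
    dropped before aggregation (the analogue of WGCNA's good-gene filtering).
    """
    X = np.asarray(expr, dtype=float)
    genes = pd.Index(expr.columns)
    n_cells = X.shape[0]
    n_draw = int(round(fraction * n_cells))
    if n_draw < 30:
        raise ValidationError(
            f"resample size {n_draw} < 30 cells; increase the input cluster"
        )
    rng = np.random.default_rng(seed)
    subsets = [rng.choice(n_cells, size=n_draw, replace=False) for _ in range(n_resamples)]
    good = np.ones(len(genes), dtype=bool)
    for idx in subsets:
        good &= X[idx].std(axis=0) > 0
    if not good.all():
        logger.info("dropping %d zero-variance genes", int((~good).sum()))
    Xg = X[:, good]
    toms = np.empty((n_resamples, good.sum(), good.sum()), dtype=np.float32)
    for r, idx in enumerate(subsets):
        corr = np.corrcoef(Xg[idx], rowvar=False)
        corr = np.nan_to_num(corr)
        toms[r] = tom_from_adjacency(signed_hybrid_adjacency(corr, beta))
    cons = np.quantile(toms, quantile, axis=0).astype(float)
    cons = (cons + cons.T) / 2.0
    np.fill_diagonal(cons, 1.0)
    gidx = genes[good]
    return TOMStack(
        pd.DataFrame(cons, index=gidx, columns=gidx),
        beta, n_resamples, fraction, quantile,
    )


# -- module detection ---------------------------------------------------------


def detect_modules(
    tom: TOMStack,
    min_size: int = 15,
    deep_split: int = 2,
    pam_stage: bool = True,
    cut_height: float | None = None,
) -> pd.Series:
    """Average-linkage clustering of 1−TOM with a dynamic-hybrid-style cut.

    Core branches come from a static cut whose height maps from ``deep_split``
    (0–4; higher splits more aggressively); clusters under ``min_size`` are
    dissolved. The PAM-like stage then assigns each unlabeled gene to the
    module with the highest mean TOM, provided the corresponding distance
    (1 − mean TOM) falls below the cut height, mirroring the published hybrid
    cut's maximum assignment distance. Returns gene -> module label
    (0 = background). Passing ``cut_height`` switches to a plain static cut.
    """
    if not 0 <= deep_split <= 4:
        raise ValidationError("deep_split must be in 0..4")
    D = 1.0 - tom.consensus.values
    genes = tom.genes
    Z = linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    if cut_height is None:
        # the published hybrid cut uses 99% of the dendrogram height range;
        # deeper splits lower the cut slightly, giving smaller, tighter cores
        frac = 0.99 - 0.01 * deep_split
        cut_height = heights.min() + frac * (heights.max() - heights.min())
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_size].index
    labels[~labels.isin(keep)] = 0
    if (labels == 0).all():
        warnings.warn("no module reached the minimum size; empty result")
        return labels
    # relabel 1..n by decreasing size
    order = labels[labels > 0].value_counts().index
    mapping = {old: i + 1 for i, old in enumerate(order)}
    labels = labels.map(lambda v: mapping.get(v, 0))

    if pam_stage:
        T = tom.consensus.values
        module_ids = sorted(set(labels) - {0})
        members_of = {m: np.where(labels.values == m)[0] for m in module_ids}
        unassigned = np.where(labels.values == 0)[0]
        assigned = {}
        for g in unassigned:
            best, best_mean = 0, -np.inf
            for m in module_ids:
                mean_tom = T[g, members_of[m]].mean()
                if mean_tom > best_mean:
                    best, best_mean = m, mean_tom
            if best and (1.0 - best_mean) < cut_height:
                assigned[g] = best
        for g, m in assigned.items():
            labels.iloc[g] = m
    return labels


# -- kIM and refinement -------------------------------------------------------


def kim_matrix(labels: pd.Series, tom: TOMStack) -> pd.DataFrame:
    """Intramodular connectivity of every gene to every module:
    kIM(g, M) = Σ_{m ∈ M, m ≠ g} TOM(g, m)."""
    T = tom.consensus
    modules = sorted(set(labels) - {0})
    out = pd.DataFrame(0.0, index=T.index, columns=modules)
    for m in modules:
        members = labels.index[labels == m]
        s = T[members].sum(axis=1)
        s[members] -= 1.0  # remove the diagonal contribution for members
        out[m] = s
    return out


@dataclass
class GeneModule:
    """A co-expressed gene set with connectivity-based membership weights."""

    name: str
    genes: list[str]
    kim: pd.Series  # kIM of every network gene to this module
    weights: pd.Series = field(default=None)  # type: ignore[assignment]
    flags: dict = field(default_factory=dict)
    condition_coef: float = np.nan
    condition_ci: tuple[float, float] = (np.nan, np.nan)
    condition_p: float = np.nan
    enrichment_z: float = np.nan
    enrichment_p: float = np.nan

    def __post_init__(self):
        if self.weights is None:
            member_kim = self.kim.loc[self.genes].clip(lower=0)
            total = member_kim.sum()
            self.weights = member_kim / total if total > 0 else member_kim

    @property
    def size(self) -> int:
        return len(self.genes)


def _merge_groups(corr: pd.DataFrame, threshold: float) -> list[set]:
    """Transitive closure of module pairs with kIM-profile correlation >= threshold."""
    mods = list(corr.index)
    parent = {m: m for m in mods}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(mods):
        for b in mods[i + 1:]:
            if corr.loc[a, b] >= threshold:
                parent[find(a)] = find(b)
    groups: dict[str, set] = {}
    for m in mods:
        groups.setdefault(find(m), set()).add(m)
    return list(groups.values())


def refine_modules(
    labels: pd.Series,
    tom: TOMStack,
    merge_cor: float = 0.85,
    reassign_ratio: float = 1.25,
    alpha: float = 0.05,
    max_iter: int = 50,
) -> tuple[pd.Series, pd.DataFrame]:
    """Merge, reassign and prune modules by intramodular connectivity.

    Module pairs whose kIM profiles (over all genes) correlate at >= merge_cor
    are merged transitively. Genes move to another module when their kIM there
    exceeds ``reassign_ratio`` times the kIM to their current module, iterating
    with recomputation until stable (cap ``max_iter``). Genes whose kIM is not
    significantly above the non-member kIM distribution of their module
    (empirical one-sided rank p, BH-adjusted at ``alpha``) are pruned to
    background. Returns (labels, kIM matrix) for the final state.
    """
    labels = labels.copy()
    if (labels > 0).sum() == 0:
        return labels, kim_matrix(labels, tom)
    # merge
    kim = kim_matrix(labels, tom)
    if kim.shape[1] > 1:
        corr = kim.corr()
        for group in _merge_groups(corr, merge_cor):
            if len(group) > 1:
                target = min(group)
                labels[labels.isin(group)] = target
        kim = kim_matrix(labels, tom)
    # reassign
    for it in range(max_iter):
        assigned = labels[labels > 0]
        current = pd.Series(
            [kim.at[g, m] for g, m in assigned.items()], index=assigned.index
        )
        moved = 0
        for g in assigned.index:
            row = kim.loc[g].drop(labels[g])
            if len(row) == 0:
                continue
            best = row.idxmax()
            if row[best] > reassign_ratio * current[g]:
                labels[g] = best
                moved += 1
        if moved == 0:
            break
        kim = kim_matrix(labels, tom)
    else:
        warnings.warn(f"reassignment did not stabilize within {max_iter} iterations")
    # prune
    pvals, keys = [], []
    for m in sorted(set(labels) - {0}):
        members = labels.index[labels == m]
        non = kim.loc[labels.index[labels != m], m].to_numpy()
        if len(non) == 0:
            continue
        for g in members:
            p = (1.0 + (non >= kim.at[g, m]).sum()) / (1.0 + len(non))
            pvals.append(p)
            keys.append(g)
    if pvals:
        padj = multipletests(pvals, method="fdr_bh")[1]
        for g, q in zip(keys, padj):
            if q > alpha:
                labels[g] = 0
    empty = [m for m in set(labels) - {0} if (labels == m).sum() == 0]
    for m in empty:
        warnings.warn(f"module {m} lost all genes during pruning")
    kim = kim_matrix(labels, tom)
    return labels, kim


def modules_from_labels(
    labels: pd.Series, kim: pd.DataFrame, prefix: str = "M"
) -> list[GeneModule]:
    out = []
    for m in sorted(set(labels) - {0}):
        genes = sorted(labels.index[labels == m])
        if genes:
            out.append(GeneModule(f"{prefix}{m}", genes, kim[m]))
    return out


# -- filter cascade -----------------------------------------------------------


def weighted_pearson(x: pd.Series, y: pd.Series, w: pd.Series) -> float:
    """Pearson correlation with non-negative observation weights."""
    idx = x.index
    xv, yv, wv = x.to_numpy(), y.reindex(idx, fill_value=0).to_numpy(), w.reindex(idx, fill_value=0).to_numpy()
    if wv.sum() == 0:
        return 0.0
    wv = wv / wv.sum()
    mx, my = (wv * xv).sum(), (wv * yv).sum()
    cov = (wv * (xv - mx) * (yv - my)).sum()
    vx = (wv * (xv - mx) ** 2).sum()
    vy = (wv * (yv - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def _overlap_stage(
    modules: list[GeneModule], overlap_frac: float, overlap_cor: float
) -> None:
    """Flag modules mostly contained in a larger module with correlated kIM.

    The weights for the weighted Pearson are the union-membership indicator
    smoothed by kIM magnitude: w(g) = |kIM_M(g)| + |kIM_L(g)| for g in M ∪ L,
    0 elsewhere.
    """
    by_size = sorted(modules, key=lambda m: (-m.size, m.name))
    for i, small in enumerate(by_size):
        for large in by_size[:i]:
            if small.flags.get("overlap_removed") or large.flags.get("overlap_removed"):
                continue
            shared = set(small.genes) & set(large.genes)
            if len(shared) / small.size < overlap_frac:
                continue
            idx = small.kim.index.union(large.kim.index)
            a = small.kim.reindex(idx, fill_value=0.0)
            b = large.kim.reindex(idx, fill_value=0.0)
            w = pd.Series(0.0, index=idx)
            union = pd.Index(sorted(set(small.genes) | set(large.genes)))
            w[union] = a[union].abs() + b[union].abs()
            if weighted_pearson(a, b, w) >= overlap_cor:
                small.flags["overlap_removed"] = True
                break


def injury_signature_p(
    module: GeneModule, neglog_p: pd.Series, n_perm: int = 10_000, seed: int = 0
) -> float:
    """Permutation p of the kIM · (−log10 p) dot product over network genes."""
    common = module.kim.index.intersection(neglog_p.index)
    k = module.kim.reindex(common, fill_value=0.0).to_numpy()
    v = neglog_p.reindex(common).fillna(0.0).to_numpy()
    observed = float(k @ v)
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        ge += (rng.permutation(k) @ v) >= observed - 1e-12
    return (1.0 + ge) / (1.0 + n_perm)


def module_expression(module: GeneModule, expr: pd.DataFrame) -> pd.Series:
    """Weighted sum over member genes of per-gene standardized expression."""
    members = [g for g in module.genes if g in expr.columns]
    sub = expr[members].to_numpy(dtype=float)
    mu, sd = sub.mean(axis=0), sub.std(axis=0)
    z = (sub - mu) / np.where(sd > 0, sd, 1.0)
    w = module.weights.reindex(members).fillna(0.0).to_numpy()
    return pd.Series(z @ w, index=expr.index)


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    """R² of an OLS fit of y on a single regressor with intercept."""
    x = x.astype(float)
    if x.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2) if np.isfinite(r) else 0.0


def filter_modules(
    modules: list[GeneModule],
    injury_neglog_p: pd.Series,
    expr: pd.DataFrame,
    sample_ids: pd.Series,
    condition: pd.Series,
    overlap_frac: float = 0.75,
    overlap_cor: float = 0.75,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> list[GeneModule]:
    """Apply the fixed filter cascade and annotate flags on each module.

    Order: (i) overlap removal (smaller module dropped); (ii) injury/postmortem
    signature (permutation p < 0.05 of the kIM · −log10 p dot product);
    (iii) sample-vs-condition confounding (any single-sample-indicator model
    explaining more module-expression variance than the condition model);
    (iv) condition-coefficient significance (two-sided OLS, α = 0.05).
    """
    import statsmodels.api as sm

    _overlap_stage(modules, overlap_frac, overlap_cor)
    cond01 = (condition.reindex(expr.index) == "case").to_numpy().astype(float)
    samples = sample_ids.reindex(expr.index)
    for mi, module in enumerate(modules):
        if module.flags.get("overlap_removed"):
            continue
        p_inj = injury_signature_p(module, injury_neglog_p, n_perm, seed + mi)
        module.flags["injury_p"] = p_inj
        if p_inj < alpha:
            module.flags["injury_removed"] = True
            continue
        me = module_expression(module, expr).to_numpy()
        r2_cond = _r2(me, cond01)
        r2_sample = max(
            _r2(me, (samples == s).to_numpy()) for s in samples.unique()
        )
        module.flags["r2_condition"] = r2_cond
        module.flags["r2_sample_max"] = r2_sample
        if r2_sample > r2_cond:
            module.flags["sample_confounded"] = True
            continue
        X = sm.add_constant(cond01)
        fit = sm.OLS(me, X).fit()
        module.condition_coef = float(fit.params[1])
        ci = fit.conf_int()[1]
        module.condition_ci = (float(ci[0]), float(ci[1]))
        module.condition_p = float(fit.pvalues[1])
        module.flags["condition_significant"] = module.condition_p < alpha
    return [
        m
        for m in modules
        if m.flags.get("condition_significant")
        and not m.flags.get("overlap_removed")
        and not m.flags.get("injury_removed")
        and not m.flags.get("sample_confounded")
    ]


# -- VIF-corrected rank-sum enrichment ---------------------------------------


def vif_ranksum_enrichment(
    module: GeneModule, curated_list, expr: pd.DataFrame
) -> tuple[float, float]:
    """One-sided rank-sum test that curated genes sit near the top of the
    module's kIM ranking, with the variance inflated by
    VIF = 1 + (m − 1)·ρ̄, where ρ̄ is the mean pairwise expression correlation
    of the in-module curated genes (floored at 0)."""
    ranked = module.kim.dropna()
    curated = [g for g in curated_list if g in ranked.index]
    m = len(curated)
    if m < 2:
        raise ValidationError("need at least 2 curated genes among ranked genes")
    n = len(ranked)
    ranks = ranked.rank(method="average")  # highest kIM -> highest rank
    W = float(ranks[curated].sum())
    in_module = [g for g in curated if g in module.genes and g in expr.columns]
    if len(in_module) >= 2:
        sub = expr[in_module].to_numpy(dtype=float)
        cmat = np.corrcoef(sub, rowvar=False)
        iu = np.triu_indices(len(in_module), k=1)
        rho = float(np.nan_to_num(cmat[iu]).mean())
    else:
        rho = 0.0
    rho = max(rho, 0.0)
    vif = 1.0 + (m - 1) * rho
    mean_w = m * (n + 1) / 2.0
    var_w = vif * m * (n - m) * (n + 1) / 12.0
    z = (W - mean_w) / np.sqrt(var_w)
    p = float(stats.norm.sf(z))
    return float(z), p
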