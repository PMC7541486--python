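"""End-to-end orchestration: from an annotated cohort to the impact report.

This glues the stage modules together in analysis order: sample filtration →
total-count normalization → joint PCA similarity scoring → per-subtype
pseudobulk DE → gene-list enrichment → GO over-representation with the
autopsy filter and term clustering → composition permutation testing → the
six-metric weighted impact score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import composition as comp_mod
from . import diffexp, impact, pathways, similarity
from .core import AnnotatedCounts, ValidationError, total_count_normalize

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    n_pcs: int = 100
    min_cells: int = 5
    max_sparse_subtypes: int = 5
    scale: float = 10_000.0
    log1p: bool = False
    z_min: float = 3.0
    umi_min: int = 1
    cell_frac: float = 0.05
    go_alpha: float = 0.05
    n_perm: int = 1000
    subtype_level: str = "level4"
    weights: dict = field(default_factory=lambda: dict(impact.DEFAULT_WEIGHTS))


@dataclass
class PipelineResult:
    similarity: similarity.SimilarityResult
    similarity_cats: pd.Series
    de_genes: dict[str, pd.Index]
    de_results: dict[str, diffexp.DEResult]
    background: set
    gwas_enrichment: dict[str, diffexp.EnrichmentResult]
    epilepsy_enrichment: dict[str, diffexp.EnrichmentResult]
    terms: pathways.TermEnrichment
    pathway_clusters: pathways.PathwayCluster | None
    composition: comp_mod.CompositionTable
    de_residuals: diffexp.RegressionResiduals
    go_residuals: diffexp.RegressionResiduals
    impact: impact.ImpactScore

    def write_report(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = dict(sep="\t", float_format="%.6g")
        self.similarity.summary.to_csv(out / "similarity_summary.tsv", **fmt)
        self.similarity.pair_table.to_csv(out / "similarity_pairs.tsv", index=False, **fmt)
        for st, de in self.de_results.items():
            safe = st.replace("/", "_")
            de.table.to_csv(out / f"de_{safe}.tsv", **fmt)
        enr_rows = []
        for lst, res in (("gwas", self.gwas_enrichment), ("epilepsy", self.epilepsy_enrichment)):
            for st, r in res.items():
                enr_rows.append(
                    {"subtype": st, "list": lst, "odds_ratio": r.odds_ratio,
                     "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p}
                )
        pd.DataFrame(enr_rows).to_csv(out / "enrichment.tsv", index=False, **fmt)
        self.terms.table.to_csv(out / "go_terms.tsv", index=False, **fmt)
        if self.pathway_clusters is not None:
            self.pathway_clusters.membership.rename("cluster").to_csv(
                out / "go_clusters.tsv", **fmt
            )
        props = self.composition.proportions.copy()
        props.to_csv(out / "composition_proportions.tsv", **fmt)
        self.composition.pvalues.rename("p").to_csv(out / "composition_p.tsv", **fmt)
        self.impact.table.to_csv(out / "impact_report.tsv", **fmt)


def run_pipeline(
    data: AnnotatedCounts,
    gene_sets: dict[str, list[str]],
    curated_genes: list[str],
    gwas_genes: list[str],
    autopsy_genes: list[str],
    params: PipelineParams | None = None,
    seed: int = 0,
    cluster_pathways: bool = True,
) -> PipelineResult:
    params = params or PipelineParams()
    level = params.subtype_level

    # sample filtration
    from .core import filter_samples_by_coverage

    retained = filter_samples_by_coverage(
        data, params.min_cells, params.max_sparse_subtypes, level
    )
    if len(retained) < len(data.samples):
        logger.info("dropping samples: %s", sorted(set(data.samples) - set(retained)))
        data = data.subset_cells(data.obs["sample_id"].isin(retained).to_numpy())

    classes = data.class_of_subtype(level)

    # similarity
    norm = total_count_normalize(data, params.scale, params.log1p)
    scores = similarity.joint_pca(norm, params.n_pcs)
    centroids = similarity.subtype_sample_centroids(
        scores, data.obs, params.min_cells, level
    )
    sim = similarity.similarity_scores(centroids)

    # per-subtype DE
    de_results, de_genes = {}, {}
    for st in data.subtypes(level):
        try:
            de = diffexp.pseudobulk_de(data, st, level)
        except ValidationError as e:
            logger.info("DE skipped for %s: %s", st, e)
            continue
        de_results[st] = de
        de_genes[st] = diffexp.filter_de_genes(
            de, data, params.z_min, params.umi_min, params.cell_frac, level
        )
    background = set().union(*(set(d.expressed_genes) for d in de_results.values()))

    # list enrichment
    gwas_enr = {
        st: diffexp.gene_list_enrichment(set(g) & background, gwas_genes, background)
        for st, g in de_genes.items()
    }
    epi_enr = {
        st: diffexp.gene_list_enrichment(set(g) & background, curated_genes, background)
        for st, g in de_genes.items()
    }

    # GO over-representation + autopsy filter (+ optional clustering)
    terms = pathways.go_overrepresentation(
        {st: set(g) for st, g in de_genes.items()},
        gene_sets, background, params.go_alpha,
    )
    terms = pathways.autopsy_filter(terms, autopsy_genes)
    clusters = None
    if cluster_pathways and len(terms.table):
        clusters = pathways.collapse_terms_across_subtypes(terms)

    # composition
    comp = comp_mod.composition_test(data, params.n_perm, seed, level)

    # common subtype set with all six metrics
    scored = set(sim.summary.dropna(subset=["z_median"]).index)
    common = sorted(scored & set(de_genes))
    if len(common) < 2:
        raise ValidationError("fewer than two subtypes carry all six metrics")

    sim_common = similarity.SimilarityResult(
        sim.pair_table[sim.pair_table["subtype"].isin(common)],
        sim.summary.loc[common], sim.degenerate,
    )
    sim_cats = similarity.classify_similarity(sim_common, classes)

    comp_common = comp_mod.CompositionTable(
        comp.proportions, comp.counts,
        comp.pvalues[common], comp.observed[common],
    )
    comp_cats = comp_mod.categorize_composition(comp_common, classes)

    gwas_cats = impact.categorize_enrichment(
        {st: gwas_enr[st] for st in common}, classes
    )
    epi_cats = impact.categorize_enrichment(
        {st: epi_enr[st] for st in common}, classes
    )

    n_cells = pd.Series({st: de_results[st].n_cells for st in common})
    n_de = pd.Series({st: len(de_genes[st]) for st in common})
    if clusters is not None:
        counts = terms.table.groupby("subtype", observed=True)["term"].count()
        n_go = counts.reindex(common).fillna(0).astype(float)
    else:
        n_go = pd.Series(0.0, index=common)
    de_res = diffexp.residual_metric(n_cells.astype(float), n_de.astype(float))
    go_res = diffexp.residual_metric(n_de.astype(float), n_go)
    de_cats = impact.categorize_count_residual(de_res, classes)
    go_cats = impact.categorize_count_residual(go_res, classes)

    ranks = pd.DataFrame(
        {
            "similarity": sim_cats.reindex(common),
            "composition": comp_cats.reindex(common),
            "go_count": go_cats.reindex(common),
            "gwas_enrichment": gwas_cats.reindex(common),
            "epilepsy_enrichment": epi_cats.reindex(common),
            "de_count": de_cats.reindex(common),
        }
    )
    score = impact.aggregate_impact(ranks, classes, params.weights)

    return PipelineResult(
        similarity=sim,
        similarity_cats=sim_cats,
        de_genes=de_genes,
        de_results=de_results,
        background=background,
        gwas_enrichment=gwas_enr,
        epilepsy_enrichment=epi_enr,
        terms=terms,
        pathway_clusters=clusters,
        composition=comp,
        de_residuals=de_res,
        go_residuals=go_res,
        impact=score,
    )
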