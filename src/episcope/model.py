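"""Model-style facade over the end-to-end impact analysis.

`ImpactModel` is constructed from an annotated cohort plus the gene-set and
gene-list resources; `fit()` runs the full pipeline and returns an
`ImpactResults` carrying per-subtype estimates (similarity scores, DE counts,
enrichment odds ratios, composition p-values), the ordinal ranks and the
weighted totals, with a `summary()` table in the statsmodels spirit.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .core import AnnotatedCounts
from .pipeline import PipelineParams, PipelineResult, run_pipeline


class ImpactModel:
    """Subtype-resolved case/control impact model for an annotated cohort."""

    def __init__(
        self,
        data: AnnotatedCounts,
        gene_sets: dict[str, list[str]],
        curated_genes: list[str],
        gwas_genes: list[str],
        autopsy_genes: list[str] | None = None,
        params: PipelineParams | None = None,
    ):
        self.data = data
        self.gene_sets = gene_sets
        self.curated_genes = list(curated_genes)
        self.gwas_genes = list(gwas_genes)
        self.autopsy_genes = list(autopsy_genes or [])
        self.params = params or PipelineParams()

    @classmethod
    def from_directory(cls, cohort_dir: str | Path, gmt: str | Path,
                       curated: str | Path, gwas: str | Path,
                       autopsy: str | Path | None = None, **kwargs) -> "ImpactModel":
        from .core import load_cohort_dir, read_gene_list, read_gmt

        return cls(
            load_cohort_dir(cohort_dir),
            read_gmt(gmt),
            read_gene_list(curated),
            read_gene_list(gwas),
            read_gene_list(autopsy) if autopsy else [],
            **kwargs,
        )

    def fit(self, seed: int = 0, cluster_pathways: bool = True) -> "ImpactResults":
        result = run_pipeline(
            self.data, self.gene_sets, self.curated_genes, self.gwas_genes,
            self.autopsy_genes, self.params, seed, cluster_pathways,
        )
        return ImpactResults(self, result)


class ImpactResults:
    """Fitted impact analysis: estimates, ranks and the weighted score."""

    def __init__(self, model: ImpactModel, result: PipelineResult):
        self.model = model
        self.result = result
        self.impact = result.impact

    @property
    def ranks(self) -> pd.DataFrame:
        return self.impact.ranks

    @property
    def total(self) -> pd.Series:
        return self.impact.total

    def estimates(self) -> pd.DataFrame:
        """Continuous per-subtype estimates underlying the ordinal ranks."""
        r = self.result
        idx = self.impact.ranks.index
        return pd.DataFrame(
            {
                "z_median": r.similarity.summary["z_median"].reindex(idx),
                "composition_p": r.composition.pvalues.reindex(idx),
                "n_de_genes": pd.Series(
                    {st: len(g) for st, g in r.de_genes.items()}
                ).reindex(idx),
                "gwas_odds_ratio": pd.Series(
                    {st: e.odds_ratio for st, e in r.gwas_enrichment.items()}
                ).reindex(idx),
                "epilepsy_odds_ratio": pd.Series(
                    {st: e.odds_ratio for st, e in r.epilepsy_enrichment.items()}
                ).reindex(idx),
                "de_count_residual": r.de_residuals.residuals.reindex(idx),
                "go_count_residual": r.go_residuals.residuals.reindex(idx),
            }
        )

    def summary(self) -> str:
        score = self.impact
        lines = ["Subtype impact summary (weighted ordinal score)", "=" * 48]
        table = score.table.sort_values(["class", "total"], ascending=[True, False])
        lines.append(table.to_string(float_format=lambda v: f"{v:.2f}"))
        lines.append("")
        lines.append(
            "weights: " + ", ".join(f"{k}={v}" for k, v in score.weights.items())
        )
        return "\n".join(lines)

    def top_subtypes(self) -> pd.Series:
        """Highest-total subtype per class."""
        out = {}
        for cls in self.impact.classes.dropna().unique():
            members = self.impact.total[self.impact.classes == cls]
            out[cls] = members.sort_index().idxmax()
        return pd.Series(out)

    def plot_heatmap(self, path: str | Path | None = None):
        """Metric × subtype rank heatmap with metric-weight shading."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        score = self.impact
        order = score.total.sort_values(ascending=False).index
        mat = score.ranks.loc[order].T
        fig, ax = plt.subplots(figsize=(max(6, 0.4 * len(order)), 3.5))
        im = ax.imshow(mat.to_numpy(), cmap="Reds", vmin=0, vmax=3, aspect="auto")
        ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
        ax.set_yticks(range(len(mat.index)), mat.index, fontsize=8)
        fig.colorbar(im, label="rank (0–3)")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig
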