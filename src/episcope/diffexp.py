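"""Pseudobulk differential expression, gene-list enrichment and the
count-vs-covariate residual metric.

Per subtype, counts are summed to sample-level pseudobulk profiles and tested
gene-wise with a negative-binomial GLM (median-of-ratios size factors,
trended dispersion shrinkage, Wald test — the DESeq2 procedure, provided by
pydeseq2). DE genes are the Wald |Z| > 3 genes that are also expressed above
1 UMI in at least 5% of the subtype's cells. Enrichment of DE genes in flat
gene lists uses Fisher's exact test with the conditional-MLE odds ratio and
its exact confidence interval. The residual metric regresses a per-subtype
count (DE genes, enriched GO terms) on a covariate with a Huber M-estimator
and scores subtypes by their residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from scipy import stats

from .core import AnnotatedCounts, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-gene Wald statistics for one subtype's case vs control contrast."""

    subtype: str
    table: pd.DataFrame  # gene-indexed: log2fc, Z, p, padj, baseMean
    n_cells: int
    expressed_genes: pd.Index  # genes passing the expression filter in this subtype


def pseudobulk_counts(
    data: AnnotatedCounts, subtype: str, subtype_level: str = "level4"
) -> pd.DataFrame:
    """Sample × gene summed counts for one subtype."""
    mask = (data.obs[subtype_level] == subtype).to_numpy()
    if not mask.any():
        raise ValidationError(f"subtype {subtype!r} not present")
    X = sp.csr_matrix(data.X)[mask]
    samples = data.obs.loc[mask, "sample_id"]
    out = {}
    for s in sorted(samples.unique()):
        out[s] = np.asarray(X[(samples == s).to_numpy()].sum(axis=0)).ravel()
    return pd.DataFrame(out, index=data.genes).T


def expressed_gene_mask(
    data: AnnotatedCounts,
    subtype: str,
    umi_min: int = 1,
    cell_frac: float = 0.05,
    subtype_level: str = "level4",
) -> pd.Series:
    """Genes with raw count > umi_min in at least ``cell_frac`` of the
    subtype's cells."""
    mask = (data.obs[subtype_level] == subtype).to_numpy()
    X = sp.csr_matrix(data.X)[mask]
    frac = np.asarray((X > umi_min).sum(axis=0)).ravel() / X.shape[0]
    return pd.Series(frac >= cell_frac, index=data.genes)


def pseudobulk_de(
    data: AnnotatedCounts, subtype: str, subtype_level: str = "level4"
) -> DEResult:
    """Case vs control Wald test on the subtype's pseudobulk profiles."""
    pb = pseudobulk_counts(data, subtype, subtype_level)
    cond = data.condition_of_sample().reindex(pb.index)
    n_per = cond.value_counts()
    if n_per.get("control", 0) < 2 or n_per.get("case", 0) < 2:
        raise ValidationError(
            f"insufficient replication for {subtype!r}: "
            f"{n_per.to_dict()} samples per condition"
        )
    nonzero = pb.sum(axis=0) > 0
    pb_t = pb.loc[:, nonzero].astype(int)

    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    meta = pd.DataFrame({"condition": cond.astype(str)}, index=pb.index)
    logging.getLogger("pydeseq2").setLevel(logging.ERROR)
    dds = DeseqDataSet(counts=pb_t, metadata=meta, design="~condition", quiet=True)
    dds.deseq2()
    ds = DeseqStats(dds, contrast=["condition", "case", "control"], quiet=True)
    ds.summary()
    res = ds.results_df
    table = pd.DataFrame(
        {
            "log2fc": res["log2FoldChange"],
            "Z": res["stat"],
            "p": res["pvalue"],
            "padj": _bh(res["pvalue"].to_numpy()),
            "baseMean": res["baseMean"],
        },
        index=res.index,
    ).dropna(subset=["Z"])
    n_cells = int((data.obs[subtype_level] == subtype).sum())
    expressed = data.genes[expressed_gene_mask(data, subtype, subtype_level=subtype_level)]
    return DEResult(subtype, table, n_cells, expressed)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjustment, NaN-safe."""
    out = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests

        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def filter_de_genes(
    de: DEResult,
    data: AnnotatedCounts,
    z_min: float = 3.0,
    umi_min: int = 1,
    cell_frac: float = 0.05,
    subtype_level: str = "level4",
) -> pd.Index:
    """DE genes: |Z| strictly above ``z_min`` AND expressed (> umi_min UMI in
    at least ``cell_frac`` of the subtype's cells)."""
    strong = de.table.index[np.abs(de.table["Z"]) > z_min]
    expressed = expressed_gene_mask(data, de.subtype, umi_min, cell_frac, subtype_level)
    return pd.Index([g for g in strong if expressed.get(g, False)])


# -- gene-list enrichment -----------------------------------------------------


@dataclass
class EnrichmentResult:
    """Fisher 2×2 enrichment of a DE set in a gene list over a background."""

    table: np.ndarray  # [[DE∩list, DE∖list], [bg∩list, bg∖list]]
    odds_ratio: float  # conditional MLE
    ci_low: float
    ci_high: float
    p: float
    defined: bool = True


def gene_list_enrichment(
    de_genes, gene_list, background, alpha: float = 0.05
) -> EnrichmentResult:
    """Two-sided Fisher exact test with conditional-MLE odds ratio and exact CI."""
    de = set(de_genes)
    lst = set(gene_list)
    bg = set(background)
    if not de <= bg:
        raise ValidationError("de_genes must be a subset of the background")
    lst &= bg
    rest = bg - de
    a = len(de & lst)
    b = len(de - lst)
    c = len(rest & lst)
    d = len(rest - lst)
    table = np.array([[a, b], [c, d]])
    if len(lst) == 0:
        return EnrichmentResult(table, np.nan, np.nan, np.nan, np.nan, defined=False)
    res = stats.contingency.odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=1 - alpha)
    p = stats.fisher_exact(table, alternative="two-sided")[1]
    return EnrichmentResult(
        table, float(res.statistic), float(ci.low), float(ci.high), float(p)
    )


# -- residual metric ----------------------------------------------------------


@dataclass
class RegressionResiduals:
    slope: float
    intercept: float
    residuals: pd.Series  # per-subtype observed − fitted


def residual_metric(x: pd.Series, y: pd.Series) -> RegressionResiduals:
    """Huber robust regression (tuning constant 1.345) of y on x; residuals
    score how far each subtype sits above the trend."""
    x = pd.Series(x).astype(float)
    y = pd.Series(y).astype(float).reindex(x.index)
    if len(x) < 3:
        raise ValidationError("residual metric needs at least 3 subtypes")
    if x.nunique() == 1:
        raise ValidationError("constant covariate: regression undefined")
    X = sm.add_constant(x.to_numpy())
    fit = sm.RLM(y.to_numpy(), X, M=sm.robust.norms.HuberT(t=1.345)).fit(
        conv="coefs", tol=1e-8, maxiter=200
    )
    intercept, slope = fit.params
    resid = y - (slope * x + intercept)
    return RegressionResiduals(float(slope), float(intercept), resid)
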