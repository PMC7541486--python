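"""Six-metric integrative impact score.

Each per-subtype metric (expression similarity, composition change, enriched
GO-term count, GWAS-gene enrichment, curated epilepsy-gene enrichment, DE-gene
count) is reduced to an ordinal rank 0–3 (not affected / affected / highly
affected / top-1 in its class), and the ranks are combined as a weighted sum
with a-priori weights reflecting trust in each metric: similarity 1.0,
composition 0.66, GO count 0.66, GWAS 0.66, epilepsy genes 0.33, DE count 0.66.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError
from .diffexp import EnrichmentResult, RegressionResiduals

logger = logging.getLogger(__name__)

METRICS = (
    "similarity",
    "composition",
    "go_count",
    "gwas_enrichment",
    "epilepsy_enrichment",
    "de_count",
)

DEFAULT_WEIGHTS = {
    "similarity": 1.0,
    "composition": 0.66,
    "go_count": 0.66,
    "gwas_enrichment": 0.66,
    "epilepsy_enrichment": 0.33,
    "de_count": 0.66,
}


def categorize_enrichment(
    results: dict[str, EnrichmentResult], class_partition: pd.Series
) -> pd.Series:
    """0 if odds ratio h <= 1; 1 if h > 1; 2 if the CI lower bound > 1;
    3 for the largest h per class."""
    cats = pd.Series(0, index=sorted(results), dtype=int)
    h = pd.Series({k: r.odds_ratio for k, r in results.items()})
    for k, r in results.items():
        if not r.defined or np.isnan(r.odds_ratio):
            logger.warning("enrichment undefined for %s; rank 0", k)
            continue
        if r.odds_ratio > 1:
            cats[k] = 1
            if r.ci_low > 1:
                cats[k] = 2
    classes = class_partition.reindex(cats.index)
    for cls in classes.dropna().unique():
        members = cats.index[classes == cls]
        hvals = h[members].dropna()
        if len(hvals):
            cats[hvals.sort_index().idxmax()] = 3
    return cats


def categorize_count_residual(
    res: RegressionResiduals, class_partition: pd.Series
) -> pd.Series:
    """Positive residual = affected; above the 75th percentile (linear
    interpolation) of affected residuals = highly affected; class maximum =
    top-1 (name-order tie-break)."""
    r = res.residuals
    cats = pd.Series(0, index=r.index, dtype=int)
    classes = class_partition.reindex(r.index)
    for cls in classes.dropna().unique():
        members = r.index[classes == cls]
        affected = members[r[members] > 0]
        cats[affected] = 1
        if len(affected):
            q75 = np.percentile(r[affected], 75)
            cats[affected[r[affected] > q75]] = 2
        top1 = r[members].sort_index().idxmax()
        cats[top1] = 3
    return cats


@dataclass
class ImpactScore:
    """Per-subtype ordinal ranks, weighted total and class rank."""

    ranks: pd.DataFrame  # subtype × metric, values 0–3
    weights: dict[str, float]
    total: pd.Series
    class_rank: pd.Series  # 1 = highest total within its class
    classes: pd.Series

    @property
    def table(self) -> pd.DataFrame:
        out = self.ranks.copy()
        out["total"] = self.total
        out["class"] = self.classes
        out["class_rank"] = self.class_rank
        return out


def aggregate_impact(
    ranks: pd.DataFrame,
    class_partition: pd.Series,
    weights: dict[str, float] | None = None,
) -> ImpactScore:
    """Weighted sum of the six ordinal ranks; subtypes ordered within class."""
    weights = dict(weights or DEFAULT_WEIGHTS)
    missing_cols = [m for m in METRICS if m not in ranks.columns]
    if missing_cols:
        raise ValidationError(f"missing metrics: {missing_cols}")
    if ranks[list(METRICS)].isna().any().any():
        gaps = ranks[list(METRICS)].isna().any(axis=1)
        raise ValidationError(
            f"missing metric ranks for subtypes: {list(ranks.index[gaps])}"
        )
    bad = ~ranks[list(METRICS)].isin([0, 1, 2, 3]).all(axis=1)
    if bad.any():
        raise ValidationError(f"ranks must be in 0..3; offending: {list(ranks.index[bad])}")
    total = sum(weights[m] * ranks[m] for m in METRICS)
    classes = class_partition.reindex(ranks.index)
    class_rank = pd.Series(index=ranks.index, dtype=int)
    for cls in classes.dropna().unique():
        members = ranks.index[classes == cls]
        # ties broken deterministically by subtype name
        order = sorted(members, key=lambda s: (-total[s], s))
        for i, s in enumerate(order):
            class_rank[s] = i + 1
    return ImpactScore(ranks[list(METRICS)], weights, total, class_rank, classes)
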