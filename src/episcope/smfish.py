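"""Intensity normalization and group comparison for smFISH quantification.

Raw integrated densities of a target channel (e.g. CNR1) and a reference
channel (e.g. VIP) are log2-transformed; the reference is quantile-normalized
across sections to absorb section-to-section staining variability; and the
target is corrected by the reference's normalization shift:

    target_normalized = target * (reference_normalized / reference)

applied on the log2 scale (an additive correction). Group differences are
tested one-sided with Welch's t (Satterthwaite df) or Mann–Whitney (exact for
n <= 20 without ties, tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "cell_id", "section_id", "group",
    "target_raw_intensity", "reference_raw_intensity",
)


def quantile_normalize_by_section(
    values: pd.Series, sections: pd.Series
) -> pd.Series:
    """Quantile-normalize values across sections of (possibly) unequal size.

    The target distribution is the mean of the sections' empirical quantile
    functions; a value of within-section rank r (out of n) maps to the mean
    across sections of the (r−1)/(n−1) quantile. For equal-sized sections this
    is the standard mean-of-sorted-columns convention; unequal sections are
    handled by linear interpolation of each section's quantile function.
    """
    section_values = {
        sec: np.sort(values[sections == sec].to_numpy())
        for sec in sorted(sections.unique())
    }
    out = pd.Series(index=values.index, dtype=float)
    for sec, sel in ((s, sections == s) for s in section_values):
        v = values[sel]
        n = len(v)
        q = (v.rank(method="average").to_numpy() - 1.0) / max(n - 1, 1)
        ref = np.mean([np.quantile(sv, q) for sv in section_values.values()], axis=0)
        out[sel] = ref
    return out


def normalize_target(table: pd.DataFrame) -> pd.DataFrame:
    """Log2-transform, quantile-normalize the reference channel across
    sections, and apply the reference correction to the target channel."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    if table["group"].nunique() < 2:
        raise ValidationError("need at least two groups")
    zero = table["reference_raw_intensity"] <= 0
    if zero.any():
        logger.warning(
            "excluding %d cells with non-positive reference intensity", int(zero.sum())
        )
        table = table[~zero]
    out = table.copy()
    out["target_log2"] = np.log2(out["target_raw_intensity"])
    out["reference_log2"] = np.log2(out["reference_raw_intensity"])
    out["reference_normalized_log2"] = quantile_normalize_by_section(
        out["reference_log2"], out["section_id"]
    )
    # target * (reference_normalized / reference), additive on the log2 scale
    out["target_normalized_log2"] = (
        out["target_log2"] + out["reference_normalized_log2"] - out["reference_log2"]
    )
    out["target_normalized"] = np.exp2(out["target_normalized_log2"])
    out["reference_normalized"] = np.exp2(out["reference_normalized_log2"])
    return out


def compare_groups(
    values: pd.Series,
    group: pd.Series,
    test: str = "welch_one_sided",
    direction: str = "greater",
) -> float:
    """One-sided p-value that the case group is shifted in ``direction``
    relative to control."""
    if direction not in ("greater", "less"):
        raise ValidationError("direction must be 'greater' or 'less'")
    case = values[group == "case"].to_numpy(dtype=float)
    ctrl = values[group == "control"].to_numpy(dtype=float)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValidationError("need at least two values per group")
    pooled = np.concatenate([case, ctrl])
    if np.ptp(pooled) == 0:
        logger.warning("constant values; no evidence either way")
        return 1.0
    if test == "welch_one_sided":
        return float(
            stats.ttest_ind(case, ctrl, equal_var=False, alternative=direction)[1]
        )
    if test == "mann_whitney_one_sided":
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(len(case), len(ctrl)) <= 20 and not has_ties) else "asymptotic"
        return float(
            stats.mannwhitneyu(case, ctrl, alternative=direction, method=method)[1]
        )
    raise ValidationError(f"unknown test {test!r}")
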