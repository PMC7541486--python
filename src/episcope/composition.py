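"""Cell-type composition change between conditions by sample-label permutation.

The statistic per subtype is the absolute difference in the condition means of
within-sample proportions; the null permutes condition labels over samples
(the exchangeable unit), and the p-value uses the add-one estimator so it is
never 0. P-values are read as a continuous measure of compositional change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AnnotatedCounts, ValidationError


@dataclass
class CompositionTable:
    proportions: pd.DataFrame  # sample × subtype within-sample proportions
    counts: pd.DataFrame  # sample × subtype cell counts
    pvalues: pd.Series  # per-subtype permutation p
    observed: pd.Series  # per-subtype observed statistic


def _statistic(props: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    return np.abs(
        props[is_case].mean(axis=0) - props[~is_case].mean(axis=0)
    )


def composition_test(
    data: AnnotatedCounts,
    n_perm: int = 10_000,
    seed: int = 0,
    subtype_level: str = "level4",
    exhaustive: bool = False,
) -> CompositionTable:
    """Permutation test of per-subtype composition difference across conditions.

    With ``exhaustive=True`` all label assignments are enumerated instead of
    sampled (feasible for small cohorts); the add-one estimator is used either
    way, counting the identity permutation once.
    """
    counts = (
        data.obs.groupby(["sample_id", subtype_level], observed=False)
        .size()
        .unstack(fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    cond = data.condition_of_sample().reindex(props.index)
    is_case = (cond == "case").to_numpy()
    n_case = int(is_case.sum())
    if n_case < 2 or (~is_case).sum() < 2:
        raise ValidationError("need at least two samples per condition")
    P = props.to_numpy()
    observed = _statistic(P, is_case)
    n = len(cond)
    if exhaustive:
        from itertools import combinations

        ge = np.zeros(P.shape[1])
        total = 0
        for case_idx in combinations(range(n), n_case):
            perm = np.zeros(n, dtype=bool)
            perm[list(case_idx)] = True
            ge += _statistic(P, perm) >= observed - 1e-12
            total += 1
        pvals = ge / total
    else:
        rng = np.random.default_rng(seed)
        ge = np.zeros(P.shape[1])
        for _ in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=n_case, replace=False)] = True
            ge += _statistic(P, perm) >= observed - 1e-12
        pvals = (1.0 + ge) / (1.0 + n_perm)
    return CompositionTable(
        props, counts, pd.Series(pvals, index=props.columns),
        pd.Series(observed, index=props.columns),
    )


def categorize_composition(
    table: CompositionTable, class_partition: pd.Series
) -> pd.Series:
    """Ordinal impact category: 1 if p < 0.2, 2 if p < 0.05, 3 for the smallest
    p per class (name-order tie-break)."""
    p = table.pvalues
    cats = pd.Series(0, index=p.index, dtype=int)
    cats[p < 0.2] = 1
    cats[p < 0.05] = 2
    classes = class_partition.reindex(p.index)
    for cls in classes.dropna().unique():
        members = p.index[classes == cls]
        top1 = p[members].sort_index().idxmin()
        cats[top1] = 3
    return cats
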