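"""Expression-similarity score across conditions.

For each subtype t and sample s a centroid v̄(t, s) is the mean of the
sample's cells in a joint 100-component PCA space. All pairwise Pearson
correlations c(t, si, sj) between sample centroids are computed; the
control–control correlations define a robust baseline via the 40% trimmed
mean m(t) and the (normal-consistent) median absolute deviation σ(t); every
(control, case) pair is then scored as z = (c − m) / σ. A score near 0 means
the subtype's case transcriptome sits inside the control-to-control
variation; negative scores mean condition-driven divergence.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .core import AnnotatedCounts, NormalizedMatrix, ValidationError

logger = logging.getLogger(__name__)


def joint_pca(
    norm: NormalizedMatrix, n_components: int = 100, scale_genes: bool = False
) -> pd.DataFrame:
    """Gene-centered PCA of the joint (both conditions) normalized matrix.

    Component signs are fixed by convention: the largest-magnitude loading of
    each component is made positive, so results are deterministic.
    """
    X = np.asarray(norm.matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("need at least two cells for PCA")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    if k < n_components:
        warnings.warn(
            f"reducing n_components from {n_components} to {k} (matrix rank limit)"
        )
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValidationError("degenerate input: all cells identical")
    if scale_genes:
        sd = Xc.std(axis=0)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=k, svd_solver="full" if min(X.shape) < 500 else "randomized",
              random_state=0)
    scores = pca.fit_transform(Xc)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(k):
        comp = pca.components_[j]
        if comp[np.argmax(np.abs(comp))] < 0:
            scores[:, j] *= -1
    return pd.DataFrame(
        scores, index=norm.cells, columns=[f"PC{j + 1}" for j in range(k)]
    )


@dataclass
class CentroidSet:
    """Per (subtype, sample) mean PC scores."""

    centroids: dict[tuple[str, str], np.ndarray]
    sample_condition: pd.Series  # sample_id -> condition
    n_components: int

    def samples_for(self, subtype: str, condition: str) -> list[str]:
        return sorted(
            s
            for (t, s) in self.centroids
            if t == subtype and self.sample_condition[s] == condition
        )

    @property
    def subtypes(self) -> list[str]:
        return sorted({t for (t, _) in self.centroids})


def subtype_sample_centroids(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    min_cells: int = 5,
    subtype_level: str = "level4",
) -> CentroidSet:
    """Arithmetic-mean centroid per (subtype, sample); small groups omitted."""
    meta = metadata.loc[scores.index]
    centroids: dict[tuple[str, str], np.ndarray] = {}
    grouped = scores.groupby(
        [meta[subtype_level], meta["sample_id"]], observed=True
    )
    for (subtype, sample), block in grouped:
        if len(block) < min_cells:
            logger.info("omitting (%s, %s): %d cells < %d", subtype, sample, len(block), min_cells)
            continue
        centroids[(str(subtype), str(sample))] = block.to_numpy().mean(axis=0)
    cond = meta.groupby("sample_id", observed=True)["condition"].first()
    return CentroidSet(centroids, cond, scores.shape[1])


def trimmed_mean(values: np.ndarray, trim: float = 0.4) -> float:
    """Trimmed mean removing ``trim`` fraction from each tail; median fallback
    when fewer than one value would remain."""
    values = np.asarray(values, dtype=float)
    if len(values) - 2 * int(len(values) * trim) < 1:
        return float(np.median(values))
    return float(stats.trim_mean(values, trim))


def mad(values: np.ndarray, scale: float = 1.4826) -> float:
    """Median absolute deviation, scaled for consistency with the normal."""
    values = np.asarray(values, dtype=float)
    return float(np.median(np.abs(values - np.median(values))) * scale)


@dataclass
class SimilarityResult:
    """Per-subtype cross-condition centroid-correlation scores."""

    pair_table: pd.DataFrame  # subtype, control_sample, case_sample, c, z
    summary: pd.DataFrame  # subtype-indexed: n_pairs, m, sigma, z_median, quartiles
    degenerate: list[str] = field(default_factory=list)


def similarity_scores(
    centroids: CentroidSet,
    trim: float = 0.4,
    mad_scale: float = 1.4826,
    min_control_samples: int = 3,
) -> SimilarityResult:
    """Compute c, m, σ and z for every subtype with sufficient coverage."""
    pair_rows, summary_rows, degenerate = [], [], []
    for t in centroids.subtypes:
        ctrl = centroids.samples_for(t, "control")
        case = centroids.samples_for(t, "case")
        if len(ctrl) < min_control_samples or len(case) < 1:
            logger.info("subtype %s skipped: %d control / %d case samples", t, len(ctrl), len(case))
            continue
        cc = np.array(
            [
                stats.pearsonr(centroids.centroids[(t, a)], centroids.centroids[(t, b)])[0]
                for a, b in itertools.combinations(ctrl, 2)
            ]
        )
        m_t = trimmed_mean(cc, trim)
        sigma_t = mad(cc, mad_scale)
        if sigma_t == 0:
            degenerate.append(t)
            summary_rows.append(
                {"subtype": t, "n_pairs": 0, "m": m_t, "sigma": 0.0,
                 "z_median": np.nan, "z_q25": np.nan, "z_q75": np.nan}
            )
            continue
        zs = []
        for a in ctrl:
            for b in case:
                c = stats.pearsonr(
                    centroids.centroids[(t, a)], centroids.centroids[(t, b)]
                )[0]
                z = (c - m_t) / sigma_t
                zs.append(z)
                pair_rows.append(
                    {"subtype": t, "control_sample": a, "case_sample": b, "c": c, "z": z}
                )
        zs = np.array(zs)
        summary_rows.append(
            {
                "subtype": t,
                "n_pairs": len(zs),
                "m": m_t,
                "sigma": sigma_t,
                "z_median": float(np.median(zs)),
                "z_q25": float(np.percentile(zs, 25)),
                "z_q75": float(np.percentile(zs, 75)),
            }
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=["subtype", "n_pairs", "m", "sigma", "z_median", "z_q25", "z_q75"],
    ).set_index("subtype")
    pairs = pd.DataFrame(
        pair_rows, columns=["subtype", "control_sample", "case_sample", "c", "z"]
    )
    return SimilarityResult(pairs, summary, degenerate)


def classify_similarity(
    result: SimilarityResult, class_partition: pd.Series
) -> pd.Series:
    """Ordinal impact category from the score distribution.

    0 = not affected; 1 = affected (upper quartile of z < 0); 2 = highly
    affected (affected and median below the class's median-of-medians);
    3 = lowest median in the class (exactly one per class).
    """
    summary = result.summary.dropna(subset=["z_median"])
    if summary.empty:
        raise ValidationError("no subtype has a defined similarity score")
    cats = pd.Series(0, index=summary.index, dtype=int)
    cats[summary["z_q75"] < 0] = 1
    classes = class_partition.reindex(summary.index)
    for cls in classes.dropna().unique():
        members = summary.index[classes == cls]
        if len(members) < 2:
            warnings.warn(f"class {cls!r} has fewer than two scored subtypes")
        med_of_med = summary.loc[members, "z_median"].median()
        highly = members[
            (cats[members] >= 1) & (summary.loc[members, "z_median"] < med_of_med)
        ]
        cats[highly] = 2
        top1 = summary.loc[members, "z_median"].sort_index().idxmin()
        cats[top1] = 3
    return cats
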