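"""Two-color array normalization and cohort quality control.

Within-array normalization removes the intensity-dependent bias of the
log-ratio M = log2(Cy5/Cy3) by subtracting a smooth fit of M on the mean
log-intensity A (the role a loess curve plays in classical MA-plot
normalization); between-array normalization aligns the A distributions
across arrays by quantile substitution (each array's sorted A replaced by
the across-array mean of sorted A, ties resolved by average ranks).
Cohort QC covers PCA-based sample outlier flagging, per-gene one-way
ANOVA filtering, and deterministic hierarchical clustering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "TwoColorArray",
    "QCReport",
    "normalize_within_array",
    "aquantile_normalize_between",
    "flag_outliers_pca",
    "anova_filter",
    "hierarchical_cluster",
]

_MIN_PROBES = 50


@dataclass
class TwoColorArray:
    """Per-probe M (log2 ratio) and A (mean log2 intensity) of one array."""

    probe_ids: np.ndarray
    m: np.ndarray
    a: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids)
        self.m = np.asarray(self.m, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if not (len(self.probe_ids) == len(self.m) == len(self.a)):
            raise ValueError("probe_ids, M and A must have equal length")
        for name, arr in (("M", self.m), ("A", self.a)):
            if np.isinf(arr[~np.isnan(arr)]).any():
                raise ValueError(f"{name} contains non-finite values")


@dataclass
class QCReport:
    pca_coordinates: pd.DataFrame  # samples x (PC1, PC2)
    flagged_outliers: tuple[str, ...]
    threshold_sd: float
    explained_variance_ratio: tuple[float, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "flagged_outliers": list(self.flagged_outliers),
            "threshold_sd": self.threshold_sd,
            "explained_variance_ratio": list(self.explained_variance_ratio),
            "pca_coordinates": {
                s: [float(x) for x in row] for s, row in self.pca_coordinates.iterrows()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _trend_basis(a: np.ndarray, span: float) -> np.ndarray:
    """Natural cubic spline design matrix with knots at A-quantiles.

    ``span`` maps to the fit's flexibility the way a loess fraction
    would: degrees of freedom ~ 2/span (+2), so the default 0.3 gives a
    9-df smooth curve.  Natural (linear-tail) splines keep the variance
    of the fit bounded at the intensity extremes.
    """
    df = max(4, int(round(2.0 / span)) + 2)
    scale = np.std(a)
    x = (a - np.mean(a)) / scale  # condition the truncated-power basis
    knots = np.unique(np.quantile(x, np.linspace(0.01, 0.99, df)))
    if len(knots) < 3:
        return np.column_stack([np.ones_like(x), x])
    k_last, k_prev = knots[-1], knots[-2]

    def d(j):
        return (np.clip(x - knots[j], 0, None) ** 3 - np.clip(x - k_last, 0, None) ** 3) / (
            k_last - knots[j]
        )

    d_ref = d(len(knots) - 2)
    cols = [np.ones_like(x), x] + [d(j) - d_ref for j in range(len(knots) - 2)]
    return np.column_stack(cols)


def normalize_within_array(array: TwoColorArray, span: float = 0.3) -> TwoColorArray:
    """Remove the intensity-dependent trend of M within one array.

    M' = M - f(A), where f is a smooth least-squares fit of M on A — the
    trend-removal role a loess curve plays in classical MA-plot
    normalization, here realised as a cubic regression spline with knots
    at A-quantiles.  Because the fit is a linear projection, the
    operation is idempotent: normalizing an already-normalized array
    changes nothing beyond floating-point residue.  A is returned
    unchanged.  Constant A (no intensity spread) falls back to
    median-centering M with a warning.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    finite = ~(np.isnan(array.m) | np.isnan(array.a))
    if finite.sum() < _MIN_PROBES:
        raise ValueError(
            f"need >= {_MIN_PROBES} probes with finite M and A, got {int(finite.sum())}"
        )
    a = array.a[finite]
    m = array.m[finite]
    if np.ptp(a) == 0.0:
        logger.warning("constant A: falling back to global median-centering of M")
        m_new = np.array(array.m, copy=True)
        m_new[finite] = m - np.median(m)
        return TwoColorArray(array.probe_ids, m_new, array.a)
    x = _trend_basis(a, span)
    beta, *_ = np.linalg.lstsq(x, m, rcond=None)
    m_new = np.array(array.m, copy=True)
    m_new[finite] = m - x @ beta
    return TwoColorArray(array.probe_ids, m_new, array.a)


def aquantile_normalize_between(arrays: list[TwoColorArray]) -> list[TwoColorArray]:
    """Quantile-normalize A across arrays; M untouched.

    Each array's sorted A is replaced by the across-array mean of sorted
    A; tied values receive the average of the reference values at their
    tied ranks.  All arrays must share one probe universe.
    """
    if len(arrays) < 2:
        raise ValueError("need at least 2 arrays")
    base = set(arrays[0].probe_ids.tolist())
    for arr in arrays[1:]:
        other = set(arr.probe_ids.tolist())
        if other != base:
            missing = sorted(base.symmetric_difference(other))
            raise ValueError(f"probe universes differ; mismatched probes e.g. {missing[:10]}")
    # align every array to the first array's probe order
    order0 = arrays[0].probe_ids
    aligned = []
    for arr in arrays:
        pos = {p: i for i, p in enumerate(arr.probe_ids.tolist())}
        take = np.array([pos[p] for p in order0.tolist()])
        aligned.append((arr, take))
    a_mat = np.column_stack([arr.a[take] for arr, take in aligned])
    if np.isnan(a_mat).any():
        raise ValueError("A must be complete for quantile normalization")
    reference = np.sort(a_mat, axis=0).mean(axis=1)
    out = []
    n = a_mat.shape[0]
    for col, (arr, take) in enumerate(aligned):
        a_col = a_mat[:, col]
        # average-tie ranks -> interpolate into the reference quantiles
        ranks = stats.rankdata(a_col, method="average")  # 1..n, ties averaged
        new_a_aligned = np.interp(ranks, np.arange(1, n + 1), reference)
        inv = np.empty_like(take)
        inv[take] = np.arange(n)
        new_a = new_a_aligned[inv]
        out.append(TwoColorArray(arr.probe_ids, arr.m.copy(), new_a))
    return out


def flag_outliers_pca(matrix: ExpressionMatrix, threshold_sd: float = 4.0) -> QCReport:
    """Flag samples far from the cohort centroid in (PC1, PC2).

    Genes are centered and unit-scaled (zero-variance genes dropped with
    a warning; missing values mean-imputed for the PCA only), samples are
    projected onto the first two principal components, and a sample is
    flagged when its robust distance — per-PC deviation from the median
    scaled by 1.4826*MAD — exceeds ``threshold_sd``.  Flagging is a
    report; removal is a separate, logged action by the caller.
    """
    if matrix.shape[1] < 4:
        raise ValueError(f"need >= 4 samples for PCA QC, got {matrix.shape[1]}")
    x = matrix.values.to_numpy().T.copy()  # samples x genes
    col_mean = np.nanmean(x, axis=0)
    nan_mask = np.isnan(x)
    if nan_mask.any():
        x[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("flag_outliers_pca: dropped %d zero-variance genes", int((~keep).sum()))
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / x[:, keep].std(axis=0, ddof=1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :2] * s[:2]
    evr = (s[:2] ** 2) / np.sum(s**2)
    coords = pd.DataFrame(scores, index=matrix.sample_ids, columns=["PC1", "PC2"])

    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0)
    robust_sd = 1.4826 * mad
    robust_sd = np.where(robust_sd > 0, robust_sd, scores.std(axis=0, ddof=1))
    dist = np.sqrt(np.sum(((scores - med) / robust_sd) ** 2, axis=1))
    flagged = tuple(matrix.sample_ids[dist > threshold_sd])
    if flagged:
        logger.info("flag_outliers_pca: flagged %s at threshold %g", flagged, threshold_sd)
    return QCReport(coords, flagged, float(threshold_sd), (float(evr[0]), float(evr[1])))


def anova_filter(
    matrix: ExpressionMatrix, groups: pd.Series, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Classical one-way fixed-effects ANOVA per gene; keep p < alpha.

    ``groups`` maps sample_id -> group label (>= 2 groups, each with >= 2
    samples).  Genes constant across all samples have an undefined F and
    are excluded with a warning.  Returns (pass list, per-gene table).
    """
    groups = groups.dropna()
    common = matrix.sample_ids.intersection(groups.index)
    groups = groups.loc[common]
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    counts = groups.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"groups with < 2 samples: {small.index.tolist()}")
    x = matrix.values.loc[:, common].to_numpy()
    n = x.shape[1]
    grand = x.mean(axis=1, keepdims=True)
    ss_total = np.sum((x - grand) ** 2, axis=1)
    ss_between = np.zeros(x.shape[0])
    for lab in labels:
        cols = (groups == lab).to_numpy()
        ni = int(cols.sum())
        ss_between += ni * (x[:, cols].mean(axis=1) - grand[:, 0]) ** 2
    ss_within = ss_total - ss_between
    df_between = len(labels) - 1
    df_within = n - len(labels)
    constant = ss_total <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    p = stats.f.sf(f, df_between, df_within)
    p = np.where(np.isnan(f) & ~constant, 0.0, p)  # within-group constant, between differ
    if constant.any():
        logger.warning("anova_filter: %d constant genes excluded", int(constant.sum()))
    table = pd.DataFrame(
        {"gene_id": matrix.feature_ids, "F": f, "p": p, "constant": constant}
    )
    passes = table.loc[(~table["constant"]) & (table["p"] < alpha), "gene_id"].tolist()
    return passes, table


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    gene_subset: list[str],
    linkage_rule: str = "average",
    distance_rule: str = "euclidean",
) -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering of samples on a gene subset.

    Samples are processed in lexical sample-id order so the tree (and its
    tie-breaking) is invariant to the input column order.  Returns the
    scipy linkage matrix plus the leaf order (sample ids).
    """
    if not gene_subset:
        raise ValueError("empty gene subset")
    sub = matrix.values.loc[list(gene_subset)]
    sub = sub.loc[:, sorted(sub.columns)]
    x = sub.to_numpy().T  # samples x genes
    if distance_rule == "correlation":
        d = pdist(x, metric="correlation")
    elif distance_rule == "euclidean":
        d = pdist(x, metric="euclidean")
    else:
        raise ValueError(f"unknown distance_rule {distance_rule!r}")
    link = hierarchy.linkage(d, method=linkage_rule)
    leaves = hierarchy.leaves_list(link)
    return link, [sub.columns[i] for i in leaves]
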