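"""Cross-dataset case/control meta-analysis (eGWAS-style weighted Z).

Each platform contributes a per-probe signed Z: a Welch t-test of case vs
control is converted to an upper one-tailed p, p+ = P(T > t), and then to
z = Phi^-1(1 - p+), so case > control yields z > 0 and case < control
z < 0 with no separate sign step.  Probe-level z is collapsed to one z
per gene (best-probe |z| by default), and gene z-scores are combined over
the datasets observing the gene by the weighted Z-method

    Z_meta = sum_i w_i z_i / sqrt(sum_i w_i^2),   w_i = sqrt(n_i),

which is N(0,1) under the joint null.  Genes with |Z_meta| above a
threshold (5 by convention here) are called significantly up- or
down-regulated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CaseControlDataset, ProbeGeneMap

logger = logging.getLogger(__name__)

__all__ = [
    "dataset_zscores",
    "collapse_probes",
    "weighted_z_combine",
    "egwas_screen",
    "manhattan_table",
]

_MIN_PER_GROUP = 2


def _nan_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = np.sum(~np.isnan(x), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # short slices yield NaN, handled below
        m = np.nanmean(x, axis=1)
        v = np.nanvar(x, axis=1, ddof=1)
    return n, m, v


def _welch(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t statistic and Satterthwaite df (NaN-aware)."""
    n1, m1, v1 = _nan_moments(case)
    n2, m2, v2 = _nan_moments(control)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def _pooled(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pooled-variance (Student) t statistic and df."""
    n1, m1, v1 = _nan_moments(case)
    n2, m2, v2 = _nan_moments(control)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, df.astype(float)


def dataset_zscores(dataset: CaseControlDataset, t_variant: str = "welch") -> pd.Series:
    """Per-probe signed z from a one-tailed case-vs-control t-test.

    Probes with fewer than 2 finite values in either group come back NaN
    (logged); probes with zero variance in both groups and equal means get
    z = 0 (degenerate).
    """
    if t_variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t_variant {t_variant!r}")
    groups = dataset.annotation.groups()
    case_ids = groups.index[groups == "case"]
    control_ids = groups.index[groups == "control"]
    case = dataset.matrix.values.loc[:, case_ids].to_numpy()
    control = dataset.matrix.values.loc[:, control_ids].to_numpy()

    n_case = np.sum(~np.isnan(case), axis=1)
    n_control = np.sum(~np.isnan(control), axis=1)
    testable = (n_case >= _MIN_PER_GROUP) & (n_control >= _MIN_PER_GROUP)
    if (~testable).any():
        logger.info(
            "%s: %d probes below min %d finite values per group -> NA",
            dataset.dataset_id,
            int((~testable).sum()),
            _MIN_PER_GROUP,
        )

    t, df = (_welch if t_variant == "welch" else _pooled)(case, control)
    degenerate = ~np.isfinite(t)  # 0/0: no variance and equal means
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate | ~np.isfinite(df), 1.0, df)
    p_upper = stats.t.sf(t, df)
    # Phi^-1(1 - p+) with tail-safe branching: isf keeps precision for tiny p
    z = np.where(p_upper <= 0.5, stats.norm.isf(p_upper), stats.norm.ppf(1.0 - p_upper))
    z = np.where(degenerate, 0.0, z)
    z = np.where(testable, z, np.nan)
    return pd.Series(z, index=dataset.matrix.feature_ids, name=dataset.dataset_id)


def collapse_probes(probe_z: pd.Series, probe_map: ProbeGeneMap, rule: str = "max_abs_z") -> pd.Series:
    """Collapse per-probe z to per-gene z.

    ``max_abs_z`` keeps the probe with the largest |z| (ties broken by the
    lexically smallest probe id); ``median_z`` takes the per-gene median.
    Unmapped probes are dropped with a logged count.
    """
    if rule not in ("max_abs_z", "median_z"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    if len(probe_map) == 0:
        raise ValueError("empty probe->gene map")
    z = probe_z.dropna()
    mapped = z.index.intersection(probe_map.probes)
    n_unmapped = len(z) - len(mapped)
    if n_unmapped:
        logger.info("collapse_probes: %d unmapped probes dropped", n_unmapped)
    if len(mapped) == 0:
        return pd.Series(dtype=float)
    frame = pd.DataFrame(
        {"z": z.loc[mapped], "gene": probe_map.mapping.loc[mapped]}, index=mapped
    )
    if rule == "median_z":
        return frame.groupby("gene")["z"].median()
    frame = frame.assign(abs_z=frame["z"].abs()).sort_index()  # lexical probe order for ties
    idx = frame.groupby("gene")["abs_z"].idxmax()  # idxmax keeps first (lexically smallest) on ties
    out = frame.loc[idx.to_numpy(), "z"]
    out.index = idx.index
    return out.sort_index()


def weighted_z_combine(z_scores, weights) -> float:
    """Weighted Z-method: Z = sum(w_i z_i) / sqrt(sum w_i^2)."""
    z = np.asarray(z_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if z.size == 0:
        raise ValueError("no z-scores to combine")
    if z.shape != w.shape:
        raise ValueError("z-scores and weights must be equal length")
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return float(np.sum(w * z) / np.sqrt(np.sum(w**2)))


def egwas_screen(
    datasets: list[CaseControlDataset],
    z_threshold: float = 5.0,
    weight_scheme: str = "sqrt_n",
    collapse_rule: str = "max_abs_z",
    t_variant: str = "welch",
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Run the full meta-analysis over a dataset collection.

    Per dataset: one-tailed Welch t -> signed z -> probe collapse; then
    per gene, combine z over the datasets observing it with weights
    sqrt(total dataset size) and flag |Z_meta| > ``z_threshold``.

    Returns (up gene list, down gene list, MetaResult table).  The table
    reports per-dataset z columns, Z_meta, the one-sided p of |Z_meta|,
    the number of datasets observing each gene, and the direction.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    if weight_scheme not in ("sqrt_n", "equal"):
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    gene_z: dict[str, pd.Series] = {}
    weights: dict[str, float] = {}
    for ds in datasets:
        probe_z = dataset_zscores(ds, t_variant=t_variant)
        gene_z[ds.dataset_id] = collapse_probes(probe_z, ds.probe_map, rule=collapse_rule)
        weights[ds.dataset_id] = np.sqrt(ds.n_total) if weight_scheme == "sqrt_n" else 1.0

    z_frame = pd.DataFrame(gene_z)  # genes x datasets, NaN where unobserved
    z_frame = z_frame.dropna(how="all")
    w = np.array([weights[c] for c in z_frame.columns])
    z_arr = z_frame.to_numpy()
    observed = ~np.isnan(z_arr)
    wz = np.where(observed, z_arr * w, 0.0).sum(axis=1)
    ww = np.where(observed, w**2, 0.0).sum(axis=1)
    z_meta = wz / np.sqrt(ww)
    p_meta = stats.norm.sf(np.abs(z_meta))  # one-sided tail beyond |Z|

    table = z_frame.add_prefix("z_").copy()
    table.insert(0, "gene_id", z_frame.index)
    table["n_datasets_observed"] = observed.sum(axis=1)
    table["Z_meta"] = z_meta
    table["p_meta"] = p_meta
    table["direction"] = np.where(z_meta >= 0, "up", "down")
    table["significant"] = np.abs(z_meta) > z_threshold
    table = table.reset_index(drop=True)

    up = table.loc[table["Z_meta"] > z_threshold, "gene_id"].tolist()
    down = table.loc[table["Z_meta"] < -z_threshold, "gene_id"].tolist()
    logger.info(
        "egwas_screen: %d genes over %d datasets, %d up / %d down at |Z|>%g",
        len(table),
        len(datasets),
        len(up),
        len(down),
        z_threshold,
    )
    return up, down, table


def manhattan_table(meta_table: pd.DataFrame, gene_order: list[str] | None = None) -> pd.DataFrame:
    """Plot-ready table: gene, position, Z_meta, -log10(p_meta), flag.

    ``gene_order`` supplies positions; when empty or None the genes are
    placed alphabetically.  No plotting happens here — the table feeds
    any renderer.
    """
    if meta_table.empty:
        raise ValueError("empty meta-analysis table")
    tab = meta_table.loc[:, ["gene_id", "Z_meta", "p_meta", "significant"]].copy()
    if gene_order:
        missing = set(tab["gene_id"]) - set(gene_order)
        if missing:
            raise ValueError(f"gene_order missing {len(missing)} genes, e.g. {sorted(missing)[:5]}")
        pos = {g: i for i, g in enumerate(gene_order)}
    else:
        pos = {g: i for i, g in enumerate(sorted(tab["gene_id"]))}
    tab["position"] = tab["gene_id"].map(pos)
    tab["neg_log10_p"] = -np.log10(tab["p_meta"])
    tab = tab.sort_values("position").reset_index(drop=True)
    return tab.loc[:, ["gene_id", "position", "Z_meta", "neg_log10_p", "significant"]]
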