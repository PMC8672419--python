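"""Jonckheere-Terpstra ordered-trend testing and per-gene screening.

The JT statistic for k ordered groups is the sum of pairwise Mann-Whitney
counts between every earlier/later group pair,

    J = sum_{i<j} sum_{x in group_i, y in group_j} [ 1(x<y) + 1/2 * 1(x=y) ],

so 0 <= J <= sum_{i<j} n_i n_j, with large J indicating values that
increase along the declared group order.  Under the permutation null

    E[J]   = (N^2 - sum n_i^2) / 4
    Var[J] = [N^2 (2N+3) - sum n_i^2 (2 n_i + 3)] / 72          (no ties)

and with ties, writing t_u for the multiplicities of tied values pooled
across groups,

    Var[J] = A/72 + B/[36 N(N-1)(N-2)] + C/[8 N(N-1)]
    A = N(N-1)(2N+5) - sum n_i(n_i-1)(2n_i+5) - sum t_u(t_u-1)(2t_u+5)
    B = [sum n_i(n_i-1)(n_i-2)] * [sum t_u(t_u-1)(t_u-2)]
    C = [sum n_i(n_i-1)] * [sum t_u(t_u-1)]

which is exact (it reproduces the moments of the full enumeration).
p-values are available by full enumeration of group assignments (exact),
by label permutation (Monte Carlo, add-one estimator), or from the normal
approximation with the tie-corrected variance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "OrderedGroups",
    "TrendResult",
    "jt_statistic",
    "jt_null_moments",
    "jt_test",
    "trend_screen",
]

EXACT_BUDGET = 10**6
_MC_TIE_FRACTION = 0.20  # auto method: fall back to Monte Carlo above this
_MC_SMALL_N = 25


@dataclass(frozen=True)
class OrderedGroups:
    """Ordered group labels plus the per-sample assignment."""

    labels: tuple[str, ...]
    assignment: tuple[int, ...]  # index into labels, one per sample

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("need at least 2 ordered groups")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("group labels must be unique")
        sizes = self.sizes
        if any(s == 0 for s in sizes):
            empty = [self.labels[i] for i, s in enumerate(sizes) if s == 0]
            raise ValueError(f"empty groups: {empty}")

    @classmethod
    def from_labels(cls, per_sample: Sequence[str], order: Sequence[str]) -> "OrderedGroups":
        order = tuple(order)
        lookup = {lab: i for i, lab in enumerate(order)}
        try:
            assignment = tuple(lookup[lab] for lab in per_sample)
        except KeyError as exc:
            raise ValueError(f"sample stage {exc} not in declared order {order}") from exc
        return cls(order, assignment)

    @property
    def sizes(self) -> tuple[int, ...]:
        counts = [0] * len(self.labels)
        for a in self.assignment:
            counts[a] += 1
        return tuple(counts)

    @property
    def n_total(self) -> int:
        return len(self.assignment)

    @property
    def max_j(self) -> float:
        n = self.sizes
        return float(sum(n[i] * n[j] for i in range(len(n)) for j in range(i + 1, len(n))))


@dataclass
class TrendResult:
    """Per-gene JT screening record."""

    gene_id: str
    statistic: float  # J
    null_mean: float  # E[J]
    null_var: float  # tie-corrected Var[J]
    z: float
    p: float  # one-sided, for `direction`
    direction: Literal["increasing", "decreasing"]
    method: Literal["exact", "montecarlo", "asymptotic"]
    degenerate: bool = False
    n_permutations: int | None = None
    seed: int | None = None


def _group_indices(groups: OrderedGroups) -> list[np.ndarray]:
    assignment = np.asarray(groups.assignment)
    return [np.flatnonzero(assignment == g) for g in range(len(groups.labels))]


def jt_statistic(values: Sequence[float] | np.ndarray, groups: OrderedGroups) -> float:
    """JT statistic for a single feature (NaN values dropped pairwise)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) != groups.n_total:
        raise ValueError("values must be 1-D and aligned with the group assignment")
    keep = ~np.isnan(values)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("jt_statistic: dropped %d NA values", n_dropped)
    assignment = np.asarray(groups.assignment)[keep]
    vals = values[keep]
    j = 0.0
    for gi in range(len(groups.labels)):
        xi = vals[assignment == gi]
        for gj in range(gi + 1, len(groups.labels)):
            xj = vals[assignment == gj]
            j += float(np.sum(xi[:, None] < xj[None, :]) + 0.5 * np.sum(xi[:, None] == xj[None, :]))
    return j


def jt_statistic_matrix(values: np.ndarray, groups: OrderedGroups) -> np.ndarray:
    """Vectorised JT statistic, one per row of a (features x samples) array."""
    values = np.asarray(values, dtype=float)
    idx = _group_indices(groups)
    j = np.zeros(values.shape[0])
    for gi in range(len(idx)):
        xi = values[:, idx[gi]]
        for gj in range(gi + 1, len(idx)):
            xj = values[:, idx[gj]]
            lt = (xi[:, :, None] < xj[:, None, :]).sum(axis=(1, 2))
            eq = (xi[:, :, None] == xj[:, None, :]).sum(axis=(1, 2))
            j += lt + 0.5 * eq
    return j


def _tie_multiplicities(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts


def jt_null_moments(
    group_sizes: Sequence[int], tie_multiplicities: Sequence[int] | None = None
) -> tuple[float, float]:
    """Exact permutation-null mean and (tie-corrected) variance of J.

    ``tie_multiplicities`` are the sizes of tied-value groups pooled over
    all samples (every multiplicity 1 for continuous data); omit for the
    untied formula.
    """
    sizes = np.asarray(group_sizes, dtype=np.int64)
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 1).any():
        raise ValueError("all group sizes must be >= 1")
    n = int(sizes.sum())
    e_j = (n**2 - int((sizes**2).sum())) / 4.0
    if tie_multiplicities is None:
        ties = np.ones(n, dtype=np.int64)
    else:
        ties = np.asarray(tie_multiplicities, dtype=np.int64)
        if int(ties.sum()) != n:
            raise ValueError("tie multiplicities must sum to the total sample count")
    if (ties == n).any():
        return e_j, 0.0  # every value identical: no free ordering
    a = (
        n * (n - 1) * (2 * n + 5)
        - int(np.sum(sizes * (sizes - 1) * (2 * sizes + 5)))
        - int(np.sum(ties * (ties - 1) * (2 * ties + 5)))
    )
    b = int(np.sum(sizes * (sizes - 1) * (sizes - 2))) * int(np.sum(ties * (ties - 1) * (ties - 2)))
    c = int(np.sum(sizes * (sizes - 1))) * int(np.sum(ties * (ties - 1)))
    var = a / 72.0
    if n > 2:
        var += b / (36.0 * n * (n - 1) * (n - 2))
    var += c / (8.0 * n * (n - 1))
    return e_j, max(var, 0.0)


def _partition_count(sizes: Sequence[int]) -> int:
    n = sum(sizes)
    count = 1
    remaining = n
    for s in sizes:
        count *= math.comb(remaining, s)
        remaining -= s
    return count


def _enumerate_j(values: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """J for every distinct assignment of the observed values to groups."""
    n = len(values)
    results: list[float] = []
    order = np.arange(n)

    def recurse(available: tuple[int, ...], chosen: list[np.ndarray], depth: int) -> None:
        if depth == len(sizes):
            j = 0.0
            for gi in range(len(chosen)):
                xi = values[list(chosen[gi])]
                for gj in range(gi + 1, len(chosen)):
                    xj = values[list(chosen[gj])]
                    j += float(
                        np.sum(xi[:, None] < xj[None, :])
                        + 0.5 * np.sum(xi[:, None] == xj[None, :])
                    )
            results.append(j)
            return
        for combo in itertools.combinations(available, sizes[depth]):
            rest = tuple(x for x in available if x not in combo)
            chosen.append(np.asarray(combo))
            recurse(rest, chosen, depth + 1)
            chosen.pop()

    recurse(tuple(order), [], 0)
    return np.asarray(results)


def jt_test(
    values: Sequence[float] | np.ndarray,
    groups: OrderedGroups,
    direction: Literal["increasing", "decreasing"] = "increasing",
    method: Literal["exact", "montecarlo", "asymptotic", "auto"] = "asymptotic",
    n_perm: int = 10_000,
    seed: int | None = None,
    gene_id: str = "",
) -> TrendResult:
    """One-sided JT trend test for a single feature.

    ``exact`` enumerates every distinct assignment of the observed values
    to the group sizes (allowed while the multinomial count stays within
    10^6); ``montecarlo`` permutes labels with the add-one estimator
    (b+1)/(n_perm+1); ``asymptotic`` uses the normal approximation with
    the tie-corrected variance and no continuity correction.  ``auto``
    picks Monte Carlo for small, heavily tied samples and the asymptotic
    route otherwise.
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"unknown direction {direction!r}")
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    vals = values[keep]
    assignment = np.asarray(groups.assignment)[keep]
    present = np.unique(assignment)
    if len(present) < 2:
        raise ValueError("fewer than 2 groups with non-missing values")
    eff_groups = OrderedGroups(
        tuple(groups.labels[g] for g in present),
        tuple(int(np.searchsorted(present, a)) for a in assignment),
    )
    sizes = eff_groups.sizes
    ties = _tie_multiplicities(vals)
    j = jt_statistic(vals, eff_groups)
    e_j, var_j = jt_null_moments(sizes, ties)

    if var_j == 0.0:
        return TrendResult(gene_id, j, e_j, 0.0, 0.0, 1.0, direction, "asymptotic", degenerate=True)

    if method == "auto":
        tie_fraction = 1.0 - len(np.unique(vals)) / len(vals)
        method = (
            "montecarlo" if (tie_fraction > _MC_TIE_FRACTION and len(vals) <= _MC_SMALL_N) else "asymptotic"
        )

    z = (j - e_j) / math.sqrt(var_j)
    if method == "exact":
        total = _partition_count(sizes)
        if total > EXACT_BUDGET:
            raise ValueError(
                f"exact enumeration needs {total} partitions (> {EXACT_BUDGET}); use montecarlo"
            )
        dist = _enumerate_j(vals, sizes)
        tol = 1e-9
        if direction == "increasing":
            p = float(np.mean(dist >= j - tol))
        else:
            p = float(np.mean(dist <= j + tol))
        return TrendResult(gene_id, j, e_j, var_j, z, p, direction, "exact")
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        hits = 0
        tol = 1e-9
        for _ in range(n_perm):
            perm = rng.permutation(vals)
            j_star = jt_statistic(perm, eff_groups)
            if direction == "increasing":
                hits += j_star >= j - tol
            else:
                hits += j_star <= j + tol
        p = (hits + 1) / (n_perm + 1)
        return TrendResult(
            gene_id, j, e_j, var_j, z, p, direction, "montecarlo", n_permutations=n_perm, seed=seed
        )
    if method == "asymptotic":
        p = float(stats.norm.sf(z)) if direction == "increasing" else float(stats.norm.cdf(z))
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
        return TrendResult(gene_id, j, e_j, var_j, z, p, direction, "asymptotic")
    raise ValueError(f"unknown method {method!r}")


def _tie_term_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row tie sums T1=sum t(t-1)(2t+5), T2=sum t(t-1)(t-2), T3=sum t(t-1)."""
    g, n = values.shape
    srt = np.sort(values, axis=1)
    t1 = np.zeros(g)
    t2 = np.zeros(g)
    t3 = np.zeros(g)
    # run-length encode each sorted row; loop is fine at screening scale
    for r in range(g):
        row = srt[r]
        boundaries = np.flatnonzero(np.diff(row) != 0)
        counts = np.diff(np.concatenate(([0], boundaries + 1, [n])))
        t = counts.astype(float)
        t1[r] = np.sum(t * (t - 1) * (2 * t + 5))
        t2[r] = np.sum(t * (t - 1) * (t - 2))
        t3[r] = np.sum(t * (t - 1))
    return t1, t2, t3


def trend_screen(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    stage_set: Sequence[str],
    alpha: float = 0.05,
    method: Literal["asymptotic", "auto"] = "asymptotic",
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Per-gene JT screen across ordered stages.

    Every gene is tested in both directions; its direction is the one with
    the smaller one-sided p (ties broken toward increasing), and it enters
    the up or down list when that p falls below ``alpha``.  For
    ``alpha < 0.5`` this coincides with listing every gene whose
    directional p is below alpha, since p_inc + p_dec >= 1.

    Returns (up gene list, down gene list, full result table).  The table
    carries raw one-sided p-values in both directions plus BH-adjusted
    columns for information; the screen itself uses raw p, and genes with
    fewer than 2 stages observed are skipped with a log entry.
    """
    stage_set = tuple(stage_set)
    if len(stage_set) < 2:
        raise ValueError("stage_set needs at least 2 stages")
    stages = annotation.stages()
    usable = stages[stages.isin(stage_set)].index.intersection(matrix.sample_ids)
    present_stages = [s for s in stage_set if (stages.loc[usable] == s).any()]
    if len(present_stages) < 2:
        raise ValueError(f"fewer than 2 stages of {stage_set} present in the data")
    sub = matrix.values.loc[:, usable]
    groups = OrderedGroups.from_labels(stages.loc[usable].tolist(), present_stages)
    sizes = np.asarray(groups.sizes, dtype=np.int64)
    n = int(sizes.sum())

    vals = sub.to_numpy()
    complete = ~np.isnan(vals).any(axis=1)
    skipped = sub.index[~complete]
    rows: list[dict] = []
    if len(skipped):
        logger.info("trend_screen: %d genes with missing values tested one-by-one", len(skipped))

    j = jt_statistic_matrix(vals[complete], groups)
    e_j = (n**2 - int((sizes**2).sum())) / 4.0
    t1, t2, t3 = _tie_term_rows(vals[complete])
    a = n * (n - 1) * (2 * n + 5) - float(np.sum(sizes * (sizes - 1) * (2 * sizes + 5))) - t1
    b = float(np.sum(sizes * (sizes - 1) * (sizes - 2))) * t2
    c = float(np.sum(sizes * (sizes - 1))) * t3
    var = a / 72.0 + b / (36.0 * n * (n - 1) * (n - 2)) + c / (8.0 * n * (n - 1))
    var = np.maximum(var, 0.0)

    degenerate = var == 0.0
    z = np.zeros_like(j)
    np.divide(j - e_j, np.sqrt(var), out=z, where=~degenerate)
    p_inc = np.where(degenerate, 1.0, stats.norm.sf(z))
    p_dec = np.where(degenerate, 1.0, stats.norm.cdf(z))

    gene_ids = sub.index[complete]
    if method == "auto":
        # per-gene fallback for heavy ties at small N
        tie_fraction = t3 / (n * (n - 1))
        needs_mc = (tie_fraction > _MC_TIE_FRACTION) & (n <= _MC_SMALL_N) & ~degenerate
        for i in np.flatnonzero(needs_mc):
            res_inc = jt_test(vals[complete][i], groups, "increasing", "montecarlo", seed=0)
            res_dec = jt_test(vals[complete][i], groups, "decreasing", "montecarlo", seed=0)
            p_inc[i], p_dec[i] = res_inc.p, res_dec.p

    table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "J": j,
            "E_J": e_j,
            "Var_J": var,
            "z": z,
            "p_increasing": p_inc,
            "p_decreasing": p_dec,
            "degenerate": degenerate,
        }
    )
    for gid in skipped:
        try:
            r_inc = jt_test(sub.loc[gid].to_numpy(), groups, "increasing", "asymptotic", gene_id=gid)
            r_dec = jt_test(sub.loc[gid].to_numpy(), groups, "decreasing", "asymptotic", gene_id=gid)
        except ValueError:
            logger.info("trend_screen: gene %s skipped (<2 stages with data)", gid)
            continue
        table.loc[len(table)] = {
            "gene_id": gid,
            "J": r_inc.statistic,
            "E_J": r_inc.null_mean,
            "Var_J": r_inc.null_var,
            "z": r_inc.z,
            "p_increasing": r_inc.p,
            "p_decreasing": r_dec.p,
            "degenerate": r_inc.degenerate,
        }

    inc_better = table["p_increasing"].to_numpy() <= table["p_decreasing"].to_numpy()
    table["direction"] = np.where(inc_better, "increasing", "decreasing")
    table["p"] = np.where(inc_better, table["p_increasing"], table["p_decreasing"])
    from statsmodels.stats.multitest import multipletests

    ok = ~table["degenerate"].to_numpy()
    for col in ("p_increasing", "p_decreasing"):
        q = np.full(len(table), np.nan)
        if ok.any():
            q[ok] = multipletests(table.loc[ok, col], method="fdr_bh")[1]
        table[f"q_{col.split('_')[1]}"] = q

    selected = table["p"].to_numpy() < alpha
    up = table.loc[selected & (table["direction"] == "increasing"), "gene_id"].tolist()
    down = table.loc[selected & (table["direction"] == "decreasing"), "gene_id"].tolist()
    table = table.sort_values("p", kind="mergesort").reset_index(drop=True)
    logger.info(
        "trend_screen: %d genes tested, %d up / %d down at alpha=%g", len(table), len(up), len(down), alpha
    )
    return up, down, table
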