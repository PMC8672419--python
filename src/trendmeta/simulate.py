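"""Synthetic cohorts with planted, recorded signals.

Two study designs are emulated on the log2 scale with Gaussian noise:

* a PBMC-like cohort with five ordered disease stages
  (HC < D1 < D2 < D3 < ESRD, default sizes 10/11/7/5/7) in which a chosen
  set of trend genes shifts linearly per stage step (signed step size in
  units of the noise SD) — the monotone alternative an ordered-trend test
  is built to detect;
* a collection of heterogeneous "glomerular" case/control datasets
  (default three platforms totalling 25 cases vs 26 controls) with
  per-dataset probe universes (many-to-one probe->gene maps), per-gene
  platform offsets, and a shared set of differentially expressed genes
  with a common case-minus-control shift.

``simulate_overlap_study`` ties the two together: a subset of genes is
planted as both a blood trend gene and a tissue DE gene with consistent
(up) sign, giving a known cross-cohort overlap every downstream stage can
be checked against.  Every planted gene, sign and effect size is recorded
in a serializable :class:`GroundTruth`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CaseControlDataset,
    ExpressionMatrix,
    ProbeGeneMap,
    SampleAnnotation,
)

__all__ = [
    "SimulationDesign",
    "GroundTruth",
    "simulate_pbmc_cohort",
    "simulate_glomerular_collection",
    "simulate_overlap_study",
]

_BASELINE_MEAN = 8.0  # log2 units
_BASELINE_SD = 1.0
_PLATFORM_SD = 0.5  # per-gene per-dataset additive offset
_PROBE_OFFSET_SD = 0.25


@dataclass
class SimulationDesign:
    """Knobs of both synthetic cohorts.

    Effect sizes are expressed in units of the noise SD:
    ``trend_step_delta`` is the per-stage-step mean shift of a blood
    trend gene, ``de_effect`` the case-minus-control shift of a tissue DE
    gene.  ``probe_multiplicity`` is the mean probes per gene (each gene
    gets 1 + Poisson(multiplicity - 1) probes, so always >= 1).
    """

    n_genes: int = 5000
    stage_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 10, "D1": 11, "D2": 7, "D3": 5, "ESRD": 7}
    )
    n_trend_genes: int = 50
    trend_step_delta: float = 0.5
    trend_stage_set: tuple[str, ...] = ("HC", "D1", "D2", "D3", "ESRD")
    n_datasets: int = 3
    n_case: tuple[int, ...] = (8, 9, 8)  # totals 25 cases
    n_control: tuple[int, ...] = (9, 9, 8)  # vs 26 controls
    n_de_genes: int = 100
    de_effect: float = 2.0
    n_overlap_genes: int = 30
    probe_multiplicity: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if any(n < 2 for n in self.stage_sizes.values()):
            small = [s for s, n in self.stage_sizes.items() if n < 2]
            raise ValueError(f"stages with < 2 samples: {small}")
        if self.n_trend_genes < 0 or self.n_de_genes < 0 or self.n_overlap_genes < 0:
            raise ValueError("planted gene counts must be non-negative")
        if self.n_overlap_genes > min(self.n_trend_genes, self.n_de_genes):
            raise ValueError(
                "n_overlap_genes must be <= min(n_trend_genes, n_de_genes)"
            )
        if self.n_trend_genes + self.n_de_genes - self.n_overlap_genes > self.n_genes:
            raise ValueError("more planted genes than genes")
        self.n_case = tuple(self.n_case)
        self.n_control = tuple(self.n_control)
        if len(self.n_case) != self.n_datasets or len(self.n_control) != self.n_datasets:
            raise ValueError("n_case/n_control must list one size per dataset")
        if any(n < 2 for n in self.n_case + self.n_control):
            raise ValueError("every dataset needs >= 2 cases and >= 2 controls")
        if self.probe_multiplicity < 1:
            raise ValueError("probe_multiplicity must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        self.trend_stage_set = tuple(self.trend_stage_set)
        unknown = set(self.trend_stage_set) - set(self.stage_sizes)
        if unknown:
            raise ValueError(f"trend_stage_set stages {sorted(unknown)} not in stage_sizes")

    @property
    def stage_order(self) -> tuple[str, ...]:
        return tuple(self.stage_sizes)

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GroundTruth:
    """Planted signals: gene -> sign maps, overlap ids, effects, seed."""

    trend_genes: dict[str, int] = field(default_factory=dict)
    de_genes: dict[str, int] = field(default_factory=dict)
    overlap_genes: tuple[str, ...] = ()
    trend_step_delta: float = 0.0
    de_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        shared = set(self.trend_genes) & set(self.de_genes)
        if not set(self.overlap_genes) <= shared:
            raise ValueError("overlap genes must be planted in both cohorts")

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["overlap_genes"] = list(self.overlap_genes)
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["overlap_genes"] = tuple(payload["overlap_genes"])
        return cls(**payload)


def _sample_ids(design: SimulationDesign) -> tuple[list[str], list[str]]:
    ids, stages = [], []
    for stage, n in design.stage_sizes.items():
        for i in range(1, n + 1):
            ids.append(f"{stage}_{i:02d}")
            stages.append(stage)
    return ids, stages


def _plant_signs(rng: np.random.Generator, genes: list[str], forced_up: set[str]) -> dict[str, int]:
    return {
        g: 1 if g in forced_up else int(rng.choice([-1, 1]))
        for g in genes
    }


def simulate_pbmc_cohort(
    design: SimulationDesign,
    seed: int | None = None,
    trend_genes: dict[str, int] | None = None,
) -> tuple[ExpressionMatrix, SampleAnnotation, GroundTruth]:
    """Ordered-stage blood cohort with planted monotone-trend genes.

    Trend-gene values follow Normal(mu_g + s_g * delta * stage_index,
    noise_sd^2), where stage_index counts steps within the design's
    ``trend_stage_set`` (stages outside that set sit at the baseline);
    all other genes are Normal(mu_g, noise_sd^2).  ``trend_genes`` lets a
    caller (the overlap study) dictate which genes carry the trend and
    their signs; by default they are drawn at random with random signs.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    gene_ids = design.gene_ids
    sample_ids, stages = _sample_ids(design)
    n_samples = len(sample_ids)

    if trend_genes is None:
        chosen = rng.choice(gene_ids, size=design.n_trend_genes, replace=False).tolist()
        trend_genes = _plant_signs(rng, chosen, forced_up=set())
    else:
        missing = set(trend_genes) - set(gene_ids)
        if missing:
            raise ValueError(f"planted trend genes absent from gene universe: {sorted(missing)[:5]}")

    stage_index = {s: i for i, s in enumerate(design.trend_stage_set)}
    step = np.array([stage_index.get(s, 0) for s in stages], dtype=float)

    mu = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=design.n_genes)
    values = mu[:, None] + rng.normal(0.0, design.noise_sd, size=(design.n_genes, n_samples))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for gene, sign in trend_genes.items():
        values[gene_pos[gene]] += sign * design.trend_step_delta * step

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), feature_kind="gene"
    )
    annotation = SampleAnnotation(
        pd.DataFrame({"stage": stages}, index=pd.Index(sample_ids, name="sample_id")),
        stage_order=design.stage_order,
    )
    truth = GroundTruth(
        trend_genes=dict(trend_genes),
        trend_step_delta=design.trend_step_delta,
        seed=int(design.seed if seed is None else seed),
    )
    return matrix, annotation, truth


def simulate_glomerular_collection(
    design: SimulationDesign,
    seed: int | None = None,
    de_genes: dict[str, int] | None = None,
) -> tuple[list[CaseControlDataset], GroundTruth]:
    """Multi-platform case/control collection with shared planted DE genes.

    Every dataset gets its own probe universe (1 + Poisson(multiplicity-1)
    probes per gene), its own per-gene additive platform offset, and the
    same DE genes shifted by ``de_effect`` (case minus control, in noise-SD
    units).  Probe values = gene-level value + probe offset + independent
    noise.
    """
    if design.n_datasets < 1:
        raise ValueError("need at least one dataset")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    gene_ids = design.gene_ids

    if de_genes is None:
        chosen = rng.choice(gene_ids, size=design.n_de_genes, replace=False).tolist()
        de_genes = _plant_signs(rng, chosen, forced_up=set())

    mu = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=design.n_genes)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    effect = np.zeros(design.n_genes)
    for gene, sign in de_genes.items():
        effect[gene_pos[gene]] = sign * design.de_effect * design.noise_sd

    datasets = []
    for d in range(design.n_datasets):
        ds_id = f"DS{d + 1}"
        n_case, n_control = design.n_case[d], design.n_control[d]
        n_probes_per_gene = 1 + rng.poisson(design.probe_multiplicity - 1.0, size=design.n_genes)
        platform = rng.normal(0.0, _PLATFORM_SD, size=design.n_genes)

        probe_ids, probe_gene_idx = [], []
        for gi, k in enumerate(n_probes_per_gene):
            for p in range(k):
                probe_ids.append(f"{ds_id}_P{gi + 1:05d}_{p + 1}")
                probe_gene_idx.append(gi)
        probe_gene_idx = np.asarray(probe_gene_idx)
        n_probes = len(probe_ids)

        sample_ids = [f"{ds_id}_case_{i:02d}" for i in range(1, n_case + 1)] + [
            f"{ds_id}_ctrl_{i:02d}" for i in range(1, n_control + 1)
        ]
        is_case = np.array([1.0] * n_case + [0.0] * n_control)

        gene_level = (mu + platform)[probe_gene_idx][:, None] + np.outer(
            effect[probe_gene_idx], is_case
        )
        probe_offset = rng.normal(0.0, _PROBE_OFFSET_SD, size=n_probes)
        noise = rng.normal(0.0, design.noise_sd, size=(n_probes, len(sample_ids)))
        values = gene_level + probe_offset[:, None] + noise

        matrix = ExpressionMatrix(
            pd.DataFrame(values, index=probe_ids, columns=sample_ids), feature_kind="probe"
        )
        annotation = SampleAnnotation(
            pd.DataFrame(
                {"group": ["case"] * n_case + ["control"] * n_control},
                index=pd.Index(sample_ids, name="sample_id"),
            )
        )
        probe_map = ProbeGeneMap(
            pd.Series(
                [gene_ids[gi] for gi in probe_gene_idx], index=pd.Index(probe_ids, name="probe_id")
            ),
            namespace="symbol",
        )
        datasets.append(CaseControlDataset(ds_id, matrix, annotation, probe_map))

    truth = GroundTruth(
        de_genes=dict(de_genes),
        de_effect=design.de_effect,
        seed=int(design.seed if seed is None else seed),
    )
    return datasets, truth


def simulate_overlap_study(
    design: SimulationDesign, seed: int | None = None
) -> tuple[
    tuple[ExpressionMatrix, SampleAnnotation],
    list[CaseControlDataset],
    GroundTruth,
]:
    """Both cohorts with a planted shared gene set.

    ``n_overlap_genes`` genes are planted up (sign +1) in both cohorts —
    mirroring an up-in-blood/up-in-tissue discovery design — while the
    remaining trend and DE genes are disjoint with random signs.
    """
    base_seed = design.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    gene_ids = design.gene_ids

    n_signal = design.n_trend_genes + design.n_de_genes - design.n_overlap_genes
    signal = rng.choice(gene_ids, size=n_signal, replace=False).tolist()
    overlap = signal[: design.n_overlap_genes]
    trend_only = signal[design.n_overlap_genes : design.n_trend_genes]
    de_only = signal[design.n_trend_genes :]

    trend_genes = {g: 1 for g in overlap}
    trend_genes.update(_plant_signs(rng, trend_only, forced_up=set()))
    de_genes = {g: 1 for g in overlap}
    de_genes.update(_plant_signs(rng, de_only, forced_up=set()))

    child = np.random.SeedSequence(base_seed).spawn(2)
    blood_seed = int(child[0].generate_state(1)[0] % (2**31))
    tissue_seed = int(child[1].generate_state(1)[0] % (2**31))
    matrix, annotation, _ = simulate_pbmc_cohort(design, seed=blood_seed, trend_genes=trend_genes)
    datasets, _ = simulate_glomerular_collection(design, seed=tissue_seed, de_genes=de_genes)

    truth = GroundTruth(
        trend_genes=trend_genes,
        de_genes=de_genes,
        overlap_genes=tuple(overlap),
        trend_step_delta=design.trend_step_delta,
        de_effect=design.de_effect,
        seed=int(base_seed),
    )
    return (matrix, annotation), datasets, truth
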