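"""In-memory containers shared by every pipeline stage.

The canonical expression container is a features x samples grid of log2
values held in a :class:`pandas.DataFrame`.  Feature ids are either probe
ids (platform-specific) or gene symbols/identifiers; the ``feature_kind``
flag records which.  Sample metadata travels separately in a
:class:`SampleAnnotation` whose ``stage`` column is an explicitly ordered
categorical (e.g. HC < D1 < D2 < D3 < ESRD for an albuminuria-staged
cohort) and whose ``group`` column labels case/control designs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "ProbeGeneMap",
    "GeneSet",
    "GeneSetCollection",
    "CaseControlDataset",
]


@dataclass
class ExpressionMatrix:
    """Features x samples grid of log2 expression values.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
        Values must be numeric; missing entries are NaN.
    feature_kind
        Either ``"probe"`` or ``"gene"``.
    """

    values: pd.DataFrame
    feature_kind: str = "gene"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("probe", "gene"):
            raise ValueError(f"feature_kind must be 'probe' or 'gene', got {self.feature_kind!r}")
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:10]}")
        if not self.values.columns.is_unique:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:10]}")
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValueError(
                f"need at least 1 feature and 2 samples, got shape {self.values.shape}"
            )
        try:
            self.values = self.values.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric expression values: {exc}") from exc
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite or NaN")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.feature_kind)

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(feature_ids)], self.feature_kind)


@dataclass
class SampleAnnotation:
    """Per-sample metadata: ordered clinical stage and/or case-control group.

    ``stage_order`` is the explicit total ordering of stage labels; it must
    cover every stage that occurs.  ``group`` values, when present, are
    ``"case"`` or ``"control"``.  Extra covariate columns are carried
    through untouched.
    """

    table: pd.DataFrame  # indexed by sample_id
    stage_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            raise ValueError("duplicate sample ids in annotation")
        self.stage_order = tuple(self.stage_order)
        if "stage" in self.table.columns and self.stage_order:
            seen = set(self.table["stage"].dropna().unique())
            missing = seen - set(self.stage_order)
            if missing:
                raise ValueError(f"stages {sorted(missing)} absent from stage_order {self.stage_order}")
        if "group" in self.table.columns:
            bad = set(self.table["group"].dropna().unique()) - {"case", "control"}
            if bad:
                raise ValueError(f"group labels must be case/control, got {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def stages(self) -> pd.Series:
        if "stage" not in self.table.columns:
            raise KeyError("annotation has no 'stage' column")
        return self.table["stage"]

    def groups(self) -> pd.Series:
        if "group" not in self.table.columns:
            raise KeyError("annotation has no 'group' column")
        return self.table["group"]

    def check_against(self, matrix: ExpressionMatrix) -> None:
        missing = self.table.index.difference(matrix.sample_ids)
        if len(missing):
            raise ValueError(f"annotated samples absent from matrix: {missing.tolist()[:10]}")


@dataclass
class ProbeGeneMap:
    """Many-to-one probe -> gene mapping.

    Each probe maps to at most one gene; probes absent from the mapping are
    treated as unmapped and dropped (with a logged count) wherever the map
    is applied.
    """

    mapping: pd.Series  # index probe_id, values gene_id
    namespace: str = "symbol"

    def __post_init__(self) -> None:
        if not self.mapping.index.is_unique:
            dupes = self.mapping.index[self.mapping.index.duplicated()].unique().tolist()
            raise ValueError(f"probe mapped more than once: {dupes[:10]}")
        self.mapping = self.mapping.dropna().astype(str)
        if len(self.mapping) == 0:
            raise ValueError("probe->gene map is empty")

    @property
    def probes(self) -> pd.Index:
        return self.mapping.index

    @property
    def genes(self) -> pd.Index:
        return pd.Index(pd.unique(self.mapping.to_numpy()))

    def __len__(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValueError(f"duplicate gene set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]


@dataclass
class CaseControlDataset:
    """One platform's probe-level matrix with case/control labels and a probe map."""

    dataset_id: str
    matrix: ExpressionMatrix
    annotation: SampleAnnotation
    probe_map: ProbeGeneMap

    def __post_init__(self) -> None:
        self.annotation.check_against(self.matrix)
        groups = self.annotation.groups()
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError(
                f"dataset {self.dataset_id}: need >=2 cases and >=2 controls, "
                f"got {self.n_case}/{self.n_control}"
            )
        unlabeled = self.matrix.sample_ids.difference(groups.dropna().index)
        if len(unlabeled):
            raise ValueError(f"unlabeled samples in {self.dataset_id}: {unlabeled.tolist()[:10]}")

    @property
    def n_case(self) -> int:
        return int((self.annotation.groups() == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.annotation.groups() == "control").sum())

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control
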