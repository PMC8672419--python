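import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from trendmeta import (
    ExpressionMatrix,
    OrderedGroups,
    SampleAnnotation,
    SimulationDesign,
)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(20, 10)),
        index=[f"G{i:03d}" for i in range(20)],
        columns=[f"S{i:02d}" for i in range(10)],
    )
    return ExpressionMatrix(values)


@pytest.fixture
def staged_annotation() -> SampleAnnotation:
    stages = ["D1"] * 4 + ["D2"] * 3 + ["D3"] * 3
    return SampleAnnotation(
        pd.DataFrame({"stage": stages}, index=pd.Index([f"S{i:02d}" for i in range(10)], name="sample_id")),
        stage_order=("D1", "D2", "D3"),
    )


@pytest.fixture
def three_groups() -> OrderedGroups:
    return OrderedGroups.from_labels(["a", "a", "b", "b", "c", "c"], ["a", "b", "c"])


@pytest.fixture
def tiny_design() -> SimulationDesign:
    """Down-scaled design for fast unit tests (keeps the stage structure)."""
    return SimulationDesign(
        n_genes=400,
        n_trend_genes=20,
        n_de_genes=30,
        n_overlap_genes=10,
        seed=11,
    )
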