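"""Readers and writers for the pipeline's file formats.

Formats handled: TSV/CSV expression matrices (plain or GEO series-matrix
dialect, whose ``!``-prefixed metadata lines are skipped), TSV sample
annotations, TSV probe->gene maps, GMT gene-set collections, JSON ground
truth, and the ranked results table whose column layout mirrors a
combined blood/tissue gene report (gene, description, p_eGWAS, p_JT,
z_meta, direction).

Matrices are stored genes-as-rows canonically; ``orientation`` lets the
reader transpose sample-as-row exports on the way in.  Missing values may
be encoded as empty fields, ``NA`` or ``NaN``.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ProbeGeneMap,
    SampleAnnotation,
)

logger = logging.getLogger(__name__)

_NA_TOKENS = ["", "NA", "NaN", "nan"]

RESULT_COLUMNS = ("gene", "description", "p_eGWAS", "p_JT", "z_meta", "direction")


class ParseError(ValueError):
    """Malformed input file."""


def _sniff_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path,
    orientation: str = "features_as_rows",
    feature_kind: str = "gene",
) -> ExpressionMatrix:
    """Read a delimited expression matrix.

    Parameters
    ----------
    path
        TSV (or CSV by extension) with one header row of sample ids and a
        first column of feature ids.  Lines starting with ``!`` (GEO
        series-matrix metadata, including the table begin/end sentinels)
        are skipped.
    orientation
        ``features_as_rows`` (canonical) or ``samples_as_rows`` (the
        table is transposed after reading).
    """
    if orientation not in ("features_as_rows", "samples_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    text_lines = [
        ln for ln in path.read_text().splitlines() if ln and not ln.startswith("!")
    ]
    if not text_lines:
        raise ParseError(f"{path}: no table content")
    buf = _io.StringIO("\n".join(text_lines))
    try:
        df = pd.read_csv(
            buf,
            sep=_sniff_sep(path),
            index_col=0,
            na_values=_NA_TOKENS,
            keep_default_na=False,
        )
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: malformed table: {exc}") from exc
    if df.index.name is None and df.columns.size == 0:
        raise ParseError(f"{path}: malformed header")
    # locate non-numeric cells precisely before the blanket cast
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ParseError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = coerced
    if orientation == "samples_as_rows":
        df = df.T
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate feature ids {dupes[:10]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df, feature_kind=feature_kind)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.values.to_csv(path, sep=_sniff_sep(path), index_label="feature_id", na_rep="NA")


def read_sample_annotation(
    path: str | Path, stage_order: Sequence[str] = ()
) -> SampleAnnotation:
    """Read a TSV with a ``sample_id`` column plus stage/group/covariates."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), na_values=_NA_TOKENS, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: annotation needs a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if not stage_order and "stage" in df.columns:
        # fall back to order of first appearance; callers should be explicit
        stage_order = tuple(pd.unique(df["stage"].dropna()))
        logger.warning("no stage_order given; using order of appearance %s", stage_order)
    return SampleAnnotation(df, stage_order=tuple(stage_order))


def write_sample_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(Path(path), sep="\t", index_label="sample_id", na_rep="NA")


def read_probe_gene_map(path: str | Path, namespace: str = "symbol") -> ProbeGeneMap:
    """Read a two-column TSV (probe_id, gene_id)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, na_values=_NA_TOKENS, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: probe map needs two columns (probe_id, gene_id)")
    probe_col, gene_col = df.columns[:2]
    n_unmapped = int(df[gene_col].isna().sum())
    if n_unmapped:
        logger.info("%s: %d unmapped probes dropped", path, n_unmapped)
    series = df.dropna(subset=[gene_col]).set_index(probe_col)[gene_col]
    return ProbeGeneMap(series, namespace=namespace)


def write_probe_gene_map(probe_map: ProbeGeneMap, path: str | Path) -> None:
    probe_map.mapping.rename("gene_id").to_csv(Path(path), sep="\t", index_label="probe_id")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB member TAB member ...)."""
    collection = GeneSetCollection()
    lines = Path(path).read_text().splitlines()
    if not any(ln.strip() for ln in lines):
        logger.warning("%s: empty GMT file", path)
        return collection
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
        name, description, *members = fields
        members = [m for m in members if m]
        deduped = list(dict.fromkeys(members))
        if len(deduped) < len(members):
            logger.warning("%s:%d: set %r has duplicated members; de-duplicated", path, lineno, name)
        collection.add(GeneSet(name=name, description=description, members=tuple(deduped)))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_set in collection:
            fh.write("\t".join([gene_set.name, gene_set.description, *gene_set.members]) + "\n")


def write_results_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write the ranked overlap table.

    Requires ``gene``, ``p_eGWAS`` and ``p_JT`` columns; ``description``,
    ``z_meta`` and ``direction`` are filled with defaults when absent.
    p-values are printed in scientific notation with four significant
    digits; read-back reproduces the printed values exactly.
    """
    mandatory = {"gene", "p_eGWAS", "p_JT"}
    missing = mandatory - set(records.columns)
    if missing:
        raise ValueError(f"results table missing mandatory columns: {sorted(missing)}")
    out = records.copy()
    if "description" not in out.columns:
        out["description"] = ""
    if "z_meta" not in out.columns:
        out["z_meta"] = np.nan
    if "direction" not in out.columns:
        out["direction"] = ""
    out = out.loc[:, list(RESULT_COLUMNS)]
    for col in ("p_eGWAS", "p_JT"):
        out[col] = out[col].map(lambda v: f"{v:.3E}" if pd.notna(v) else "NA")
    out["z_meta"] = out["z_meta"].map(lambda v: f"{v:.4f}" if pd.notna(v) else "NA")
    out.to_csv(Path(path), sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", na_values=_NA_TOKENS, keep_default_na=False)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: results table missing columns {sorted(missing)}")
    return df


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
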