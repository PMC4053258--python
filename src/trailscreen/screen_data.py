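"""Well-level screen data model, I/O and per-plate control normalization.

The unit of raw data is one luminescence reading from one well of a 384-well
plate, tied to a screen batch, plate, sample role (experimental siRNA or one
of the transfection controls), gene/siRNA identity, treatment condition and
assay endpoint.  All downstream analysis operates on *fold changes*: each
raw signal divided by the mean signal of the negative-control (siNeg) wells
of the same plate and assay in the vehicle (no-TRAIL) condition.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "WELL_COLUMNS",
    "SAMPLE_ROLES",
    "CONTROL_ROLES",
    "CONDITIONS",
    "ASSAYS",
    "ScreenValidationError",
    "parse_well",
    "format_well",
    "validate_wells",
    "read_screen_table",
    "write_screen_table",
    "read_plate_map",
    "apply_plate_map",
    "read_annotation",
    "normalize_to_plate_control",
    "aggregate_sirna",
    "role_counts",
]

#: Required columns of a long-format well table, in canonical order.
WELL_COLUMNS = [
    "screen_batch",
    "plate_id",
    "well",
    "sample_role",
    "gene_id",
    "sirna_id",
    "condition",
    "assay",
    "raw_signal",
]

CONTROL_ROLES = frozenset({"cells_only", "siNeg", "siCelldeath", "siCASP8", "siFLIP"})
SAMPLE_ROLES = frozenset({"experimental"}) | CONTROL_ROLES
CONDITIONS = frozenset({"vehicle", "treated"})
ASSAYS = frozenset({"caspase8", "caspase3_7", "viability"})

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")

#: Key that must be unique within a dataset.
_UNIQUE_KEY = ["plate_id", "well", "assay", "condition"]


class ScreenValidationError(ValueError):
    """Raised when a well table violates the data contract.

    Attributes
    ----------
    rows : list[int]
        Zero-based positional indices of the offending rows, when applicable.
    """

    def __init__(self, message: str, rows: Iterable[int] | None = None):
        self.rows = sorted(rows) if rows is not None else []
        if self.rows:
            shown = ", ".join(map(str, self.rows[:10]))
            more = "" if len(self.rows) <= 10 else f" (+{len(self.rows) - 10} more)"
            message = f"{message} [rows: {shown}{more}]"
        super().__init__(message)


def parse_well(well: str) -> tuple[int, int]:
    """Parse a well label like ``"B07"`` (or ``"B7"``) into (row, column).

    Rows are 0-based indices into A..P; columns are 1..24.
    """
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ValueError(f"unparseable well coordinate: {well!r}")
    row = ord(m.group(1).upper()) - ord("A")
    col = int(m.group(2))
    if not 1 <= col <= 24:
        raise ValueError(f"well column out of range 1..24: {well!r}")
    return row, col


def format_well(row: int, col: int) -> str:
    """Format (row index 0..15, column 1..24) as a zero-padded label, e.g. ``"B07"``."""
    if not (0 <= row <= 15 and 1 <= col <= 24):
        raise ValueError(f"well coordinates out of 384-well range: row={row}, col={col}")
    return f"{chr(ord('A') + row)}{col:02d}"


def _canonical_wells(series: pd.Series) -> pd.Series:
    return series.map(lambda w: format_well(*parse_well(w)))


def validate_wells(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a long-format well table.

    Checks the column set, enumerations, well coordinates, signal positivity,
    the experimental-role/gene-identity equivalence and key uniqueness.
    Returns a copy with zero-padded well labels, string identity columns
    (missing gene/siRNA as ``""``) and columns in canonical order.
    """
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenValidationError(f"missing required columns: {missing}")
    out = df.loc[:, WELL_COLUMNS].copy().reset_index(drop=True)
    for col in ("screen_batch", "plate_id", "sample_role", "condition", "assay"):
        out[col] = out[col].astype(str)
    for col in ("gene_id", "sirna_id"):
        out[col] = out[col].fillna("").astype(str).replace({"nan": ""})

    bad = out.index[~out["sample_role"].isin(SAMPLE_ROLES)]
    if len(bad):
        raise ScreenValidationError(
            f"unknown sample_role values: {sorted(out.loc[bad, 'sample_role'].unique())}", bad
        )
    bad = out.index[~out["condition"].isin(CONDITIONS)]
    if len(bad):
        raise ScreenValidationError(
            f"unknown condition values: {sorted(out.loc[bad, 'condition'].unique())}", bad
        )
    bad = out.index[~out["assay"].isin(ASSAYS)]
    if len(bad):
        raise ScreenValidationError(
            f"unknown assay values: {sorted(out.loc[bad, 'assay'].unique())}", bad
        )

    try:
        out["well"] = _canonical_wells(out["well"])
    except ValueError as exc:
        bad = [i for i, w in enumerate(out["well"]) if _WELL_RE.match(str(w).strip()) is None]
        raise ScreenValidationError(str(exc), bad) from exc

    out["raw_signal"] = pd.to_numeric(out["raw_signal"], errors="coerce")
    bad = out.index[~(out["raw_signal"] > 0) | out["raw_signal"].isna()]
    if len(bad):
        raise ScreenValidationError("raw_signal must be strictly positive", bad)

    is_exp = out["sample_role"] == "experimental"
    has_ids = (out["gene_id"] != "") & (out["sirna_id"] != "")
    bad = out.index[is_exp & ~has_ids]
    if len(bad):
        raise ScreenValidationError("experimental wells require gene_id and sirna_id", bad)
    bad = out.index[~is_exp & (out["sirna_id"] != "")]
    # Control wells may carry a gene_id (siCASP8 targets CASP8) but not an
    # experimental sirna_id slot; tolerate labels, this is not an error.
    _ = bad

    dup = out.duplicated(subset=_UNIQUE_KEY, keep=False)
    if dup.any():
        raise ScreenValidationError(
            "duplicate (plate_id, well, assay, condition) keys", out.index[dup]
        )
    return out


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def read_screen_table(path: str | Path, layout: str | Path | None = None) -> pd.DataFrame:
    """Read a long-format well table (CSV/TSV) and validate it.

    If ``layout`` is given, it is a plate-map CSV supplying per-well
    ``sample_role``/``gene_id``/``sirna_id``; the main table then only needs
    the measurement columns (screen_batch, plate_id, well, condition, assay,
    raw_signal).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if layout is not None:
        df = apply_plate_map(df, read_plate_map(layout))
    return validate_wells(df)


def write_screen_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a well table (optionally with ``fold_change``) in canonical column order."""
    path = Path(path)
    cols = WELL_COLUMNS + [c for c in ("fold_change",) if c in df.columns]
    df.loc[:, cols].to_csv(path, sep=_sep_for(path), index=False)


def read_plate_map(path: str | Path) -> pd.DataFrame:
    """Read a plate map: plate_id, well, sample_role, gene_id, sirna_id."""
    path = Path(path)
    pm = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = ["plate_id", "well", "sample_role"]
    missing = [c for c in required if c not in pm.columns]
    if missing:
        raise ScreenValidationError(f"plate map missing columns: {missing}")
    for col in ("gene_id", "sirna_id"):
        if col not in pm.columns:
            pm[col] = ""
        pm[col] = pm[col].fillna("").astype(str)
    pm["well"] = _canonical_wells(pm["well"])
    return pm


def apply_plate_map(measurements: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Join measurement rows (plate_id, well, condition, assay, raw_signal, ...)
    with a plate map to produce a full well table."""
    df = measurements.copy()
    df["well"] = _canonical_wells(df["well"])
    merged = df.merge(
        plate_map[["plate_id", "well", "sample_role", "gene_id", "sirna_id"]],
        on=["plate_id", "well"],
        how="left",
        validate="many_to_one",
    )
    if merged["sample_role"].isna().any():
        bad = merged.index[merged["sample_role"].isna()]
        raise ScreenValidationError("wells missing from plate map", bad)
    return merged


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene -> gene-set annotation (gene_id, gene_set[, n_sirnas])."""
    path = Path(path)
    ann = pd.read_csv(path, sep=_sep_for(path), dtype={"gene_id": str, "gene_set": str})
    missing = [c for c in ("gene_id", "gene_set") if c not in ann.columns]
    if missing:
        raise ScreenValidationError(f"annotation missing columns: {missing}")
    if "n_sirnas" not in ann.columns:
        ann["n_sirnas"] = 4
    dup = ann.duplicated(subset=["gene_id"], keep=False)
    if dup.any():
        raise ScreenValidationError("gene_id duplicated in annotation", ann.index[dup])
    return ann.reset_index(drop=True)


def normalize_to_plate_control(records: pd.DataFrame) -> pd.DataFrame:
    """Per-plate fold-change normalization against untreated siNeg wells.

    For every plate x assay, F = raw_signal / mean(raw_signal of that plate
    and assay's siNeg vehicle wells).  Control wells are normalized too and
    retained.  Raises :class:`ScreenValidationError` naming any plate x assay
    without siNeg vehicle wells.
    """
    df = validate_wells(records)
    is_ref = (df["sample_role"] == "siNeg") & (df["condition"] == "vehicle")
    ref = (
        df.loc[is_ref]
        .groupby(["plate_id", "assay"], sort=False)["raw_signal"]
        .mean()
        .rename("_ref_mean")
    )
    merged = df.merge(ref, on=["plate_id", "assay"], how="left")
    if merged["_ref_mean"].isna().any():
        missing = (
            merged.loc[merged["_ref_mean"].isna(), ["plate_id", "assay"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        names = ", ".join(f"{p}/{a}" for p, a in missing)
        raise ScreenValidationError(f"no siNeg vehicle wells on plate x assay: {names}")
    merged["fold_change"] = merged["raw_signal"] / merged["_ref_mean"]
    return merged.drop(columns="_ref_mean")


def aggregate_sirna(measurements: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate wells to one fold-change per (gene, siRNA, assay, condition).

    Experimental wells are averaged (arithmetic mean of F) over replicates,
    with the replicate count recorded in ``n_wells``.  Control wells pass
    through one record per well (``n_wells = 1``), so per-role counts are
    conserved and control distributions stay available for threshold
    estimation.
    """
    if "fold_change" not in measurements.columns:
        raise ScreenValidationError("aggregate_sirna expects normalized input (fold_change)")
    cols = ["screen_batch", "sample_role", "gene_id", "sirna_id", "assay", "condition"]
    exp = measurements[measurements["sample_role"] == "experimental"]
    ctrl = measurements[measurements["sample_role"] != "experimental"]
    agg = (
        exp.groupby(cols, sort=False, as_index=False)
        .agg(fold_change=("fold_change", "mean"), n_wells=("fold_change", "size"))
    )
    ctrl_out = ctrl.loc[:, cols + ["plate_id", "well", "fold_change"]].copy()
    ctrl_out["n_wells"] = 1
    exp_out = agg.reindex(columns=cols + ["fold_change", "n_wells"])
    exp_out["plate_id"] = ""
    exp_out["well"] = ""
    out = pd.concat(
        [exp_out[cols + ["plate_id", "well", "fold_change", "n_wells"]],
         ctrl_out[cols + ["plate_id", "well", "fold_change", "n_wells"]]],
        ignore_index=True,
    )
    return out


def role_counts(df: pd.DataFrame) -> pd.Series:
    """Number of records per sample_role (diagnostic)."""
    return df["sample_role"].value_counts().sort_index()
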