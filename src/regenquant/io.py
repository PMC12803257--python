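"""CSV table schemata and multichannel TIFF reading.

All intermediate products of the pipeline travel as plain CSV with fixed,
documented columns so that runs can be inspected, diffed and resumed.
Schema violations are reported with the offending row number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .phantom import CHANNELS

__all__ = [
    "SchemaError",
    "COHORT_COLUMNS",
    "MORPHOMETRY_COLUMNS",
    "CALLS_COLUMNS",
    "NUCLEI_COLUMNS",
    "read_cohort_table",
    "write_cohort_table",
    "read_table",
    "write_table",
    "read_section",
]

COHORT_COLUMNS = ["sample_id", "age", "status", "n_igg", "n_emhc", "n_total"]
MORPHOMETRY_COLUMNS = [
    "fiber_id", "area_um2", "min_feret_um", "perimeter_um",
    "circularity", "centroid_y", "centroid_x",
]
CALLS_COLUMNS = ["fiber_id", "mean_emhc", "mean_igg", "is_emhc_pos", "is_igg_pos"]
NUCLEI_COLUMNS = [
    "nucleus_id", "centroid_y", "centroid_x", "mean_pax7",
    "is_pax7_pos", "fiber_context",
]


class SchemaError(ValueError):
    """A table does not conform to its documented schema."""


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {missing}")


def _check_rows(df: pd.DataFrame, what: str) -> None:
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based, after the header line
        for col in ("n_igg", "n_emhc", "n_total"):
            v = row[col]
            if not np.isfinite(v):
                raise SchemaError(f"{what} table row {rowno}: {col} is not numeric")
            if v < 0:
                raise SchemaError(f"{what} table row {rowno}: {col} is negative ({v})")
        if row["n_igg"] > row["n_total"] or row["n_emhc"] > row["n_total"]:
            raise SchemaError(
                f"{what} table row {rowno}: marker count exceeds total fibers"
            )
        if row["status"] not in ("DMD", "CTRL"):
            raise SchemaError(
                f"{what} table row {rowno}: status must be DMD or CTRL, got {row['status']!r}"
            )


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a cohort counts table.

    Columns: sample_id, age, status (DMD|CTRL), n_igg, n_emhc, n_total.
    Counts may be fractional (replicate-section averages).
    """
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, "cohort")
    for col in ("age", "n_igg", "n_emhc", "n_total"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            rowno = int(bad.idxmax()) + 2
            raise SchemaError(f"cohort table row {rowno}: {col} is not numeric")
        df[col] = coerced
    _check_rows(df, "cohort")
    return df


def write_cohort_table(df: pd.DataFrame, path) -> None:
    _require_columns(df, COHORT_COLUMNS, "cohort")
    df.to_csv(path, index=False, columns=[c for c in df.columns])


_SCHEMAS = {
    "morphometry": MORPHOMETRY_COLUMNS,
    "calls": CALLS_COLUMNS,
    "nuclei": NUCLEI_COLUMNS,
    "cohort": COHORT_COLUMNS,
}


def read_table(path, kind: str) -> pd.DataFrame:
    """Read any documented pipeline table, validating its columns."""
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; one of {sorted(_SCHEMAS)}")
    if kind == "cohort":
        return read_cohort_table(path)
    df = pd.read_csv(path)
    _require_columns(df, _SCHEMAS[kind], kind)
    return df


def write_table(df: pd.DataFrame, path, kind: str) -> None:
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; one of {sorted(_SCHEMAS)}")
    _require_columns(df, _SCHEMAS[kind], kind)
    df.to_csv(path, index=False)


def read_section(path, channel_order: dict[str, int] | None = None,
                 pixel_size: float | None = None) -> tuple[dict[str, np.ndarray], float]:
    """Read a multichannel section TIFF into named channels.

    Channel names and pixel size are taken from the TIFF metadata when
    present (as written by :meth:`Phantom.write`); ``channel_order`` (name →
    page index) and ``pixel_size`` override or supply them otherwise.

    Returns (channels dict, pixel size in µm/px).
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = (tf.shaped_metadata or [{}])[0] if tf.shaped_metadata else {}
        names = meta.get("channel_names")
        if pixel_size is None:
            pixel_size = meta.get("pixel_size_um")
        if pixel_size is None:
            page = tf.pages[0]
            res, unit = page.tags.get("XResolution"), page.tags.get("ResolutionUnit")
            if res is not None and unit is not None and unit.value == 3:
                num, den = res.value
                pixel_size = 1e4 * den / num
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a (C, H, W) image, got shape {arr.shape}")
    if channel_order is not None:
        mapping = {name: int(i) for name, i in channel_order.items()}
    elif names is not None:
        mapping = {str(n): i for i, n in enumerate(names)}
    else:
        mapping = {n: i for i, n in enumerate(CHANNELS[: arr.shape[0]])}
    bad = [n for n, i in mapping.items() if not (0 <= i < arr.shape[0])]
    if bad:
        raise ValueError(f"channel indices out of range for {bad} (image has {arr.shape[0]} pages)")
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("calibration error: pixel size missing; pass pixel_size explicitly")
    return {n: arr[i] for n, i in mapping.items()}, float(pixel_size)
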