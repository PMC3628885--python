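"""Readers and writers for the pipeline's tab-separated dialects.

All on-disk formats are plain text: ScanTables, sample tables, matrices and
Ct tables as TSV with documented headers; calibration results and run
manifests as JSON; dendrograms as Newick.  Readers validate in strict mode
(fractions in [0,1], non-negative intensities) and report the offending
1-based line number; unknown columns pass through untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .qc import LogRatioMatrix

SCAN_COLUMNS = (
    "feature_id",
    "annotation_source",
    "channel",
    "scan_power",
    "median_fg",
    "median_bg",
    "bg_sd",
    "frac_pixels_gt_bg2sd",
    "r_squared",
    "frac_saturated",
    "flag",
)

_FRACTION_COLUMNS = ("frac_pixels_gt_bg2sd", "frac_saturated")
_NONNEGATIVE_COLUMNS = ("median_fg", "median_bg", "bg_sd")


def write_scan_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_scan_table(path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a ScanTable TSV.

    In strict mode, out-of-range fractions or negative intensities raise
    :class:`ParseError` naming the first offending line (1-based, header is
    line 1).  Lenient mode returns the rows as parsed.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise ParseError(f"no features in {path}") from None
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns {missing} in {path}")
    if df.empty:
        raise ParseError(f"no features in {path}")
    if strict:
        for col in _FRACTION_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = ~((vals >= 0) & (vals <= 1))
            if bad.any():
                raise ParseError(
                    f"{col} outside [0,1] (value {df[col][bad].iloc[0]!r})",
                    line=int(np.flatnonzero(bad)[0]) + 2,
                )
        for col in _NONNEGATIVE_COLUMNS:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = ~(vals >= 0)
            if bad.any():
                raise ParseError(
                    f"{col} negative or non-numeric (value {df[col][bad].iloc[0]!r})",
                    line=int(np.flatnonzero(bad)[0]) + 2,
                )
    return df


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "age_category"):
        if col not in df.columns:
            raise ParseError(f"sample table missing column {col!r}")
    return df


def write_matrix(matrix: LogRatioMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t")


def read_matrix(path, samples: pd.DataFrame | None = None,
                row_annot: pd.DataFrame | None = None) -> LogRatioMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    return LogRatioMatrix(
        values=values,
        row_annot=row_annot if row_annot is not None else pd.DataFrame(index=values.index),
        samples=samples if samples is not None else pd.DataFrame(),
    )


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="assay_id")


def read_ct_table(path, strict: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="assay_id")
    if "strand" not in df.columns:
        raise ParseError(f"Ct table missing 'strand' column in {path}")
    values = df.drop(columns="strand")
    if strict:
        arr = values.to_numpy(float)
        bad = ~((arr > 0) & (arr <= 40))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"Ct value {arr[i, j]!r} outside (0, 40] for assay "
                f"{values.index[i]!r}",
                line=int(i) + 2,
            )
    return df


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


def write_fits(fits: pd.DataFrame, path) -> None:
    fits.to_csv(path, sep="\t", index=False)


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False,
                       na_values=[""], dtype={"pattern": str, "partition": str})
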