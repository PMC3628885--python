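"""Merge 10%- and 100%-power scans into one extended-dynamic-range table.

Scanning bright arrays twice — once with the photomultiplier tuned so nothing
saturates, once at full power — extends dynamic range: dim features are
quantified far better at full power, while features that clip at the 16-bit
ceiling retain usable signal only in the low-power scan.  The two scans are
related by an approximately linear gain, so the merge is: fit a robust
(least-absolute-deviations) line of high-scan on low-scan background-
subtracted intensity over features unsaturated in both scans, keep high-scan
values where valid, and substitute ``slope * low + intercept`` where the
high scan is saturated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CalibrationError, InputError

#: a feature counts as saturated when at least this fraction of pixels clip
SATURATION_FRAC = 0.20
MIN_SUPPORT = 10


@dataclass(frozen=True)
class ScanCalibration:
    """Linear relation high = slope * low + intercept for one channel."""

    slope: float
    intercept: float
    n_support: int
    channel: str


def background_subtracted(table: pd.DataFrame) -> pd.Series:
    """Median foreground minus median background, floored at 1 intensity unit.

    The floor keeps downstream log2 operations finite.
    """
    return np.maximum(table["median_fg"] - table["median_bg"], 1.0)


def _channel(table: pd.DataFrame, channel: str) -> pd.DataFrame:
    sub = table[table["channel"] == channel]
    if sub.empty:
        raise InputError(f"no rows for channel {channel!r}")
    return sub.set_index("feature_id")


def fit_scan_calibration(
    low: pd.DataFrame, high: pd.DataFrame, channel: str
) -> ScanCalibration:
    """LAD fit of high-scan on low-scan intensity over the unsaturated support.

    Support features must be unsaturated in both scans and above background
    in both.  Fewer than 10 support features, or a non-positive slope
    (a symptom of swapped inputs), raise :class:`CalibrationError`.
    """
    lo = _channel(low, channel)
    hi = _channel(high, channel)
    if not lo.index.equals(hi.index):
        common = lo.index.intersection(hi.index)
        if len(common) == 0:
            raise InputError("scan tables share no feature ids")
        lo, hi = lo.loc[common], hi.loc[common]
    x = background_subtracted(lo)
    y = background_subtracted(hi)
    support = (
        (lo["frac_saturated"] < SATURATION_FRAC)
        & (hi["frac_saturated"] < SATURATION_FRAC)
        & (lo["median_fg"] > lo["median_bg"])
        & (hi["median_fg"] > hi["median_bg"])
    )
    n_support = int(support.sum())
    if n_support < MIN_SUPPORT:
        raise CalibrationError(
            f"only {n_support} unsaturated above-background features "
            f"(need >= {MIN_SUPPORT}) in channel {channel!r}"
        )
    xs = x[support].to_numpy(float)
    ys = y[support].to_numpy(float)
    if np.ptp(xs) == 0:
        raise CalibrationError("support features have constant low-scan intensity")
    import warnings

    from statsmodels.tools.sm_exceptions import IterationLimitWarning

    with warnings.catch_warnings():
        # LAD on exactly-linear support can cycle at machine precision
        warnings.simplefilter("ignore", IterationLimitWarning)
        model = sm.QuantReg(ys, sm.add_constant(xs)).fit(q=0.5)
    intercept, slope = float(model.params[0]), float(model.params[1])
    if slope <= 0:
        raise CalibrationError(
            f"non-positive slope {slope:.3g} in channel {channel!r}; "
            "are the low/high inputs swapped?"
        )
    return ScanCalibration(slope=slope, intercept=intercept,
                           n_support=n_support, channel=channel)


def merge_scans(
    low: pd.DataFrame, high: pd.DataFrame, calibrations: dict
) -> pd.DataFrame:
    """Merged ScanTable: high-scan values, low-scan substitution where clipped.

    ``calibrations`` maps channel name to its :class:`ScanCalibration`.
    Features saturated in the high scan (``frac_saturated >= 0.20``) get
    ``slope * low_signal + intercept`` (re-expressed as a foreground above
    the low scan's background); everything else keeps the high-scan row.
    QC fields take the per-field more reliable scan: pixel fraction and
    regression R² the better of the two, saturation fraction / flag /
    background from the scan actually used.  ``source_scan`` records the
    provenance per row.
    """
    merged_parts = []
    for channel in sorted(low["channel"].unique()):
        if channel not in calibrations:
            raise InputError(f"no calibration for channel {channel!r}")
        calib = calibrations[channel]
        lo = _channel(low, channel)
        hi = _channel(high, channel)
        if not lo.index.equals(hi.index):
            raise InputError(f"feature-id mismatch between scans in {channel!r}")
        use_low = (hi["frac_saturated"] >= SATURATION_FRAC).to_numpy()
        out = hi.copy()
        low_signal = background_subtracted(lo)
        substituted = calib.slope * low_signal + calib.intercept
        out.loc[use_low, "median_bg"] = lo.loc[use_low, "median_bg"]
        out.loc[use_low, "median_fg"] = (
            substituted[use_low] + lo.loc[use_low, "median_bg"]
        )
        out.loc[use_low, "bg_sd"] = lo.loc[use_low, "bg_sd"]
        out.loc[use_low, "frac_saturated"] = lo.loc[use_low, "frac_saturated"]
        out.loc[use_low, "flag"] = lo.loc[use_low, "flag"]
        out["frac_pixels_gt_bg2sd"] = np.maximum(
            lo["frac_pixels_gt_bg2sd"], hi["frac_pixels_gt_bg2sd"]
        )
        out["r_squared"] = np.maximum(lo["r_squared"], hi["r_squared"])
        out["source_scan"] = np.where(use_low, "low", "high")
        merged_parts.append(out.reset_index())
    return pd.concat(merged_parts, ignore_index=True)


def fit_and_merge(low: pd.DataFrame, high: pd.DataFrame) -> tuple:
    """Convenience: calibrate every channel then merge; returns (table, calibs)."""
    calibs = {
        ch: fit_scan_calibration(low, high, ch)
        for ch in sorted(low["channel"].unique())
    }
    return merge_scans(low, high, calibs), calibs
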