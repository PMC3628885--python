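"""Feature QC filters, per-array LOWESS normalization, matrix assembly.

Four feature filters, applied to the merged scan table of each array:

1. at least 70% of pixels more than 2 SDs above background in either channel
   (consumed as the precomputed ``frac_pixels_gt_bg2sd`` column);
2. spot-regression R² strictly greater than 0.5 (feature uniformity);
3. fewer than 20% of pixels saturated in *both* channels;
4. no visual-inspection flag.

Surviving features yield M = log2(sample/reference) and A = mean log2
intensity; M is recentred by subtracting a robust LOWESS fit of M on A
(intensity-dependent dye bias removal), and the per-array results are
assembled into a genes x samples matrix keeping genes observed on at least
``presence_min`` of the arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import AssemblyError, InputError, NormalizationError

QC_COLUMNS = ("frac_pixels_gt_bg2sd", "r_squared", "frac_saturated", "flag")


@dataclass(frozen=True)
class FilterThresholds:
    min_frac_pixels_above_bg: float = 0.70
    min_r_squared: float = 0.5  # strict inequality
    max_frac_saturated_both: float = 0.20
    exclude_flagged: bool = True

    def __post_init__(self):
        for name in ("min_frac_pixels_above_bg", "min_r_squared",
                     "max_frac_saturated_both"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class LogRatioMatrix:
    """Normalized log2(sample/reference) ratios, genes x samples.

    ``values`` is a DataFrame indexed by gene id with sample-id columns
    (missing entries NaN); ``row_annot`` carries ``annotation_source`` and
    ``large_ncrna`` per gene; ``samples`` is the sample metadata table.
    """

    values: pd.DataFrame
    row_annot: pd.DataFrame = field(default_factory=pd.DataFrame)
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def genes(self):
        return self.values.index

    def categories(self) -> np.ndarray:
        lut = self.samples.set_index("sample_id")["age_category"]
        return lut.loc[self.values.columns].to_numpy()


def apply_feature_filters(
    merged: pd.DataFrame, thresholds: FilterThresholds | None = None
) -> pd.DataFrame:
    """Per-feature keep/drop decision with reason codes.

    Expects a merged scan table (rows = feature x channel).  Returns a
    DataFrame indexed by feature id with a boolean ``keep`` and a
    semicolon-joined ``reasons`` string among
    ``pixels | r_squared | saturation | flag`` (empty when kept).
    """
    t = thresholds or FilterThresholds()
    missing = [c for c in QC_COLUMNS if c not in merged.columns]
    if missing:
        raise InputError(f"missing QC columns: {missing}")
    g = merged.groupby("feature_id", sort=True)
    pix_best = g["frac_pixels_gt_bg2sd"].max()
    r2_best = g["r_squared"].max()
    sat_worst = g["frac_saturated"].min()  # saturated in BOTH = min over channels
    any_flag = g["flag"].max() > 0
    ok_pix = pix_best >= t.min_frac_pixels_above_bg
    ok_r2 = r2_best > t.min_r_squared
    ok_sat = sat_worst < t.max_frac_saturated_both
    ok_flag = ~any_flag if t.exclude_flagged else pd.Series(True, index=pix_best.index)
    keep = ok_pix & ok_r2 & ok_sat & ok_flag
    reasons = []
    for f in pix_best.index:
        r = []
        if not ok_pix[f]:
            r.append("pixels")
        if not ok_r2[f]:
            r.append("r_squared")
        if not ok_sat[f]:
            r.append("saturation")
        if not ok_flag[f]:
            r.append("flag")
        reasons.append(";".join(r))
    return pd.DataFrame({"keep": keep, "reasons": reasons}, index=pix_best.index)


def log_ratios(merged: pd.DataFrame) -> pd.DataFrame:
    """Per-feature M (log2 green/red) and A (mean log2 intensity) values."""
    green = merged[merged["channel"] == "green"].set_index("feature_id")
    red = merged[merged["channel"] == "red"].set_index("feature_id")
    if not green.index.equals(red.index):
        raise InputError("green/red channels cover different features")
    sg = np.maximum(green["median_fg"] - green["median_bg"], 1.0)
    sr = np.maximum(red["median_fg"] - red["median_bg"], 1.0)
    m = np.log2(sg) - np.log2(sr)
    a = 0.5 * (np.log2(sg) + np.log2(sr))
    return pd.DataFrame({"M": m, "A": a})


def lowess_normalize(
    m, a, span: float = 0.4, iterations: int = 3
) -> np.ndarray:
    """Recenter M-values by a robust LOWESS fit of M on A.

    Tricube-weighted local linear regression with ``iterations`` robustness
    reweightings (the usual MA-plot normalization).  Requires at least 30
    features; linear in M, so adding a constant to all M-values leaves the
    output unchanged.
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    ok = np.isfinite(m) & np.isfinite(a)
    if ok.sum() < 30:
        raise NormalizationError(
            f"only {int(ok.sum())} usable features on this array (need >= 30)"
        )
    fit = sm.nonparametric.lowess(
        m[ok], a[ok], frac=span, it=iterations, return_sorted=False
    )
    out = np.full_like(m, np.nan)
    out[ok] = m[ok] - fit
    return out


def normalize_array(
    merged: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    span: float = 0.4,
) -> pd.DataFrame:
    """Filter one array's merged table and LOWESS-normalize its log-ratios.

    Returns a DataFrame indexed by feature id with columns ``M`` (normalized
    log ratio, NaN where the feature failed QC), ``A``, ``keep`` and
    ``reasons``.  The LOWESS fit uses only passing features.
    """
    mask = apply_feature_filters(merged, thresholds)
    ma = log_ratios(merged).join(mask)
    m = ma["M"].to_numpy(float).copy()
    m[~ma["keep"].to_numpy(bool)] = np.nan
    ma["M"] = lowess_normalize(m, ma["A"].to_numpy(float), span=span)
    return ma


def assemble_matrix(
    per_array: dict,
    samples: pd.DataFrame,
    presence_min: float = 0.70,
    row_annot: pd.DataFrame | None = None,
) -> LogRatioMatrix:
    """Cross-array gene x sample matrix under the presence rule.

    ``per_array`` maps sample id to that array's :func:`normalize_array`
    output.  A gene is retained when it passed QC (non-missing normalized M)
    on at least ``presence_min`` of the arrays; remaining holes stay NaN and
    are tolerated by the per-gene fits downstream.
    """
    if len(per_array) < 2:
        raise AssemblyError("need >= 2 arrays to assemble a matrix")
    cols = {sid: df["M"] for sid, df in per_array.items()}
    values = pd.DataFrame(cols)
    values = values[list(per_array)]  # preserve sample order
    present = values.notna().mean(axis=1)
    values = values.loc[present >= presence_min]
    if values.empty:
        raise AssemblyError("no gene passes the presence rule")
    values.index.name = "gene"
    annot = pd.DataFrame(index=values.index)
    if row_annot is not None:
        annot = row_annot.reindex(values.index)
    return LogRatioMatrix(values=values, row_annot=annot, samples=samples)


def exclusion_report(masks: dict) -> dict:
    """Per-filter exclusion counts across arrays (for the QC report JSON)."""
    counts = {"pixels": 0, "r_squared": 0, "saturation": 0, "flag": 0}
    n_excluded = 0
    for df in masks.values():
        dropped = df.loc[~df["keep"], "reasons"]
        n_excluded += len(dropped)
        for rs in dropped:
            for r in rs.split(";"):
                if r:
                    counts[r] += 1
    return {"excluded_feature_arrays": n_excluded, "by_filter": counts}
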