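"""Pooled-sample qPCR relative expression: the 2^-ddCt screen.

The Ct (threshold cycle) is inversely log2-proportional to abundance.  Each
assay's Ct is normalized to the geometric mean of three small-RNA references
(RNU44, RNU48, U6) — on the Ct scale the geometric mean of linear quantities
is the arithmetic mean of Cts — giving dCt; fold changes relative to a named
reference timepoint are 2^-(dCt - dCt_ref) = 2^-ddCt.  Assays that never
amplify robustly (raw Ct > 29 at every timepoint) and passenger-strand
assays are excluded; a pooled 2-SD screen on log2 fold changes flags
single-timepoint expression spikes.  Censored reactions (Ct = 40,
"undetermined") propagate as bounds, never point values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ScreenError, TabulationError

REFERENCE_ASSAYS = ("RNU44", "RNU48", "U6")
CT_CENSOR = 40.0
DEFAULT_CT_MAX = 29.0


def _split(table: pd.DataFrame):
    """Split a Ct table into (strand Series, Ct value frame)."""
    if "strand" not in table.columns:
        raise InputError("Ct table needs a 'strand' column")
    strand = table["strand"]
    values = table.drop(columns=["strand"]).astype(float)
    if values.shape[1] < 2:
        raise InputError("Ct table needs >= 2 timepoint columns")
    return strand, values


def normalize_ct(table: pd.DataFrame, refs=REFERENCE_ASSAYS) -> pd.DataFrame:
    """dCt per assay and timepoint: Ct minus the reference-mean normalizer.

    The per-column normalizer is the arithmetic mean of the reference
    assays' Cts (equivalent to geometric-mean normalization on the linear
    2^-Ct scale).  Censored references invalidate their column.  Reference
    rows are dropped from the output.
    """
    strand, values = _split(table)
    missing = [r for r in refs if r not in values.index]
    if missing:
        raise InputError(f"reference assays missing from Ct table: {missing}")
    ref_ct = values.loc[list(refs)]
    censored_cols = ref_ct.columns[(ref_ct >= CT_CENSOR).any(axis=0)]
    if len(censored_cols):
        raise InputError(
            f"censored reference Ct in columns: {list(censored_cols)}"
        )
    normalizer = ref_ct.mean(axis=0)
    delta = values.drop(index=list(refs)) - normalizer
    return delta


def robust_expression_filter(
    table: pd.DataFrame, ct_max: float = DEFAULT_CT_MAX
) -> pd.Index:
    """Assays retained for fold-change analysis.

    Drops assays whose raw Ct exceeds ``ct_max`` at *every* timepoint (no
    robust expression anywhere) and passenger-strand assays (only mature,
    guide-strand miRNAs are analysed).  Reference rows are not returned.
    """
    strand, values = _split(table)
    target = strand.index[(strand != "reference") & (strand != "passenger")]
    expressed = (values.loc[target] <= ct_max).any(axis=1)
    return expressed.index[expressed]


@dataclass
class FoldChangeTable:
    """Fold changes relative to a reference timepoint.

    ``log2`` holds log2 fold changes (exactly 0 in the reference column);
    ``fold`` the linear 2^log2 values; ``censored`` marks entries computed
    from a censored Ct — such values are detection-limit bounds, not point
    estimates.
    """

    log2: pd.DataFrame
    reference_timepoint: str
    censored: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def fold(self) -> pd.DataFrame:
        return 2.0**self.log2


def fold_changes(
    delta: pd.DataFrame,
    reference_timepoint,
    censored: pd.DataFrame | None = None,
) -> FoldChangeTable:
    """ddCt fold changes: log2FC = -(dCt - dCt at the reference timepoint)."""
    if reference_timepoint not in delta.columns:
        raise InputError(f"reference timepoint {reference_timepoint!r} not present")
    ddct = delta.sub(delta[reference_timepoint], axis=0)
    log2 = -ddct
    if censored is None:
        censored = pd.DataFrame(False, index=delta.index, columns=delta.columns)
    else:
        censored = censored.reindex(index=delta.index, columns=delta.columns,
                                    fill_value=False)
        # a censored reference Ct censors the whole row's fold changes
        censored = censored | censored[reference_timepoint].to_numpy()[:, None]
    return FoldChangeTable(
        log2=log2, reference_timepoint=str(reference_timepoint), censored=censored
    )


def censor_mask(table: pd.DataFrame, ct_censor: float = CT_CENSOR) -> pd.DataFrame:
    """Boolean mask of censored ("undetermined", Ct >= 40) reactions."""
    _, values = _split(table)
    return values >= ct_censor


def sd_outlier_screen(
    fc: FoldChangeTable, k: float = 2.0, scale: str = "log2"
) -> pd.DataFrame:
    """Flag (assay, timepoint) entries beyond k SDs of the pooled fold changes.

    All log2 fold changes across assays and non-reference timepoints are
    pooled; entries with \\|value - mean\\| > k * SD are flagged.  ``scale``
    may be ``"log2"`` (default; symmetric in up/down) or ``"linear"``.
    Returns a tidy frame (assay, timepoint, log2fc, z, censored) sorted by
    \\|z\\| descending; per-assay any-timepoint hits are its unique assays.
    """
    cols = [c for c in fc.log2.columns if c != fc.reference_timepoint]
    pool_df = fc.log2[cols] if scale == "log2" else 2.0 ** fc.log2[cols]
    if scale not in ("log2", "linear"):
        raise ScreenError(f"unknown scale {scale!r}")
    pooled = pool_df.to_numpy().ravel()
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size < 10:
        raise ScreenError(f"need >= 10 fold-change values, have {pooled.size}")
    mu, sd = pooled.mean(), pooled.std(ddof=1)
    if not np.isfinite(k):
        return pd.DataFrame(columns=["assay_id", "timepoint", "log2fc", "z", "censored"])
    if sd == 0:
        raise ScreenError("zero-variance fold-change pool")
    z = (pool_df - mu) / sd
    hits = []
    for tp in cols:
        over = z.index[np.abs(z[tp]) > k]
        for assay in over:
            hits.append(
                (
                    assay,
                    tp,
                    float(fc.log2.loc[assay, tp]),
                    float(z.loc[assay, tp]),
                    bool(fc.censored.loc[assay, tp])
                    if not fc.censored.empty
                    else False,
                )
            )
    out = pd.DataFrame(hits, columns=["assay_id", "timepoint", "log2fc", "z", "censored"])
    return out.reindex(out["z"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


DEFAULT_BINS = (2.0, 5.0, 10.0, 100.0)
EPOCH_PAIRS = (("fetal", "adult"), ("young", "adult"), ("fetal", "young"))


def tabulate_fold_bins(
    delta: pd.DataFrame, epoch_of: dict, bins=DEFAULT_BINS
) -> pd.DataFrame:
    """Counts of assays exceeding each fold difference per epoch pair.

    ``epoch_of`` maps each timepoint column to its epoch (fetal/young/adult).
    An epoch's expression is the mean log2 relative quantity (-dCt) over its
    pools; for each ordered pair (first, second) the fold is
    2^(mean_first - mean_second).  ``increase`` counts fold > bin,
    ``decrease`` counts reciprocal fold > bin.  Result is indexed by bin with
    a (pair, direction) column MultiIndex.
    """
    unknown = [c for c in delta.columns if c not in epoch_of]
    if unknown:
        raise TabulationError(f"timepoints without epoch assignment: {unknown}")
    epoch_cols = {}
    for e in ("fetal", "young", "adult"):
        cols = [c for c in delta.columns if epoch_of[c] == e]
        if not cols:
            raise TabulationError(f"epoch {e!r} has no timepoint columns")
        epoch_cols[e] = cols
    log2q = {e: (-delta[cols]).mean(axis=1) for e, cols in epoch_cols.items()}
    data = {}
    for first, second in EPOCH_PAIRS:
        diff = log2q[first] - log2q[second]  # log2 fold, first vs second
        name = f"{first.capitalize()} vs. {second.capitalize()}"
        data[(name, "increase")] = [
            int((diff > np.log2(b)).sum()) for b in bins
        ]
        data[(name, "decrease")] = [
            int((-diff > np.log2(b)).sum()) for b in bins
        ]
    out = pd.DataFrame(data, index=pd.Index(list(bins), name="fold"))
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["pair", "direction"])
    return out


def qq_data(values) -> pd.DataFrame:
    """Sorted values vs standard-normal quantiles at Blom plotting positions.

    Used on pooled log2 fold changes to eyeball distributional shape; returns
    a frame with ``theoretical`` and ``empirical`` columns of equal length.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = np.sort(v[np.isfinite(v)])
    n = v.size
    pos = (np.arange(1, n + 1) - 0.375) / (n + 0.25)
    return pd.DataFrame({"theoretical": stats.norm.ppf(pos), "empirical": v})
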