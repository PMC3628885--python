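"""Simulation-based FDR calibration in the style of SAM.

Rather than an analytic multiple-testing correction, the false discovery
rate at a candidate p-value threshold ``t`` is estimated by permutation:
age-category labels are permuted whole-column (preserving gene-gene
correlation), every gene's omnibus p-value is recomputed, and

    FDR(t) = median over simulations of  #{null p <= t} / max(1, #{obs p <= t})

(after a running-maximum monotone adjustment in ``t``).  The chosen
threshold is the largest observed p-value whose estimated FDR does not
exceed the target rate — by default 1%, the rate the analysis is designed
around.  With none qualifying, the smallest observed p is reported with
zero discoveries.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .anova import covariate_scan, omnibus_pvalues
from .errors import CalibrationError

DEFAULT_TARGET_FDR = 0.01
DEFAULT_N_SIMULATIONS = 2500


@dataclass(frozen=True)
class CalibrationResult:
    threshold: float
    target_fdr: float
    n_simulations: int
    estimated_fdr: float
    n_discoveries: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "target_fdr": self.target_fdr,
            "n_simulations": self.n_simulations,
            "estimated_fdr": self.estimated_fdr,
            "n_discoveries": self.n_discoveries,
            "seed": self.seed,
        }


def _n_distinct_permutations(categories) -> float:
    counts = Counter(categories)
    n = sum(counts.values())
    out = math.factorial(n)
    for c in counts.values():
        out //= math.factorial(c)
    return out


def simulate_null_pvalues(
    X, categories, n_sims: int, seed: int | None = None, rng=None
) -> np.ndarray:
    """Permutation-null omnibus p-values, shape (n_sims, n_genes).

    Each simulation permutes the category labels across samples (equivalently
    permutes whole columns, preserving the gene-gene correlation structure)
    and recomputes every gene's omnibus p-value.  For tiny designs with fewer
    distinct label permutations than ``n_sims`` a warning is issued (sampling
    is with replacement regardless).
    """
    if n_sims < 1:
        raise CalibrationError("n_sims must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    categories = np.asarray(categories)
    if len(set(categories.tolist())) < 2:
        raise CalibrationError("need >= 2 categories")
    if _n_distinct_permutations(categories) < n_sims:
        warnings.warn(
            "fewer distinct label permutations than requested simulations; "
            "sampling with replacement",
            stacklevel=2,
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    pools = np.empty((n_sims, X.shape[0]))
    for s in range(n_sims):
        perm = rng.permutation(len(categories))
        pools[s] = omnibus_pvalues(X, categories[perm])
    return pools


def simulate_null_pvalues_covariate(
    X, covariate, n_sims: int, seed: int | None = None, rng=None
) -> np.ndarray:
    """Permutation null for the within-period covariate scan.

    Same machinery as :func:`simulate_null_pvalues` but permuting the numeric
    covariate (gestational weeks or postnatal days) across samples and
    recomputing slope-test p-values.
    """
    if n_sims < 1:
        raise CalibrationError("n_sims must be >= 1")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    covariate = np.asarray(covariate, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    pools = np.empty((n_sims, X.shape[0]))
    for s in range(n_sims):
        perm = rng.permutation(len(covariate))
        pools[s] = covariate_scan(X, covariate[perm])["p_value"].to_numpy()
    return pools


def calibrate_threshold(
    observed_p,
    null_pools,
    target_fdr: float = DEFAULT_TARGET_FDR,
    summary: str = "median",
    seed: int | None = None,
) -> CalibrationResult:
    """Choose the loosest p-value threshold with estimated FDR <= target.

    Candidate thresholds are the sorted observed p-values.  ``summary`` is
    the statistic taken across simulations of the null exceedance count
    (``median`` by default, ``mean`` available).
    """
    if not 0 < target_fdr <= 1:
        raise CalibrationError("target_fdr must be in (0,1]")
    observed_p = np.asarray(observed_p, dtype=float)
    observed_p = observed_p[np.isfinite(observed_p)]
    if observed_p.size == 0:
        raise CalibrationError("empty observed p-value set")
    null_pools = np.asarray(null_pools, dtype=float)
    if null_pools.ndim == 1:
        null_pools = null_pools[None, :]
    if null_pools.size == 0:
        raise CalibrationError("empty null pools")
    n_sims = null_pools.shape[0]

    obs_sorted = np.sort(observed_p)
    thresholds = obs_sorted
    # counts of observed p <= t for each candidate t (ties inclusive)
    obs_counts = np.searchsorted(obs_sorted, thresholds, side="right")
    null_counts = np.empty((n_sims, thresholds.size))
    for s in range(n_sims):
        null_counts[s] = np.searchsorted(
            np.sort(null_pools[s]), thresholds, side="right"
        )
    if summary == "median":
        null_summary = np.median(null_counts, axis=0)
    elif summary == "mean":
        null_summary = null_counts.mean(axis=0)
    else:
        raise CalibrationError(f"unknown summary {summary!r}")
    est = null_summary / np.maximum(obs_counts, 1)
    # monotone non-decreasing in t via the standard q-value-style adjustment:
    # est(t) <- min over t' >= t of est(t').  (A left-to-right running maximum
    # is also monotone but lets the noisy tiny-denominator estimates at the
    # smallest thresholds poison the whole curve.)
    est = np.minimum.accumulate(est[::-1])[::-1]
    ok = est <= target_fdr
    if ok.any():
        idx = np.max(np.flatnonzero(ok))
        threshold = float(thresholds[idx])
        return CalibrationResult(
            threshold=threshold,
            target_fdr=target_fdr,
            n_simulations=n_sims,
            estimated_fdr=float(est[idx]),
            n_discoveries=int(obs_counts[idx]),
            seed=seed,
        )
    return CalibrationResult(
        threshold=float(thresholds[0]),
        target_fdr=target_fdr,
        n_simulations=n_sims,
        estimated_fdr=float(est[0]),
        n_discoveries=0,
        seed=seed,
    )


def calibrate(
    X,
    categories,
    target_fdr: float = DEFAULT_TARGET_FDR,
    n_sims: int = DEFAULT_N_SIMULATIONS,
    seed: int | None = None,
    summary: str = "median",
) -> CalibrationResult:
    """End-to-end calibration: observed p's, permutation nulls, threshold."""
    observed = omnibus_pvalues(X, categories)
    pools = simulate_null_pvalues(X, categories, n_sims, seed=seed)
    return calibrate_threshold(observed, pools, target_fdr, summary=summary, seed=seed)


def bh_threshold(observed_p, target_fdr: float = DEFAULT_TARGET_FDR) -> float:
    """Benjamini-Hochberg step-up threshold (analytic cross-check only)."""
    p = np.sort(np.asarray(observed_p, dtype=float))
    n = p.size
    crit = target_fdr * np.arange(1, n + 1) / n
    ok = np.flatnonzero(p <= crit)
    return float(p[ok.max()]) if ok.size else 0.0
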