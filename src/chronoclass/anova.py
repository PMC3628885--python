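"""Per-gene ANOVA, backward model selection and directional classification.

Each gene's expression (normalized log2 sample/reference ratios) is modelled
by one mean per age category (fetal, young, adult).  Two questions are asked
per gene:

1. *Is anything changing?*  Answered by the classical one-way omnibus F test
   of the three-mean model against a single common mean.  Its p-value is
   exactly uniform under a Gaussian null, which is what the simulation-based
   FDR calibration (see :mod:`chronoclass.fdr`) requires of its input.
2. *What is changing?*  Answered by backward model selection at a working
   significance level ``alpha``: starting from three distinct means, the two
   merges of adjacent groups (adjacent in estimated-mean order) are tested by
   partial F tests against the current model; the merge with the largest
   p-value is applied if that p exceeds ``alpha``, and the procedure repeats
   until no merge is acceptable or all means are merged.  The surviving
   structure, ordered by its estimated group means, is the gene's mean
   pattern (model class), e.g. ``F<Y=A``.

The greedy merge path is data-driven and does not depend on ``alpha``; only
the stopping point does.  ``path_p`` — the smallest partial-F p along the
path — is therefore the smallest ``alpha`` at which a gene retains any
structure, and is reported alongside the omnibus p-value.

All heavy lifting is vectorized across genes; :func:`fit_gene` is a thin
single-gene wrapper returning a :class:`GeneFit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ScanError
from .patterns import (
    CANONICAL_LABELS,
    MeanPattern,
    pattern_by_label,
    pattern_from_ordered_groups,
)

#: Category display letters in fixed order; codes 0, 1, 2.
CATEGORY_LETTERS = ("F", "Y", "A")
CATEGORY_NAMES = ("fetal", "young", "adult")

_EPS = 1e-12


def encode_categories(categories) -> np.ndarray:
    """Map category labels (names or letters) to integer codes 0/1/2."""
    lut = {}
    for code, (name, letter) in enumerate(zip(CATEGORY_NAMES, CATEGORY_LETTERS)):
        lut[name] = code
        lut[letter] = code
    try:
        return np.array([lut[str(c)] for c in categories], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - defensive
        raise FitError(f"unknown age category {exc}") from None


# ---------------------------------------------------------------------------
# vectorized class-index lookups
# ---------------------------------------------------------------------------


def _build_lookup_tables():
    """Class-index lookups for vectorized pattern assignment.

    ``strict[perm]`` maps the ascending-mean permutation of category codes
    (encoded base 3) to the canonical class index of the strict ordering.
    ``twogroup[singleton, is_high]`` maps the singleton category and whether
    it sits above the merged pair to the class index.
    """
    strict = np.zeros(27, dtype=np.intp)
    for perm_codes in [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]:
        groups = tuple(frozenset({CATEGORY_LETTERS[c]}) for c in perm_codes)
        pat = pattern_from_ordered_groups(groups)
        strict[perm_codes[0] * 9 + perm_codes[1] * 3 + perm_codes[2]] = (
            CANONICAL_LABELS.index(pat.label) + 1
        )
    twogroup = np.zeros((3, 2), dtype=np.intp)
    for s in range(3):
        rest = frozenset(CATEGORY_LETTERS[c] for c in range(3) if c != s)
        single = frozenset({CATEGORY_LETTERS[s]})
        for is_high, groups in ((0, (single, rest)), (1, (rest, single))):
            pat = pattern_from_ordered_groups(groups)
            twogroup[s, is_high] = CANONICAL_LABELS.index(pat.label) + 1
    return strict, twogroup


_STRICT_LUT, _TWOGROUP_LUT = _build_lookup_tables()
_ALL_EQUAL_CLASS = CANONICAL_LABELS.index("F=Y=A") + 1


def _group_stats(X: np.ndarray, codes: np.ndarray):
    """Missing-data-aware per-group counts, means and total sum of squares."""
    mask = np.isfinite(X)
    Xz = np.where(mask, X, 0.0)
    ns = np.stack([mask[:, codes == g].sum(axis=1) for g in range(3)], axis=1)
    sums = np.stack([Xz[:, codes == g].sum(axis=1) for g in range(3)], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    ss = (Xz**2).sum(axis=1)
    return ns, means, sums, ss


def _safe_f_sf(num_dev: np.ndarray, rss: np.ndarray, df1, df2: np.ndarray,
               scale: np.ndarray) -> np.ndarray:
    """p-value of a partial F test, robust to exact fits (rss ~ 0).

    ``num_dev`` is the RSS increase of the restriction (numerator on df1 df),
    ``rss`` the residual SS of the fuller model on ``df2`` df.  When the
    residual variance is exactly zero the test degenerates: p = 0 if the
    restriction costs anything, 1 otherwise.
    """
    tol = _EPS * np.maximum(scale, 1.0)
    ok = (rss > tol) & (df2 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (num_dev / df1) / np.where(ok, rss / np.maximum(df2, 1), np.nan)
    p = np.where(ok, stats.f.sf(np.where(ok, F, 0.0), df1, np.maximum(df2, 1)), np.nan)
    exact = ~ok
    p = np.where(exact & (num_dev > tol), 0.0, p)
    p = np.where(exact & (num_dev <= tol), 1.0, p)
    return p


def omnibus_pvalues(X: np.ndarray, categories) -> np.ndarray:
    """One-way omnibus ANOVA p-value per gene (row of ``X``).

    Tests the per-category-mean model against a single common mean over the
    categories actually observed for that gene; missing values tolerated.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    codes = encode_categories(categories)
    ns, means, sums, ss = _group_stats(X, codes)
    present = ns > 0
    k = present.sum(axis=1)
    N = ns.sum(axis=1)
    m2 = np.where(present, means, 0.0) ** 2
    rss_full = ss - (ns * m2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        grand = sums.sum(axis=1) / np.maximum(N, 1)
    rss_null = ss - N * grand**2
    between = np.maximum(rss_null - rss_full, 0.0)
    df1 = np.maximum(k - 1, 1)
    df2 = N - k
    p = _safe_f_sf(between, rss_full, df1, df2, ss)
    p = np.where(k < 2, 1.0, p)
    return p


# ---------------------------------------------------------------------------
# backward model selection
# ---------------------------------------------------------------------------


def select_patterns(X: np.ndarray, categories, alpha: float):
    """Vectorized backward model selection for every gene.

    Returns a dict of arrays: ``class_index`` (1..13, 0 where a category is
    entirely missing), ``p_value`` (omnibus), ``path_p``, per-category means
    and counts, and ``exact_fit`` flags.  Genes with a missing category get
    ``class_index`` 0 and NaN pattern downstream; their omnibus p is still
    computed over the present categories.
    """
    if not 0 < alpha < 1:
        raise FitError(f"alpha must be in (0,1), got {alpha}")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    codes = encode_categories(categories)
    ns, means, sums, ss = _group_stats(X, codes)
    G = X.shape[0]
    N = ns.sum(axis=1)
    present_all = (ns > 0).all(axis=1)

    p_omni = omnibus_pvalues(X, categories)

    m2 = np.where(ns > 0, means, 0.0) ** 2
    rss_full = ss - (ns * m2).sum(axis=1)

    # Work on a safe copy for genes lacking a category; results masked later.
    means_s = np.where(ns > 0, means, 0.0)
    order = np.argsort(means_s, axis=1, kind="stable")
    ms = np.take_along_axis(means_s, order, axis=1)
    nss = np.take_along_axis(ns, order, axis=1).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        d01 = nss[:, 0] * nss[:, 1] / np.maximum(nss[:, 0] + nss[:, 1], 1) \
            * (ms[:, 0] - ms[:, 1]) ** 2
        d12 = nss[:, 1] * nss[:, 2] / np.maximum(nss[:, 1] + nss[:, 2], 1) \
            * (ms[:, 1] - ms[:, 2]) ** 2
    merge01 = d01 <= d12
    dmin = np.where(merge01, d01, d12)
    p1 = _safe_f_sf(dmin, rss_full, 1, N - 3, ss)

    # two-group model after the greedy merge
    nA = np.where(merge01, nss[:, 0] + nss[:, 1], nss[:, 0])
    nB = np.where(merge01, nss[:, 2], nss[:, 1] + nss[:, 2])
    with np.errstate(invalid="ignore", divide="ignore"):
        mA = np.where(
            merge01,
            (nss[:, 0] * ms[:, 0] + nss[:, 1] * ms[:, 1]) / np.maximum(nA, 1),
            ms[:, 0],
        )
        mB = np.where(
            merge01,
            ms[:, 2],
            (nss[:, 1] * ms[:, 1] + nss[:, 2] * ms[:, 2]) / np.maximum(nB, 1),
        )
    rss2 = rss_full + dmin
    d2 = nA * nB / np.maximum(nA + nB, 1) * (mA - mB) ** 2
    p2 = _safe_f_sf(d2, rss2, 1, N - 2, ss)
    path_p = np.minimum(p1, p2)

    accept1 = p1 > alpha
    accept2 = p2 > alpha

    # class index, vectorized
    perm_code = order[:, 0] * 9 + order[:, 1] * 3 + order[:, 2]
    cls_strict = _STRICT_LUT[perm_code]
    singleton = np.where(merge01, order[:, 2], order[:, 0])
    cls_two = _TWOGROUP_LUT[singleton, merge01.astype(np.intp)]
    class_index = np.where(
        ~accept1, cls_strict, np.where(~accept2, cls_two, _ALL_EQUAL_CLASS)
    )
    class_index = np.where(present_all, class_index, 0)
    # exact-fit genes (zero residual variance) still classify by their means
    tol = _EPS * np.maximum(ss, 1.0)
    exact = rss_full <= tol

    path_p = np.where(present_all, path_p, np.nan)
    return {
        "class_index": class_index.astype(np.intp),
        "p_value": p_omni,
        "path_p": path_p,
        "means": means,
        "ns": ns,
        "sigma2": np.where(N - (ns > 0).sum(axis=1) > 0,
                           rss_full / np.maximum(N - (ns > 0).sum(axis=1), 1),
                           np.nan),
        "exact_fit": exact,
        "missing_category": ~present_all,
        "n_genes": G,
    }


def fit_genes(X, categories, alpha: float, gene_ids=None) -> pd.DataFrame:
    """Backward-selection fits for all genes as a tidy DataFrame.

    Columns: ``gene, partition, pattern, class_index, p_value, path_p,
    mean_F, mean_Y, mean_A, n_F, n_Y, n_A, sigma2, flags``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    res = select_patterns(X, categories, alpha)
    G = res["n_genes"]
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(G)]
    labels = np.array([""] + list(CANONICAL_LABELS), dtype=object)
    pat = labels[res["class_index"]]
    partition = np.array(
        [_partition_string(lab) if lab else "" for lab in pat], dtype=object
    )
    flags = []
    for i in range(G):
        f = []
        if res["missing_category"][i]:
            f.append("missing_category")
        if res["exact_fit"][i]:
            f.append("exact_fit")
        flags.append(";".join(f))
    return pd.DataFrame(
        {
            "gene": gene_ids,
            "partition": partition,
            "pattern": pat,
            "class_index": res["class_index"],
            "p_value": res["p_value"],
            "path_p": res["path_p"],
            "mean_F": res["means"][:, 0],
            "mean_Y": res["means"][:, 1],
            "mean_A": res["means"][:, 2],
            "n_F": res["ns"][:, 0],
            "n_Y": res["ns"][:, 1],
            "n_A": res["ns"][:, 2],
            "sigma2": res["sigma2"],
            "flags": flags,
        }
    )


def _partition_string(label: str) -> str:
    """Partition spelling (``F|YA``, ``FY|A``, ``FA|Y``, ``F|Y|A``, ``FYA``)."""
    pat = pattern_by_label(label)
    blocks = sorted(
        ("".join(c for c in CATEGORY_LETTERS if c in g) for g in pat.groups),
        key=lambda b: CATEGORY_LETTERS.index(b[0]),
    )
    return "|".join(blocks)


@dataclass
class GeneFit:
    """Result of backward model selection for a single gene."""

    gene: str
    partition: str
    pattern: MeanPattern | None
    p_value: float
    path_p: float
    means: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)
    sigma2: float = float("nan")
    flags: tuple = ()


def fit_gene(values, categories, alpha: float, gene: str = "gene") -> GeneFit:
    """Fit a single gene; see module docstring for the selection procedure.

    ``values`` may contain NaN; at least two categories must have ≥1 usable
    value (two non-missing values overall in ≥2 categories).
    """
    values = np.asarray(values, dtype=float)
    codes = encode_categories(categories)
    finite = np.isfinite(values)
    n_cats = len({int(c) for c in codes[finite]})
    if finite.sum() < 2 or n_cats < 2:
        raise FitError("need >=2 non-missing values in >=2 categories")
    df = fit_genes(values[None, :], categories, alpha, gene_ids=[gene])
    row = df.iloc[0]
    pattern = pattern_by_label(row["pattern"]) if row["pattern"] else None
    return GeneFit(
        gene=gene,
        partition=row["partition"],
        pattern=pattern,
        p_value=float(row["p_value"]),
        path_p=float(row["path_p"]),
        means={L: float(row[f"mean_{L}"]) for L in CATEGORY_LETTERS},
        n={L: int(row[f"n_{L}"]) for L in CATEGORY_LETTERS},
        sigma2=float(row["sigma2"]),
        flags=tuple(f for f in row["flags"].split(";") if f),
    )


def classify_direction(fit: GeneFit) -> MeanPattern:
    """Directional pattern implied by a fit's partition and estimated means.

    Groups are ordered by their (sample-size weighted) estimated means; exact
    ties between distinct groups are resolved conservatively by merging.
    """
    if fit.pattern is None:
        raise FitError("fit is restricted (missing category); no 3-way pattern")
    blocks = fit.partition.split("|")
    stats_ = []
    for b in blocks:
        w = sum(fit.n[c] for c in b)
        m = sum(fit.n[c] * fit.means[c] for c in b) / max(w, 1)
        stats_.append((m, frozenset(b)))
    stats_.sort(key=lambda t: t[0])
    # conservative tie merging
    groups: list[tuple[float, set]] = []
    for m, g in stats_:
        if groups and abs(m - groups[-1][0]) <= _EPS * max(1.0, abs(m)):
            groups[-1] = (groups[-1][0], groups[-1][1] | set(g))
        else:
            groups.append((m, set(g)))
    return pattern_from_ordered_groups(tuple(frozenset(g) for _, g in groups))


# ---------------------------------------------------------------------------
# covariate scans and diagnostics
# ---------------------------------------------------------------------------


def covariate_scan(X, covariate, gene_ids=None) -> pd.DataFrame:
    """Per-gene simple linear regression of expression on a numeric covariate.

    Used within one age period (gestational weeks within fetal samples, days
    within young).  Returns slope, slope-test p-value and the per-gene sample
    count; constant genes get slope 0 and p 1.  The p-values feed the same
    permutation-based FDR calibration as the category analysis.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    cov = np.asarray(covariate, dtype=float)
    usable = np.isfinite(cov)
    if usable.sum() < 3:
        raise ScanError("need >=3 samples with the covariate")
    X = X[:, usable]
    cov = cov[usable]
    mask = np.isfinite(X)
    nv = mask.sum(axis=1)
    Xz = np.where(mask, X, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_c = (mask * cov).sum(axis=1) / np.maximum(nv, 1)
        mean_x = Xz.sum(axis=1) / np.maximum(nv, 1)
        dc = np.where(mask, cov[None, :] - mean_c[:, None], 0.0)
        dx = np.where(mask, X - mean_x[:, None], 0.0)
        sxy = (dc * dx).sum(axis=1)
        scc = (dc**2).sum(axis=1)
        sxx = (dx**2).sum(axis=1)
        slope = np.where(scc > 0, sxy / np.maximum(scc, _EPS), 0.0)
        r2 = np.where(
            (scc > 0) & (sxx > 0), sxy**2 / np.maximum(scc * sxx, _EPS), 0.0
        )
        r2 = np.clip(r2, 0.0, 1.0)
        df = nv - 2
        t2 = np.where(df > 0, r2 * df / np.maximum(1 - r2, _EPS), 0.0)
    p = np.where(
        (df > 0) & (sxx > 0) & (scc > 0) & (r2 < 1),
        2 * stats.t.sf(np.sqrt(np.maximum(t2, 0.0)), np.maximum(df, 1)),
        np.where((r2 >= 1) & (df > 0), 0.0, 1.0),
    )
    p = np.where(sxx <= 0, 1.0, p)  # constant expression: no evidence
    if gene_ids is None:
        gene_ids = [f"gene_{i:05d}" for i in range(X.shape[0])]
    return pd.DataFrame({"gene": gene_ids, "slope": slope, "p_value": p, "n": nv})


def residual_diagnostics(X, categories) -> dict:
    """Pooled residual normality and variance-homogeneity summaries.

    Residuals are taken around the per-gene per-category means, standardized
    by each gene's residual SD, pooled across genes, and summarised as a
    normal Q-Q slope (Blom plotting positions), excess kurtosis, and
    per-category variance ratios.  Report only — nothing is gated on it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.size == 0 or X.shape[0] == 0:
        return {"n_residuals": 0, "qq_slope": float("nan"),
                "excess_kurtosis": float("nan"), "variance_ratio": {}}
    codes = encode_categories(categories)
    ns, means, _, ss = _group_stats(X, codes)
    fitted = np.full_like(X, np.nan)
    for g in range(3):
        cols = codes == g
        fitted[:, cols] = means[:, g][:, None]
    resid = X - fitted
    k = (ns > 0).sum(axis=1)
    N = ns.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m2 = np.where(ns > 0, means, 0.0) ** 2
        rss = ss - (ns * m2).sum(axis=1)
        sigma = np.sqrt(np.maximum(rss, 0.0) / np.maximum(N - k, 1))
    keep = (sigma > 0) & (N - k > 0)
    std = resid[keep] / sigma[keep][:, None]
    pooled = std[np.isfinite(std)]
    if pooled.size < 3:
        return {"n_residuals": int(pooled.size), "qq_slope": float("nan"),
                "excess_kurtosis": float("nan"), "variance_ratio": {}}
    srt = np.sort(pooled)
    n = srt.size
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    qq_slope = float(np.polyfit(q, srt, 1)[0])
    var_ratio = {}
    overall = float(np.nanvar(resid[keep]))
    for g, name in enumerate(CATEGORY_NAMES):
        cols = codes == g
        v = resid[keep][:, cols]
        v = v[np.isfinite(v)]
        var_ratio[name] = float(v.var() / overall) if v.size > 1 and overall > 0 else float("nan")
    return {
        "n_residuals": int(n),
        "qq_slope": qq_slope,
        "excess_kurtosis": float(stats.kurtosis(pooled, fisher=True)),
        "variance_ratio": var_ratio,
    }
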