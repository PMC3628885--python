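"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design it is meant to exercise: dual-channel
spotted arrays where each sample (Cy3, "green") is competitively hybridized
against a common reference pool (Cy5, "red") mixed from all samples; each
array scanned twice, at 10% laser power (in range) and at 100% power (gain
~10x, bright features clipped at the 16-bit ceiling); per-feature pixel-QC
summary columns of the kind a GenePix/Acuity export carries; and pooled
TaqMan Ct tables with three small-RNA reference assays (RNU44, RNU48, U6).

True expression structure is planted per feature as one of the 13 mean
patterns over the fetal/young/adult category means (see
:mod:`chronoclass.patterns`); per-sample log2 ratios are the category mean
plus i.i.d. Gaussian noise.  Everything is driven by one integer seed and is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .patterns import CANONICAL_LABELS, pattern_by_label

REFERENCE_ASSAYS = ("RNU44", "RNU48", "U6")

#: default class mix: 90% flat, the rest spread evenly over the 12
#: directional classes (the regime the calibration studies use).
_DIRECTIONAL = tuple(lab for lab in CANONICAL_LABELS if lab != "F=Y=A")


def default_class_mix(frac_nonnull: float = 0.10) -> dict:
    mix = {lab: frac_nonnull / len(_DIRECTIONAL) for lab in _DIRECTIONAL}
    mix["F=Y=A"] = 1.0 - frac_nonnull
    return mix


@dataclass
class SynthConfig:
    """Knobs of the synthetic study.

    The defaults mirror the emulated design: 1083 array features of which 373
    are vendor-predicted "novel" sequences, an unbalanced 36/9/2
    fetal/young/adult sample layout, a 10x gain between scans clipped at the
    16-bit ceiling, and a 90/10 null/directional class mix with mean
    separation ``effect_size`` = 6 noise SDs between unequal category means.
    """

    n_features: int = 1083
    frac_novel: float = 373 / 1083
    n_samples_per_category: dict = field(
        default_factory=lambda: {"fetal": 36, "young": 9, "adult": 2}
    )
    class_mix: dict = field(default_factory=default_class_mix)
    effect_size: float = 1.5  # log2 units between unequal adjacent means
    noise_sd: float = 0.25  # log2 units
    sat_threshold: float = 65535.0
    seed: int = 0

    # array plumbing
    gain: float = 10.0  # 100% vs 10% scan
    scan_noise_sd: float = 0.03  # multiplicative (log) noise between scans
    ref_log2_range: tuple = (8.0, 13.0)  # reference-pool feature brightness
    bg_mean: float = 100.0
    bg_sd: float = 15.0
    dye_bias: float = 0.3  # constant M offset, removed by LOWESS
    dye_bias_slope: float = -0.05  # intensity-dependent M trend
    qc_fail_frac: dict = field(
        default_factory=lambda: {"pixels": 0.03, "r_squared": 0.02, "flag": 0.01}
    )
    frac_large_ncrna: float = 0.10  # of novel features

    # TaqMan plumbing
    n_assays: int = 120
    frac_passenger: float = 0.15
    frac_low_expressed: float = 0.10  # raw Ct > 29 everywhere
    frac_spike: float = 0.05
    spike_log2: float = 6.0
    taqman_noise_sd: float = 0.15  # cycles
    ref_cts: dict = field(
        default_factory=lambda: {"RNU44": 20.0, "RNU48": 22.0, "U6": 24.0}
    )
    ct_censor: float = 40.0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        if not 0 <= self.frac_novel <= 1:
            raise ConfigError("frac_novel must be in [0,1]")
        if set(self.n_samples_per_category) != {"fetal", "young", "adult"}:
            raise ConfigError("n_samples_per_category needs fetal/young/adult keys")
        if any(v < 1 for v in self.n_samples_per_category.values()):
            raise ConfigError("all category counts must be >= 1")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_mix fractions sum to {total}, not 1")
        unknown = set(self.class_mix) - set(CANONICAL_LABELS)
        if unknown:
            raise ConfigError(f"unknown mean-pattern labels in class_mix: {unknown}")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not set(REFERENCE_ASSAYS) <= set(self.ref_cts):
            raise ConfigError(f"ref_cts must include {REFERENCE_ASSAYS}")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


def _largest_remainder_counts(n: int, fracs: dict) -> dict:
    """Integer counts per key summing to n, proportional to ``fracs``."""
    keys = list(fracs)
    raw = np.array([fracs[k] * n for k in keys])
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[:short]:
        base[i] += 1
    return dict(zip(keys, base))


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------


def generate_sample_table(config: SynthConfig) -> pd.DataFrame:
    """One row per donor sample: id, age category, age, TaqMan pool.

    Fetal samples get gestational weeks uniform over 14-24; young samples get
    postnatal ages in days (5-300); adults carry no age.  The pool id groups
    samples of identical age within a category (the scheme used to mix RNA
    for the TaqMan arrays), numbered in developmental order.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    rows = []
    nf = config.n_samples_per_category["fetal"]
    ny = config.n_samples_per_category["young"]
    na = config.n_samples_per_category["adult"]
    weeks = np.sort(rng.integers(14, 25, size=nf))
    for i, w in enumerate(weeks):
        rows.append((f"F{i + 1:02d}", "fetal", int(w), np.nan))
    days = np.sort(rng.integers(5, 301, size=ny))
    for i, d in enumerate(days):
        rows.append((f"Y{i + 1:02d}", "young", np.nan, int(d)))
    for i in range(na):
        rows.append((f"A{i + 1:02d}", "adult", np.nan, np.nan))
    df = pd.DataFrame(
        rows, columns=["sample_id", "age_category", "gestational_weeks", "postnatal_days"]
    )
    # pools: unique fetal weeks in order, then unique young day values, then adult
    pool = np.zeros(len(df), dtype=int)
    next_pool = 1
    for w in sorted(set(weeks)):
        pool[(df["age_category"] == "fetal") & (df["gestational_weeks"] == w)] = next_pool
        next_pool += 1
    for d in sorted(set(days)):
        pool[(df["age_category"] == "young") & (df["postnatal_days"] == d)] = next_pool
        next_pool += 1
    pool[df["age_category"] == "adult"] = next_pool
    df["pool"] = pool
    return df


# ---------------------------------------------------------------------------
# array scans
# ---------------------------------------------------------------------------


def _feature_truth(config: SynthConfig, rng) -> pd.DataFrame:
    n = config.n_features
    n_novel = int(round(config.frac_novel * n))
    source = np.array(["known"] * (n - n_novel) + ["novel"] * n_novel, dtype=object)
    rng.shuffle(source)
    feature_ids = np.array(
        [
            f"sim-miR-{i + 1:04d}" if s == "known" else f"sim-novel-{i + 1:04d}"
            for i, s in enumerate(source)
        ],
        dtype=object,
    )
    counts = _largest_remainder_counts(n, config.class_mix)
    patterns = np.concatenate([[lab] * c for lab, c in counts.items()]).astype(object)
    rng.shuffle(patterns)
    means = np.zeros((n, 3))
    for i, lab in enumerate(patterns):
        pat = pattern_by_label(lab)
        g = pat.n_groups
        for j, letter in enumerate(("F", "Y", "A")):
            rank = pat.rank_of(letter)
            means[i, j] = (rank - (g - 1) / 2) * config.effect_size
    large = np.zeros(n, dtype=bool)
    novel_idx = np.flatnonzero(source == "novel")
    n_large = int(round(config.frac_large_ncrna * len(novel_idx)))
    if n_large:
        large[rng.choice(novel_idx, size=n_large, replace=False)] = True
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "pattern": patterns,
            "mean_F": means[:, 0],
            "mean_Y": means[:, 1],
            "mean_A": means[:, 2],
            "annotation_source": source,
            "large_ncrna": large,
        }
    )


def _array_qc(config, weak, rng):
    """Per-array QC realization, shared by both scans of the array.

    A bad spot is a physical property of the printed array, so its QC
    summaries are drawn once per feature x channel and reused for the 10%-
    and 100%-power scans.  ``weak`` maps filter name -> boolean per-feature
    chronic-weakness flags; weak features fail their filter on most arrays,
    sound ones almost never.
    """
    n = len(next(iter(weak.values())))
    qc = {}
    for channel in ("green", "red"):
        fail_p = {
            f: np.where(weak[f], 0.85, 0.005) for f in ("pixels", "r_squared", "flag")
        }
        pix = rng.uniform(0.85, 1.0, size=n)
        bad_pix = rng.random(n) < fail_p["pixels"]
        pix = np.where(bad_pix, rng.uniform(0.3, 0.69, size=n), pix)
        r2 = rng.uniform(0.7, 0.99, size=n)
        bad_r2 = rng.random(n) < fail_p["r_squared"]
        r2 = np.where(bad_r2, rng.uniform(0.1, 0.5, size=n), r2)
        flag = (rng.random(n) < fail_p["flag"]).astype(int)
        bg = np.maximum(rng.normal(config.bg_mean, config.bg_sd / 3, size=n), 1.0)
        qc[channel] = {"pix": pix, "r2": r2, "flag": flag, "bg": bg}
    return qc


def _scan_table(config, feature_ids, source, signals, qc, rng, power):
    """Assemble one ScanTable (rows = feature x channel) from true signals.

    ``signals`` maps channel name -> true foreground signal above background
    at this power (already gain-scaled and clipped for the 100% scan);
    ``qc`` is the array's shared QC realization from :func:`_array_qc`.
    """
    n = len(feature_ids)
    frames = []
    for channel in ("green", "red"):
        sig = signals[channel]
        ch = qc[channel]
        frac_sat = np.where(
            sig >= config.sat_threshold - 0.5,
            np.clip(0.25 + rng.uniform(0, 0.6, size=n), 0, 1),
            rng.uniform(0, 0.02, size=n),
        )
        frames.append(
            pd.DataFrame(
                {
                    "feature_id": feature_ids,
                    "annotation_source": source,
                    "channel": channel,
                    "scan_power": power,
                    "median_fg": np.round(sig + ch["bg"], 2),
                    "median_bg": np.round(ch["bg"], 2),
                    "bg_sd": np.round(ch["bg"] * 0.1, 2),
                    "frac_pixels_gt_bg2sd": np.round(ch["pix"], 4),
                    "r_squared": np.round(ch["r2"], 4),
                    "frac_saturated": np.round(frac_sat, 4),
                    "flag": ch["flag"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_array_dataset(config: SynthConfig):
    """Dual-scan tables for every array plus sample metadata and truth.

    Returns ``(scans, samples, truth)`` where ``scans`` maps sample id to a
    ``{"low": ScanTable, "high": ScanTable}`` pair, one array per sample.
    The 100%-power scan is ``gain`` times the 10%-power scan with
    multiplicative noise, clipped at ``sat_threshold``; the sample channel
    carries the planted log-ratio plus an intensity-dependent dye bias that
    LOWESS normalization is expected to remove.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    truth = _feature_truth(config, rng)
    samples = generate_sample_table(config)
    n = config.n_features
    lo, hi = config.ref_log2_range
    ref_log2 = rng.uniform(lo, hi, size=n)
    cat_col = {"fetal": "mean_F", "young": "mean_Y", "adult": "mean_A"}
    # chronic per-feature weakness: these features fail their filter on most
    # arrays and are removed by the cross-array presence rule
    weak = {
        f: rng.random(n) < config.qc_fail_frac.get(f, 0.0)
        for f in ("pixels", "r_squared", "flag")
    }
    scans = {}
    true_ratios = np.zeros((n, len(samples)))
    for j, row in enumerate(samples.itertuples()):
        mu = truth[cat_col[row.age_category]].to_numpy()
        lr = mu + rng.normal(0.0, config.noise_sd, size=n)
        true_ratios[:, j] = lr
        a = ref_log2  # mean log2 intensity proxy
        bias = config.dye_bias + config.dye_bias_slope * (a - a.mean())
        green_low = 2.0 ** (ref_log2 + (lr + bias) / 2.0)
        red_low = 2.0 ** (ref_log2 - (lr + bias) / 2.0)
        signals_low = {"green": green_low, "red": red_low}
        signals_high = {}
        for ch, sig in signals_low.items():
            noisy = config.gain * sig * np.exp(
                rng.normal(0.0, config.scan_noise_sd, size=n)
            )
            signals_high[ch] = np.minimum(noisy, config.sat_threshold)
        qc = _array_qc(config, weak, rng)
        low = _scan_table(
            config, truth["feature_id"], truth["annotation_source"],
            signals_low, qc, rng, 10,
        )
        high = _scan_table(
            config, truth["feature_id"], truth["annotation_source"],
            signals_high, qc, rng, 100,
        )
        scans[row.sample_id] = {"low": low, "high": high}
    truth = truth.copy()
    truth.attrs["true_log_ratios"] = true_ratios
    return scans, samples, truth


def generate_expression_matrix(config: SynthConfig):
    """Planted log-ratio matrix without the array-scan plumbing.

    Directly emits ``(X, categories, truth)``: the per-sample normalized
    log2 ratios each feature would show after merging, filtering and
    normalization — category mean plus i.i.d. Gaussian noise — with the
    same planted truth table as :func:`generate_array_dataset`.  This is the
    object the calibration and power studies operate on.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 404]))
    truth = _feature_truth(config, rng)
    counts = config.n_samples_per_category
    categories = np.repeat(
        ["fetal", "young", "adult"],
        [counts["fetal"], counts["young"], counts["adult"]],
    )
    mu = truth[["mean_F", "mean_Y", "mean_A"]].to_numpy()
    cat_idx = pd.Categorical(
        categories, categories=["fetal", "young", "adult"]
    ).codes
    X = mu[:, cat_idx] + rng.normal(
        0.0, config.noise_sd, size=(config.n_features, len(categories))
    )
    return X, categories, truth


# ---------------------------------------------------------------------------
# TaqMan Ct tables
# ---------------------------------------------------------------------------


def generate_taqman_dataset(config: SynthConfig, timepoints):
    """Pooled-sample Ct table plus per-assay truth.

    One Ct column per timepoint pool, in the given developmental order.
    Reference assays are near-constant across pools; each target's
    ``Ct = baseline - log2(relative abundance) + noise``, clipped at the
    censoring value (40, the SDS "undetermined" convention).  A fraction of
    guide-strand assays carry a planted single-timepoint spike of
    ``spike_log2`` log2 units; a fraction are low-expressed everywhere
    (raw Ct > 29) so the robust-expression filter has something to drop.
    """
    config.validate()
    timepoints = list(timepoints)
    if len(timepoints) < 2:
        raise ConfigError("need >=2 timepoints")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    T = len(timepoints)
    n = config.n_assays
    n_pass = int(round(config.frac_passenger * n))
    strands = np.array(["guide"] * (n - n_pass) + ["passenger"] * n_pass, dtype=object)
    rng.shuffle(strands)
    names = np.array(
        [
            f"sim-miR-{i + 1:04d}" + ("*" if s == "passenger" else "")
            for i, s in enumerate(strands)
        ],
        dtype=object,
    )
    baseline = rng.uniform(22.0, 28.0, size=n)
    low = rng.random(n) < config.frac_low_expressed
    baseline = np.where(low, rng.uniform(31.0, 36.0, size=n), baseline)
    profile = np.zeros((n, T))
    guide_idx = np.flatnonzero((strands == "guide") & ~low)
    n_spike = int(round(config.frac_spike * n))
    spike_assay = rng.choice(guide_idx, size=min(n_spike, len(guide_idx)), replace=False)
    spike_tp = rng.integers(0, T, size=len(spike_assay))
    for a, t in zip(spike_assay, spike_tp):
        profile[a, t] += config.spike_log2
    noise = rng.normal(0.0, config.taqman_noise_sd, size=(n, T))
    ct = baseline[:, None] - profile + noise
    ct = np.clip(ct, 1.0, config.ct_censor)
    table = pd.DataFrame(np.round(ct, 3), index=pd.Index(names, name="assay_id"),
                         columns=timepoints)
    table.insert(0, "strand", strands)
    for ref in REFERENCE_ASSAYS:
        ref_row = config.ref_cts[ref] + rng.normal(0.0, config.taqman_noise_sd / 3.0, size=T)
        table.loc[ref] = ["reference"] + list(np.round(ref_row, 3))
    spiked = np.zeros(n, dtype=bool)
    spiked[spike_assay] = True
    spike_col = np.full(n, "", dtype=object)
    for a, t in zip(spike_assay, spike_tp):
        spike_col[a] = timepoints[t]
    truth = pd.DataFrame(
        {
            "assay_id": names,
            "strand": strands,
            "baseline_ct": baseline,
            "low_expressed": low,
            "spiked": spiked,
            "spike_timepoint": spike_col,
        }
    )
    truth.attrs["true_log2_profile"] = profile
    return table, truth
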