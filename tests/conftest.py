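import numpy as np
import pandas as pd
import pytest

from chronoclass.synthetic import (
    SynthConfig,
    generate_array_dataset,
    generate_expression_matrix,
    generate_taqman_dataset,
)

TIMEPOINTS = ["14wk", "16wk", "17wk", "18wk", "19wk", "20wk",
              "98d", "1.5yr", "4.5yr", "adult"]


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(
        n_features=120,
        frac_novel=0.3,
        n_samples_per_category={"fetal": 8, "young": 6, "adult": 4},
        seed=42,
    )


@pytest.fixture(scope="session")
def array_dataset(small_config):
    return generate_array_dataset(small_config)


@pytest.fixture(scope="session")
def expression_dataset():
    cfg = SynthConfig(
        n_features=400,
        n_samples_per_category={"fetal": 12, "young": 12, "adult": 12},
        seed=7,
    )
    return generate_expression_matrix(cfg)


@pytest.fixture(scope="session")
def taqman_dataset(small_config):
    return generate_taqman_dataset(small_config, TIMEPOINTS)


def make_scan_pair(n=40, gain=10.0, seed=0, sat=65535.0,
                   low_noise=0.0, high_noise=0.0):
    """Hand-rolled low/high scan tables with a known gain relation."""
    rng = np.random.default_rng(seed)
    rows_low, rows_high = [], []
    true_low = np.exp(rng.uniform(np.log(50), np.log(20000), size=n))
    for ch in ("green", "red"):
        for i in range(n):
            bg = 100.0
            lo = true_low[i] * np.exp(rng.normal(0, low_noise))
            hi_unclipped = gain * true_low[i] * np.exp(rng.normal(0, high_noise))
            hi = min(hi_unclipped, sat)
            sat_frac = 0.5 if hi_unclipped > sat else 0.0
            common = dict(
                annotation_source="known", bg_sd=10.0,
                frac_pixels_gt_bg2sd=0.95, r_squared=0.9, flag=0,
            )
            rows_low.append(dict(feature_id=f"f{i:03d}", channel=ch, scan_power=10,
                                 median_fg=lo + bg, median_bg=bg,
                                 frac_saturated=0.0, **common))
            rows_high.append(dict(feature_id=f"f{i:03d}", channel=ch, scan_power=100,
                                  median_fg=hi + bg, median_bg=bg,
                                  frac_saturated=sat_frac, **common))
    return pd.DataFrame(rows_low), pd.DataFrame(rows_high), true_low
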