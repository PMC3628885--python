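"""Feature filters, LOWESS normalization and matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chronoclass.errors import AssemblyError, InputError, NormalizationError
from chronoclass.qc import (
    FilterThresholds,
    apply_feature_filters,
    assemble_matrix,
    lowess_normalize,
    normalize_array,
)


def two_channel_rows(feature_id, pixels=(0.95, 0.95), r2=(0.9, 0.9),
                     sat=(0.0, 0.0), flag=(0, 0), fg=(5000.0, 5000.0)):
    rows = []
    for i, ch in enumerate(("green", "red")):
        rows.append(
            dict(feature_id=feature_id, annotation_source="known", channel=ch,
                 scan_power=100, median_fg=fg[i], median_bg=100.0, bg_sd=10.0,
                 frac_pixels_gt_bg2sd=pixels[i], r_squared=r2[i],
                 frac_saturated=sat[i], flag=flag[i])
        )
    return rows


def test_pixel_filter_requires_seventy_percent_in_either_channel():
    table = pd.DataFrame(
        two_channel_rows("low_both", pixels=(0.69, 0.69))
        + two_channel_rows("ok_one", pixels=(0.69, 0.70))
    )
    mask = apply_feature_filters(table)
    assert not mask.loc["low_both", "keep"]
    assert mask.loc["low_both", "reasons"] == "pixels"
    assert mask.loc["ok_one", "keep"]


def test_r_squared_filter_is_strict_inequality():
    table = pd.DataFrame(
        two_channel_rows("boundary", r2=(0.5, 0.5))
        + two_channel_rows("above", r2=(0.501, 0.501))
    )
    mask = apply_feature_filters(table)
    assert not mask.loc["boundary", "keep"]
    assert "r_squared" in mask.loc["boundary", "reasons"]
    assert mask.loc["above", "keep"]


def test_saturation_filter_requires_both_channels():
    table = pd.DataFrame(
        two_channel_rows("one_channel", sat=(0.25, 0.05))
        + two_channel_rows("both_channels", sat=(0.25, 0.21))
    )
    mask = apply_feature_filters(table)
    assert mask.loc["one_channel", "keep"]
    assert not mask.loc["both_channels", "keep"]
    assert "saturation" in mask.loc["both_channels", "reasons"]


def test_flag_filter_and_missing_columns():
    table = pd.DataFrame(two_channel_rows("flagged", flag=(0, 1)))
    mask = apply_feature_filters(table)
    assert not mask.loc["flagged", "keep"]
    with pytest.raises(InputError):
        apply_feature_filters(table.drop(columns=["r_squared"]))


def test_filters_are_idempotent_and_order_independent():
    rng = np.random.default_rng(0)
    rows = []
    for i in range(50):
        rows += two_channel_rows(
            f"f{i:02d}",
            pixels=tuple(rng.uniform(0.5, 1.0, 2)),
            r2=tuple(rng.uniform(0.3, 1.0, 2)),
            sat=tuple(rng.uniform(0, 0.4, 2)),
            flag=tuple(rng.integers(0, 2, 2)),
        )
    table = pd.DataFrame(rows)
    mask1 = apply_feature_filters(table)
    kept = table[table["feature_id"].isin(mask1.index[mask1["keep"]])]
    mask2 = apply_feature_filters(kept)
    assert mask2["keep"].all()
    shuffled = table.sample(frac=1.0, random_state=1)
    mask3 = apply_feature_filters(shuffled)
    pd.testing.assert_frame_equal(mask1, mask3)


def test_lowess_constant_m_maps_to_zero():
    rng = np.random.default_rng(1)
    a = rng.uniform(6, 14, 200)
    m = np.full(200, 0.8)
    out = lowess_normalize(m, a)
    assert np.allclose(out, 0.0, atol=1e-9)


def test_lowess_recentres_constant_dye_bias():
    rng = np.random.default_rng(2)
    a = rng.uniform(6, 14, 500)
    m = 0.8 + rng.normal(0, 0.2, 500)
    out = lowess_normalize(m, a)
    assert abs(np.median(out)) < 0.05


def test_lowess_removes_intensity_dependent_trend():
    rng = np.random.default_rng(3)
    a = rng.uniform(6, 14, 500)
    m = 0.3 * a - 2 + rng.normal(0, 0.1, 500)
    out = lowess_normalize(m, a)
    slope = stats.linregress(a, out).slope
    assert abs(slope) < 0.02
    assert np.median(np.abs(out)) <= np.median(np.abs(m))


def test_lowess_shift_invariance():
    rng = np.random.default_rng(4)
    a = rng.uniform(6, 14, 300)
    m = rng.normal(0, 0.3, 300)
    assert np.allclose(lowess_normalize(m, a), lowess_normalize(m + 5.0, a),
                       atol=1e-9)


def test_lowess_needs_thirty_features():
    with pytest.raises(NormalizationError):
        lowess_normalize(np.zeros(29), np.arange(29.0))


def _norm_frame(m_values):
    idx = pd.Index([f"g{i}" for i in range(len(m_values))], name="feature_id")
    return pd.DataFrame({"M": m_values, "A": 10.0, "keep": True,
                         "reasons": ""}, index=idx)


def test_assembly_presence_rule():
    n_genes, n_arrays = 40, 10
    rng = np.random.default_rng(5)
    per_array = {}
    drop = {"g0": 6, "g1": 2}  # g0 missing on 60% of arrays, g1 on 20%
    for j in range(n_arrays):
        m = rng.normal(0, 1, n_genes)
        df = _norm_frame(m)
        for g, n_miss in drop.items():
            if j < n_miss:
                df.loc[g, "M"] = np.nan
        per_array[f"s{j}"] = df
    samples = pd.DataFrame(
        {"sample_id": [f"s{j}" for j in range(n_arrays)],
         "age_category": ["fetal"] * n_arrays}
    )
    matrix = assemble_matrix(per_array, samples, presence_min=0.70)
    assert "g0" not in matrix.values.index  # present on 40% < 70%
    assert "g1" in matrix.values.index  # present on 80%
    present = matrix.values.notna().mean(axis=1)
    assert (present >= 0.70).all()
    with pytest.raises(AssemblyError):
        assemble_matrix({"s0": per_array["s0"]}, samples)


def test_assembly_retained_count_matches_binomial_expectation():
    # each gene independently observed per array with prob 1-q; the retained
    # count should match the closed-form binomial survival probability
    n_genes, n_arrays, q = 2000, 20, 0.2
    rng = np.random.default_rng(6)
    per_array = {}
    for j in range(n_arrays):
        m = rng.normal(0, 1, n_genes)
        m[rng.random(n_genes) < q] = np.nan
        per_array[f"s{j}"] = _norm_frame(m)
    samples = pd.DataFrame(
        {"sample_id": list(per_array), "age_category": ["fetal"] * n_arrays}
    )
    matrix = assemble_matrix(per_array, samples, presence_min=0.70)
    need = int(np.ceil(0.70 * n_arrays))
    p_keep = stats.binom.sf(need - 1, n_arrays, 1 - q)
    expected = n_genes * p_keep
    sd = np.sqrt(n_genes * p_keep * (1 - p_keep))
    assert abs(len(matrix.values) - expected) < 4 * sd + 1


def test_normalize_array_masks_failing_features(array_dataset):
    scans, _, _ = array_dataset
    from chronoclass.scan_merge import fit_and_merge

    pair = next(iter(scans.values()))
    merged, _ = fit_and_merge(pair["low"], pair["high"])
    res = normalize_array(merged, FilterThresholds())
    assert res.loc[~res["keep"], "M"].isna().all()
    assert res.loc[res["keep"], "M"].notna().all()
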