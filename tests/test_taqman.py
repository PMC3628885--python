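"""2^-ddCt relative quantification and the fold-change screens."""

import numpy as np
import pandas as pd
import pytest

from chronoclass.errors import InputError, ScreenError, TabulationError
from chronoclass.synthetic import SynthConfig, generate_taqman_dataset
from chronoclass.taqman import (
    censor_mask,
    fold_changes,
    normalize_ct,
    qq_data,
    robust_expression_filter,
    sd_outlier_screen,
    tabulate_fold_bins,
)

from conftest import TIMEPOINTS


def small_ct_table():
    cols = ["14wk", "17wk", "adult"]
    data = {
        "strand": ["reference", "reference", "reference", "guide", "guide",
                   "passenger"],
        "14wk": [20.0, 22.0, 24.0, 25.0, 30.0, 24.0],
        "17wk": [20.0, 22.0, 24.0, 24.0, 30.0, 24.0],
        "adult": [20.0, 22.0, 24.0, 22.0, 30.0, 24.0],
    }
    idx = ["RNU44", "RNU48", "U6", "miR-a", "miR-b", "miR-c*"]
    return pd.DataFrame(data, index=pd.Index(idx, name="assay_id"))[["strand"] + cols]


def test_normalizer_is_reference_mean_per_column():
    delta = normalize_ct(small_ct_table())
    # refs at 20/22/24 -> normalizer 22 in every column
    assert delta.loc["miR-a", "14wk"] == pytest.approx(3.0)
    assert delta.loc["miR-a", "adult"] == pytest.approx(0.0)
    assert "RNU44" not in delta.index


def test_column_shift_invariance():
    table = small_ct_table()
    shifted = table.copy()
    shifted["17wk"] = shifted["17wk"].where(
        shifted["strand"].eq("___"), shifted["17wk"].astype(float) + 3.0
    )
    d0 = normalize_ct(table)
    d1 = normalize_ct(shifted)
    pd.testing.assert_frame_equal(d0, d1)
    fc0 = fold_changes(d0, "14wk")
    fc1 = fold_changes(d1, "14wk")
    pd.testing.assert_frame_equal(fc0.log2, fc1.log2)


def test_censored_reference_invalidates_column():
    table = small_ct_table()
    table.loc["U6", "17wk"] = 40.0
    with pytest.raises(InputError, match="17wk"):
        normalize_ct(table)


def test_robust_expression_filter_rules():
    cols = TIMEPOINTS
    rows = {
        "strand": ["reference"] * 3 + ["guide", "guide", "passenger"],
    }
    for c in cols:
        rows[c] = [20.0, 22.0, 24.0, 30.0, 35.0, 20.0]
    idx = ["RNU44", "RNU48", "U6", "dim_everywhere", "one_bright", "strong_star"]
    table = pd.DataFrame(rows, index=pd.Index(idx, name="assay_id"))
    table.loc["one_bright", cols[3]] = 28.0
    kept = robust_expression_filter(table)
    assert "dim_everywhere" not in kept  # Ct 30 > 29 at all timepoints
    assert "one_bright" in kept  # robust at one timepoint suffices
    assert "strong_star" not in kept  # passenger strand excluded
    assert "RNU44" not in kept


def test_fold_change_definitions_and_reference_column():
    delta = normalize_ct(small_ct_table())
    fc = fold_changes(delta, "14wk")
    # ddCt = -1 -> fold 2; reference column is exactly 1
    assert fc.fold.loc["miR-a", "17wk"] == pytest.approx(2.0)
    assert fc.fold.loc["miR-a", "adult"] == pytest.approx(8.0)
    assert (fc.log2["14wk"] == 0).all()
    assert (fc.fold["14wk"] == 1).all()
    with pytest.raises(InputError):
        fold_changes(delta, "99wk")


def test_censored_targets_are_flagged_not_point_values():
    table = small_ct_table()
    table.loc["miR-b", "17wk"] = 40.0
    delta = normalize_ct(table)
    fc = fold_changes(delta, "14wk", censored=censor_mask(table))
    assert bool(fc.censored.loc["miR-b", "17wk"])
    assert not bool(fc.censored.loc["miR-a", "17wk"])


def test_noiseless_generator_roundtrip_is_exact():
    cfg = SynthConfig(n_assays=30, taqman_noise_sd=0.0, frac_low_expressed=0.0,
                      frac_spike=0.2, spike_log2=2.0, seed=13)
    table, truth = generate_taqman_dataset(cfg, TIMEPOINTS)
    retained = robust_expression_filter(table)
    delta = normalize_ct(table).loc[retained]
    fc = fold_changes(delta, TIMEPOINTS[0])
    profile = pd.DataFrame(
        truth.attrs["true_log2_profile"], index=truth["assay_id"], columns=TIMEPOINTS
    ).loc[retained]
    expected = profile.sub(profile[TIMEPOINTS[0]], axis=0)
    # planted 4-fold (2 log2 units) spikes recovered exactly
    assert np.allclose(fc.log2, expected, atol=1e-9)
    assert (2.0 ** expected.to_numpy().max()) == pytest.approx(4.0)


def test_sd_screen_flags_single_spike():
    rng = np.random.default_rng(14)
    cols = TIMEPOINTS
    n = 30
    log2fc = pd.DataFrame(rng.normal(0, 0.2, size=(n, len(cols))),
                          index=[f"m{i}" for i in range(n)], columns=cols)
    log2fc[cols[0]] = 0.0
    log2fc.loc["m5", "17wk"] = 8.0  # the week-17 spike scenario
    from chronoclass.taqman import FoldChangeTable

    fc = FoldChangeTable(log2=log2fc, reference_timepoint=cols[0])
    hits = sd_outlier_screen(fc, k=2.0)
    assert ("m5", "17wk") in set(zip(hits["assay_id"], hits["timepoint"]))
    assert hits.iloc[0]["assay_id"] == "m5"  # largest |z| first
    # pooled mean/SD oracle
    pool = log2fc[cols[1:]].to_numpy().ravel()
    z = (8.0 - pool.mean()) / pool.std(ddof=1)
    assert hits.iloc[0]["z"] == pytest.approx(z)
    assert sd_outlier_screen(fc, k=np.inf).empty


def test_sd_screen_degenerate_pools_rejected():
    from chronoclass.taqman import FoldChangeTable

    flat = FoldChangeTable(
        log2=pd.DataFrame(np.zeros((5, 4)), columns=list("abcd")),
        reference_timepoint="a",
    )
    with pytest.raises(ScreenError):
        sd_outlier_screen(flat, k=2.0)
    tiny = FoldChangeTable(
        log2=pd.DataFrame(np.zeros((2, 3)), columns=list("abc")),
        reference_timepoint="a",
    )
    with pytest.raises(ScreenError):
        sd_outlier_screen(tiny, k=2.0)


def epoch_map():
    return {tp: ("fetal" if tp.endswith("wk") else "adult" if tp == "adult"
                 else "young") for tp in TIMEPOINTS}


def test_fold_bin_tabulation_matches_brute_force():
    rng = np.random.default_rng(15)
    n = 50
    delta = pd.DataFrame(rng.normal(0, 3, size=(n, len(TIMEPOINTS))),
                         index=[f"m{i}" for i in range(n)], columns=TIMEPOINTS)
    table = tabulate_fold_bins(delta, epoch_map())
    em = epoch_map()
    q = {e: (-delta[[c for c in delta.columns if em[c] == e]]).mean(axis=1)
         for e in ("fetal", "young", "adult")}
    for first, second in (("fetal", "adult"), ("young", "adult"), ("fetal", "young")):
        name = f"{first.capitalize()} vs. {second.capitalize()}"
        fold = 2.0 ** (q[first] - q[second])
        for b in (2, 5, 10, 100):
            assert table.loc[b, (name, "increase")] == int((fold > b).sum())
            assert table.loc[b, (name, "decrease")] == int((1 / fold > b).sum())
    # monotone across widening bins
    for col in table.columns:
        assert (np.diff(table[col].to_numpy()) <= 0).all()


def test_fold_bin_edge_cases():
    delta = pd.DataFrame(
        {"14wk": [-np.log2(6.0)], "98d": [0.0], "adult": [0.0]}, index=["m0"]
    )
    em = {"14wk": "fetal", "98d": "young", "adult": "adult"}
    table = tabulate_fold_bins(delta, em)
    # fetal/adult fold 6: counted above 2 and 5, not 10
    assert table.loc[2, ("Fetal vs. Adult", "increase")] == 1
    assert table.loc[5, ("Fetal vs. Adult", "increase")] == 1
    assert table.loc[10, ("Fetal vs. Adult", "increase")] == 0
    flat = pd.DataFrame({"14wk": [0.0], "98d": [0.0], "adult": [0.0]}, index=["m0"])
    assert (tabulate_fold_bins(flat, em).to_numpy() == 0).all()
    with pytest.raises(TabulationError):
        tabulate_fold_bins(delta, {"14wk": "fetal", "98d": "young"})
    with pytest.raises(TabulationError):
        tabulate_fold_bins(delta[["14wk", "98d"]], {"14wk": "fetal", "98d": "young"})


def test_qq_data_shape_and_slope():
    rng = np.random.default_rng(16)
    qq = qq_data(rng.normal(0, 1, 2000))
    slope = np.polyfit(qq["theoretical"], qq["empirical"], 1)[0]
    assert abs(slope - 1.0) < 0.1
    ten = qq_data(np.arange(10.0))
    assert len(ten) == 10
    flat = qq_data(np.zeros(12))
    assert (flat["empirical"] == 0).all()
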