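"""Ground-truth generators: dimensions, determinism, planted structure."""

import numpy as np
import pandas as pd
import pytest

from chronoclass.anova import select_patterns
from chronoclass.errors import ConfigError
from chronoclass.patterns import CANONICAL_LABELS
from chronoclass.synthetic import (
    REFERENCE_ASSAYS,
    SynthConfig,
    generate_array_dataset,
    generate_expression_matrix,
    generate_sample_table,
    generate_taqman_dataset,
)

from conftest import TIMEPOINTS


def test_sample_table_dimensions_and_categories():
    cfg = SynthConfig(n_samples_per_category={"fetal": 36, "young": 9, "adult": 2})
    t = generate_sample_table(cfg)
    assert len(t) == 47
    assert t["age_category"].value_counts().to_dict() == {
        "fetal": 36, "young": 9, "adult": 2
    }


def test_sample_table_seeded_determinism():
    cfg = SynthConfig(
        n_samples_per_category={"fetal": 3, "young": 3, "adult": 3}, seed=11
    )
    pd.testing.assert_frame_equal(
        generate_sample_table(cfg), generate_sample_table(cfg)
    )


def test_fetal_ages_within_study_window():
    t = generate_sample_table(SynthConfig(seed=3))
    fetal = t[t["age_category"] == "fetal"]
    assert fetal["gestational_weeks"].between(14, 24).all()
    assert fetal["postnatal_days"].isna().all()
    young = t[t["age_category"] == "young"]
    assert young["gestational_weeks"].isna().all()
    assert young["postnatal_days"].notna().all()


def test_pool_ids_group_samples_of_identical_age():
    t = generate_sample_table(SynthConfig(seed=4))
    fetal = t[t["age_category"] == "fetal"]
    assert (fetal.groupby("gestational_weeks")["pool"].nunique() == 1).all()
    # pools are numbered in developmental order
    assert t[t["age_category"] == "adult"]["pool"].max() == t["pool"].max()


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        generate_sample_table(
            SynthConfig(n_samples_per_category={"fetal": 0, "young": 1, "adult": 1})
        )
    with pytest.raises(ConfigError):
        SynthConfig(class_mix={"F=Y=A": 0.5}).validate()
    with pytest.raises(ConfigError):
        SynthConfig(noise_sd=0.0).validate()


def test_array_dataset_shapes_and_determinism(small_config, array_dataset):
    scans, samples, truth = array_dataset
    assert len(scans) == len(samples)
    one = next(iter(scans.values()))
    # rows = features x 2 channels, in both scans
    assert len(one["low"]) == 2 * small_config.n_features
    assert len(one["high"]) == 2 * small_config.n_features
    scans2, samples2, truth2 = generate_array_dataset(small_config)
    sid = samples["sample_id"].iloc[0]
    assert scans[sid]["low"].to_csv() == scans2[sid]["low"].to_csv()
    assert truth.to_csv() == truth2.to_csv()


def test_high_scan_is_gain_times_low_clipped_at_ceiling(array_dataset, small_config):
    scans, _, _ = array_dataset
    pair = next(iter(scans.values()))
    lo = pair["low"].set_index(["feature_id", "channel"])
    hi = pair["high"].set_index(["feature_id", "channel"])
    sig_lo = lo["median_fg"] - lo["median_bg"]
    sig_hi = hi["median_fg"] - hi["median_bg"]
    assert (sig_hi <= small_config.sat_threshold + 1e-6).all()
    bright = sig_lo > small_config.sat_threshold / small_config.gain * 1.2
    assert bright.any()
    # bright features clip and are marked saturated
    assert (sig_hi[bright] >= small_config.sat_threshold - 1).all()
    assert (hi.loc[bright.index[bright], "frac_saturated"] >= 0.2).all()
    # dim features scale ~linearly with the gain
    dim = sig_lo < small_config.sat_threshold / small_config.gain / 2
    ratio = sig_hi[dim] / sig_lo[dim]
    assert abs(np.median(ratio) - small_config.gain) < 1.0


def test_all_null_mix_plants_only_the_null_pattern():
    cfg = SynthConfig(n_features=50, class_mix={"F=Y=A": 1.0}, seed=1)
    _, _, truth = generate_array_dataset(cfg)
    assert (truth["pattern"] == "F=Y=A").all()
    assert (truth[["mean_F", "mean_Y", "mean_A"]] == 0).all().all()


def test_novel_fraction_and_truth_equalities(array_dataset, small_config):
    _, _, truth = array_dataset
    frac = (truth["annotation_source"] == "novel").mean()
    assert abs(frac - small_config.frac_novel) <= 1.0 / small_config.n_features
    # pattern-implied equalities hold exactly in the true means
    for _, row in truth.iterrows():
        from chronoclass.patterns import pattern_by_label

        pat = pattern_by_label(row["pattern"])
        means = {"F": row["mean_F"], "Y": row["mean_Y"], "A": row["mean_A"]}
        for g in pat.groups:
            vals = [means[c] for c in g]
            assert len(set(vals)) == 1
        ordered = [next(iter(sorted(means[c] for c in g))) for g in pat.groups]
        assert ordered == sorted(ordered)


def test_planted_class_recovered_downstream():
    # features planted as F<Y=A are recovered by the classifier
    cfg = SynthConfig(
        n_features=300,
        class_mix={"F<Y=A": 1.0},
        effect_size=2.0,
        noise_sd=0.3,
        n_samples_per_category={"fetal": 12, "young": 12, "adult": 12},
        seed=21,
    )
    X, cats, truth = generate_expression_matrix(cfg)
    res = select_patterns(X, cats, alpha=0.0019)
    labels = np.array([""] + list(CANONICAL_LABELS), dtype=object)
    recovered = labels[res["class_index"]] == "F<Y=A"
    assert recovered.mean() >= 0.95


def test_taqman_ct_encodes_log2_abundance(small_config):
    cfg = SynthConfig(
        n_assays=40, taqman_noise_sd=0.0, frac_low_expressed=0.0, seed=5,
        spike_log2=1.0, frac_spike=0.3,
    )
    table, truth = generate_taqman_dataset(cfg, TIMEPOINTS)
    profile = truth.attrs["true_log2_profile"]
    values = table.drop(columns="strand").loc[truth["assay_id"]].to_numpy(float)
    expect = truth["baseline_ct"].to_numpy()[:, None] - profile
    # 2-fold abundance (profile +1) lowers Ct by exactly 1 cycle
    assert np.allclose(values, np.clip(expect, 1, 40), atol=5e-4)
    spiked = truth[truth["spiked"]]
    assert len(spiked) > 0
    for _, row in spiked.iterrows():
        base = table.loc[row["assay_id"]].drop(["strand", row["spike_timepoint"]])
        assert table.loc[row["assay_id"], row["spike_timepoint"]] <= (
            base.astype(float).min() - 0.9
        )


def test_taqman_reference_rows_and_bounds(taqman_dataset):
    table, _ = taqman_dataset
    for ref in REFERENCE_ASSAYS:
        assert ref in table.index
        vals = table.loc[ref].drop("strand").astype(float)
        assert vals.std() < 0.2
    vals = table.drop(columns="strand").to_numpy(float)
    assert ((vals > 0) & (vals <= 40)).all()


def test_taqman_requires_two_timepoints(small_config):
    with pytest.raises(ConfigError):
        generate_taqman_dataset(small_config, ["14wk"])
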