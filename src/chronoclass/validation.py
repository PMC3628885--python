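"""Simulation studies that check the pipeline's operating characteristics.

These are first-class, reusable experiments (the tests and the
reproducibility script both run them): chiefly the FDR-calibration study —
does the permutation-calibrated p-value threshold actually deliver the
nominal false-discovery rate against planted ground truth?
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .anova import omnibus_pvalues, select_patterns
from .fdr import calibrate_threshold, simulate_null_pvalues
from .patterns import CANONICAL_LABELS
from .synthetic import SynthConfig, default_class_mix, generate_expression_matrix

#: study conditions: 2000 features, 12/12/12 samples, 10% non-null spread
#: over the 12 directional classes, mean separation 6 noise SDs.
STUDY_CONFIG = SynthConfig(
    n_features=2000,
    n_samples_per_category={"fetal": 12, "young": 12, "adult": 12},
    class_mix=default_class_mix(0.10),
    noise_sd=0.25,
    effect_size=1.5,
)


def fdr_calibration_study(
    n_replicates: int = 50,
    n_sims: int = 300,
    target_fdr: float = 0.01,
    seed: int = 0,
    config: SynthConfig = STUDY_CONFIG,
) -> pd.DataFrame:
    """Realized false-discovery proportion of the calibrated threshold.

    For each replicate: generate a planted dataset, calibrate the p-value
    threshold by label-permutation simulation at the nominal target rate,
    and score the discoveries against ground truth.  Returns one row per
    replicate with ``threshold``, ``n_discoveries``, ``n_false`` and ``fdp``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates) % (2**31)
    rows = []
    for r in range(n_replicates):
        cfg = replace(config, seed=int(seeds[2 * r]))
        X, cats, truth = generate_expression_matrix(cfg)
        observed = omnibus_pvalues(X, cats)
        pools = simulate_null_pvalues(X, cats, n_sims, seed=int(seeds[2 * r + 1]))
        res = calibrate_threshold(observed, pools, target_fdr)
        disc = observed <= res.threshold if res.n_discoveries else np.zeros_like(
            observed, dtype=bool
        )
        is_null = (truth["pattern"] == "F=Y=A").to_numpy()
        n_disc = int(disc.sum())
        n_false = int((disc & is_null).sum())
        rows.append(
            {
                "replicate": r,
                "threshold": res.threshold,
                "estimated_fdr": res.estimated_fdr,
                "n_discoveries": n_disc,
                "n_false": n_false,
                "fdp": n_false / max(1, n_disc),
            }
        )
    return pd.DataFrame(rows)


def pattern_recovery_study(
    n_features: int = 2000,
    n_per_category: int = 12,
    effect_over_noise: float = 6.0,
    noise_sd: float = 0.25,
    alpha: float = 0.001901,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of planted directional genes whose pattern is recovered.

    All features are non-null, spread evenly over the 12 directional
    classes; classification runs at the given working alpha.  Returns
    per-class recovery rates.
    """
    mix = {lab: 1 / 12 for lab in CANONICAL_LABELS if lab != "F=Y=A"}
    cfg = SynthConfig(
        n_features=n_features,
        n_samples_per_category={
            "fetal": n_per_category, "young": n_per_category, "adult": n_per_category
        },
        class_mix=mix,
        noise_sd=noise_sd,
        effect_size=effect_over_noise * noise_sd,
        seed=seed,
    )
    X, cats, truth = generate_expression_matrix(cfg)
    res = select_patterns(X, cats, alpha)
    assigned = np.array([""] + list(CANONICAL_LABELS), dtype=object)[
        res["class_index"]
    ]
    truth = truth.assign(assigned=assigned, correct=assigned == truth["pattern"])
    by_class = truth.groupby("pattern")["correct"].agg(["mean", "size"])
    by_class.loc["overall"] = [truth["correct"].mean(), len(truth)]
    return by_class
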