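"""End-to-end driver: simulate -> merge -> normalize -> calibrate ->
classify -> enrich -> cluster -> taqman.

Each stage persists its outputs under the run directory as plain text and
records counts in a machine-readable manifest.  A single config seed fans
out deterministically into per-stage child seeds, so a stage can be re-run
alone with the same randomness; the whole run is byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .anova import fit_genes
from .cluster import cluster_matrix
from .enrich import annotation_enrichment
from .errors import PipelineError
from .fdr import calibrate_threshold, simulate_null_pvalues
from .anova import omnibus_pvalues
from .qc import FilterThresholds, assemble_matrix, exclusion_report, normalize_array
from .scan_merge import fit_and_merge
from .synthetic import SynthConfig, generate_array_dataset, generate_taqman_dataset
from .taqman import (
    censor_mask,
    fold_changes,
    normalize_ct,
    qq_data,
    robust_expression_filter,
    sd_outlier_screen,
    tabulate_fold_bins,
)

log = logging.getLogger("chronoclass")

STAGES = (
    "simulate",
    "merge",
    "normalize",
    "calibrate",
    "classify",
    "enrich",
    "cluster",
    "taqman",
)


@dataclass
class PipelineConfig:
    """Everything a full synthetic run needs; YAML-loadable."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0
    target_fdr: float = 0.01
    n_sims: int = 2500
    n_perm: int = 999
    enrich_class: str = "F<Y=A"
    presence_min: float = 0.70
    lowess_span: float = 0.4
    linkage: str = "average"
    taqman_timepoints: tuple = (
        "14wk", "16wk", "17wk", "18wk", "19wk", "20wk",
        "98d", "1.5yr", "4.5yr", "adult",
    )
    taqman_reference: str = "14wk"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        cfg = cls(synth=synth, **raw)
        return cfg


def _stage_seeds(seed: int) -> dict:
    """Deterministic per-stage child seeds below 2**31."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {name: int(s % (2**31)) for name, s in zip(STAGES, state)}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all eight stages; returns (and persists) the run manifest.

    Any stage error aborts the run with :class:`PipelineError` naming the
    stage; outputs of completed stages and the partial manifest persist.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {"seed": config.seed, "stages": {}, "parameters": {
        "target_fdr": config.target_fdr,
        "n_sims": config.n_sims,
        "n_perm": config.n_perm,
        "presence_min": config.presence_min,
        "lowess_span": config.lowess_span,
        "linkage": config.linkage,
    }}
    state: dict = {}

    def _run(stage, fn):
        log.info("stage %s: starting", stage)
        try:
            counts = fn()
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            io.write_json(manifest, out / "manifest.json")
            raise PipelineError(stage, exc) from exc
        manifest["stages"][stage] = {"status": "completed", **counts}
        io.write_json(manifest, out / "manifest.json")
        log.info("stage %s: done %s", stage, counts)

    # 1 — simulate
    def simulate():
        synth = replace(config.synth, seed=seeds["simulate"])
        scans, samples, truth = generate_array_dataset(synth)
        ct, ct_truth = generate_taqman_dataset(synth, config.taqman_timepoints)
        io.write_sample_table(samples, out / "samples.tsv")
        truth.drop(columns=[], errors="ignore").to_csv(
            out / "ground_truth.tsv", sep="\t", index=False
        )
        io.write_ct_table(ct, out / "taqman_ct.tsv")
        ct_truth.to_csv(out / "taqman_truth.tsv", sep="\t", index=False)
        scan_dir = out / "scans"
        scan_dir.mkdir(exist_ok=True)
        for sid, pair in scans.items():
            io.write_scan_table(pair["low"], scan_dir / f"{sid}_low.tsv")
            io.write_scan_table(pair["high"], scan_dir / f"{sid}_high.tsv")
        state.update(scans=scans, samples=samples, truth=truth, ct=ct,
                     ct_truth=ct_truth)
        return {"n_features": int(config.synth.n_features),
                "n_arrays": len(scans), "n_taqman_assays": int(len(ct))}

    _run("simulate", simulate)

    # 2 — merge
    def merge():
        merged = {}
        n_sub = 0
        for sid, pair in state["scans"].items():
            table, _ = fit_and_merge(pair["low"], pair["high"])
            n_sub += int((table["source_scan"] == "low").sum())
            merged[sid] = table
        all_merged = pd.concat(
            [t.assign(array_id=sid) for sid, t in merged.items()],
            ignore_index=True,
        )
        all_merged.to_csv(out / "merged_scans.tsv", sep="\t", index=False)
        state["merged"] = merged
        return {"n_arrays": len(merged), "n_substituted_rows": n_sub}

    _run("merge", merge)

    # 3 — normalize (filter + LOWESS + assemble)
    def normalize():
        thresholds = FilterThresholds()
        per_array, masks = {}, {}
        for sid, table in state["merged"].items():
            res = normalize_array(table, thresholds, span=config.lowess_span)
            per_array[sid] = res
            masks[sid] = res[["keep", "reasons"]]
        annot = state["truth"].set_index("feature_id")[
            ["annotation_source", "large_ncrna"]
        ]
        matrix = assemble_matrix(
            per_array, state["samples"], presence_min=config.presence_min,
            row_annot=annot,
        )
        io.write_matrix(matrix, out / "matrix.tsv")
        io.write_json(exclusion_report(masks), out / "qc_report.json")
        state["matrix"] = matrix
        return {"n_genes": int(matrix.values.shape[0]),
                "n_samples": int(matrix.values.shape[1])}

    _run("normalize", normalize)

    # 4 — calibrate FDR
    def calibrate_stage():
        matrix = state["matrix"]
        X = matrix.values.to_numpy(float)
        cats = matrix.categories()
        observed = omnibus_pvalues(X, cats)
        pools = simulate_null_pvalues(X, cats, config.n_sims,
                                      seed=seeds["calibrate"])
        result = calibrate_threshold(observed, pools, config.target_fdr,
                                     seed=seeds["calibrate"])
        io.write_json(result.to_dict(), out / "calibration.json")
        state["calibration"] = result
        state["observed_p"] = observed
        return {"threshold": result.threshold,
                "n_discoveries": result.n_discoveries}

    _run("calibrate", calibrate_stage)

    # 5 — classify
    def classify():
        matrix = state["matrix"]
        alpha = state["calibration"].threshold
        fits = fit_genes(
            matrix.values.to_numpy(float), matrix.categories(), alpha,
            gene_ids=list(matrix.genes),
        )
        fits["significant"] = fits["p_value"] <= alpha
        io.write_fits(fits, out / "fits.tsv")
        occupancy = (
            fits.loc[fits["significant"], "class_index"].value_counts().sort_index()
        )
        state["fits"] = fits
        return {
            "n_significant": int(fits["significant"].sum()),
            "class_occupancy": {int(k): int(v) for k, v in occupancy.items()},
        }

    _run("classify", classify)

    # 6 — enrich
    def enrich():
        matrix = state["matrix"]
        annot = matrix.row_annot["annotation_source"].to_numpy()
        res = annotation_enrichment(
            matrix.values.to_numpy(float),
            matrix.categories(),
            annot,
            config.enrich_class,
            alpha=state["calibration"].threshold,
            n_perm=config.n_perm,
            seed=seeds["enrich"],
        )
        io.write_json(
            {
                "target_class": res.target_class,
                "observed_novel_in_class": res.observed,
                "p_value": res.p_value,
                "n_perm": res.n_perm,
                "null_mean": res.null_mean,
            },
            out / "enrichment.json",
        )
        return {"p_value": res.p_value, "observed": res.observed}

    _run("enrich", enrich)

    # 7 — cluster
    def cluster_stage():
        matrix = state["matrix"]
        sig = state["fits"].loc[state["fits"]["significant"], "gene"]
        sub = matrix.values.loc[sig]
        # drop rows that are constant or too sparse to correlate
        usable = sub.notna().sum(axis=1) >= 3
        sub = sub.loc[usable]
        sub = sub.loc[sub.std(axis=1, skipna=True) > 0]
        if len(sub) < 2:
            (out / "dendrogram.nwk").write_text(";\n")
            (out / "leaf_order.tsv").write_text("gene\n")
            return {"n_clustered": int(len(sub))}
        genes, cols = cluster_matrix(sub, linkage=config.linkage)
        (out / "dendrogram.nwk").write_text(genes.to_newick() + "\n")
        pd.DataFrame(
            {"gene": [genes.labels[i] for i in genes.leaf_order]}
        ).to_csv(out / "leaf_order.tsv", sep="\t", index=False)
        return {"n_clustered": int(len(sub))}

    _run("cluster", cluster_stage)

    # 8 — taqman
    def taqman_stage():
        ct = state["ct"]
        retained = robust_expression_filter(ct)
        delta = normalize_ct(ct).loc[retained]
        cens = censor_mask(ct).loc[retained]
        fc = fold_changes(delta, config.taqman_reference, censored=cens)
        fc.log2.to_csv(out / "taqman_log2fc.tsv", sep="\t")
        hits = sd_outlier_screen(fc)
        hits.to_csv(out / "taqman_outliers.tsv", sep="\t", index=False)
        epoch_of = {}
        for tp in delta.columns:
            if tp.endswith("wk"):
                epoch_of[tp] = "fetal"
            elif tp == "adult":
                epoch_of[tp] = "adult"
            else:
                epoch_of[tp] = "young"
        bins = tabulate_fold_bins(delta, epoch_of)
        bins.to_csv(out / "taqman_fold_bins.tsv", sep="\t")
        qq = qq_data(fc.log2.drop(columns=fc.reference_timepoint).to_numpy())
        qq.to_csv(out / "taqman_qq.tsv", sep="\t", index=False)
        return {"n_retained_assays": int(len(retained)),
                "n_outlier_entries": int(len(hits))}

    _run("taqman", taqman_stage)

    manifest["completed"] = all(
        s["status"] == "completed" for s in manifest["stages"].values()
    )
    io.write_json(manifest, out / "manifest.json")
    return manifest
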