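"""Cohort tables and the end-to-end pipeline runner.

A cohort feature table is a delimited-text file with the fixed header
``neuron_id,age_days,stage`` followed by the 16 feature columns in canonical
order; missing values are empty fields (never zeros).

``run_pipeline`` chains generate -> extract -> classify -> stack -> cluster
-> pca (-> perturb) from a JSON/YAML-style config dict, writing every
artifact into an output directory.  Identical (config, seed) produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import multivariate as mv
from .features import FEATURE_NAMES, FeatureVector, extract_features
from .patterns import classify_firing, pattern_proportions
from .perturb import LeakSpec, PharmacologySpec, apply_perturbation, phenotype_shift
from .stagestats import build_stacking_table
from .synth import (
    ground_truth_features,
    iter_cohort,
    load_default_calibration,
    sample_neuron_params,
)
from .traces import read_recording_set, write_recording_set

__all__ = [
    "write_feature_table",
    "read_feature_table",
    "run_pipeline",
    "PIPELINE_STAGES",
]

log = logging.getLogger("ephysdev")

TABLE_COLUMNS = ["neuron_id", "age_days", "stage", *FEATURE_NAMES]

PIPELINE_STAGES = ("generate", "extract", "classify", "stack", "cluster",
                   "pca", "perturb")


def write_feature_table(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort feature table with the canonical fixed header."""
    if cohort.empty:
        raise ValueError("cohort table is empty")
    out = cohort.reindex(columns=TABLE_COLUMNS)
    out.to_csv(path, index=False, na_rep="")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: feature table lacks columns {missing}")
    return df


def _features_to_row(neuron_id: str, age: int, stage: str,
                     fv: FeatureVector) -> dict:
    return {"neuron_id": neuron_id, "age_days": age, "stage": stage,
            **fv.to_dict()}


class DependencyError(RuntimeError):
    """A pipeline stage was requested without its upstream artifact."""


def run_pipeline(config: dict) -> dict:
    """Execute the requested pipeline stages.

    Config keys: ``stages`` (list; ``["all"]`` expands to every stage),
    ``out`` (output directory), ``seed``, and a ``generate`` section
    (``plan`` as {stage: n}, ``duration_s``, ``noise_sd``, ``write_hdf5``),
    plus optional ``input_dir`` (read recordings instead of generating),
    ``normalization``, ``k`` (fixed class count) and a ``perturb`` section
    (``ahp_block``, ``na_scale``, ``leak_target``, ``kappa``, ``stage``,
    ``n``).

    Returns a dict of the in-memory results; every stage also writes its
    artifact under ``out``.
    """
    stages = list(config.get("stages", []))
    if not stages:
        raise ValueError("config must request at least one stage")
    if "all" in stages:
        stages = list(PIPELINE_STAGES)
    unknown = [s for s in stages if s not in PIPELINE_STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stages {unknown}")

    outdir = Path(config.get("out", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    results: dict = {}

    def timed(name, fn):
        t0 = time.perf_counter()
        r = fn()
        log.info("stage %-8s finished in %.2f s", name, time.perf_counter() - t0)
        return r

    features = None
    gt = None
    if "generate" in stages:
        gcfg = config.get("generate", {})
        plan = ([(s, int(n)) for s, n in gcfg["plan"].items()]
                if "plan" in gcfg else None)
        write_hdf5 = bool(gcfg.get("write_hdf5"))
        if write_hdf5:
            (outdir / "recordings").mkdir(exist_ok=True)

        def _gen():
            # recordings are streamed: extracted (and/or written) one at a
            # time so a full-size cohort never sits in memory at once
            gt_rows, feat_rows = [], []
            for rec, row in iter_cohort(
                    plan=plan, seed=seed,
                    duration_s=float(gcfg.get("duration_s", 60.0)),
                    noise_sd=float(gcfg.get("noise_sd", 0.3))):
                gt_rows.append(row)
                if write_hdf5:
                    write_recording_set(
                        rec, str(outdir / "recordings" / f"{rec.neuron_id}.h5"))
                if "extract" in stages:
                    fv = extract_features(rec)
                    feat_rows.append(_features_to_row(
                        rec.neuron_id, rec.age_days, rec.stage, fv))
            return pd.DataFrame(gt_rows), (
                pd.DataFrame(feat_rows) if feat_rows else None)

        gt, features = timed("generate+extract", _gen)
        gt.to_csv(outdir / "ground_truth.csv", index=False,
                  float_format="%.8g")
        results["ground_truth"] = gt
        log.info("generated %d neurons", len(gt))

    if "extract" in stages:
        if features is None:
            input_dir = config.get("input_dir")
            if input_dir is None:
                raise DependencyError(
                    "extract requested without generated recordings or "
                    "an input_dir"
                )

            def _extract():
                rows = []
                for p in sorted(Path(input_dir).glob("*.h5")):
                    rec = read_recording_set(str(p))
                    fv = extract_features(rec)
                    rows.append(_features_to_row(rec.neuron_id, rec.age_days,
                                                 rec.stage, fv))
                return pd.DataFrame(rows)

            features = timed("extract", _extract)
        write_feature_table(features, outdir / "features.csv")
        results["features"] = features

    if features is None and any(s in stages for s in
                                ("classify", "stack", "cluster", "pca",
                                 "perturb")):
        fpath = outdir / "features.csv"
        if fpath.exists():
            features = read_feature_table(fpath)
        else:
            raise DependencyError(
                "downstream stages requested without extracted features"
            )

    if "classify" in stages:
        labels = features[["neuron_id", "stage", "cv_isi"]].copy()
        labels["label"] = labels["cv_isi"].map(
            lambda c: classify_firing(c) if pd.notna(c) else None)
        labels.to_csv(outdir / "labels.csv", index=False)
        props = pattern_proportions(features)
        props.to_csv(outdir / "pattern_proportions.csv")
        results["labels"] = labels
        results["pattern_proportions"] = props

    if "stack" in stages:
        stacking = timed("stack", lambda: build_stacking_table(features))
        stacking.to_csv(outdir / "stacking.csv", index=False,
                        float_format="%.6g")
        results["stacking"] = stacking

    matrix = None
    if "cluster" in stages or "pca" in stages or "perturb" in stages:
        matrix = mv.normalize_features(
            features, mode=config.get("normalization", "mean"))

    if "cluster" in stages:
        Z = mv.ahc_ward(matrix)
        classes = mv.auto_cut(Z, matrix, k=config.get("k"))
        (outdir / "dendrogram.nwk").write_text(
            mv.dendrogram_to_newick(Z, list(features["neuron_id"])))
        cls_df = features[["neuron_id", "stage", "age_days"]].copy()
        cls_df["class_id"] = classes.labels
        cls_df.to_csv(outdir / "classes.csv", index=False)
        results["linkage"] = Z
        results["classes"] = classes

    model = None
    if "pca" in stages or "perturb" in stages:
        model = mv.pca_covariance(matrix)
        scores = pd.DataFrame(model.scores[:, :2], columns=["f1", "f2"])
        scores.insert(0, "neuron_id", features["neuron_id"].to_numpy())
        scores.to_csv(outdir / "scores.csv", index=False,
                      float_format="%.8g")
        with open(outdir / "pca_model.json", "w") as fh:
            json.dump({
                "columns": model.columns,
                "means": model.means.tolist(),
                "divisors": model.divisors.tolist(),
                "components": model.components.tolist(),
                "eigenvalues": model.eigenvalues.tolist(),
                "variance_fractions": model.variance_fractions.tolist(),
            }, fh, indent=1)
        traj = mv.stage_trajectory(model.scores, features["stage"],
                                   features["age_days"])
        traj.to_csv(outdir / "trajectory.csv", index=False,
                    float_format="%.8g")
        ell = mv.variability_ellipse(traj)
        ell.to_csv(outdir / "ellipses.csv", index=False, float_format="%.8g")
        results["pca"] = model
        results["trajectory"] = traj
        results["ellipses"] = ell

    if "perturb" in stages:
        pcfg = config.get("perturb", {})
        stage = pcfg.get("stage", "P8-P9")
        n = int(pcfg.get("n", 10))
        pharm = PharmacologySpec(
            ahp_block_fraction=float(pcfg.get("ahp_block", 0.775)),
            sodium_scale=float(pcfg.get("na_scale", 1.0)))
        leak = (LeakSpec(target_r_in=float(pcfg["leak_target"]))
                if "leak_target" in pcfg else None)
        kappa = float(pcfg.get("kappa", 4.0))
        calib = load_default_calibration()
        rng = np.random.default_rng(seed + 1)
        before_rows, after_rows = [], []
        for i in range(n):
            truth = sample_neuron_params(stage, calib, rng)
            pert = apply_perturbation(truth, leak=leak, pharm=pharm,
                                      kappa=kappa)
            before_rows.append(ground_truth_features(truth))
            after_rows.append(ground_truth_features(pert))
        before = pd.DataFrame(before_rows)
        after = pd.DataFrame(after_rows)
        shift = phenotype_shift(model, before, after)
        pd.DataFrame({
            "condition": ["before", "after", "shift"],
            "f1": [shift.before_mean[0], shift.after_mean[0], shift.shift[0]],
            "f2": [shift.before_mean[1], shift.after_mean[1], shift.shift[1]],
        }).to_csv(outdir / "shift.csv", index=False, float_format="%.8g")
        results["shift"] = shift

    return results
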