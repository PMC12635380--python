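"""End-to-end desk-scale demo pipeline.

Runs the whole workflow on synthetic data: build a connectome, calibrate the
global coupling against a reference FCD sample, generate a training set,
train an inverse regressor, simulate a two-cohort pseudo-study, infer
bifurcation parameters and run the group/individual analyses.  Every stage
derives its own seed deterministically from the global seed, writes plain
CSV/text artifacts, and is recorded in a run manifest.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .analysis import (
    NetworkMap,
    classify_cohorts_svm,
    network_activation,
    node_mean,
    pairwise_mwu_bh,
    permutation_importance,
)
from .calibration import simulate_group_fcd, sweep_global_coupling
from .inference import infer_cohorts
from .regression import TrainingConfig, save_regressor, train_regressor
from .sim import SimulationConfig
from .synthdata import generate_pseudo_cohorts, generate_training_set, random_connectome

__all__ = ["DemoConfig", "run_demo", "stage_seed"]


@dataclass(frozen=True)
class DemoConfig:
    """Configuration of the demo pipeline; round-trips losslessly via JSON."""

    seed: int = 0
    n_regions: int = 10
    # calibration stage
    g_true: float = 1.0
    g_min: float = 0.0
    g_max: float = 2.0
    g_step: float = 0.1
    calib_subjects: int = 6
    calib_samples: int = 150
    # training stage
    train_samples: int = 1500
    window: int = 50
    epochs: int = 12
    model_scale: str = "tiny"
    approach: str = "sequence"
    # cohort stage
    cohort_means: tuple = (-0.10, 0.05)
    cohort_labels: tuple = ("rest", "task")
    a_spread: float = 0.05
    subjects_per_cohort: int = 150
    t_range: tuple = (120, 200)

    @classmethod
    def from_file(cls, path: str | Path) -> "DemoConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("cohort_means", "cohort_labels", "t_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def stage_seed(global_seed: int, stage: int) -> int:
    """Deterministic per-stage seed fan-out (documented derivation)."""
    return int(np.random.SeedSequence([int(global_seed), stage]).generate_state(1)[0] % (2**31))


def run_demo(config: DemoConfig, out_dir: str | Path, log=print) -> dict:
    """Execute all six stages and return the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}

    def record(name, seed, t0, artifacts, **extra):
        entry = {"stage": name, "seed": seed, "elapsed_s": round(time.perf_counter() - t0, 2),
                 "artifacts": artifacts, **extra}
        manifest["stages"].append(entry)
        log(f"[{name}] done in {entry['elapsed_s']}s -> {', '.join(artifacts) or '-'}")
        return entry

    # stage 0: connectome
    t0 = time.perf_counter()
    seed0 = stage_seed(config.seed, 0)
    conn = random_connectome(config.n_regions, seed=seed0)
    hio.save_matrix(conn.weights, out / "connectome.txt", header=" ".join(conn.region_names))
    record("connectome", seed0, t0, ["connectome.txt"], n_regions=config.n_regions)

    # stage 1: calibrate G against a reference FCD sample generated at g_true
    t0 = time.perf_counter()
    seed1 = stage_seed(config.seed, 1)
    sim_cfg = SimulationConfig(seed=seed1)
    rng = np.random.default_rng(seed1)
    omega = rng.uniform(0.05, 0.25, size=config.n_regions)
    reference = simulate_group_fcd(
        conn, omega, config.g_true, config.calib_subjects, config.calib_samples, sim_cfg, rng
    )
    grid = np.arange(config.g_min, config.g_max + config.g_step / 2, config.g_step)
    sweep = sweep_global_coupling(
        reference, conn, omega, grid,
        n_subjects=config.calib_subjects, config=sim_cfg, n_samples=config.calib_samples,
    )
    pd.DataFrame({"G": sweep.g_grid, "ks": sweep.ks_values}).to_csv(out / "sweep.csv", index=False)
    record("calibrate", seed1, t0, ["sweep.csv"], g_true=config.g_true, g_opt=sweep.g_opt)

    # stage 2: synthetic training set at the calibrated coupling
    t0 = time.perf_counter()
    seed2 = stage_seed(config.seed, 2)
    train_set = generate_training_set(
        config.train_samples, config.window, conn, sweep.g_opt,
        SimulationConfig(seed=seed2),
    )
    record("gen-data", seed2, t0, [], S=config.train_samples, W=config.window, G=sweep.g_opt)

    # stage 3: train the inverse regressor
    t0 = time.perf_counter()
    seed3 = stage_seed(config.seed, 3)
    model = train_regressor(
        train_set,
        TrainingConfig(approach=config.approach, epochs=config.epochs,
                       model_scale=config.model_scale, seed=seed3),
    )
    save_regressor(model, out / "model.npz")
    pd.DataFrame(model.history).to_csv(out / "history.csv", index=False)
    val_nrmse = model.history[-1]["val_nrmse"]
    record("train", seed3, t0, ["model.npz", "model.json", "history.csv"], val_nrmse=val_nrmse)

    # stage 4: pseudo-cohorts + inference
    t0 = time.perf_counter()
    seed4 = stage_seed(config.seed, 4)
    cohorts = generate_pseudo_cohorts(
        len(config.cohort_means), config.subjects_per_cohort, conn, sweep.g_opt,
        SimulationConfig(seed=seed4),
        cohort_a_means=np.array(config.cohort_means), a_spread=config.a_spread,
        T_range=tuple(config.t_range), cohort_labels=list(config.cohort_labels),
    )
    preds = infer_cohorts(model, cohorts, W=config.window)
    long = [
        {"cohort": preds.cohort_labels[c], "subject": s, "region": conn.region_names[n],
         "a_hat": preds.a_hat[c, s, n]}
        for c in range(preds.a_hat.shape[0])
        for s in range(preds.a_hat.shape[1])
        for n in range(preds.a_hat.shape[2])
    ]
    pd.DataFrame(long).to_csv(out / "predictions.csv", index=False)
    record("infer", seed4, t0, ["predictions.csv"],
           cohorts=list(preds.cohort_labels), subjects=config.subjects_per_cohort)

    # stage 5: group + individual analyses
    t0 = time.perf_counter()
    seed5 = stage_seed(config.seed, 5)
    means = node_mean(preds)
    tests = pairwise_mwu_bh(means, cohort_labels=list(preds.cohort_labels))
    tests.to_csv(out / "tests.csv", index=False)
    C, S, N = preds.a_hat.shape
    features = preds.a_hat.reshape(C * S, N)
    labels = np.repeat(list(preds.cohort_labels), S)
    svm = classify_cohorts_svm(features, labels, seed=seed5)
    pd.DataFrame(svm.confusion, index=svm.classes, columns=svm.classes).to_csv(out / "confusion.csv")
    importance = permutation_importance(svm.model, svm.X_test, svm.y_test, seed=seed5,
                                        feature_names=conn.region_names)
    importance.to_csv(out / "importance.csv", index=False)
    half = [f"net{1 + (i % 2)}" for i in range(N)]
    nmap = NetworkMap(dict(zip(conn.region_names, half)), ("net1", "net2"))
    activation = network_activation(preds, nmap, rest_label=config.cohort_labels[0],
                                    region_names=conn.region_names)
    activation.to_csv(out / "activation.csv")
    record("analyze", seed5, t0,
           ["tests.csv", "confusion.csv", "importance.csv", "activation.csv"],
           min_p_adj=float(tests["p_adj"].min()), svm_test_accuracy=svm.test_accuracy,
           svm_cv_mean=svm.cv_mean)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
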