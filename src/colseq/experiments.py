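"""Named experiments reproducing the study protocol end to end.

Each experiment builds network instance(s), trains on its canonical
sequence, runs cued recall, computes the analysis metrics and writes a
results bundle (config, spike files, weight trajectories, metrics) under a
run directory.  Instance counts default to desk-scale values; the full
counts are config-selectable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (
    convergence_trial,
    count_deviation_outliers,
    modified_zscore,
    ordered_fraction,
    pooled_isi_cv,
    recall_metrics,
)
from .architecture import apply_weight_overrides, build_network
from .config import NetworkConfig, save_config
from .protocol import RunResult, StimulusSequence, run_recall, run_training

__all__ = ["ExperimentSpec", "EXPERIMENTS", "run_experiment", "sweep", "generate_fixtures", "train_and_recall"]

# canonical stimulus sequences
SEQUENCES = {
    "fig1": StimulusSequence.of([500.0, 1000.0, 700.0, 1800.0]),
    "robustness": StimulusSequence.of([700.0] * 4),
    "three": StimulusSequence.of([700.0] * 3),
    "two": StimulusSequence.of([700.0] * 2),
    "two_short": StimulusSequence.of([500.0] * 2),
}


@dataclass(frozen=True)
class ExperimentSpec:
    """One named experiment: variant + sequence + overrides + scale."""

    name: str
    sequence: str
    variant: str = "baseline"
    n_columns: int | None = None          # default: sequence length
    n_per_pop: int = 100
    n_train: int = 100
    n_recall: int = 50
    n_instances: int = 3
    weight_overrides: dict = field(default_factory=dict)
    config_overrides: dict = field(default_factory=dict)
    randomize: str | None = None


EXPERIMENTS = {
    "fig1_sequence": ExperimentSpec("fig1_sequence", "fig1", n_instances=1),
    "robustness_weights": ExperimentSpec("robustness_weights", "robustness", n_instances=3),
    "robustness_learning": ExperimentSpec(
        "robustness_learning", "robustness", n_instances=3, randomize="per_trial"
    ),
    "inhibition_sweep": ExperimentSpec(
        "inhibition_sweep", "three", n_instances=2, weight_overrides={"t_to_it": 40.0}
    ),
    # scaled wiring needs weaker local T->I_T and cross-columnar inhibition
    # on top of the sqrt(N/N') static rescale (I_T must decay faster than its
    # Timer yet spare the other columns' ignition)
    "scaling": ExperimentSpec(
        "scaling", "three", variant="scaled", n_per_pop=400, n_instances=1,
        weight_overrides={"t_to_it": -30.0, "it_to_t": -30.0},
    ),
    "all_to_all": ExperimentSpec("all_to_all", "robustness", variant="all_to_all", n_instances=1),
    "all_to_all_low_noise": ExperimentSpec(
        "all_to_all_low_noise",
        "robustness",
        variant="all_to_all",
        n_instances=1,
        weight_overrides={"m_to_im": ("abs", 0.84), "w_in": ("abs", 110.0),
                          "t_to_m": ("abs", 0.70), "it_to_m": ("abs", 2.0)},
        config_overrides={"noise.sigma_xi": 50.0, "synapse.g_sat_exc": 12.0, "synapse.u_dep": 0.015},
    ),
    "all_to_all_high_threshold": ExperimentSpec(
        "all_to_all_high_threshold",
        "robustness",
        variant="all_to_all",
        n_instances=1,
        config_overrides={"traces.r_th_ff": 30.0},
    ),
    "local_inhibition": ExperimentSpec(
        "local_inhibition", "two", variant="local_inhibition", n_instances=1
    ),
}


def _apply_config_overrides(config: NetworkConfig, overrides: dict) -> NetworkConfig:
    """Dotted-path overrides, e.g. {"noise.sigma_xi": 50.0}."""
    for path, value in overrides.items():
        group, _, name = path.partition(".")
        if not name:
            config = config.replace(**{group: value})
        else:
            sub = dataclasses.replace(getattr(config, group), **{name: value})
            config = config.replace(**{group: sub})
    return config


def build_for(spec: ExperimentSpec, seed: int):
    seq = SEQUENCES[spec.sequence]
    config = NetworkConfig(
        n_columns=spec.n_columns or len(seq.elements),
        n_per_pop=spec.n_per_pop,
        variant=spec.variant,
    )
    config = _apply_config_overrides(config, spec.config_overrides)
    model = build_network(config, seed)
    if spec.weight_overrides:
        model = apply_weight_overrides(model, spec.weight_overrides)
    return model, seq


def train_and_recall(
    spec: ExperimentSpec, seed: int, record_spikes: bool = True
) -> tuple[RunResult, RunResult]:
    """One instance: build, train, recall."""
    model, seq = build_for(spec, seed)
    train = run_training(
        model, seq, n_trials=spec.n_train, seed=seed + 10_000, randomize=spec.randomize
    )
    recall = run_recall(model, seq, n_trials=spec.n_recall, seed=seed + 20_000,
                        record_spikes=record_spikes)
    return train, recall


def _instance_metrics(train: RunResult, recall: RunResult) -> dict:
    seq = recall.seq
    df = recall_metrics(recall)
    last = df[df["position"] == len(seq.elements) - 1]
    rec_cls = [c for c in train.model.pl_class_names if c.startswith("T")]
    w_rec = np.mean([train.weight_series(c) for c in rec_cls], axis=0)
    out = {
        "ordered_fraction": ordered_fraction(recall),
        "cv_timer": pooled_isi_cv(recall, "T"),
        "cv_messenger": pooled_isi_cv(recall, "M"),
        "convergence_trial": convergence_trial(w_rec, rel_tol=0.02, patience=None),
        "last_col_median_rel_ms": float(np.nanmedian(last["t_rel"])),
        "outliers_140ms_last_col": count_deviation_outliers(
            last["t_rel"], last["expected_end"] - last["expected_onset"]
        ),
    }
    z_flags = []
    for pos, grp in df.groupby("position"):
        if np.isfinite(grp["t_abs"]).sum() >= 2:
            _, flags = modified_zscore(grp["t_abs"])
            z_flags.append(flags.sum())
    out["zscore_outliers_mean"] = float(np.mean(z_flags)) if z_flags else float("nan")
    return out


def run_experiment(name: str, seed: int = 0, out_dir: str | Path | None = None,
                   n_instances: int | None = None) -> pd.DataFrame:
    """Run all instances of a named experiment; optionally write a bundle.

    Returns one metrics row per instance.  The bundle contains the config
    (YAML), per-instance recall metrics and weight trajectories (CSV) and
    the first recall trial's spikes in gdf-style text, one file per
    population.
    """
    spec = EXPERIMENTS[name]
    if n_instances is not None:
        spec = dataclasses.replace(spec, n_instances=n_instances)
    rows = []
    bundles = []
    for k in range(spec.n_instances):
        train, recall = train_and_recall(spec, seed + 1000 * k)
        row = {"experiment": name, "instance": k, **_instance_metrics(train, recall)}
        rows.append(row)
        bundles.append((train, recall))
    metrics = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir) / name
        out.mkdir(parents=True, exist_ok=True)
        model = bundles[0][0].model
        save_config(model.config, out / "config.yaml")
        metrics.to_csv(out / "metrics.csv", index=False)
        weights = pd.DataFrame(
            {c: bundles[0][0].weight_series(c) for c in model.pl_class_names}
        )
        weights.index.name = "trial"
        weights.to_csv(out / "weights.csv")
        for inst, (train, recall) in enumerate(bundles):
            recall_metrics(recall).to_csv(out / f"recall_times_inst{inst}.csv", index=False)
        tr0 = bundles[0][1].trials[0]
        if tr0.spikes is not None:
            spikes_dir = out / "spikes"
            spikes_dir.mkdir(exist_ok=True)
            for p in model.populations:
                rec = tr0.spikes.select(p.ids)
                rec.to_gdf(spikes_dir / f"{p.role}{p.column}_recall0.gdf")
    return metrics


def sweep(
    classes: list[str],
    grid: list[float],
    seq_name: str = "robustness",
    n_instances: int = 2,
    n_train: int = 100,
    n_recall: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Cartesian weight sweep: percent deltas applied per class.

    Per grid cell: train fresh instances with the shifted class mean(s),
    run recall, report outlier counts and the median recall-time deviation.
    Unstable cells (no recall) are flagged, not fatal.
    """
    seq = SEQUENCES[seq_name]
    rows = []
    mesh = np.meshgrid(*([grid] * len(classes)), indexing="ij")
    cells = np.stack([m.ravel() for m in mesh], axis=-1)
    for cell in cells:
        overrides = {cls: float(d) for cls, d in zip(classes, cell)}
        for k in range(n_instances):
            config = NetworkConfig(n_columns=len(seq.elements))
            model = build_network(config, seed + 97 * k)
            model = apply_weight_overrides(model, overrides)
            train = run_training(model, seq, n_trials=n_train, seed=seed + 7 + k)
            recall = run_recall(model, seq, n_trials=n_recall, seed=seed + 13 + k,
                                record_spikes=False)
            df = recall_metrics(recall)
            last = df[df["position"] == len(seq.elements) - 1]
            n_fail = int((~np.isfinite(last["t_abs"])).sum())
            rows.append(
                {
                    **{f"delta_{c}": d for c, d in overrides.items()},
                    "instance": k,
                    "outliers_140ms_last_col": count_deviation_outliers(
                        last["t_rel"], last["expected_end"] - last["expected_onset"]
                    ),
                    "median_dev_last_col_ms": float(
                        np.nanmedian(last["t_rel"] - (last["expected_end"] - last["expected_onset"]))
                    ),
                    "failed_recalls": n_fail,
                    "unstable": bool(n_fail > n_recall // 2),
                }
            )
    return pd.DataFrame(rows)


def generate_fixtures(kind: str, out_dir: str | Path | None = None):
    """Canonical sequences and per-experiment configs.

    kind in {"fig1", "robustness", "scaling", "two", "two_short", "all"}:
    returns the sequence(s); with ``out_dir`` also writes one YAML config
    per named experiment plus a sequences.json.
    """
    kinds = {
        "fig1": "fig1",
        "robustness": "robustness",
        "scaling": "three",
        "two": "two",
        "two_short": "two_short",
    }
    if kind != "all" and kind not in kinds:
        raise ValueError(f"unknown fixture kind {kind!r}")
    names = list(kinds) if kind == "all" else [kind]
    seqs = {n: SEQUENCES[kinds[n]] for n in names}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            n: [[c, d] for c, d in s.elements] for n, s in seqs.items()
        }
        (out / "sequences.json").write_text(json.dumps(payload, indent=2))
        for name, spec in EXPERIMENTS.items():
            seq = SEQUENCES[spec.sequence]
            config = NetworkConfig(
                n_columns=spec.n_columns or len(seq.elements),
                n_per_pop=spec.n_per_pop,
                variant=spec.variant,
            )
            config = _apply_config_overrides(config, spec.config_overrides)
            save_config(config, out / f"{name}.yaml")
    return seqs if kind == "all" else seqs[kind]
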