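"""Measurement procedures: recall times, outlier statistics, spike stats.

Recall time of a column is the time at which its Timer population rate
(mean of per-neuron exponentially filtered rates, tau_r = 40 ms) drops
below 10 spks/sec, after having first exceeded that threshold for at least
20 ms (onset guard against pre-activation crossings).  *Relative* recall
times are measured from the column's expected onset on the stimulation
grid; *absolute* times from sequence start.

Outliers are counted two ways: deviations beyond a fixed tolerance
(140 ms, i.e. 20% of a 700 ms interval) from the expected interval, and a
modified z-score based on the median absolute deviation
(z = 0.6745 (x - median)/MAD, outlier if |z| > 3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import ROLES, NetworkModel
from .dynamics import SpikeRecord
from .protocol import RunResult, StimulusSequence, TrialResult

__all__ = [
    "recall_time",
    "activation_onset",
    "count_deviation_outliers",
    "modified_zscore",
    "isi_cv",
    "weight_trajectory",
    "convergence_trial",
    "recall_metrics",
    "pooled_isi_cv",
    "activation_order",
    "ordered_fraction",
]

RATE_THRESHOLD = 10.0  # spks/sec


def _sustained_onset(times, trace, threshold, guard_ms, search_from):
    """Index of the first sample where the rate has stayed >= threshold
    for guard_ms; None if the population never activates."""
    if len(times) < 2:
        return None
    dt = times[1] - times[0]
    need = max(1, int(round(guard_ms / dt)))
    above = (trace >= threshold) & (times >= search_from)
    run = 0
    for k, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= need:
            return k
    return None


def recall_time(
    times: np.ndarray,
    trace: np.ndarray,
    threshold: float = RATE_THRESHOLD,
    onset_guard_ms: float = 20.0,
    search_from: float = 0.0,
) -> float:
    """First threshold down-crossing after a sustained activation.

    Returns NaN (sentinel) if the population never activates, and the end
    of the trace if the rate never falls back below threshold.
    """
    k0 = _sustained_onset(times, trace, threshold, onset_guard_ms, search_from)
    if k0 is None:
        return np.nan
    below = np.flatnonzero(trace[k0:] < threshold)
    if len(below) == 0:
        return float(times[-1])
    return float(times[k0 + below[0]])


def activation_onset(
    times: np.ndarray,
    trace: np.ndarray,
    threshold: float = RATE_THRESHOLD,
    onset_guard_ms: float = 20.0,
    search_from: float = 0.0,
) -> float:
    """Start of the first sustained supra-threshold excursion (NaN if none)."""
    k0 = _sustained_onset(times, trace, threshold, onset_guard_ms, search_from)
    if k0 is None:
        return np.nan
    dt = times[1] - times[0]
    need = max(1, int(round(onset_guard_ms / dt)))
    return float(times[k0 - need + 1])


def count_deviation_outliers(times, expected, tol: float = 140.0) -> int:
    """Number of |time - expected| > tol; NaN (failed recall) counts as one."""
    times = np.asarray(times, dtype=float)
    expected = np.broadcast_to(np.asarray(expected, dtype=float), times.shape)
    dev = np.abs(times - expected)
    return int(np.sum(~np.isfinite(dev) | (dev > tol)))


def modified_zscore(values) -> tuple[np.ndarray, np.ndarray]:
    """Iglewicz-Hoaglin modified z-scores and |z| > 3 outlier flags.

    z_i = 0.6745 (x_i - median) / MAD.  If the MAD is zero all scores are
    zero by convention.  NaN inputs get NaN scores and are never flagged.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError("need at least two finite values")
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    z = np.full_like(x, np.nan)
    if mad == 0.0:
        z[finite] = 0.0
    else:
        z[finite] = 0.6745 * (x[finite] - med) / mad
    flags = np.zeros_like(finite)
    flags[finite] = np.abs(z[finite]) > 3.0
    return z, flags


def isi_cv(
    record: SpikeRecord,
    neuron_ids: np.ndarray,
    t_min: float | None = None,
    t_max: float | None = None,
) -> float:
    """Coefficient of variation of pooled inter-spike intervals.

    ISIs are differenced per neuron, then pooled across the population;
    NaN if fewer than two intervals are available.
    """
    isis = record.isis(neuron_ids, t_min, t_max)
    if len(isis) < 2:
        return np.nan
    return float(np.std(isis) / np.mean(isis))


def weight_trajectory(result: RunResult, class_name: str) -> np.ndarray:
    """Per-trial mean weight of one plastic class over training."""
    return result.weight_series(class_name)


def convergence_trial(
    series: np.ndarray,
    rel_tol: float = 0.02,
    patience: int | None = 20,
) -> float:
    """First trial after which the per-trial relative change stays small.

    Returns the 1-based trial index i such that
    |w[k] - w[k-1]| / |w[k-1]| < rel_tol for the next ``patience``
    consecutive trials (all remaining trials if ``patience`` is None);
    NaN if the series never settles.
    """
    w = np.asarray(series, dtype=float)
    if len(w) < 2:
        return 1.0
    denom = np.maximum(np.abs(w[:-1]), 1e-12)
    small = np.abs(np.diff(w)) / denom < rel_tol
    n = len(small)
    for i in range(n):
        horizon = n if patience is None else min(n, i + patience)
        if horizon == i:
            break
        if small[i:horizon].all():
            return float(i + 1)
    return np.nan


def recall_metrics(
    recall: RunResult,
    expected_onsets: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tidy per-trial, per-column recall-time table.

    Columns: trial, column, position, expected_onset, expected_end, t_abs
    (absolute recall time, NaN if the column never activated), t_rel
    (measured from the expected onset).
    """
    seq, model = recall.seq, recall.model
    onsets = seq.onsets if expected_onsets is None else np.asarray(expected_onsets)
    rows = []
    for tr in recall.trials:
        for pos, (col, dur) in enumerate(seq.elements):
            trace = tr.rate(model, "T", col)
            t_abs = recall_time(tr.rate_times, trace)
            rows.append(
                {
                    "trial": tr.trial,
                    "column": col,
                    "position": pos,
                    "expected_onset": onsets[pos],
                    "expected_end": onsets[pos] + dur,
                    "t_abs": t_abs,
                    "t_rel": t_abs - onsets[pos],
                }
            )
    return pd.DataFrame(rows)


def pooled_isi_cv(
    recall: RunResult,
    role: str = "T",
    threshold: float = RATE_THRESHOLD,
) -> float:
    """Population CV of ISIs during the columns' active epochs, pooled
    across columns and recall trials."""
    model, seq = recall.model, recall.seq
    isis = []
    for tr in recall.trials:
        if tr.spikes is None:
            continue
        for col, _ in seq.elements:
            trace = tr.rate(model, role, col)
            t_on = activation_onset(tr.rate_times, trace, threshold)
            t_off = recall_time(tr.rate_times, trace, threshold)
            if not np.isfinite(t_on) or not np.isfinite(t_off):
                continue
            ids = model.pop(role, col).ids
            isis.append(tr.spikes.isis(ids, t_on, t_off))
    if not isis:
        return np.nan
    pooled = np.concatenate(isis)
    if len(pooled) < 2:
        return np.nan
    return float(np.std(pooled) / np.mean(pooled))


def activation_order(
    trial: TrialResult,
    model: NetworkModel,
    threshold: float = RATE_THRESHOLD,
    guard_ms: float = 20.0,
) -> list[int]:
    """Columns ordered by the onset of their Timer activation (absent
    columns omitted)."""
    onsets = []
    for col in range(1, model.config.n_columns + 1):
        t_on = activation_onset(trial.rate_times, trial.rate(model, "T", col), threshold, guard_ms)
        if np.isfinite(t_on):
            onsets.append((t_on, col))
    return [c for _, c in sorted(onsets)]


def ordered_fraction(recall: RunResult) -> float:
    """Fraction of recall trials whose column activation order matches the
    stimulation order of the sequence."""
    target = [c for c, _ in recall.seq.elements]
    hits = sum(1 for tr in recall.trials if activation_order(tr, recall.model) == target)
    return hits / len(recall.trials)
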