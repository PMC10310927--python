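"""Stimulus construction, reward scheduling and trial orchestration.

A stimulus sequence is an ordered list of (column, duration) elements.
Within a trial the elements are contiguous: element k+1 starts at element
k's offset.  Each element onset triggers a 50 ms step stimulus, encoded as
independent Poisson spike trains (30 spks/sec) to the stimulated column's
afferent neurons.  A global reward/novelty gate of 25 ms opens 25 ms after
every element offset (interior offsets coincide with the next onset; a
final window follows the last element).

Training trials run with plasticity on and commit the accumulated weight
changes at the trial boundary; membrane state and traces are reset at every
trial start.  Recall trials deliver a single cue to the sequence's first
column, with no reward and no weight updates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _engine
from .architecture import ROLES, NetworkModel
from .config import TraceParams
from .dynamics import SimState, SpikeRecord

__all__ = [
    "StimulusSequence",
    "TrialResult",
    "RunResult",
    "make_stimulus",
    "schedule_rewards",
    "run_training",
    "run_recall",
    "randomize_learning_params",
]


@dataclass(frozen=True)
class StimulusSequence:
    """Ordered sequence elements: (column index 1..N_C, duration ms)."""

    elements: tuple[tuple[int, float], ...]

    def __post_init__(self):
        cols = [c for c, _ in self.elements]
        if len(set(cols)) != len(cols):
            raise ValueError("stimulus-to-column mapping must be unique")

    @classmethod
    def of(cls, durations, columns=None) -> "StimulusSequence":
        if columns is None:
            columns = range(1, len(tuple(durations)) + 1)
        return cls(tuple((int(c), float(d)) for c, d in zip(columns, durations)))

    @property
    def onsets(self) -> np.ndarray:
        d = np.array([dur for _, dur in self.elements])
        return np.concatenate([[0.0], np.cumsum(d)[:-1]])

    @property
    def offsets(self) -> np.ndarray:
        return np.cumsum([dur for _, dur in self.elements]).astype(float)

    @property
    def total(self) -> float:
        return float(sum(dur for _, dur in self.elements))

    def validate(self, model: NetworkModel) -> None:
        nc = model.config.n_columns
        pulse = model.config.stimulus.pulse_ms
        for col, dur in self.elements:
            if not 1 <= col <= nc:
                raise ValueError(f"column {col} outside 1..{nc}")
            if dur <= pulse:
                raise ValueError(f"element duration {dur} ms must exceed the {pulse} ms pulse")


def make_stimulus(
    model: NetworkModel,
    column: int,
    onset: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson afferent spikes for one 50 ms stimulus pulse.

    Every afferent neuron of the stimulated column (Timers and I_T in the
    baseline wiring; Timers only under local inhibition) receives an
    independent 30 spks/sec train over [onset, onset + 50 ms), delivered
    through the input channel with weight ``model.input_w``.
    """
    st = model.config.stimulus
    targets = np.flatnonzero(model.input_mask & (model.column == column))
    counts = rng.poisson(st.nu_in * st.pulse_ms / 1000.0, size=len(targets))
    tgt = np.repeat(targets, counts)
    times = onset + rng.uniform(0.0, st.pulse_ms, size=len(tgt))
    return times, tgt


def _trial_input(model, seq: StimulusSequence, rng, cue_only=False):
    times, tgts = [], []
    elements = seq.elements[:1] if cue_only else seq.elements
    for (col, _), onset in zip(elements, seq.onsets):
        t, g = make_stimulus(model, col, onset, rng)
        times.append(t)
        tgts.append(g)
    return np.concatenate(times), np.concatenate(tgts)


def schedule_rewards(seq: StimulusSequence, reward, include_onset: bool = True) -> np.ndarray:
    """Reward windows [t, t + duration) at the element boundaries.

    The reward/novelty gate marks each stimulus onset and offset; interior
    onsets coincide with the previous element's offset, so the schedule is
    one window per element offset (delayed by ``d_reward``), plus one for
    the first element's onset at t = 0 when ``include_onset`` is set.  The
    onset window matters for symmetry: every later column has its freshly
    activated traces consumed (and made refractory) by the preceding
    element's reward; the onset window does the same for the first column,
    so all columns accumulate eligibility from an equal footing.  Raises if
    windows would overlap (elements shorter than delay + duration).
    """
    if not seq.elements:
        return np.empty((0, 2))
    starts = seq.offsets + reward.d_reward
    if include_onset:
        starts = np.concatenate([[reward.d_reward], starts])
    windows = np.column_stack([starts, starts + reward.duration])
    if np.any(windows[1:, 0] < windows[:-1, 1]):
        raise ValueError("reward windows overlap; elements too short")
    return windows


def randomize_learning_params(
    params: TraceParams,
    rng: np.random.Generator,
    spread: float = 0.2,
) -> TraceParams:
    """Independently jitter trace time constants and activation rates.

    Each of tau_p, tau_d, tau_ffp, tau_ffd, eta_p, eta_d, eta_ffp, eta_ffd
    is multiplied by an independent uniform draw from [1-spread, 1+spread].
    """
    if spread < 0:
        raise ValueError("spread must be >= 0")
    names = ("tau_p", "tau_d", "tau_ffp", "tau_ffd", "eta_p", "eta_d", "eta_ffp", "eta_ffd")
    factors = rng.uniform(1.0 - spread, 1.0 + spread, size=len(names))
    return dataclasses.replace(params, **{n: getattr(params, n) * f for n, f in zip(names, factors)})


@dataclass
class TrialResult:
    """Per-trial record: rates on the 1 ms grid, weights, optional spikes."""

    trial: int
    phase: str                      # "train" or "recall"
    rate_times: np.ndarray
    pop_rates: np.ndarray           # (n_rec, 4 * n_columns) float32
    class_means: dict[str, float]   # plastic class -> mean weight after commit
    spikes: SpikeRecord | None = None

    def rate(self, model: NetworkModel, role: str, column: int) -> np.ndarray:
        return self.pop_rates[:, (column - 1) * 4 + ROLES[role]].astype(float)


@dataclass
class RunResult:
    trials: list[TrialResult]
    model: NetworkModel
    seq: StimulusSequence

    def weight_series(self, class_name: str) -> np.ndarray:
        return np.array([t.class_means[class_name] for t in self.trials])


def _class_means(packed: _engine.PackedNet, names: list[str]) -> dict[str, float]:
    out = {}
    for i, name in enumerate(names):
        mask = packed.p_class == i
        out[name] = float(packed.p_w[mask].mean()) if mask.any() else 0.0
    return out


def _run_phase(
    model: NetworkModel,
    seq: StimulusSequence,
    n_trials: int,
    seed: int,
    phase: str,
    randomize: str | None = None,
    spread: float = 0.2,
    record_spikes: bool = False,
    trial_offset: int = 0,
) -> RunResult:
    cfg = model.config
    seq.validate(model)
    rng = np.random.default_rng(seed)
    packed = _engine.pack_network(model)
    train = phase == "train"
    tail = cfg.sim.train_tail if train else cfg.sim.recall_tail
    duration = seq.total + tail
    rewards = schedule_rewards(seq, cfg.reward) if train else None
    base_traces = cfg.traces
    if randomize == "per_instance":
        model.config = cfg.replace(traces=randomize_learning_params(base_traces, rng, spread))

    results: list[TrialResult] = []
    rate = np.zeros(model.n_neurons)
    for k in range(n_trials):
        if randomize == "per_trial":
            model.config = cfg.replace(traces=randomize_learning_params(base_traces, rng, spread))
        state = SimState.initial(model.n_neurons, cfg.neuron.v_rest)
        rate[:] = 0.0
        inputs = _trial_input(model, seq, rng, cue_only=not train)
        out = _engine.run_trial(
            packed, model, state, inputs[0], inputs[1],
            duration=duration, seed=int(rng.integers(2**31)),
            plasticity=train, reward_windows=rewards, rate=rate,
        )
        if train:
            # end-of-trial commit; mid-trial propagation used start values
            packed.p_w += out.pending_dw
            np.clip(packed.p_w, 0.0, None, out=packed.p_w)
        results.append(
            TrialResult(
                trial=trial_offset + k,
                phase=phase,
                rate_times=out.rate_times,
                pop_rates=out.pop_rates.astype(np.float32),
                class_means=_class_means(packed, model.pl_class_names),
                spikes=out.spikes if record_spikes else None,
            )
        )
    packed.sync_to_model(model)
    model.config = cfg
    return RunResult(results, model, seq)


def run_training(
    model: NetworkModel,
    seq: StimulusSequence,
    n_trials: int = 100,
    seed: int = 0,
    randomize: str | None = None,
    spread: float = 0.2,
    record_spikes: bool = False,
) -> RunResult:
    """Train the network on a stimulus sequence.

    Per trial: reset membranes/conductances/traces, stimulate the columns at
    their element onsets, integrate with plasticity and the reward schedule,
    and commit the accumulated weight changes at the trial end.  ``model``
    is updated in place with the learned plastic weights.
    ``randomize`` in {None, "per_trial", "per_instance"} applies the
    learning-parameter jitter of :func:`randomize_learning_params`.
    """
    if randomize not in (None, "per_trial", "per_instance"):
        raise ValueError("randomize must be None, 'per_trial' or 'per_instance'")
    return _run_phase(model, seq, n_trials, seed, "train", randomize, spread, record_spikes)


def run_recall(
    model: NetworkModel,
    seq: StimulusSequence,
    n_trials: int = 50,
    seed: int = 1,
    record_spikes: bool = True,
) -> RunResult:
    """Cued recall: a single 50 ms cue to the sequence's first column.

    No reward is delivered and plasticity is disabled, so weights are
    unchanged; full spike records are kept by default for the spiking
    statistics.
    """
    return _run_phase(model, seq, n_trials, seed, "recall", record_spikes=record_spikes)
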