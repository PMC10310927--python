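"""Clock-driven LIF integration with saturating conductance synapses.

Membrane dynamics (forward Euler, step ``dt``):

    C_m dV/dt = g_L (V_rest - V) + g_e (E_exc - V) + g_i (E_inh - V) + xi(t)

with four conductance channels per neuron (excitation onto excitatory
targets, excitation onto inhibitory targets, inhibition, external input)
decaying exponentially between spikes.  Each arriving spike of weight w
increments its channel by w * (1 - g / g_sat), so conductances saturate
at g_sat; recurrent Timer synapses additionally carry the short-term
resource of :class:`~colseq.config.SynapseParams`.  Threshold crossings are registered with a delay of one
integration step; the effective refractory period (minimum inter-spike
interval) is 3 ms.

Update order per step (shared with the fused numba engine, which is the
fast path used by the protocol layer):

    1. deliver spikes whose conduction delay expires this step
       (decay conductances, then apply saturating increments),
    2. integrate the membrane with the fresh conductances; neurons inside
       their refractory window stay clamped at V_reset,
    3. register threshold crossings at t + dt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .architecture import CH_EXC, CH_EXC_I, CH_INH, CH_INPUT, NetworkModel

__all__ = ["SimState", "SpikeRecord", "integrate_step", "update_conductances", "run_window"]

N_CHANNELS = 4


@dataclass
class SimState:
    """Membrane and synaptic state of all neurons at one instant."""

    v: np.ndarray            # (n,) mV
    g: np.ndarray            # (n, 4) nS per channel
    ref_until: np.ndarray    # (n,) ms
    x: np.ndarray            # (n,) synaptic resource of outgoing synapses
    t: float                 # ms

    @classmethod
    def initial(cls, n: int, v_rest: float, t: float = 0.0) -> "SimState":
        return cls(
            v=np.full(n, v_rest, dtype=float),
            g=np.zeros((n, N_CHANNELS), dtype=float),
            ref_until=np.full(n, -np.inf),
            x=np.ones(n, dtype=float),
            t=t,
        )

    def check_finite(self) -> None:
        if not np.all(np.isfinite(self.v)):
            bad = np.flatnonzero(~np.isfinite(self.v))[:5]
            raise FloatingPointError(f"non-finite membrane potential at neurons {bad.tolist()}")


@dataclass
class SpikeRecord:
    """Spike events of one simulation window, sorted by time."""

    times: np.ndarray        # ms
    ids: np.ndarray          # neuron ids
    window: tuple[float, float]
    n_neurons: int

    def __len__(self) -> int:
        return len(self.times)

    def select(self, neuron_ids: np.ndarray) -> "SpikeRecord":
        mask = np.isin(self.ids, neuron_ids)
        return SpikeRecord(self.times[mask], self.ids[mask], self.window, self.n_neurons)

    def isis(self, neuron_ids: np.ndarray | None = None, t_min: float | None = None,
             t_max: float | None = None) -> np.ndarray:
        """Inter-spike intervals, differenced per neuron then pooled."""
        times, ids = self.times, self.ids
        if t_min is not None or t_max is not None:
            lo = -np.inf if t_min is None else t_min
            hi = np.inf if t_max is None else t_max
            m = (times >= lo) & (times <= hi)
            times, ids = times[m], ids[m]
        if neuron_ids is not None:
            m = np.isin(ids, neuron_ids)
            times, ids = times[m], ids[m]
        if len(times) < 2:
            return np.empty(0)
        order = np.lexsort((times, ids))
        times, ids = times[order], ids[order]
        d = np.diff(times)
        same = np.diff(ids) == 0
        return d[same]

    def to_gdf(self, path: str | Path) -> None:
        """Two-column whitespace text: neuron id, spike time (ms)."""
        np.savetxt(path, np.column_stack([self.ids, self.times]), fmt="%d %.3f")

    @classmethod
    def from_gdf(cls, path: str | Path, n_neurons: int = 0) -> "SpikeRecord":
        data = np.loadtxt(path, ndmin=2)
        if data.size == 0:
            return cls(np.empty(0), np.empty(0, dtype=int), (0.0, 0.0), n_neurons)
        order = np.argsort(data[:, 1], kind="stable")
        data = data[order]
        return cls(data[:, 1], data[:, 0].astype(int),
                   (float(data[0, 1]), float(data[-1, 1])), n_neurons)


def update_conductances(
    state: SimState,
    arriving: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
    tau_ch: np.ndarray,
    g_sat_ch: np.ndarray,
    dt: float,
) -> SimState:
    """Decay all channels by exp(-dt/tau), then apply saturating increments.

    ``arriving`` holds (target ids, weights, channel codes) of spikes whose
    conduction delay expires at this step.  Increments are applied
    sequentially per event: g += w * (1 - g/g_sat), keeping g in [0, g_sat].
    """
    state.g *= np.exp(-dt / tau_ch)
    if arriving is not None:
        tgt, w, ch = arriving
        if np.any(w < 0):
            raise ValueError("negative synaptic weight; inhibition is routed by channel")
        for k in range(len(tgt)):
            c = ch[k]
            g0 = state.g[tgt[k], c]
            state.g[tgt[k], c] = g0 + w[k] * (1.0 - g0 / g_sat_ch[c])
    return state


def integrate_step(
    state: SimState,
    v_th: np.ndarray,
    neuron,
    dt: float,
    noise: np.ndarray | float = 0.0,
) -> np.ndarray:
    """One forward-Euler membrane step; returns ids of neurons that spiked.

    Spikes are registered at ``state.t + dt`` (one-step delay convention);
    the caller is responsible for scheduling their delayed arrival.
    Refractory neurons stay clamped at V_reset and do not integrate.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    v, g = state.v, state.g
    i_syn = (g[:, CH_EXC] + g[:, CH_INPUT] + g[:, CH_EXC_I]) * (neuron.e_exc - v) + g[:, CH_INH] * (neuron.e_inh - v)
    dv = (dt / neuron.c_m) * (neuron.g_l * (neuron.v_rest - v) + i_syn + noise)
    # half-step tolerance keeps refractory release off the FP knife edge
    active = state.t >= state.ref_until - 0.5 * dt
    v[active] += dv[active]
    v[~active] = neuron.v_reset
    state.check_finite()
    spiking = np.flatnonzero(active & (v >= v_th))
    t_spike = state.t + dt
    v[spiking] = neuron.v_reset
    state.ref_until[spiking] = t_spike + neuron.t_ref
    state.t = t_spike
    return spiking


def run_window(
    model: NetworkModel,
    state: SimState | None,
    external_input: tuple[np.ndarray, np.ndarray] | None,
    duration: float,
    seed: int = 0,
    record_rates: bool = True,
) -> tuple[SimState, SpikeRecord, np.ndarray | None]:
    """Advance the network ``duration`` ms without plasticity.

    ``external_input`` is (spike_times_ms, target_ids) of stimulus afferent
    spikes, delivered through the input channel with weight ``model.input_w``
    after the global conduction delay.  Returns the advanced state, the
    spike record and (optionally) per-population rate traces on the 1 ms
    recording grid.  Deterministic for a fixed seed.
    """
    from . import _engine

    cfg = model.config
    dt = cfg.sim.dt
    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9:
        raise ValueError("duration must be a multiple of dt")
    if state is None:
        state = SimState.initial(model.n_neurons, cfg.neuron.v_rest)
    packed = _engine.pack_network(model)
    if external_input is None:
        in_t = np.empty(0)
        in_tgt = np.empty(0, dtype=np.int64)
    else:
        in_t, in_tgt = external_input
    result = _engine.run_trial(
        packed, model, state, in_t, in_tgt,
        duration=duration, seed=seed, plasticity=False,
        traces=None, reward_windows=None, record_rates=record_rates,
    )
    return result.state, result.spikes, (result.pop_rates if record_rates else None)
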