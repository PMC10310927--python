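"""Reward-gated eligibility-trace plasticity.

Each plastic synapse carries two competing traces, an LTP trace T^p and an
LTD trace T^d, driven by a thresholded Hebbian term H (product of the
pre- and postsynaptic exponentially filtered firing rates):

    tau_a dT^a/dt = -T^a + eta_a * H * (Tmax_a - T^a),   a in {p, d}

Traces are bounded in [0, Tmax_a].  A globally broadcast reward gate of
25 ms converts the trace difference into a tentative weight change,

    dw/dt = eta * R(t) * (T^p - T^d),

after which the traces are consumed (reset to zero and frozen for a 25 ms
trace-refractory period).  Weight changes are accumulated during the trial
and committed only at the trial boundary.

The functions here are the reference (numpy) implementations; the fused
simulation loop in :mod:`colseq._engine` applies the identical update order
and is cross-checked against these in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TraceState",
    "estimate_rate",
    "hebbian_term",
    "update_trace",
    "accumulate_reward_update",
    "consume_traces",
    "commit_weights",
]


@dataclass
class TraceState:
    """Per-plastic-synapse eligibility state."""

    t_p: np.ndarray
    t_d: np.ndarray
    refractory_until: np.ndarray   # ms; traces pinned at 0 while t < this
    pending_dw: np.ndarray         # accumulated weight change (nS)

    @classmethod
    def zeros(cls, n_syn: int) -> "TraceState":
        return cls(
            t_p=np.zeros(n_syn),
            t_d=np.zeros(n_syn),
            refractory_until=np.full(n_syn, -np.inf),
            pending_dw=np.zeros(n_syn),
        )

    def reset(self) -> None:
        self.t_p[:] = 0.0
        self.t_d[:] = 0.0
        self.refractory_until[:] = -np.inf
        self.pending_dw[:] = 0.0


def estimate_rate(
    spike_times: np.ndarray,
    tau_r: float,
    dt: float,
    duration: float,
    t_start: float = 0.0,
) -> np.ndarray:
    """Causal exponential rate estimate of a single spike train.

    The kernel (1/tau_r) exp(-t/tau_r) is normalized to unit integral, so a
    regular train at rate nu converges to nu.  Returned in spks/sec on the
    grid ``t_start + k*dt``, k = 0 .. duration/dt.  A single spike produces
    an instantaneous jump of 1000/tau_r spks/sec.
    """
    if tau_r <= 0:
        raise ValueError("tau_r must be positive")
    n = int(round(duration / dt)) + 1
    rate = np.zeros(n)
    if len(spike_times) == 0:
        return rate
    decay = np.exp(-dt / tau_r)
    jump = 1000.0 / tau_r
    counts = np.zeros(n)
    idx = np.round((np.asarray(spike_times, dtype=float) - t_start) / dt).astype(int)
    ok = (idx >= 0) & (idx < n)
    np.add.at(counts, idx[ok], 1.0)
    acc = 0.0
    for k in range(n):
        acc = acc * decay + jump * counts[k]
        rate[k] = acc
    return rate


def hebbian_term(r_i, r_j, r_th: float, mode: str = "product"):
    """Thresholded Hebbian activation H = r_i * r_j.

    ``mode="product"`` gates on the rate product (H nonzero iff
    r_i * r_j > r_th); ``mode="each"`` requires both rates individually to
    exceed r_th.  The two coincide for r_i == r_j with r_th expressed as a
    squared rate; they differ when a quiescent neuron's rate estimate jumps
    from a single noise spike (see docs/methods.md).
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    prod = r_i * r_j
    if mode == "product":
        gate = prod > r_th
    elif mode == "each":
        gate = (r_i > r_th) & (r_j > r_th)
    else:
        raise ValueError("mode must be 'product' or 'each'")
    return np.where(gate, prod, 0.0)


def update_trace(t_a, h, tau_a: float, eta_a: float, tmax_a: float, dt: float):
    """One forward-Euler step of the trace ODE, clamped to [0, Tmax]."""
    t_a = np.asarray(t_a, dtype=float)
    h = np.asarray(h, dtype=float)
    t_new = t_a + (dt / tau_a) * (-t_a + eta_a * h * (tmax_a - t_a))
    return np.clip(t_new, 0.0, tmax_a)


def accumulate_reward_update(
    traces: TraceState,
    reward_active: bool,
    eta,
    dt: float,
    weights: np.ndarray | None = None,
    w_max: float | np.ndarray = np.inf,
) -> TraceState:
    """Accumulate dw = eta * (T^p - T^d) * dt while the reward gate is open.

    ``eta`` may be a scalar or a per-synapse array (recurrent vs feedforward
    learning rates).  Potentiation is softly bounded: positive increments
    are scaled by (1 - w/w_max) given the start-of-trial ``weights``.
    Outside the reward window this is a no-op.
    """
    if reward_active:
        dw = np.asarray(eta) * (traces.t_p - traces.t_d) * dt
        if weights is not None and np.any(np.isfinite(w_max)):
            bound = np.clip(1.0 - weights / w_max, 0.0, None)
            dw = np.where(dw > 0.0, dw * bound, dw)
        traces.pending_dw += dw
    return traces


def consume_traces(traces: TraceState, t_now: float, trace_refractory: float) -> TraceState:
    """Reset traces at the end of a reward window and start their refractory."""
    traces.t_p[:] = 0.0
    traces.t_d[:] = 0.0
    traces.refractory_until[:] = t_now + trace_refractory
    return traces


def commit_weights(weights: np.ndarray, traces: TraceState) -> np.ndarray:
    """Apply accumulated weight changes at the trial boundary.

    Plastic weights are clipped below at zero; the pending accumulator is
    zeroed.  Mid-trial reads of ``weights`` therefore always see the
    start-of-trial values.
    """
    weights = weights + traces.pending_dw
    np.clip(weights, 0.0, None, out=weights)
    traces.pending_dw[:] = 0.0
    return weights
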