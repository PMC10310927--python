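"""Parameter containers and YAML (de)serialization.

All tunables of the model live here, grouped by the aspect of the model they
control.  Defaults reproduce the baseline four-column network: LIF neurons
with conductance-based saturating synapses, competing LTP/LTD eligibility
traces, and a global 25 ms reward gate at element boundaries.  Values that
the source publications leave unstated (membrane constants, static weight
means, trace time constants, conductance saturation, noise conversion) were
calibrated once against the network's dynamical fingerprint and are frozen
here; docs/methods.md records the calibration rationale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "NoiseParams",
    "WeightParams",
    "TraceParams",
    "RewardParams",
    "StimulusParams",
    "SimParams",
    "NetworkConfig",
    "load_config",
    "save_config",
]

VARIANTS = ("baseline", "all_to_all", "local_inhibition", "scaled")


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire neuron constants.

    Units: capacitance pF, conductance nS, potentials mV, times ms.
    Excitatory cells spike at -55 mV; inhibitory cells at -50 mV.  The higher
    inhibitory threshold (plus their lack of recurrence) makes inhibitory
    rates decay faster than Timer rates after stimulus offset, opening the
    Messenger window.  ``t_ref`` is the *effective* refractory period: the
    nominal 2 ms plus the one-step spike registration delay.
    """

    c_m: float = 250.0
    g_l: float = 16.7
    v_rest: float = -70.0
    v_reset: float = -70.0
    v_th_exc: float = -55.0
    v_th_inh: float = -50.0
    t_ref: float = 3.0
    e_exc: float = 0.0
    e_inh: float = -75.0

    def __post_init__(self) -> None:
        if self.v_reset >= self.v_th_exc or self.v_reset >= self.v_th_inh:
            raise ValueError("v_reset must lie below the spike thresholds")
        if self.t_ref <= 0:
            raise ValueError("t_ref must be positive")


@dataclass
class SynapseParams:
    """Conductance-channel time constants, delay and saturation.

    Four conduction channels per neuron: network excitation onto excitatory
    targets (tau 80 ms), network excitation onto inhibitory targets
    (tau 80 ms, separate saturation), inhibition (tau 10 ms) and external
    input (tau 10 ms).  Each presynaptic spike of weight ``w`` increments
    the target channel by ``w * x * (1 - g/g_sat)``, where ``x`` is the
    presynaptic neuron's short-term resource (the adaptation term: depleted
    by a factor ``1 - u_dep`` at each spike of an excitatory source,
    recovering with ``tau_dep``) and the second factor keeps conductances
    below ``g_sat``.  All synapses share a single conduction delay.

    The E->E saturation is the duration-encoding knob: it caps the
    recurrent Timer drive marginally above the excitatory threshold, so
    sustained activity is a slowly eroding transient whose lifetime grows
    with the learned recurrent weight.
    """

    tau_exc: float = 80.0
    tau_inh: float = 10.0
    tau_input: float = 10.0
    delay: float = 1.0
    u_dep: float = 0.03       # per-spike resource depletion (recurrent T->T synapses)
    tau_dep: float = 2000.0   # resource recovery time constant (ms)
    dep_refractory: float = 15.0  # min interval between depletion events (ms)
    g_sat_exc: float = 9.0
    g_sat_exc_inh: float = 12.0
    g_sat_inh: float = 150.0
    g_sat_input: float = 200.0

    def __post_init__(self) -> None:
        for name in ("tau_exc", "tau_inh", "tau_input"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.delay <= 0:
            raise ValueError("delay must be positive")


@dataclass
class NoiseParams:
    """Additive Gaussian membrane noise.

    ``sigma_xi`` is the dial printed with the model (baseline 100, halved in
    the low-noise variant).  It is converted to a piecewise-constant current,
    redrawn every ``update_interval`` ms with standard deviation
    ``sigma_xi * xi_gain`` pA.  ``xi_gain`` was calibrated once so that the
    unstimulated excitatory population fires at 1-2 spks/sec.
    """

    sigma_xi: float = 100.0
    xi_gain: float = 5.2
    update_interval: float = 1.0


@dataclass
class WeightParams:
    """Mean static synaptic weights per connection class (nS).

    Static weights are drawn from a normal around the class mean and
    clipped below at zero; with ``sd_mode="relative"`` (default) the spread
    is ``sd * mean`` per class, with ``sd_mode="absolute"`` it is ``sd`` nS
    for every class.  Plastic weights start uniform in
    [0, plastic_init_max].  Inhibitory weights are stored as positive
    conductances routed to the inhibitory channel.
    """

    t_to_it: float = 0.20      # Timer -> local L5 inhibition
    t_to_m: float = 0.55       # Timer -> local Messenger
    t_to_im: float = 0.20      # Timer -> local L2/3 inhibition (local-inhibition variant)
    m_to_im: float = 0.80      # Messenger -> local L2/3 inhibition
    it_to_m: float = 4.0       # I_T -> local Messenger (inh)
    it_to_t: float = 0.8       # I_T -> cross-column Timers (inh)
    im_to_m: float = 2.0       # I_M -> cross-column Messengers (inh)
    w_in: float = 100.0        # stimulus -> T and I_T
    sd: float = 0.05
    sd_mode: str = "relative"
    plastic_init_max: float = 0.01


@dataclass
class TraceParams:
    """Eligibility-trace dynamics and Hebbian gating.

    Two competing traces per plastic synapse (LTP and LTD) follow

        tau_a dT/dt = -T + eta_a * H * (Tmax_a - T)

    with H the thresholded product of pre/post rates.  The LTD saturation
    level is slightly higher than LTP's while the LTP trace decays slower;
    both orderings are required for the recurrent learning fixed point.
    ``eta_*`` are the printed activation rates; the effective rate is
    ``eta_* * eta_scale`` per ms.  ``threshold_mode`` selects whether the
    Hebbian gate compares the rate *product* against ``r_th`` or requires
    *each* rate to exceed it (default; see docs/methods.md).
    """

    tau_p: float = 2000.0
    tau_d: float = 850.0
    tau_ffp: float = 1000.0
    tau_ffd: float = 1000.0
    eta_p: float = 45.0
    eta_d: float = 25.0
    eta_ffp: float = 20.0
    eta_ffd: float = 15.0
    eta_scale: float = 1.0 / 600.0
    tmax_p: float = 0.0033
    tmax_d: float = 0.00345
    tmax_ffp: float = 0.0034
    tmax_ffd: float = 0.00345
    r_th: float = 10.0
    r_th_ff: float = 20.0
    threshold_mode: str = "each"
    tau_rate: float = 40.0     # rate filter for display/analysis (ms)
    tau_rate_hebb: float = 65.0   # rate filter feeding the feedforward Hebbian gate (ms)
    trace_dt: float = 1.0      # trace integration step (ms)

    def __post_init__(self) -> None:
        if not self.tmax_d > self.tmax_p:
            raise ValueError("LTD saturation must exceed LTP saturation")
        if not self.tau_p > self.tau_d:
            raise ValueError("LTP trace must decay slower than LTD trace")
        if self.threshold_mode not in ("each", "product"):
            raise ValueError("threshold_mode must be 'each' or 'product'")


@dataclass
class RewardParams:
    """Global reward/novelty gate and learning rates."""

    d_reward: float = 25.0       # delay after element offset (ms)
    duration: float = 25.0       # reward window length (ms)
    trace_refractory: float = 25.0
    eta: float = 0.16            # recurrent learning rate
    eta_ff: float = 20.0         # feedforward learning rate
    w_max: float = 1.0           # soft bound on recurrent potentiation (nS)
    w_max_ff: float = 0.145      # soft bound on feedforward potentiation (nS)


@dataclass
class StimulusParams:
    """Poisson step stimulus delivered at element onsets."""

    pulse_ms: float = 50.0
    nu_in: float = 30.0          # spks/sec
    input_density: float = 1.0   # fraction of target neurons with an afferent train


@dataclass
class SimParams:
    """Integration grid and trial bookkeeping."""

    dt: float = 0.1              # forward-Euler step (ms)
    rate_record_dt: float = 1.0  # population-rate recording grid (ms)
    train_tail: float = 300.0    # silent tail after the last element (ms)
    recall_tail: float = 700.0
    max_rate: float = 500.0      # sustained rate (spks/sec) treated as runaway
    spike_buffer: int = 400_000  # preallocated spike capacity per trial


@dataclass
class NetworkConfig:
    """Complete description of one network instance."""

    n_columns: int = 4
    n_per_pop: int = 100
    variant: str = "baseline"
    phi: float = 0.26
    neuron: NeuronParams = field(default_factory=NeuronParams)
    synapse: SynapseParams = field(default_factory=SynapseParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    weights: WeightParams = field(default_factory=WeightParams)
    traces: TraceParams = field(default_factory=TraceParams)
    reward: RewardParams = field(default_factory=RewardParams)
    stimulus: StimulusParams = field(default_factory=StimulusParams)
    sim: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n_columns < 1:
            raise ValueError("n_columns must be >= 1")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be a probability")
        if self.synapse.delay < self.sim.dt:
            raise ValueError("conduction delay must be at least one integration step")

    def replace(self, **kwargs: Any) -> "NetworkConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "NetworkConfig":
        data = dict(data)
        for name, sub in (
            ("neuron", NeuronParams),
            ("synapse", SynapseParams),
            ("noise", NoiseParams),
            ("weights", WeightParams),
            ("traces", TraceParams),
            ("reward", RewardParams),
            ("stimulus", StimulusParams),
            ("sim", SimParams),
        ):
            if name in data and isinstance(data[name], dict):
                data[name] = sub(**data[name])
        return cls(**data)


def save_config(config: NetworkConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path: str | Path) -> NetworkConfig:
    return NetworkConfig.from_dict(yaml.safe_load(Path(path).read_text()))
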