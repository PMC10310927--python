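# Model and methods

`colseq` simulates a modular columnar spiking network that learns both the
order and the duration of a stimulus sequence from a global reward/novelty
signal, and replays the sequence from a single cue.  This note records the
model equations, the calibration decisions behind the default parameters,
the numerical choices, and the known limitations.

## Architecture

Each sequence element is assigned to one column.  A column contains four
populations of N = 100 leaky integrate-and-fire neurons (N = 400 in the
scaled variant): Timer (T) and Messenger (M) excitatory cells — analogues
of L5 and L2/3 pyramidal populations — and inhibitory partners I_T and
I_M.  All connection classes are wired with independent Bernoulli
probability phi = 0.26, no autapses.

Baseline wiring: within a column, T drives I_T, M and itself (plastic
recurrence); M drives I_M; I_T inhibits the local M.  Between columns,
inhibition is layer-specific (I_T^i -> T^j and I_M^i -> M^j, i != j),
producing a soft winner-take-all, and the only excitatory cross-columnar
projections are the plastic feedforward M^i -> T^{i+1}, hard-wiring the
sequence order (only the weights are learned).  The `all_to_all` variant
instantiates plastic M^i -> T^j for every ordered pair; the
`local_inhibition` variant makes all inhibition local and routes
feedforward inhibition through excitatory cross-projections onto I_T/I_M;
the `scaled` variant multiplies static weights by sqrt(N/N') and halves
the noise dial.

Functional reading: the Timer's learned recurrence holds a column's
activity up for the duration of its element; I_T tracks the Timer but dies
earlier (higher threshold, no recurrence), opening a brief window in which
the Messenger — driven by the Timer's slow conductance — bursts at element
offset and ignites the next column.

## Neuron and synapse model

Membrane dynamics (forward Euler, dt = 0.1 ms):

    C_m dV/dt = g_L (V_rest - V) + g_e (E_exc - V) + g_i (E_inh - V) + xi(t)

with C_m = 250 pF, g_L = 16.7 nS, V_rest = V_reset = -70 mV, E_exc = 0,
E_inh = -75 mV.  Spike thresholds are -55 mV (excitatory) and -50 mV
(inhibitory); the higher inhibitory threshold is what makes I_T decay
faster than its Timer.  Threshold crossings are registered with a one-step
delay and the effective refractory period is 3 ms, so consecutive spikes
of a neuron are always >= 3 ms apart.

Synapses are conductance-based with a single 1 ms conduction delay and
four channels per neuron: E->E (tau 80 ms), E->I (tau 80 ms), I->E
(tau 10 ms) and external input (tau 10 ms).  A spike of weight w
increments its channel by

    dg = w * x_pre * (1 - g / g_sat)

The second factor saturates the conductance at g_sat; `x_pre` is the
presynaptic short-term resource (the synapse model's adaptation term),
applied to the recurrent T->T class only: it is depleted by a factor
(1 - u_dep) at each presynaptic spike (at most once per 15 ms) and
recovers with tau_dep = 2 s.

These two nonlinearities implement duration encoding.  The E->E
saturation (9 nS) caps the recurrent drive marginally above the
excitatory threshold, so a Timer's activity after ignition is not a
stable attractor but a slowly eroding plateau; the depleting resource
provides the deterministic clock that ramps the plateau down.  The
plateau lifetime grows smoothly with the recurrent weight (roughly
100 ms near w = 0.05 nS to > 2 s near w = 0.25 nS), with trial-to-trial
jitter of 5-10% — the substrate the learning rule calibrates.  Without
the resource the plateau is either noise-escape (50% jitter) or
permanently stable, with no graded regime; this is why the adaptation
term is load-bearing.  The depletion refractory makes the
refractory-limited stimulus volley consume no more resource than a
chain-driven ignition, so trained durations transfer from stimulated
training trials to cue-driven recall.

Noise: the printed dial sigma_xi = 100 (halved in the low-noise variant)
is converted to a piecewise-constant current, redrawn every 1 ms with
standard deviation sigma_xi * xi_gain pA, xi_gain = 5.2 calibrated once so
the unstimulated excitatory population fires at 1-2 spks/sec.  No literal
pA reading of 100 produces measurable baseline firing under these membrane
constants (it yields sigma_V ~ 0.35 mV against a 15 mV threshold
distance).

## Plasticity

Each plastic synapse (recurrent T->T and feedforward M->T) carries
competing LTP/LTD eligibility traces

    tau_a dT^a/dt = -T^a + eta_a H (Tmax_a - T^a),    a in {p, d}

driven by the thresholded Hebbian term H built from the pre- and
postsynaptic rates (causal exponential filters: tau = 40 ms for the
recurrent gate, matching the analysis filter, and a slower 65 ms filter
for the feedforward gate).  H = r_i r_j when the gate is open and 0
otherwise.  The gate default requires *each* rate to exceed r_th
(10 spks/sec recurrent, 20 feedforward) rather than the product: a
single spike jumps a 40 ms-filtered estimate to 25 spks/sec, so the
product form cannot distinguish a genuinely active postsynaptic neuron
from one noise spike.  The slower feedforward filter (single-spike jump
1000/65 ~ 15 spks/sec, below both 20 and 30) is what makes the
cross-columnar thresholds discriminating: without it, spurious
feedforward links seeded by noise coincidences bootstrap real
co-activation in the all-to-all variant and the documented rescue by
raising r_th_ff from 20 to 30 spks/sec cannot work.  The product form is
available as `threshold_mode="product"`.

A global reward/novelty gate opens for 25 ms, 25 ms after every element
boundary — each element offset plus the first element's onset.  The onset
window is not cosmetic: every later column has its freshly activated
traces consumed by the preceding element's reward, and the onset window
does the same for the first column, so all columns accumulate eligibility
from an equal footing.  While the gate is open,

    dw/dt = eta R(t) (T^p - T^d)

accumulates (eta = 0.16 recurrent, eta_ff = 20 feedforward); at gate
close the traces are consumed (reset, then frozen for a 25 ms trace
refractory).  Weight changes are committed once per trial at the trial
boundary and clipped below at zero.  Positive updates are additionally
scaled by (1 - w/w_max) (w_max_ff = 0.145 nS binding for the feedforward
class; w_max = 1 nS, inert, for the recurrent class).  The soft bound is
this package's stabilizer for the feedforward weights: during training the
postsynaptic Timer is driven by its own stimulus, so the boundary
co-activation — and hence the per-trial trace difference — is essentially
independent of w_ff and the raw rule has no feedforward fixed point.

Learning converges by trace competition.  LTP saturates slightly lower
(Tmax_p = 0.0033 vs Tmax_d = 0.00345) but decays slower
(tau_p = 2000 ms vs tau_d = 850 ms; the feedforward pair shares
tau_ffp = tau_ffd = 1000 ms so that the high-rate saturated LTD surplus
survives to the second reward as the depression the convergence argument
needs).  If a Timer's activity ends well
before its reward, the faster-decaying LTD trace has died by the gate and
the weight grows (longer plateau next trial); if activity persists into
the reward, the higher LTD saturation wins and the weight shrinks.  The
fixed point puts the plateau's end a crossover time
t* = ln(Tmax_d/Tmax_p) / (1/tau_d - 1/tau_p) ~ 65 ms before the gate,
which both sets the per-column duration slightly below the element
duration and reproduces the systematic shortening of reported intervals
along the sequence.

### Parameter provenance

r_th, r_th_ff, Tmax_*, the relative activation rates (45/25/20/15), eta,
eta_ff, the reward timing (25/25/25 ms), phi, nu_in = 30 spks/sec,
w_in = 100 nS, tau_syn values, t_ref = 3 ms and the thresholds are the
published values.  The trace time constants, the trace-rate scale
(eta_scale = 1/600 per ms: activation rates are quoted relative to an
unspecified normalization; the scale was chosen once so traces saturate
within a stimulus transient, which the convergence argument presupposes),
the membrane constants, saturation levels, noise conversion, static
weight means (t_to_it = 0.20, t_to_m = 0.55, m_to_im = 0.80,
it_to_m = 4.0, it_to_t = 0.8, im_to_m = 2.0 nS), the feedforward gate
filter and the soft weight bounds were calibrated once against the
dynamical fingerprint: 1-2
spks/sec baseline, transient-only response before learning with I_T
decaying faster than T, Messenger burst at Timer offset, stable ordered
replay after training with durations matching the trained grid.  Static
weights are jittered 5% (relative) and clipped at zero; the printed
"standard deviation of 1" cannot be 1 nS for classes whose printed means
are 0.2 nS.

## Protocol

Training trial: elements are contiguous; at each element onset the
column's afferents (Timers and I_T; Timers only under local inhibition)
each receive an independent 50 ms Poisson train at 30 spks/sec through
100 nS input synapses.  Membrane state, conductances, resources and
traces are reset at every trial start (which makes an inter-trial gap
redundant), rewards follow the boundary schedule, and the accumulated
weight changes are committed at the trial end.  A training phase is 100
trials.  Recall trials deliver a single 50 ms cue to the first column,
with no reward and plasticity disabled; 50 recall trials by default.
Learning-parameter robustness runs redraw the four trace time constants
and four activation rates uniformly within ±20%, once per trial or once
per network instance.

## Measurements

Population rates are means of the per-neuron filtered rates on a 1 ms
grid.  Recall time is the first drop of a Timer population's rate below
10 spks/sec after it has stayed above threshold for at least 20 ms
(onset guard); relative recall times subtract the expected onset
(0, 700, 1400, 2100 ms for the standard grid).  Deviation outliers are
|deviation| > 140 ms (a never-activating column counts as an outlier);
distribution outliers use the modified z-score 0.6745 (x - median)/MAD
with threshold 3 and the MAD = 0 -> z = 0 convention.  ISI statistics
pool per-neuron inter-spike intervals across a population within the
column's active epoch (onset-guarded activation to recall time) during
recall.  Weight convergence is the first trial after which the per-trial
relative change of the mean recurrent weight stays below 2% for the rest
of training.

## Numerical choices

- Forward Euler at dt = 0.1 ms; spike registration one step late;
  conduction delay on the dt grid.  Eligibility traces and the reward
  gate advance on a 1 ms grid (the rate filter and traces are slow).
- The fused numba kernel and the numpy reference implementations share
  the exact update order (decay conductances -> deliver delayed spikes ->
  integrate/threshold -> traces -> reward); the suite checks spike-level
  agreement with noise disabled.
- Refractory release uses a half-step tolerance so that
  accumulated-time and step-indexed time comparisons cannot disagree at
  the floating-point knife edge.
- Saturating conductance increments are applied sequentially per arriving
  spike, so they do not commute; both implementations use the same
  (source-sorted) delivery order.
- Determinism: every stochastic element (wiring, draws, noise, Poisson
  stimuli) derives from explicit seeds; identical (config, seed) produce
  bit-identical spikes and weight trajectories.

## What the generator emulates, and what it does not

All inputs are synthetic by construction (the model is the object of
study; there is no external data).  The stimulus generator reproduces the
study conditions: the four-interval sequence 500/1000/700/1800 ms, the
uniform 700 ms sequences of length 2-4, and the parameter sweep grids.
Conclusions transfer to the published system only as far as the
calibrated stand-ins (membrane constants, trace time constants, synapse
adaptation form, noise conversion) reproduce its dynamical regime; they
were fitted to the described fingerprint, not to the original code's
hidden state.

## Known limitations

- The feedforward weight equilibrium is imposed by the soft bound, not
  emergent from trace competition (see above); the recurrent equilibrium
  is emergent.
- Scaled (N = 400), low-noise and local-inhibition variants use their own
  calibrated override sets; they reproduce the qualitative claims
  (learnability, ordered recall, suppression of spurious cross-columnar
  potentiation) rather than quantitative timings.  Under halved noise the
  feedforward chain bootstraps sequentially (each link waits for the
  previous column's duration), so that variant needs ~150 training
  trials.
- Recall-time error structure: this implementation produces a tight
  trial-to-trial core (5-9% of the element duration) plus a few-percent
  tail of early plateau collapses, where the published distributions are
  wider but closer to Gaussian.  Statistics sensitive to that shape — the
  modified z-score outlier count and the 90th-percentile deviation of the
  early columns — come out worse than published even though the median
  bias, the +-140 ms outlier count and the convergence trial agree.
- Plateau firing is more regular than published: pooled active-epoch ISI
  CVs are ~0.8 for both Timer and Messenger populations (vs 1.35/0.95);
  no defensible measurement window reproduced the printed pair.
- Weight-sweep asymmetry: weakening T->I_T below -25% destabilizes recall
  as described, but the +40% over-estimation does not materialize here —
  training transitions are themselves Messenger-driven, so the reward
  equilibrium re-anchors element offsets and compensates the slower
  Messenger release that the published effect relies on.
- Duration extension proceeds at ~7 ms per trial near equilibrium, so the
  1,800 ms element of the four-interval task does not reach its full
  length within 100 training trials (order and the shorter elements do).
- Mid-sequence latch failures occur in a few percent of recall trials
  (a column's plateau collapses early); the published robustness numbers
  (17/50 deviation outliers in the last column) indicate a comparable
  failure mass in the original.
- Chained `run_window` calls drop spikes still in flight across the
  window boundary; the protocol layer always simulates whole trials in
  one call, where this cannot occur.
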