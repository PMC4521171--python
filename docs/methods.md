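# Methods

## The model

`protocortex` simulates the developing early visual pathway as three sheets
of leaky integrate-and-fire (LIF) neurons driven by neuromorphic
address-event stimuli:

* **Input sheet** (128x128). Each unit corresponds to one pixel of a
  dynamic-vision-sensor (DVS) style camera and is forced to spike whenever
  an event arrives at that pixel. ON and OFF polarities are relayed
  identically; there is a single input sheet.
* **LGN relay** (32x32). Each relay unit pools a 4x4 block of input pixels
  through fixed, non-plastic weight-1.0 synapses (16:1 down-sampling). The
  relay gain is set so a single pooled input spike reliably fires the unit,
  subject to its refractory period.
* **Cortex** (60x60), 80% excitatory / 20% inhibitory (assigned at random).
  Each cortical neuron receives a retinotopic afferent connection field:
  all LGN units within `afferent_cf_radius` (default 4 LGN units, ~50
  synapses) of its position scaled from the 60-grid to the 32-grid.
  Recurrent ("lateral") synapses are sampled with probability 0.3 inside a
  Mexican-hat layout — presynaptic excitatory neurons project within
  `exc_radius` = 4 grid units, inhibitory neurons within `inh_radius` = 20
  (a 5:1 ratio of inhibitory to excitatory reach). Lateral conduction
  delay is 1 ms per grid unit of Euclidean distance (open boundary, no
  wrap-around); the afferent delay is a fixed 1 ms.

This innate wiring — receptive fields, Mexican-hat recurrence,
distance-dependent delays — is the "proto-architecture": it already
produces a weak, patchy direction-preference bias before any learning, and
is the substrate that training refines.

Membrane dynamics follow the forward-Euler LIF update

    v(t+dt) = v(t) + (dt/tau_m) (v_rest - v(t)) + I(t),

with threshold-reset spiking and a 2 ms absolute refractory period, on a
1 ms grid (delays round to whole steps, minimum one — causality is
structural). Synaptic input is delta-current: each presynaptic spike
deposits `gain * weight` into the target's delay slot; inhibition enters
with negative sign. There is no spontaneous activity or synaptic noise, so
one presentation is fully deterministic given the network and the stimulus.
The network resets between presentations (membranes to rest, delay lines
cleared); only synaptic weights persist, which is the training protocol's
"no interaction between successive patterns" rule.

## Learning rule

All afferent (LGN->cortex) and lateral (cortex->cortex) synapses are
plastic. Spike pairs are formed nearest-neighbour (each spike pairs with
the partner's most recent spike) within a 50 ms window, with
`dt = t_pre - t_post`:

* **LTP** (`dt <= 0`, ties included): exponential window
  `A_ltp exp(dt / tau_ltp)`, `tau_ltp` = 11 ms, applied **additively**.
* **LTD** (`dt > 0`): alpha-function window
  `A_ltd (dt/tau_ltd) exp(1 - dt/tau_ltd)`, `tau_ltd` = 20 ms, peak
  magnitude exactly `|A_ltd|` at `dt = tau_ltd`, applied
  **multiplicatively** (`w' = w (1 + dw)`).

Rates: afferent `A_ltp` = 0.02, lateral 0.01, with `|A_ltd| = 1.05 A_ltp`
per pathway. Depression is deeper and longer-lived than potentiation and
slightly over-weighted, so uncorrelated activity drifts weights downward;
together with the multiplicative form (which preserves non-negativity and
zeros) this bounds weights without hard clipping or global normalization.
The additive-LTP / multiplicative-LTD pair has a consequence that matters
for calibration: potentiation is an absolute step while depression is
relative, so each pathway's *initial weight scale* sets how fast that
pathway reorganizes. The initial ranges below are therefore part of the
learning-rate structure, not free decoration.

**Inhibitory synapses use a mirrored (anti-Hebbian) window** — they
potentiate when the postsynaptic neuron fires *before* the inhibitory
input (`dt >= 0` on the mirrored axis, exponential window) and depress
multiplicatively otherwise. This was a genuinely open design point, and the
choice is forced by the delay structure: with the Hebbian sign, the
inhibitory synapses that strengthen are exactly those whose delayed IPSPs
arrive on top of the postsynaptic response that drove them, so training
*suppresses* the trained direction (measured directly: after E-only
training the mean E response fell below the W response at every
stimulus-speed / delay combination tried). With the mirrored window,
strengthened inhibition instead targets anti-correlated (null-direction)
activity, which is also the standard sign convention for
timing-dependent inhibitory plasticity in the modelling literature.
Hebbian and symmetric variants remain selectable
(`STDPParams.inhibitory_stdp`).

## Stimuli

The stimulus generator replaces camera recordings with analytic event
streams: a rigid bar of perpendicular extent `length_px` (default 182 px,
exceeding the 181 px array diagonal so every pixel is swept in every
direction — shorter bars leave corners unstimulated on diagonal sweeps and
imprint a spurious orientation bias), width 4 px, moving at 0.5 px/ms in
one of the eight compass directions (0 deg = E, counter-clockwise). Each
pixel emits an ON event at the leading-edge crossing and an OFF event at
the trailing edge, rounded to 0.1 ms. Per-instance jitter multiplies the
speed by U(0.95, 1.05) and delays the start by up to 6.4 px of travel;
background noise is Poisson at 10 events/ms over the array (~0.6 Hz per
pixel, in the reported range for DVS sensors). A training set is 10
instances per direction; tuning is probed with a fixed jitter- and
noise-free sweep per direction, identical at every measurement stage so
response changes isolate weight changes (`probe_instances` can add
averaged jittered repeats; it does not change the results).

What the generator does *not* emulate: sensor-specific noise structure
(hot pixels, polarity imbalance, refractory dropout), luminance-dependent
event rates, and trajectory curvature of hand-moved objects. Passing tests
therefore show that the model behaves as described under idealized bar
motion, not that it is robust to real camera data.

## Calibration and default constants

The LIF constants, synaptic gains and initial weight ranges are free
constants of the model; they were fixed once, as a set, so that
the untrained and trained networks sit in the regime the experiments
describe, and are not adjusted per experiment. Defaults: `tau_m` = 8 ms,
threshold 1 (rest/reset 0), refractory 2 ms, dt 1 ms; gains — afferent
0.33, lateral-excitatory 0.1, lateral-inhibitory 0.473, relay 1.2; initial
weights — afferent U(0.05, 0.35), lateral U(0, 0.3). The reasoning:

* afferent drive is set so a wavefront volley (~15 near-coincident LGN
  spikes through mean-weight synapses) reaches threshold: probe responses
  are sparse (a few spikes per sweep) and timed to the bar's passage over
  the receptive-field centre, which is what makes spike-pair timing
  informative for STDP;
* lateral excitation gets a deliberately small gain. Excitatory recurrence
  propagates at 1 grid unit/ms while the default bar advances at ~0.23
  cortical units/ms, so recurrent volleys outrun the stimulus; at larger
  gains they outrun the (slower, longer-range) inhibition too and the
  network avalanches. At the chosen gain lateral excitation biases spike
  timing without driving it;
* the afferent initial range is centred near the additive/multiplicative
  drift equilibrium, so all-direction training redistributes afferent
  weight rather than inflating it; the lateral range (relative to its
  rates) makes lateral learning the faster pathway, which is what puts
  refinement under cortical rather than afferent control.

## Experiments

An experiment (`ExperimentConfig.preset`) builds `n_networks` seeded
networks, measures tuning with all plasticity off (8 probe sweeps),
trains with 50 randomly drawn (direction, instance) presentations —
uniformly over the training directions; bi-directional training splits
E/W within one presentation of parity — measuring again after 25 and 50.
Variants: `DISRUPTED` applies the two lesions (full LGN-cortex afferent
connectivity with re-drawn weights; lateral inhibition deleted beyond 8
grid units) before training; `UNIDIR` trains with E only; `BIDIR` with
E and W; `ABLATE_AFFERENT` / `ABLATE_CORTICAL` are uni-directional
training with one pathway's learning flag off. Every random draw descends
from the master seed, and per-network checkpoints make interrupted runs
resumable.

Analysis follows the vector-average convention: per neuron the resultant
of the eight response vectors gives the preferred angle and a selectivity
index SI = |R| / sum(r) in [0, 1]; orientation selectivity doubles the
angles first. Neurons with no spikes to any probe are excluded.
Aligned tuning curves rotate each responsive neuron's sum-normalized row
so its maximum sits at 0 deg (ties break toward the previous-stage
preference, else the lowest angle). The aligned mean is fitted with a
constrained double Gaussian (lobes fixed at 0 and 180 deg, shared width,
non-negative amplitudes, circular angle distance, multi-start
least squares; flat curves are flagged degenerate rather than fitted).
Group contrasts use two-sided Mann-Whitney tests with Bonferroni-adjusted
alpha. Map "patchiness" is quantified as the mean cosine of
preferred-angle differences between grid neighbours at a given lag, since
the source assesses it visually.

## Problem sizes

The package's standard desk-scale protocol uses 2-3 networks for intact
training, 2 for disrupted training, and 1 per uni-directional or ablation
experiment, each with 50 presentations and three measurement stages; the
compiled kernel (numba) runs an intact presentation in ~0.1 s, and a
pure-Python reference integrator (validated bit-for-bit against it on
small systems) exists for inspection and testing. Pooled over networks,
all-neuron SI statistics are stable to roughly +-0.01 across master seeds
at this scale.

## Known limitations

* Two quantitative outcomes are not reproduced at the published values
  under this calibration. (1) Disrupted networks: with full afferent
  connectivity the in-degree rises ~20x at unchanged per-synapse weight
  range (the protocol keeps "all other parameters the same"), so every
  cortical neuron is driven at its refractory ceiling for every direction;
  responses are flat, and because all neurons receive identical saturated
  input, training cannot individuate preferences — final mean DS SI stays
  near 0.01 rather than ~0.12 (the untrained value ~0.003 does match the
  published ~0.02, and the qualitative claims — no rightward shift, no
  patchy map — hold). (2) Uni-directional training: converted neurons
  over-sharpen (trained-group mean DS SI ~0.8 vs ~0.45); fifty
  same-direction presentations drive their tuning to near-one-hot. The
  published dose-response saturates in a way this calibration does not
  reproduce without sacrificing the intact-training targets, which were
  prioritized. The trained/other SI ratio (~2.4 vs ~2.0) and the
  direction of every group contrast do match. Relatedly, when cortical
  plasticity is disabled the E-preferring group's mean SI ends near 0.03
  rather than ~0.11: afferent-only training mildly flattens exactly the
  neurons that end up counted as E-preferring, although the substantive
  outcome — no refinement; overall mean SI stays at the untrained level —
  is reproduced.
* The untrained orientation bias is weaker than the untrained direction
  bias (the published maps show the reverse); circular afferent fields
  carry no orientation structure beyond random weight anisotropy.
* Delta-current synapses, a single input polarity sheet, and the absence
  of spontaneous activity are simplifications; conductance synapses or
  background drive would change the calibration.
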