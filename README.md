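# protocortex

A spiking-network model of how direction selectivity in early visual
cortex can be *innate* — present before any visual experience — and then
rapidly refined by it. The package is for computational neuroscientists
who want to simulate, lesion, and analyze this "proto-architecture": a
three-layer leaky integrate-and-fire (LIF) network (128x128 input sheet →
32x32 LGN relay → 60x60 recurrent cortex) whose retinotopic afferent
connection fields, Mexican-hat lateral connectivity (short-range
excitation, long-range inhibition) and distance-dependent conduction
delays produce a weak, patchy direction-preference map with no learning at
all. Training with moving-bar event streams and spike-timing-dependent
plasticity (STDP) then sharpens the map in a few dozen presentations.

The measurements mirror developmental physiology: with plasticity
switched off, each network is probed with bars moving in the eight compass
directions, and each neuron's spike counts `r_k` at angles `theta_k` give
a vector-average preferred direction and selectivity index

    R = sum_k r_k exp(i theta_k),   SI = |R| / sum_k r_k  in [0, 1]

(orientation selectivity doubles the angles). The STDP rule is asymmetric:
potentiation follows an exponential window `A_ltp exp(dt/tau_ltp)`
(`dt = t_pre - t_post <= 0`, `tau_ltp` = 11 ms) and is additive; depression
follows an alpha-function window `A_ltd (dt/tau_ltd) exp(1 - dt/tau_ltd)`
(`dt > 0`, `tau_ltd` = 20 ms) and is multiplicative, so depression is
deeper and longer-lived than potentiation and weights stay non-negative
without hard bounds. Moving-bar stimuli are synthesized as DVS-camera-style
address events (ON/OFF polarity at leading/trailing edge crossings), so no
recordings are needed.

## Worked example

Train one randomly initialized network with 50 random bar presentations
spanning all eight directions, measuring tuning (plasticity off) before,
midway, and after:

```python
from protocortex.experiments import ExperimentConfig, run_experiment

config = ExperimentConfig.preset("INTACT", n_networks=1, seed=42)
report = run_experiment(config)
for stage in ("initial", "mid", "final"):
    print(f"{stage:>7}: mean DS SI = {report.mean_si(stage, 'DS'):.3f}, "
          f"mean OR SI = {report.mean_si(stage, 'OR'):.3f}")
aligned = report.aligned_mean("final")
print(f"aligned final tuning (0/90/180 deg): "
      f"{aligned[0]:.3f} / {aligned[2]:.3f} / {aligned[4]:.3f}")
```

prints

```
initial: mean DS SI = 0.099, mean OR SI = 0.124
    mid: mean DS SI = 0.292, mean OR SI = 0.256
  final: mean DS SI = 0.366, mean OR SI = 0.318
aligned final tuning (0/90/180 deg): 0.381 / 0.092 / 0.085
```

Before training the average direction-selectivity index is ~0.1 — the
innate bias. Fifty presentations more than triple it, and the aligned
tuning curve (each neuron's sum-normalized responses rotated so its
preferred direction sits at 0 deg) ends with the preferred response more
than four times the null (180 deg) response. Other presets:
`DISRUPTED` (full LGN-cortex connectivity + truncated inhibition, which
permanently prevents refinement), `UNIDIR`/`BIDIR` (training restricted to
one or two directions), and `ABLATE_AFFERENT`/`ABLATE_CORTICAL`
(per-pathway plasticity knock-outs showing that the cortico-cortical
pathway drives refinement).

Command line:

```bash
stimgen --direction E --instances 10 --seed 42 --out streams/
protocortex run --experiment INTACT --networks 2 --seed 1 --out results/
```

Event streams are plain-text columnar files (`#direction=`, `#instance=`,
`#duration_ms=` headers, then `t_ms x y polarity` rows); networks and
spike records serialize to HDF5; reports export CSV/JSON.

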