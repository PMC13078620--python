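# isorhythm

Tools for studying a striking regularity in animal communication: across
taxa, modalities and eight orders of magnitude in body weight, many species
signal isochronously — metronome-like — at tempos of roughly 0.5–4 Hz.  One
candidate explanation is that this band matches the resonant response of
small neural "receiver" circuits in the perceiving animal.  This package
implements both sides of that question:

* **model side** — small circuits of Kuramoto phase oscillators driven by a
  periodic external stimulus, used to compute resonance curves, Arnold
  tongues, and the sensitivity of entrainment to circuit topology;
* **data side** — inter-onset-interval (IOI) statistics and the isochrony
  criterion, log-normal fits of cross-species tempo samples, and the
  spectrogram pipelines that extract a dominant tempo from firefly
  flash-count series and cricket-like audio.

It is aimed at quantitative biologists and physicists who want to
reproduce, perturb, or extend these analyses entirely from synthetic data —
no downloads are required.

## The model

Each receiver circuit is `N` phase oscillators coupled on a binary digraph
`A` and forced by an external stimulus treated as an extra node:

```
dθ_i/dt = ω_i + (K/N) [ Σ_j A_ij sin(θ_j − θ_i) + K_ext sin(θ_ext − θ_i) ]
```

with `θ_ext(t) = 2π f_ext t`.  Natural frequencies are Gaussian,
`ω_i ~ N(2πμ, (2πσ)²)` with `μ = 2 Hz`.  The internal coupling is set just
below the infinite-`N` critical value, `K = (1 − ε) K_c` with `ε = 0.1` and
`K_c = 2/(π g(0)) = 2σ_ω √(2/π)`, so the circuit synchronizes only under
forcing.  Synchrony/entrainment is measured by the order parameter

```
R(t) = | Σ_j e^{iθ_j} + e^{iθ_ext} | / (N + 1)
```

and experiments report the time average `R̄` after a transient, averaged
over seeded realizations.  Topologies are the nonisomorphic simple digraphs
on five vertices with ten arcs — 1,665 classes once topologies with a
decoupled (isolated) oscillator are excluded — enumerated exhaustively with
canonical labeling.

On the data side, a signal is *isochronous* when it has at least 5 IOIs
with standard deviation ≤ 25% of the mean, its tempo is `1/mean(IOI)`, and
tempo samples are fitted by `ln f ~ N(μ_ln, σ_ln²)` via maximum likelihood
(mode `e^{μ−σ²}`, median `e^{μ}`, KS goodness of fit).

## Worked example

```python
import numpy as np
from isorhythm import (
    NaturalFrequencySpec, IntegrationConfig, resonance_curve,
    sample_tempos, fit_lognormal,
)

spec = NaturalFrequencySpec(mean_tempo=2.0, spread=0.3)
config = IntegrationConfig(dt=1e-3, duration=30.0, transient=10.0, seed=7)
curve = resonance_curve(np.arange(0.0, 4.01, 0.25), k_ext=1.0,
                        freq_spec=spec, config=config, n_realizations=10)
print("peak response at", curve.peak_tempo, "Hz")
print("R at peak:", round(float(curve.mean_order.max()), 3))

fit = fit_lognormal(sample_tempos(5000, seed=42))
print("mu_ln=%.3f sigma_ln=%.3f median=%.2f Hz" % (fit.mu_ln, fit.sigma_ln, fit.median))
```

prints

```
peak response at 2.0 Hz
R at peak: 0.738
mu_ln=1.082 sigma_ln=0.899 median=2.95 Hz
```

The resonance curve of the all-to-all five-oscillator circuit peaks exactly
at the 2 Hz mean natural tempo (the circuit "inherits" its elements'
timescale), and the maximum-likelihood fit recovers the generating
log-normal parameters (1.1, 0.90) of the synthetic cross-species tempo
sample — whose implied median, `e^{1.1} ≈ 3.0 Hz`, sits in the delta band.

A command-line interface exposes the same operations
(`isorhythm --help`): graph enumeration, the three simulation sweeps,
event-train analysis, tempo-table fitting, tempo extraction from WAV or
flash-count files, and `make-fixtures` for a complete synthetic dataset.

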