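# Methods

## Model and assumptions

The receiver circuit is a network of `N` Kuramoto phase oscillators with
binary coupling `A` (row `i` lists the inputs of oscillator `i`; an edge
tail→head sets `A[head, tail] = 1`) and an external periodic stimulus
treated as an `(N+1)`-th node:

    dθ_i/dt = ω_i + (K/N)[ Σ_j A_ij sin(θ_j − θ_i) + K_ext sin(θ_ext − θ_i) ]

* The forcing phase evolves by uniform rotation, `θ_ext(t) = φ_0 + 2π f_ext t`,
  with `φ_0 = 0` by default.  `f_ext = 0` is allowed and acts as a static
  attractor phase.
* `K_ext` is dimensionless, in units of `K`, and enters **inside** the
  bracket: the forcing amplitude on each oscillator is `K·K_ext/N`, exactly
  like a single internal link of strength `K_ext`.  This is deliberate and
  documented because "in units of K" is easy to misread as bypassing the
  `1/N` factor (a 5× stronger forcing at `N = 5`).
* Natural frequencies are Gaussian: user-facing tempos are in Hz, internals
  in rad/s (`ω = 2πf`).  The critical coupling `K_c = 2/(π g(0)) =
  2σ_ω√(2/π)` is evaluated at the angular spread so `K` and `ω` share
  units; circuits run subcritically at `K = (1 − ε)K_c`, `ε = 0.1`.
* The order parameter divides by `N + 1` and includes the forcing phasor,
  so `R̄` measures entrainment to the stimulus, not just internal
  synchrony.  An `include_forcing=False` variant exposes the
  oscillators-only quantity used in the subcriticality check.

Phases are stored wrapped to `[0, 2π)`; integration operates on unwrapped
values within a step.

## Integration

Classical fixed-step 4th-order Runge–Kutta, default `dt = 1 ms`.  The
dynamics are smooth and slow (|dθ/dt| ≈ 13 rad/s), so the integrator is far
from its accuracy limit: the test suite verifies agreement with an adaptive
Dormand–Prince reference (`scipy.solve_ivp`, DOP853, tolerances 1e-11) to
better than 1e-4 rad over 10 s (measured ≈ 4e-10 rad), 4th-order step-halving
convergence, the exact uncoupled rotation solution to 1e-6 rad, and
phase-shift equivariance of `R(t)`.  Parameter sweeps in the tests use
`dt = 2 ms`, which the same convergence evidence covers with a wide margin.

Run lengths: 30 s with the first 10 s discarded from time averages
(configurable).  The slowest relevant timescale is the locking rate
`K·K_ext/N ≈ 0.5 rad/s`, so 10 s of transient is several locking times.

## Experiments and problem sizes

Each realization draws fresh uniform phases and Gaussian frequencies from a
composite seed `(base_seed, stream, realization)`, making every sweep
bitwise reproducible and independent of evaluation order.  In the resonance
and tongue sweeps a realization keeps its draws across the whole forcing
grid, so the reported curve is the mean of per-realization curves.

* **Topology sweep**: every topology's `R̄` under 2 Hz forcing, `K_ext = 1`,
  σ = 0.5 Hz.  The full experiment uses all 1,665 five-vertex ten-arc
  classes and 100 realizations; the packaged acceptance test runs a seeded
  100-graph subsample at 5 realizations, which already shows the
  characteristic shape: a flat bulk (interdecile spread ≈ 0.07, well below
  0.15) with a steeper low-`R̄` tail (the drop across the lowest 20 graphs
  exceeds that of any equal-width window of the central bulk).
* **Resonance curves**: all-to-all `N = 5`, `f_ext` from 0 to 4 Hz in
  0.25 Hz steps, 10 realizations, σ defaults {0.1, 0.3, 1.0} Hz and
  `K_ext` defaults {0.25, 0.5, 1, 2, 4}.  The peak sits at the 2 Hz mean
  natural tempo across seeds.
* **Arnold tongue**: `R̄` over the `(K_ext, f_ext)` product grid.  Tongue
  width at a forcing strength is the span `f[hi] − f[lo]` of the contiguous
  supra-threshold interval around the row maximum (single-point intervals
  are degenerate, width 0; threshold default 0.6).  Width is nondecreasing
  in `K_ext`.

A note on baselines: at `N = 5` the unforced subcritical circuit is not
incoherent — finite-size partial synchrony puts the off-resonance baseline
of `R̄` near 0.59 (not the `1/√(N+1) ≈ 0.41` of independent phases).  With
the literal `K·K_ext/N` forcing scaling, `K_ext = 1` yields a modest
resonance peak (`R̄(2 Hz) ≈ 0.65–0.75` vs baseline ≈ 0.59), and the
4 Hz/2 Hz response ratio is about 0.85–0.93; it falls below 0.8 only for
`K_ext ≥ 2`.  There is no tongue at the 4 Hz harmonic at any strength — the
4 Hz response equals the unforced baseline.

## Digraph enumeration

Canonical form = lexicographically minimal row-major adjacency bit string
over all `n!` vertex relabelings, computed by a full permutation scan
(exact; at these sizes a refinement algorithm buys nothing).  Enumeration
iterates every edge subset of the requested size, vectorizes the
permutation scan over all subsets, and keeps the first representative of
each class in lexicographic edge-set order.  The `(5, 10)` census —
184,756 subsets × 120 permutations — completes in a few seconds.

The unconstrained class count at `(5, 10)` is 1,670; exactly five classes
place all ten arcs among four vertices, leaving one oscillator decoupled.
The published census of 1,665 receiver circuits corresponds to excluding
those (`exclude_isolated=True`), which is what the experiments use.  Both
counts are verified in tests against an independent VF2-partition oracle at
small sizes, and were cross-checked against a Burnside/cycle-index count
during development.

## Tempo statistics

* "Standard deviation ≤ 25%" is read as the coefficient of variation of
  the IOIs (std/mean ≤ 0.25), the only unit-free reading; the boundary is
  inclusive.  At least 5 intervals are required.
* Two sd conventions coexist deliberately: descriptive `IOIStats` uses the
  `n−1` sample sd (small samples), the log-normal fit uses the `1/n` MLE.
* Tempo is `1/mean(IOI)`, not the mean of `1/IOI`.
* The KS test treats the fitted parameters as known (plain KS, no
  Lilliefors correction) — the simplest variant consistent with "a
  log-normal cannot be rejected".
* Sample medians use the midpoint convention for even `n`.
* The mode implied by the fitted parameters (1.1, 0.90) is
  `e^{1.1−0.81} ≈ 1.34 Hz`; published summaries sometimes round this to
  1.4 Hz, presumably from unrounded fit parameters upstream.  The package
  always reports the formula value.

The packaged 50-row tempo table (`data/xeno_tempo_table_synthetic.csv`) is
a synthetic stand-in: 10 placeholder species in each of five animal groups
with tempos drawn from the fitted cross-species log-normal and the two
central order statistics fixed at 3.40/3.50 Hz so the sample median equals
the published 3.45 Hz.  Tests against it validate the summary code path
and the distribution's plausibility, not any real field data.

## Signal pipelines

* Flash counts (29.97 frames/s video): Savitzky–Golay smoothing (order 2,
  frame 9), mean subtraction, Hann spectrogram (window 100 samples =
  3.34 s, 50% overlap, one-sided).  Frequency resolution rate/window ≈
  0.3 Hz.
* Audio: 4th-order Butterworth high-pass at 5 kHz applied
  forward-backward (zero phase), analytic-signal magnitude (Hilbert),
  sliding-window maximum over 3,000 samples (≈ 68 ms at 44.1 kHz), mean
  subtraction, polyphase down-sampling to ≤ 150 samples/s, spectrogram
  (8 s window by default).  A spline-through-maxima envelope was considered
  and not needed; the sliding maximum is the simpler reading of a "peak
  envelope".
* Dominant tempo = frequency of maximal time-averaged **linear** power
  within 0.25–10 Hz (powers are stored in dB but averaged in linear units;
  mean subtraction guarantees the DC bin cannot win).
* For resolving the ≈10% tempo difference between the two synthetic field
  signals (2.4 vs 2.16 Hz, a 0.24 Hz gap), the comparison uses a 512-sample
  window (0.06 Hz bins) so the gap spans ~4 bins.

## What the synthetic data does and does not emulate

Generators are seed-deterministic.  Event trains draw IOIs from a
truncated Gaussian — adequate for a criterion based only on the IOI mean
and sd, but without the serial correlation or drift of real calling bouts.
The flash-count generator sums periodic 2-frame flashes of `n = 21`
individuals with Gaussian timing scatter (sd 0.05 s) about a common phase:
the emulated swarm is already synchronized (uniform random offsets would
cancel the group periodicity), so it tests tempo extraction, not
synchronization dynamics.  The chirp generator gates an 8 kHz carrier at
the chirp tempo (duty 0.3) over broadband noise; real chirps have
structured spectra and amplitude envelopes.  Passing tests therefore
demonstrate that the pipelines recover known tempos under realistic
sampling, jitter and noise — not that they are robust to every artifact of
field recordings.

## Known limitations

* No inhibitory, weighted or continuous coupling; no amplitude dynamics
  (Stuart–Landau); no bifurcation continuation.
* The isolated-vertex exclusion is the only connectivity constraint the
  enumeration knows; no general isomorphism solver for large `n`.
* The tongue geometry is validated through monotone width and harmonic
  suppression, not against a reference heat map.
* Whether the forcing's initial phase was randomized per realization in
  the original experiments is unknown; it is fixed at 0 here (oscillator
  phases are already random), and `R̄` is invariant to a common phase
  shift.
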