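"""The three circuit-entrainment experiments: topology sweep, resonance curves, Arnold tongue.

Each experiment integrates forced five-oscillator circuits over many seeded
realizations (fresh random phases and natural frequencies per realization)
and averages the post-transient order parameter R̄.  Averaging is over the
per-realization time averages, i.e., the reported curve is the mean of the
individual realization curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digraphs import Digraph, canonical_form, complete_digraph, to_adjacency
from .kuramoto import (
    TWO_PI,
    Forcing,
    IntegrationConfig,
    NaturalFrequencySpec,
    batch_mean_order,
    critical_coupling,
    subcritical_coupling,
)

__all__ = [
    "TopologySweepResult",
    "ResonanceCurve",
    "ArnoldTongueMap",
    "topology_sweep",
    "resonance_curve",
    "arnold_tongue_map",
    "tongue_width",
]


@dataclass(frozen=True)
class TopologySweepResult:
    """Mean order parameter per circuit topology, plus the sorted response curve."""

    mean_order: dict
    sorted_curve: np.ndarray
    n_realizations: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.mean_order.values()))
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("mean order values must lie in [0, 1]")


@dataclass(frozen=True)
class ResonanceCurve:
    """Mean order parameter versus forcing tempo at fixed K_ext and spread."""

    f_grid: np.ndarray
    mean_order: np.ndarray
    k_ext: float
    spread: float
    n_realizations: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.f_grid) <= 0):
            raise ValueError("f_grid must be strictly increasing")
        if self.mean_order.shape != self.f_grid.shape:
            raise ValueError("grid / value shape mismatch")

    @property
    def peak_tempo(self) -> float:
        """Forcing tempo of the maximal mean response."""
        return float(self.f_grid[int(np.argmax(self.mean_order))])


@dataclass(frozen=True)
class ArnoldTongueMap:
    """Mean order parameter over the (K_ext, f_ext) product grid."""

    k_ext_grid: np.ndarray
    f_grid: np.ndarray
    mean_order: np.ndarray  # shape (len(k_ext_grid), len(f_grid))
    n_realizations: int

    def __post_init__(self) -> None:
        if self.mean_order.shape != (len(self.k_ext_grid), len(self.f_grid)):
            raise ValueError("matrix shape must be |K_ext grid| x |f grid|")


def _realization_draws(
    freq_spec: NaturalFrequencySpec,
    n_oscillators: int,
    n_realizations: int,
    base_seed: int,
    stream: int = 0,
):
    """Seeded per-realization natural frequencies and initial phases.

    Each (stream, realization) pair gets an independent deterministic
    substream of the base seed, so sweeps are reproducible and insensitive
    to evaluation order.
    """
    omegas = np.empty((n_realizations, n_oscillators))
    phases = np.empty((n_realizations, n_oscillators))
    for r in range(n_realizations):
        rng = np.random.default_rng([base_seed, stream, r])
        omegas[r] = rng.normal(
            freq_spec.mean_angular, freq_spec.spread_angular, size=n_oscillators
        )
        phases[r] = rng.uniform(0.0, TWO_PI, size=n_oscillators)
    return omegas, phases


def _subcritical_k(freq_spec: NaturalFrequencySpec, epsilon: float) -> float:
    return subcritical_coupling(critical_coupling(freq_spec.spread_angular), epsilon)


def topology_sweep(
    graphs,
    freq_spec: NaturalFrequencySpec,
    forcing: Forcing,
    config: IntegrationConfig,
    n_realizations: int = 100,
    epsilon: float = 0.1,
) -> TopologySweepResult:
    """Mean entrainment R̄ for every circuit topology in ``graphs``.

    For each graph, ``n_realizations`` independent realizations (fresh
    random phases and Gaussian frequencies, deterministic sub-seeds of
    ``config.seed``) are integrated under the given forcing and their
    post-transient R̄ values averaged.  Realization draws depend only on
    the realization index, not on the graph's position in the list, so the
    per-graph values are invariant to input order.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("graph list must be nonempty")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    n = graphs[0].n_vertices
    k = _subcritical_k(freq_spec, epsilon)
    omegas, phases = _realization_draws(freq_spec, n, n_realizations, config.seed)
    result = {}
    for g in graphs:
        r_vals = batch_mean_order(to_adjacency(g), omegas, k, forcing, config, phases)
        result[canonical_form(g).label] = float(r_vals.mean())
    values = np.sort(np.asarray(list(result.values())))
    params = {
        "mean_tempo_hz": freq_spec.mean_tempo,
        "spread_hz": freq_spec.spread,
        "k_ext": forcing.relative_strength,
        "f_ext_hz": forcing.tempo,
        "epsilon": epsilon,
        "coupling_rad_s": k,
        "seed": config.seed,
    }
    return TopologySweepResult(
        mean_order=result, sorted_curve=values, n_realizations=n_realizations, params=params
    )


def resonance_curve(
    f_grid,
    k_ext: float,
    freq_spec: NaturalFrequencySpec,
    config: IntegrationConfig,
    n_realizations: int = 10,
    n_oscillators: int = 5,
    epsilon: float = 0.1,
) -> ResonanceCurve:
    """Mean response R̄ of the all-to-all circuit as the forcing tempo varies.

    One realization contributes a whole curve (its frequency and phase
    draws are held fixed across the f grid); the returned curve is the mean
    of the realization curves — it peaks at the circuit's mean natural
    tempo and both forcing strength and oscillator heterogeneity widen and
    amplify the peak.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if np.any(f_grid < 0):
        raise ValueError("forcing tempos must be nonnegative")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    adj = to_adjacency(complete_digraph(n_oscillators))
    k = _subcritical_k(freq_spec, epsilon)
    omegas, phases = _realization_draws(freq_spec, n_oscillators, n_realizations, config.seed)
    curve = np.empty(len(f_grid))
    for i, f in enumerate(f_grid):
        forcing = Forcing(tempo=float(f), relative_strength=k_ext)
        curve[i] = float(batch_mean_order(adj, omegas, k, forcing, config, phases).mean())
    return ResonanceCurve(
        f_grid=f_grid,
        mean_order=curve,
        k_ext=k_ext,
        spread=freq_spec.spread,
        n_realizations=n_realizations,
    )


def arnold_tongue_map(
    k_ext_grid,
    f_grid,
    freq_spec: NaturalFrequencySpec,
    config: IntegrationConfig,
    n_realizations: int = 10,
    n_oscillators: int = 5,
    epsilon: float = 0.1,
) -> ArnoldTongueMap:
    """R̄ over the forcing-strength x forcing-tempo grid (all-to-all circuit).

    The locked region forms a tongue around the mean natural tempo that
    widens with the forcing strength; no secondary tongues appear at the
    harmonics or subharmonics.
    """
    k_ext_grid = np.asarray(k_ext_grid, dtype=float)
    f_grid = np.asarray(f_grid, dtype=float)
    if k_ext_grid.size == 0 or f_grid.size == 0:
        raise ValueError("grids must be nonempty")
    rows = [
        resonance_curve(
            f_grid, float(k_ext), freq_spec, config, n_realizations, n_oscillators, epsilon
        ).mean_order
        for k_ext in k_ext_grid
    ]
    return ArnoldTongueMap(
        k_ext_grid=k_ext_grid,
        f_grid=f_grid,
        mean_order=np.vstack(rows),
        n_realizations=n_realizations,
    )


def tongue_width(tongue: ArnoldTongueMap, k_ext: float, threshold: float = 0.6) -> float:
    """Width (Hz) of the locked interval at one forcing strength.

    The maximal contiguous span of forcing tempos, around the row's global
    maximum, where R̄ >= threshold; 0 when even the maximum stays below the
    threshold (a single qualifying grid point is a degenerate zero-width
    interval).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    matches = np.nonzero(np.isclose(tongue.k_ext_grid, k_ext))[0]
    if matches.size == 0:
        raise KeyError(f"K_ext={k_ext} not in the map's grid")
    row = tongue.mean_order[matches[0]]
    peak = int(np.argmax(row))
    if row[peak] < threshold:
        return 0.0
    lo = peak
    while lo > 0 and row[lo - 1] >= threshold:
        lo -= 1
    hi = peak
    while hi < len(row) - 1 and row[hi + 1] >= threshold:
        hi += 1
    return float(tongue.f_grid[hi] - tongue.f_grid[lo])
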