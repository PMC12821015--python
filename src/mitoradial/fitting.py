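"""Grid-search least-squares fit of the transport model to radial histograms.

Observed (experimental or synthetic) normalized radial density histograms
are compared with steady-state histograms of simulated walker radii on the
same bins; the objective is the sum of squared density differences. A full
grid over (pka_signal, k_bind, v_plus, step_scale) is evaluated with common
random numbers so the objective surface is smooth and the argmin stable.

Caveat carried over from the source analysis: pixel-based observed
histograms are compared against point-based simulated walkers without a
size-kernel correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .radial import RadialHistogram
from .transport import SimParams, run_simulation

__all__ = [
    "FitGrid",
    "FitResult",
    "histogram_sse",
    "fit_distribution",
    "classify_peak_location",
    "simulate_histogram",
]

_PARAM_COLUMNS = ("pka_signal", "k_bind", "v_plus", "step_scale")


@dataclass(frozen=True)
class FitGrid:
    """Candidate parameter values and the fixed base simulation settings.

    ``step_scale`` multiplies the free-diffusion step size (i.e. scales
    the diffusion constant by ``step_scale**2``); it stands in for an
    overall reduction of random motility.
    """

    pka_signal: tuple[float, ...]
    k_bind: tuple[float, ...] = (0.025,)
    v_plus: tuple[float, ...] = (0.4,)
    step_scale: tuple[float, ...] = (1.0,)
    base: SimParams = field(default_factory=SimParams)

    def __post_init__(self) -> None:
        for name in _PARAM_COLUMNS:
            values = getattr(self, name)
            if len(values) == 0:
                raise ValueError(f"grid for {name} must be nonempty")
            if any(v < 0 for v in values):
                raise ValueError(f"grid values for {name} must be >= 0")

    def points(self):
        return itertools.product(self.pka_signal, self.k_bind, self.v_plus, self.step_scale)

    def params_at(self, pka: float, k_bind: float, v_plus: float, step_scale: float) -> SimParams:
        return self.base.replace(
            pka_signal=pka,
            k_bind=k_bind,
            v_plus=v_plus,
            diffusion=self.base.diffusion * step_scale**2,
        )


@dataclass
class FitResult:
    """Best grid point, its objective, and the full objective surface."""

    best_params: dict[str, float]
    best_objective: float
    surface: pd.DataFrame
    seed: int


def histogram_sse(h1: RadialHistogram, h2: RadialHistogram) -> float:
    """Sum of squared density differences; requires identical bin edges."""
    if h1.bin_edges.shape != h2.bin_edges.shape or not np.allclose(h1.bin_edges, h2.bin_edges):
        raise ValueError("histograms must share identical bin edges")
    return float(np.sum((h1.densities - h2.densities) ** 2))


def simulate_histogram(params: SimParams, bin_edges: np.ndarray) -> RadialHistogram:
    """Steady-state radii of one simulation, histogrammed on given edges."""
    result = run_simulation(params)
    densities, _ = np.histogram(result.radii, bins=bin_edges, density=True)
    return RadialHistogram(bin_edges=np.asarray(bin_edges, float), densities=densities)


def fit_distribution(observed: RadialHistogram, grid: FitGrid) -> FitResult:
    """Exhaustive grid search minimizing ``histogram_sse`` to ``observed``.

    Every grid point is simulated with the same seed (common random
    numbers). Grid points whose simulation fails to reach the steady-state
    criterion are recorded with a NaN objective, excluded from the argmin,
    and reported via a warning.
    """
    rows = []
    for pka, kb, vp, sc in grid.points():
        params = grid.params_at(pka, kb, vp, sc)
        res = run_simulation(params)
        if not res.converged:
            warnings.warn(
                f"simulation did not converge at pka={pka}, k_bind={kb}, "
                f"v_plus={vp}, step_scale={sc}; grid point excluded",
                stacklevel=2,
            )
            sse = np.nan
        else:
            densities, _ = np.histogram(res.radii, bins=observed.bin_edges, density=True)
            sse = histogram_sse(observed, RadialHistogram(observed.bin_edges, densities))
        rows.append({"pka_signal": pka, "k_bind": kb, "v_plus": vp, "step_scale": sc, "sse": sse})
    surface = pd.DataFrame(rows)
    valid = surface.dropna(subset=["sse"])
    if valid.empty:
        raise RuntimeError("no grid point produced a converged simulation")
    best = valid.loc[valid["sse"].idxmin()]
    return FitResult(
        best_params={k: float(best[k]) for k in _PARAM_COLUMNS},
        best_objective=float(best["sse"]),
        surface=surface,
        seed=grid.base.seed,
    )


def classify_peak_location(h: RadialHistogram) -> str:
    """Label the histogram mode: 'inner' (<1/3), 'mid' ([1/3, 2/3]) or
    'peripheral' (>2/3) by the centre of the maximal-density bin.

    Exact ties between bins are broken toward the outermost maximal bin
    and flagged with a warning.
    """
    dens = h.densities
    if dens.size == 0:
        raise ValueError("histogram has no bins")
    maxima = np.flatnonzero(dens == dens.max())
    if maxima.size > 1:
        warnings.warn("histogram mode is tied; using the outermost maximal bin", stacklevel=2)
    center = h.bin_centers[maxima[-1]]
    if center < 1.0 / 3.0:
        return "inner"
    if center <= 2.0 / 3.0:
        return "mid"
    return "peripheral"
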