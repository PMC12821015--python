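"""Two-state biased random walk of organelles in a unit disk.

Walkers switch stochastically between a microtubule-bound state, in which
they move radially with a signal-dependent drift velocity, and a free state,
in which they diffuse isotropically. The disk boundary (radius 1) reflects
free walkers and clamps bound ones. Time is measured in units of the
unbinding time (``k_unbind = 1``) and length in disk radii.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SimParams",
    "SimState",
    "SimResult",
    "drift_velocity",
    "advance_state",
    "run_simulation",
    "mean_position_sweep",
]

#: hard cap on steps when running to convergence
MAX_STEPS = 100_000
#: window length (steps) for the steady-state criterion
CONVERGENCE_WINDOW = 1_000
#: |Δ window mean radius| below which a window counts as converged
CONVERGENCE_TOL = 5e-3
#: consecutive converged windows required
CONVERGENCE_RUNS = 3


def drift_velocity(pka_signal: float, v_plus: float, v_minus: float) -> float:
    """Net radial speed of a bound walker (positive = outward).

    ``v = v_plus * pka/(1+pka) - v_minus/(1+pka)``: anterograde motor
    activity saturates with signal strength while retrograde activity is
    suppressed by it. Bounded in ``(-v_minus, v_plus)`` and strictly
    increasing in ``pka_signal`` whenever ``v_plus + v_minus > 0``.
    """
    if pka_signal < 0:
        raise ValueError(f"pka_signal must be >= 0, got {pka_signal}")
    if v_plus < 0 or v_minus < 0:
        raise ValueError("speeds must be >= 0")
    return (pka_signal * v_plus - v_minus) / (1.0 + pka_signal)


@dataclass(frozen=True)
class SimParams:
    """Parameters of the two-state transport simulation.

    Rates are in units of ``k_unbind``, speeds in disk radii per unit
    time, ``diffusion`` in disk radii^2 per unit time.
    """

    k_bind: float = 0.025
    k_unbind: float = 1.0
    pka_signal: float = 0.7
    v_plus: float = 0.4
    v_minus: float = 0.4
    diffusion: float = 8e-4
    dt: float = 0.01
    n_mito: int = 5000
    n_steps: int | None = None
    seed: int = 0
    record_every: int = 10

    def __post_init__(self) -> None:
        for name in ("k_bind", "k_unbind", "pka_signal", "v_plus", "v_minus", "diffusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.dt * max(self.k_bind, self.k_unbind) > 0.1:
            raise ValueError(
                "dt * max(k_bind, k_unbind) must be <= 0.1 for the per-step "
                "Bernoulli switching approximation to hold"
            )
        if self.n_mito < 1:
            raise ValueError("n_mito must be >= 1")
        if self.n_steps is not None and self.n_steps < 1:
            raise ValueError("n_steps must be >= 1 when given")

    @property
    def v_drift(self) -> float:
        return drift_velocity(self.pka_signal, self.v_plus, self.v_minus)

    def replace(self, **kwargs) -> "SimParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimState:
    """Positions (n, 2) and bound flags (n,) of the walker population."""

    positions: np.ndarray
    bound: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.bound = np.asarray(self.bound, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if self.bound.shape != (self.positions.shape[0],):
            raise ValueError("bound flags must have shape (n,)")

    @property
    def radii(self) -> np.ndarray:
        return np.hypot(self.positions[:, 0], self.positions[:, 1])


@dataclass
class SimResult:
    """Outcome of a simulation run."""

    radii: np.ndarray
    bound: np.ndarray
    mean_radius_trajectory: np.ndarray
    record_every: int
    params: SimParams
    seed: int
    converged: bool
    n_steps_run: int

    @property
    def mean_radius(self) -> float:
        return float(self.radii.mean())


def _reflect_radially(positions: np.ndarray) -> None:
    """Map r > 1 to 2 - r along the same ray, in place; clamp if still out."""
    r = np.hypot(positions[:, 0], positions[:, 1])
    out = r > 1.0
    if not np.any(out):
        return
    r_out = r[out]
    r_new = 2.0 - r_out
    # a step can in principle overshoot past r = 2; mirror again, then clamp
    r_new = np.abs(r_new)
    np.clip(r_new, 0.0, 1.0, out=r_new)
    scale = np.where(r_out > 0, r_new / r_out, 0.0)
    positions[out] *= scale[:, None]


def advance_state(state: SimState, params: SimParams, rng: np.random.Generator) -> SimState:
    """Advance the population by one time step ``params.dt`` (in place).

    Per walker: switch binding state (unbound->bound with probability
    ``k_bind*dt``, bound->unbound with ``k_unbind*dt``), then move. Free
    walkers take Gaussian steps of standard deviation ``sqrt(2*D*dt)`` per
    axis with radial reflection at the boundary; bound walkers step
    radially by ``v_drift*dt`` (clamped at r=1 going out, passing through
    the origin going in).
    """
    pos = state.positions
    bound = state.bound
    n = pos.shape[0]
    dt = params.dt

    u = rng.random(n)
    p_switch = np.where(bound, params.k_unbind * dt, params.k_bind * dt)
    bound ^= u < p_switch
    free = ~bound

    if params.diffusion > 0:
        sd = np.sqrt(2.0 * params.diffusion * dt)
        # normals drawn for every walker (keeps the stream layout simple);
        # zeroed for bound walkers before applying
        steps = rng.normal(0.0, sd, size=(n, 2))
        steps *= free[:, None]
        pos += steps

    drift_step = params.v_drift * dt
    r = np.hypot(pos[:, 0], pos[:, 1])
    # free walkers overshooting the boundary: radial mirror r -> 2 - r
    # (re-mirrored then clamped for pathological overshoots)
    r_target = np.where(r > 1.0, np.clip(np.abs(2.0 - r), 0.0, 1.0), r)
    if drift_step != 0.0:
        # bound walkers step radially; outward motion clamps at the
        # boundary, inward motion through the center flips the ray
        r_drifted = r_target + drift_step
        flip = bound & (r_drifted < 0)
        r_drifted = np.clip(np.abs(r_drifted), 0.0, 1.0)
        r_target = np.where(bound, r_drifted, r_target)
    else:
        flip = None
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, r_target / r, 0.0)
    pos *= scale[:, None]
    if flip is not None and flip.any():
        pos[flip] *= -1.0
    return state


def initial_state(params: SimParams, rng: np.random.Generator) -> SimState:
    """Uniform-over-area positions; binding flags from the stationary law."""
    n = params.n_mito
    r = np.sqrt(rng.random(n))
    theta = rng.random(n) * 2.0 * np.pi
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    p_bound = params.k_bind / (params.k_bind + params.k_unbind) if (params.k_bind + params.k_unbind) > 0 else 0.0
    bound = rng.random(n) < p_bound
    return SimState(positions, bound)


def run_simulation(params: SimParams) -> SimResult:
    """Run the walk to a steady state and return final radial distances.

    With ``params.n_steps`` set the run has fixed length; otherwise it
    stops once the mean radius averaged over successive 1,000-step windows
    changes by less than 5e-3 for 3 consecutive windows (hard cap 1e5
    steps, reported via ``converged``).
    """
    rng = np.random.default_rng(params.seed)
    state = initial_state(params, rng)

    fixed = params.n_steps is not None
    cap = params.n_steps if fixed else MAX_STEPS
    traj: list[float] = []
    window_sum = 0.0
    prev_window_mean: float | None = None
    quiet_windows = 0
    converged = fixed
    step = 0
    while step < cap:
        advance_state(state, params, rng)
        step += 1
        mean_r = float(state.radii.mean())
        if step % params.record_every == 0:
            traj.append(mean_r)
        if not fixed:
            window_sum += mean_r
            if step % CONVERGENCE_WINDOW == 0:
                window_mean = window_sum / CONVERGENCE_WINDOW
                window_sum = 0.0
                if prev_window_mean is not None and abs(window_mean - prev_window_mean) < CONVERGENCE_TOL:
                    quiet_windows += 1
                else:
                    quiet_windows = 0
                prev_window_mean = window_mean
                if quiet_windows >= CONVERGENCE_RUNS:
                    converged = True
                    break

    return SimResult(
        radii=state.radii,
        bound=state.bound.copy(),
        mean_radius_trajectory=np.asarray(traj),
        record_every=params.record_every,
        params=params,
        seed=params.seed,
        converged=converged,
        n_steps_run=step,
    )


def mean_position_sweep(
    pka_grid: Sequence[float],
    kbind_grid: Sequence[float],
    base_params: SimParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state mean radius over a (pka, k_bind) grid.

    Returns ``(mean_r, stderr)`` arrays of shape
    ``(len(pka_grid), len(kbind_grid))``. The same seed is reused at every
    grid cell (common random numbers) so the surface is smooth in the
    parameters rather than in the noise.
    """
    pka_grid = list(pka_grid)
    kbind_grid = list(kbind_grid)
    if not pka_grid or not kbind_grid:
        raise ValueError("parameter grids must be nonempty")
    mean_r = np.empty((len(pka_grid), len(kbind_grid)))
    stderr = np.empty_like(mean_r)
    for i, pka in enumerate(pka_grid):
        for j, kb in enumerate(kbind_grid):
            res = run_simulation(base_params.replace(pka_signal=pka, k_bind=kb))
            mean_r[i, j] = res.mean_radius
            stderr[i, j] = float(res.radii.std(ddof=1) / np.sqrt(res.radii.size))
    return mean_r, stderr
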