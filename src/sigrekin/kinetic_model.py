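"""ODE kinetic model of regulator-driven gene expression, fitted by
multi-restart simulated annealing.

The target transcript level ``z(t)`` responds to one or more regulator
profiles ``y_i(t)`` through a sigmoidal synthesis term with first-order decay:

    dz/dt = k1 * sigma( sum_i w_i * y_i(t) + b ) - k2 * z,
    sigma(x) = 1 / (1 + exp(-x))

with maximal synthesis rate ``k1`` (expression units/h), degradation rate
``k2`` (1/h), regulation bias ``b`` and signed regulatory weights ``w``.  The
sign of ``w`` is the biological readout: positive means the regulator
stimulates the target, negative means it represses it.

Fitting minimizes the sum of squared differences (SSE) between the simulated
trajectory (simple forward-Euler integration) and the observed linear-scale
profile.  The optimizer is simulated annealing restarted many times
(256 by default) from random initial parameter vectors; the minimum-SSE fit
wins.  A fit whose SSE, normalized by the observed profile's total sum of
squares about its mean, stays above a threshold counts as *regulation
disproved*; otherwise regulation by the tested regulator(s) is possible.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit

from .errors import ParameterError, StructuralError
from .expression_profiles import ExpressionProfile, Scale

DEFAULT_N_RESTARTS = 256


class Verdict(str, enum.Enum):
    REGULATION_POSSIBLE = "regulation_possible"
    REGULATION_DISPROVED = "regulation_disproved"


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the kinetic model (see module docstring for units)."""

    k1: float
    k2: float
    b: float
    w: tuple[float, ...]
    z0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", tuple(float(x) for x in np.atleast_1d(self.w)))
        if self.k1 < 0 or self.k2 < 0:
            raise ParameterError("k1 and k2 must be non-negative")
        if self.z0 < 0:
            raise ParameterError("z0 must be non-negative")


@dataclass(frozen=True)
class KineticFit:
    params: KineticParams
    sse: float
    normalized_sse: float
    trajectory: ExpressionProfile
    verdict: Verdict
    n_restarts: int
    master_seed: int
    regulator_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric-cooling schedule for the annealer.

    ``t0`` defaults to the objective value at the starting point (so the first
    few moves are nearly free), cooled by ``cooling`` each iteration.  Gaussian
    proposals start at sd ``proposal_scale`` times the width of each bound and
    shrink by ``proposal_decay`` per iteration, so late iterations refine the
    incumbent locally.
    """

    n_iter: int = 400
    cooling: float = 0.975
    proposal_scale: float = 0.2
    proposal_decay: float = 0.985
    t0: float | None = None
    t0_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ParameterError("n_iter must be >= 1")
        if not (0 < self.cooling < 1):
            raise ParameterError("cooling must be in (0, 1)")
        if self.proposal_scale <= 0:
            raise ParameterError("proposal_scale must be positive")
        if not (0 < self.proposal_decay <= 1):
            raise ParameterError("proposal_decay must be in (0, 1]")


@dataclass(frozen=True)
class FitConfig:
    """Plausibility bounds and acceptance criterion for kinetic fits.

    Bounds keep the model biologically sensible: degradation within
    ``[k2_min, k2_max]`` (mRNA half-lives of minutes to tens of hours),
    synthesis capped so steady states stay within ``k1_scale`` times the
    observed maximum, and weights/bias within symmetric boxes.  A fit is
    accepted ("regulation possible") when SSE / sum((x - mean(x))^2) falls
    below ``nsse_threshold``.
    """

    k2_min: float = 0.02
    k2_max: float = 3.0
    k1_scale: float = 10.0
    w_max: float = 10.0
    b_max: float = 10.0
    nsse_threshold: float = 0.2
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _common_grid(regulators: Sequence[ExpressionProfile]) -> np.ndarray:
    if not regulators:
        raise ParameterError("need at least one regulator profile")
    grid = regulators[0].times
    for r in regulators[1:]:
        if not r.same_grid(regulators[0]):
            raise StructuralError("regulator profiles are on different time grids")
    return grid


def integrate_model(
    params: KineticParams,
    regulators: Sequence[ExpressionProfile],
    dt: float,
) -> ExpressionProfile:
    """Forward-Euler solution of the model, sampled on the regulators' grid.

    Regulator values are linearly interpolated between their grid points.  The
    step count is chosen so uniform steps of (at most) ``dt`` tile the span
    exactly; the solution is then interpolated back onto the observation grid
    (a no-op when ``dt`` equals the grid step of a uniform grid).
    """
    grid = _common_grid(regulators)
    if len(params.w) != len(regulators):
        raise StructuralError(
            f"{len(params.w)} weights for {len(regulators)} regulators"
        )
    if dt <= 0:
        raise ParameterError("dt must be positive")
    gaps = np.diff(grid)
    if len(gaps) and dt > gaps.min() + 1e-12:
        raise ParameterError(
            f"dt={dt} exceeds the smallest observation gap {gaps.min():.6g}"
        )
    t0, t1 = grid[0], grid[-1]
    n_steps = max(1, int(np.ceil((t1 - t0) / dt - 1e-9)))
    dt_eff = (t1 - t0) / n_steps
    fine_times = t0 + np.arange(n_steps + 1) * dt_eff
    y = np.column_stack([np.interp(fine_times, grid, r.values) for r in regulators])
    w = np.asarray(params.w)
    z = np.empty(n_steps + 1)
    z[0] = params.z0
    for i in range(n_steps):
        s = expit(float(y[i] @ w) + params.b)
        z[i + 1] = z[i] + dt_eff * (params.k1 * s - params.k2 * z[i])
    z_obs = np.interp(grid, fine_times, z)
    return ExpressionProfile("model", grid, np.maximum(z_obs, 0.0), Scale.LINEAR)


def sse(trajectory: ExpressionProfile, observed: ExpressionProfile) -> float:
    """Sum of squared differences between two profiles on a shared grid."""
    if not trajectory.same_grid(observed):
        raise StructuralError("trajectory and observation grids differ")
    d = trajectory.values - observed.values
    return float(d @ d)


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

def restart_seed(master_seed: int, restart_index: int) -> np.random.SeedSequence:
    """Seed for one restart; depends only on (master_seed, restart_index)."""
    return np.random.SeedSequence([int(master_seed), int(restart_index)])


def _draw_randoms(rng: np.random.Generator, n_iter: int, lower, upper):
    """All random numbers one annealing run consumes, in a fixed order."""
    d = len(lower)
    x0 = lower + rng.random(d) * (upper - lower)
    steps = rng.standard_normal((n_iter, d))
    us = rng.random(n_iter)
    return x0, steps, us


def _anneal_batch(
    objective_batch: Callable[[np.ndarray], np.ndarray],
    lower: np.ndarray,
    upper: np.ndarray,
    seeds: Sequence,
    schedule: AnnealSchedule,
    trace: bool = False,
):
    """Run one annealing chain per seed, vectorized across chains.

    Each chain's trajectory depends only on its own seed: its random stream is
    pre-drawn independently, so results are identical whether chains run alone
    or in a batch.
    """
    n_r, d = len(seeds), len(lower)
    n_iter = schedule.n_iter
    x = np.empty((n_r, d))
    steps = np.empty((n_r, n_iter, d))
    us = np.empty((n_r, n_iter))
    for r, s in enumerate(seeds):
        rng = np.random.default_rng(s)
        x[r], steps[r], us[r] = _draw_randoms(rng, n_iter, lower, upper)
    f = objective_batch(x)
    if not np.all(np.isfinite(f)):
        raise ParameterError("objective is not finite at a starting point")
    best_x, best_f = x.copy(), f.copy()
    if schedule.t0 is not None:
        temp = np.full(n_r, float(schedule.t0))
    else:
        temp = np.maximum(np.abs(f), schedule.t0_floor)
    width = upper - lower
    best_trace = np.empty((n_iter, n_r)) if trace else None
    for i in range(n_iter):
        sigma = schedule.proposal_scale * (schedule.proposal_decay ** i) * width
        prop = np.clip(x + steps[:, i, :] * sigma, lower, upper)
        fp = objective_batch(prop)
        with np.errstate(over="ignore", invalid="ignore"):
            accept = (fp <= f) | (us[:, i] < np.exp(-(fp - f) / temp))
        x = np.where(accept[:, None], prop, x)
        f = np.where(accept, fp, f)
        improved = fp < best_f
        best_x = np.where(improved[:, None], prop, best_x)
        best_f = np.where(improved, fp, best_f)
        if trace:
            best_trace[i] = best_f
        temp = temp * schedule.cooling
    return best_x, best_f, best_trace


def anneal(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    schedule: AnnealSchedule | None = None,
    seed=0,
    return_trace: bool = False,
):
    """Simulated annealing of a scalar objective on a bound box.

    Returns the best-seen parameter vector (plus its objective value and the
    per-iteration best-seen trace when ``return_trace``).  Deterministic given
    ``seed``; proposals are clipped to the box and accepted by the Metropolis
    rule at the current temperature.
    """
    if not bounds:
        raise ParameterError("bounds must be non-empty")
    lower = np.array([lo for lo, _ in bounds], dtype=float)
    upper = np.array([hi for _, hi in bounds], dtype=float)
    if np.any(upper < lower) or not np.all(np.isfinite(lower) & np.isfinite(upper)):
        raise ParameterError("bounds must be finite intervals with lo <= hi")
    schedule = schedule or AnnealSchedule()

    def batch(X: np.ndarray) -> np.ndarray:
        return np.array([objective(row) for row in X], dtype=float)

    best_x, best_f, tr = _anneal_batch(
        batch, lower, upper, [seed], schedule, trace=return_trace
    )
    if return_trace:
        return best_x[0], float(best_f[0]), tr[:, 0]
    return best_x[0]


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _check_fit_inputs(target: ExpressionProfile, regulators: Sequence[ExpressionProfile]):
    grid = _common_grid(regulators)
    if not target.same_grid(regulators[0]):
        raise StructuralError("target and regulators are on different time grids")
    if target.scale is not Scale.LINEAR:
        raise StructuralError("fit expects preprocessed linear-scale profiles")
    gaps = np.diff(grid)
    if not np.allclose(gaps, gaps[0], rtol=1e-6):
        raise StructuralError("fit expects a uniform (resampled) time grid")
    return grid, float(gaps[0])


def _make_objective_batch(
    observed: np.ndarray, regulator_matrix: np.ndarray, dt: float, z0: float
) -> Callable[[np.ndarray], np.ndarray]:
    """Vectorized SSE objective: rows of P are (k1, k2, b, w_1..w_m).

    Euler steps run directly on the (uniform) observation grid, so the
    simulated value at every grid point is compared with the observation.
    """
    n_obs, m = regulator_matrix.shape

    def objective(P: np.ndarray) -> np.ndarray:
        k1, k2, b = P[:, 0], P[:, 1], P[:, 2]
        W = P[:, 3:3 + m]
        z = np.full(len(P), z0)
        total = np.zeros(len(P))
        for i in range(n_obs - 1):
            s = expit(W @ regulator_matrix[i] + b)
            z = z + dt * (k1 * s - k2 * z)
            d = z - observed[i + 1]
            total += d * d
        return total

    return objective


def _fit_bounds(
    observed: np.ndarray,
    n_regulators: int,
    config: FitConfig,
    w_bounds: Sequence[tuple[float, float]] | None,
) -> tuple[np.ndarray, np.ndarray]:
    x_max = max(float(np.max(observed)), 1e-6)
    lower = [1e-9, config.k2_min, -config.b_max]
    upper = [config.k1_scale * config.k2_max * x_max, config.k2_max, config.b_max]
    if w_bounds is None:
        w_bounds = [(-config.w_max, config.w_max)] * n_regulators
    if len(w_bounds) != n_regulators:
        raise ParameterError("one weight bound per regulator required")
    for lo, hi in w_bounds:
        if lo > hi:
            raise ParameterError(f"empty weight bound [{lo}, {hi}]")
        lower.append(lo)
        upper.append(hi)
    return np.array(lower), np.array(upper)


def fit_regulators(
    target: ExpressionProfile,
    regulators: Sequence[ExpressionProfile],
    n_restarts: int = DEFAULT_N_RESTARTS,
    master_seed: int = 0,
    config: FitConfig | None = None,
    w_bounds: Sequence[tuple[float, float]] | None = None,
) -> KineticFit:
    """Fit the kinetic model of ``target`` driven by ``regulators``.

    Runs ``n_restarts`` independent annealing chains (seeded from
    ``master_seed`` and the restart index) and keeps the minimum-SSE result;
    ties break to the lowest restart index.  ``z0`` is fixed to the first
    observed value.  Optional ``w_bounds`` constrain weight signs (e.g.
    activator ``(0, w_max)``, repressor ``(-w_max, 0)``).
    """
    if n_restarts < 1:
        raise ParameterError("n_restarts must be >= 1")
    config = config or FitConfig()
    grid, dt = _check_fit_inputs(target, regulators)
    observed = target.values
    Y = np.column_stack([r.values for r in regulators])
    z0 = float(observed[0])
    objective = _make_objective_batch(observed, Y, dt, z0)
    lower, upper = _fit_bounds(observed, len(regulators), config, w_bounds)
    seeds = [restart_seed(master_seed, r) for r in range(n_restarts)]
    best_x, best_f, _ = _anneal_batch(objective, lower, upper, seeds, config.schedule)
    winner = int(np.argmin(best_f))  # argmin takes the first (lowest index) on ties
    p = best_x[winner]
    params = KineticParams(
        k1=float(p[0]), k2=float(p[1]), b=float(p[2]),
        w=tuple(p[3:3 + len(regulators)]), z0=z0,
    )
    trajectory = integrate_model(params, regulators, dt)
    fit_sse = sse(trajectory, target)
    tss = float(np.sum((observed - observed.mean()) ** 2))
    nsse = fit_sse / tss if tss > 0 else np.inf
    verdict = (
        Verdict.REGULATION_POSSIBLE
        if nsse < config.nsse_threshold
        else Verdict.REGULATION_DISPROVED
    )
    return KineticFit(
        params=params,
        sse=fit_sse,
        normalized_sse=nsse,
        trajectory=trajectory,
        verdict=verdict,
        n_restarts=n_restarts,
        master_seed=master_seed,
        regulator_ids=tuple(r.gene_id for r in regulators),
    )


def fit_single_regulator(
    target: ExpressionProfile,
    regulator: ExpressionProfile,
    n_restarts: int = DEFAULT_N_RESTARTS,
    master_seed: int = 0,
    config: FitConfig | None = None,
) -> KineticFit:
    """Single-regulator fit (one signed weight)."""
    return fit_regulators(target, [regulator], n_restarts, master_seed, config)


def fit_dual_regulator(
    target: ExpressionProfile,
    activator: ExpressionProfile,
    repressor: ExpressionProfile,
    constrain_signs: bool = False,
    n_restarts: int = DEFAULT_N_RESTARTS,
    master_seed: int = 0,
    config: FitConfig | None = None,
    w_bounds: Sequence[tuple[float, float]] | None = None,
) -> KineticFit:
    """Two-regulator fit combining a candidate activator and repressor.

    With ``constrain_signs`` the activator weight is restricted to be
    non-negative and the repressor weight non-positive (bound boxes);
    explicit ``w_bounds`` override this.
    """
    config = config or FitConfig()
    if w_bounds is None and constrain_signs:
        w_bounds = [(0.0, config.w_max), (-config.w_max, 0.0)]
    return fit_regulators(
        target, [activator, repressor], n_restarts, master_seed, config, w_bounds
    )


def screen_regulators(
    target: ExpressionProfile,
    candidate_activators: Sequence[ExpressionProfile],
    fixed_repressor: ExpressionProfile,
    n_restarts: int = DEFAULT_N_RESTARTS,
    master_seed: int = 0,
    config: FitConfig | None = None,
    constrain_signs: bool = True,
) -> list[KineticFit]:
    """Try every candidate activator together with one fixed repressor.

    Returns the dual fits ranked by ascending SSE (ties by candidate gene id,
    so the ranking is invariant under reordering of the candidate list).  The
    per-candidate seed is derived from the candidate's gene id, not its
    position, for the same reason.
    """
    if not candidate_activators:
        raise ParameterError("candidate list must be non-empty")
    fits = []
    for cand in candidate_activators:
        seed = np.random.SeedSequence(
            [int(master_seed), zlib.crc32(cand.gene_id.encode())]
        ).generate_state(1)[0]
        fits.append(
            fit_dual_regulator(
                target, cand, fixed_repressor,
                constrain_signs=constrain_signs,
                n_restarts=n_restarts, master_seed=int(seed), config=config,
            )
        )
    return sorted(fits, key=lambda f: (f.sse, f.regulator_ids[0]))
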