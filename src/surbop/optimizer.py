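"""Projected gradient-descent loop for band-selective universal-rotation pulses.

One iteration: forward-propagate every isochromat, backpropagate the costates,
average the analytic gradients over offsets and the B1 ensemble, step the
controls along the descent direction, and radially clip to the peak-amplitude
constraint.  The printed update rule in the optimal-control literature moves
the controls *along* the gradient of a quantity that is here a cost to be
minimized; this implementation therefore steps against the gradient
(``u <- u - eps * grad``), which is the direction of guaranteed first-order
improvement.

With the backtracking line search (default) every accepted step strictly
decreases the cost evaluated *after* clipping, so the cost trace is monotone
with the constraint active.  A fixed-step mode reproduces the literal
constant-``eps`` update; a Polak--Ribiere conjugate-gradient direction is
available for faster convergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bands import BandSpec
from .cost import CostWeights, GradientField, cost_and_gradient, total_cost
from .pulse import ControlLimits, ShapedPulse, clip_to_limit, random_start

__all__ = [
    "OptimizerConfig",
    "OptimizationResult",
    "OptimizationError",
    "update_controls",
    "optimize",
    "multi_start",
]


class OptimizationError(RuntimeError):
    """Raised when the cost becomes non-finite; carries diagnostic state."""

    def __init__(self, message, iteration=None, cost_trace=None):
        super().__init__(message)
        self.iteration = iteration
        self.cost_trace = cost_trace


@dataclass(frozen=True)
class OptimizerConfig:
    """Settings of the gradient loop.

    ``step_mode``: 'line_search' (backtracking, monotone) or 'fixed'.
    ``epsilon0``: initial step size in Hz per unit gradient; the line search
    adapts it between iterations.
    ``tolerance``: relative cost change below which (for ``tol_window``
    consecutive iterations) the run is declared converged.
    ``scheme``: 'steepest' or 'conjugate' (Polak--Ribiere) descent direction.
    """

    step_mode: str = "line_search"
    epsilon0: float = 1e8
    max_iterations: int = 5000
    tolerance: float = 1e-8
    tol_window: int = 10
    seed: int = 0
    restarts: int = 1
    scheme: str = "steepest"

    def __post_init__(self):
        if self.epsilon0 <= 0 or self.tolerance <= 0:
            raise ValueError("epsilon0 and tolerance must be positive")
        if self.step_mode not in ("line_search", "fixed"):
            raise ValueError("step_mode must be 'line_search' or 'fixed'")
        if self.scheme not in ("steepest", "conjugate"):
            raise ValueError("scheme must be 'steepest' or 'conjugate'")


@dataclass
class OptimizationResult:
    pulse: ShapedPulse
    cost_trace: np.ndarray
    converged: bool
    iterations_used: int
    seed: int
    gradient_norm: float
    log: list = field(default_factory=list)

    @property
    def final_cost(self) -> float:
        return float(self.cost_trace[-1])


def update_controls(
    pulse: ShapedPulse,
    gradient: GradientField,
    epsilon: float,
    limits: ControlLimits | None = None,
) -> ShapedPulse:
    """One descent step ``u <- u - eps * g`` followed by amplitude clipping."""
    if gradient.g_x.size != pulse.n_steps:
        raise ValueError("gradient length does not match pulse")
    new = pulse.with_controls(
        pulse.u_x - epsilon * gradient.g_x, pulse.u_y - epsilon * gradient.g_y
    )
    if limits is not None:
        new = clip_to_limit(new, limits)
    return new


def _step_along(pulse, dx, dy, epsilon, limits):
    new = pulse.with_controls(pulse.u_x + epsilon * dx, pulse.u_y + epsilon * dy)
    if limits is not None:
        new = clip_to_limit(new, limits)
    return new


def _line_search(pulse, dx, dy, cost, eps, band, U_F, weights, limits):
    """Approximate line minimization along the (projected) direction.

    From the last accepted step size: if the first trial already improves,
    keep doubling while the cost drops; otherwise backtrack by halving until
    the first improvement.  Returns ``(pulse, cost, eps)`` of the best point
    found, or ``None`` when no step size yields a strict decrease.
    """

    def phi(e):
        cand = _step_along(pulse, dx, dy, e, limits)
        return cand, total_cost(cand, band, U_F, weights)

    def refine(best, c_lo, c_hi):
        """One parabolic refinement on the bracket (e/2, e, 2e) around the best."""
        e1 = best[2]
        c1 = best[1]
        # vertex of the parabola through (e1/2, c_lo), (e1, c1), (2*e1, c_hi)
        x0, x1, x2 = 0.5 * e1, e1, 2.0 * e1
        d0, d2 = c_lo - c1, c_hi - c1
        denom = d0 * (x2 - x1) + d2 * (x1 - x0)
        if denom <= 0:
            return best
        e_star = x1 + 0.5 * (d0 * (x2 - x1) ** 2 - d2 * (x1 - x0) ** 2) / denom
        if not (x0 < e_star < x2) or e_star == e1:
            return best
        cand, c_star = phi(e_star)
        return (cand, c_star, e_star) if c_star < c1 else best

    def expand(best, c_prev):
        e = best[2]
        c_lo = c_prev
        for _ in range(80):
            e *= 2.0
            cand, c2 = phi(e)
            if c2 >= best[1]:
                return refine(best, c_lo, c2)
            c_lo = best[1]
            best = (cand, c2, e)
        return best

    candidate, cand_cost = phi(eps)
    if cand_cost < cost:
        return expand((candidate, cand_cost, eps), cost)
    # the remembered step may be too large (overshoot) or too small (change
    # below resolution): probe downwards first, then upwards
    e = eps
    c_above = cand_cost
    for _ in range(60):
        e *= 0.5
        cand, c2 = phi(e)
        if c2 < cost:
            return refine((cand, c2, e), cost, c_above)
        c_above = c2
    e = eps
    for _ in range(80):
        e *= 2.0
        cand, c2 = phi(e)
        if c2 < cost:
            return expand((cand, c2, e), cost)
    return None


def optimize(
    start: ShapedPulse,
    band: BandSpec,
    U_F,
    weights: CostWeights,
    config: OptimizerConfig,
    limits: ControlLimits | None = None,
) -> OptimizationResult:
    """Run the iterative optimization from one starting shape.

    Every iterate satisfies the amplitude constraint; with the line search the
    cost trace is non-increasing.  Aborts with :class:`OptimizationError` if
    the cost turns non-finite.
    """
    pulse = clip_to_limit(start, limits) if limits is not None else start
    cost = total_cost(pulse, band, U_F, weights)
    if not np.isfinite(cost):
        raise OptimizationError("starting cost is non-finite", 0, [cost])
    trace = [cost]
    log = []
    eps = config.epsilon0
    flat = 0
    converged = False
    grad_norm = np.inf
    dx_prev = dy_prev = None
    g_prev = None
    iterations = 0

    for iterations in range(1, config.max_iterations + 1):
        cost_here, grad = cost_and_gradient(pulse, band, U_F, weights)
        grad_norm = grad.norm()
        if grad_norm == 0.0:
            converged = True
            break

        dx_steepest, dy_steepest = -grad.g_x, -grad.g_y
        dx, dy = dx_steepest, dy_steepest
        if config.scheme == "conjugate" and g_prev is not None:
            beta = max(
                0.0,
                (
                    np.dot(grad.g_x, grad.g_x - g_prev.g_x)
                    + np.dot(grad.g_y, grad.g_y - g_prev.g_y)
                )
                / (np.dot(g_prev.g_x, g_prev.g_x) + np.dot(g_prev.g_y, g_prev.g_y)),
            )
            dx = dx + beta * dx_prev
            dy = dy + beta * dy_prev
            if np.dot(dx, grad.g_x) + np.dot(dy, grad.g_y) >= 0:
                dx, dy = dx_steepest, dy_steepest  # restart on a non-descent direction
        g_prev, dx_prev, dy_prev = grad, dx, dy

        if config.step_mode == "fixed":
            pulse = _step_along(pulse, dx, dy, eps, limits)
            new_cost = total_cost(pulse, band, U_F, weights)
        else:
            found = _line_search(
                pulse, dx, dy, cost, eps, band, U_F, weights, limits
            )
            if found is None and (dx is not dx_steepest):
                # projected conjugate direction gave no descent: restart
                dx, dy = dx_steepest, dy_steepest
                dx_prev, dy_prev, g_prev = dx, dy, grad
                found = _line_search(
                    pulse, dx, dy, cost, eps, band, U_F, weights, limits
                )
            if found is None:
                converged = True  # no descent at any step size along -grad
                break
            pulse, new_cost, eps = found

        if not np.isfinite(new_cost):
            raise OptimizationError(
                "cost became non-finite", iterations, trace + [new_cost]
            )
        rel_change = abs(cost - new_cost) / max(cost, np.finfo(float).tiny)
        cost = new_cost
        trace.append(cost)
        log.append(
            {"iteration": iterations, "cost": cost, "epsilon": eps, "grad_norm": grad_norm}
        )
        flat = flat + 1 if rel_change < config.tolerance else 0
        if flat >= config.tol_window or cost == 0.0:
            converged = True
            break

    return OptimizationResult(
        pulse=pulse,
        cost_trace=np.asarray(trace),
        converged=converged,
        iterations_used=iterations,
        seed=config.seed,
        gradient_norm=grad_norm,
        log=log,
    )


def multi_start(
    band: BandSpec,
    U_F,
    weights: CostWeights,
    config: OptimizerConfig,
    n_starts: int,
    n_steps: int,
    dt: float,
    limits: ControlLimits,
):
    """Optimize from ``n_starts`` random shapes and keep the best.

    Start seeds are ``config.seed, config.seed + 1, ...``.  Returns
    ``(best_result, summary)`` where ``summary`` is a cost-ranked list of
    ``{'seed', 'final_cost', 'converged', 'iterations'}`` dicts.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    results = []
    for i in range(n_starts):
        seed = config.seed + i
        start = random_start(n_steps, dt, limits, seed=seed)
        cfg = OptimizerConfig(
            step_mode=config.step_mode,
            epsilon0=config.epsilon0,
            max_iterations=config.max_iterations,
            tolerance=config.tolerance,
            tol_window=config.tol_window,
            seed=seed,
            restarts=1,
            scheme=config.scheme,
        )
        results.append(optimize(start, band, U_F, weights, cfg, limits))
    order = np.argsort([r.final_cost for r in results], kind="stable")
    summary = [
        {
            "seed": results[i].seed,
            "final_cost": results[i].final_cost,
            "converged": results[i].converged,
            "iterations": results[i].iterations_used,
        }
        for i in order
    ]
    return results[order[0]], summary
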