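"""Limited-memory quasi-Newton (l-BFGS) with registration stopping rules.

Following the convention of variational-registration frameworks, the
optimizer declares convergence when the three local criteria hold *jointly*
  * progress:      |J_k - J_{k-1}|  <  min_progress * (1 + |J_0|)
  * gradient:      ||g_k||          <  min_gradient * (1 + |J_0|)
  * step:          max component of the accepted step < min_step
or when the relative gradient alone collapses
  * rel. gradient: ||g_k|| / ||g_0|| < rel_gradient
or when the line search can make no further progress.  All tolerances
default to 0.001 and the iteration cap to 100.  Stopping on any tolerance
counts as convergence; hitting the iteration cap does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import OptimizationError

__all__ = ["StoppingCriteria", "OptimizationLog", "lbfgs_optimize"]


@dataclass
class StoppingCriteria:
    min_progress: float = 1e-3
    min_gradient: float = 1e-3
    rel_gradient: float = 1e-3
    min_step: float = 1e-3
    max_iterations: int = 100

    def __post_init__(self):
        for name in ("min_progress", "min_gradient", "rel_gradient", "min_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class OptimizationLog:
    """Per-iteration objective values and the stopping reason."""

    objective: list = field(default_factory=list)
    grad_norm: list = field(default_factory=list)
    step: list = field(default_factory=list)
    stop_reason: str = ""
    converged: bool = False

    def record(self, J: float, gnorm: float, step: float):
        self.objective.append(float(J))
        self.grad_norm.append(float(gnorm))
        self.step.append(float(step))


def _two_loop(g, s_list, y_list):
    q = g.copy()
    alphas = []
    for s, y in zip(reversed(s_list), reversed(y_list)):
        rho = 1.0 / np.dot(y, s)
        a = rho * np.dot(s, q)
        alphas.append(a)
        q -= a * y
    if s_list:
        s, y = s_list[-1], y_list[-1]
        q *= np.dot(s, y) / np.dot(y, y)
    for (s, y), a in zip(zip(s_list, y_list), reversed(alphas)):
        rho = 1.0 / np.dot(y, s)
        b = rho * np.dot(y, q)
        q += (a - b) * s
    return -q


def lbfgs_optimize(objective, x0, stop: StoppingCriteria | None = None, memory: int = 10):
    """Minimize ``objective(x) -> (value, gradient)`` from ``x0``.

    Uses the two-loop recursion with Armijo backtracking line search, which
    guarantees a non-increasing objective log.  Returns ``(x_star, log)``.
    """
    stop = stop or StoppingCriteria()
    x = np.asarray(x0, dtype=float).copy()
    J, g = objective(x)
    g = np.asarray(g, dtype=float)
    if not (np.isfinite(J) and np.all(np.isfinite(g))):
        raise OptimizationError("objective not finite at the starting point", last_iterate=x)

    log = OptimizationLog()
    log.record(J, np.linalg.norm(g), 0.0)
    J0, g0n = J, np.linalg.norm(g)
    s_list: list[np.ndarray] = []
    y_list: list[np.ndarray] = []

    for k in range(1, stop.max_iterations + 1):
        gnorm = np.linalg.norm(g)
        if g0n > 0 and gnorm / g0n < stop.rel_gradient:
            log.stop_reason, log.converged = "rel_gradient", True
            break

        d = _two_loop(g, s_list, y_list)
        if np.dot(d, g) >= 0:  # not a descent direction; fall back
            d = -g
        t = 1.0 if s_list else min(1.0, 1.0 / max(1.0, g0n))
        c1 = 1e-4
        gd = np.dot(g, d)
        accepted = False
        for _ in range(40):
            x_new = x + t * d
            J_new, g_new = objective(x_new)
            if np.isfinite(J_new) and J_new <= J + c1 * t * gd:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            log.stop_reason, log.converged = "line_search", True
            break
        if not np.all(np.isfinite(np.asarray(g_new))):
            raise OptimizationError(
                f"non-finite gradient at iteration {k}", last_iterate=x
            )

        s = t * d
        y = np.asarray(g_new, dtype=float) - g
        step_size = float(np.max(np.abs(s)))
        sy = np.dot(s, y)
        if sy > 1e-12 * np.linalg.norm(s) * np.linalg.norm(y):
            s_list.append(s)
            y_list.append(y)
            if len(s_list) > memory:
                s_list.pop(0)
                y_list.pop(0)

        J_prev = J
        x, J, g = x_new, float(J_new), np.asarray(g_new, dtype=float)
        log.record(J, np.linalg.norm(g), step_size)

        progress_ok = abs(J - J_prev) < stop.min_progress * (1.0 + abs(J0))
        gradient_ok = np.linalg.norm(g) < stop.min_gradient * (1.0 + abs(J0))
        step_ok = step_size < stop.min_step
        if progress_ok and gradient_ok and step_ok:
            log.stop_reason, log.converged = "tolerance", True
            break
    else:
        log.stop_reason, log.converged = "max_iterations", False

    return x, log
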