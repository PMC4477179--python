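"""Small damped-Newton maximizer shared by the likelihood fitters.

All models in this package maximize smooth concave (or near-concave)
log-likelihoods over a handful of parameters on tables with at most 60
cells, so a dense Newton iteration with step halving is both simple and
fast.  Callers supply a function returning ``(loglik, gradient, hessian)``
and, optionally, a feasibility predicate (the log-binomial model must
keep every linear predictor negative).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np


@dataclass
class NewtonResult:
    x: np.ndarray
    loglik: float
    grad: np.ndarray
    hess: np.ndarray
    converged: bool
    niter: int
    message: str = ""


def maximize_newton(
    fgh: Callable[[np.ndarray], tuple[float, np.ndarray, np.ndarray]],
    x0: np.ndarray,
    feasible: Optional[Callable[[np.ndarray], bool]] = None,
    tol: float = 1e-10,
    gtol: float = 1e-8,
    soft_gtol: float = 1e-4,
    maxiter: int = 100,
    ridge: float = 1e-10,
    max_halvings: int = 40,
) -> NewtonResult:
    """Maximize ``fgh`` by Newton steps with backtracking.

    The step is halved until the iterate is feasible and the log-likelihood
    does not decrease.  Convergence requires a small gradient; a stall
    (negligible improvement or failed line search while the gradient is
    still large, as happens at constraint boundaries) is reported as
    non-convergence so callers can switch to a constrained optimizer.
    The iterate never moves to a point with a lower log-likelihood, so
    the result is always at least as good as the starting point.
    """
    x = np.asarray(x0, dtype=float).copy()
    if feasible is not None and not feasible(x):
        raise ValueError("infeasible starting point")
    ll, g, h = fgh(x)
    if not np.isfinite(ll):
        raise ValueError("non-finite log-likelihood at starting point")
    for it in range(1, maxiter + 1):
        if np.max(np.abs(g)) < gtol:
            return NewtonResult(x, ll, g, h, True, it)
        a = -(h - ridge * np.eye(len(x)))
        try:
            step = np.linalg.solve(a, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(a, g, rcond=None)[0]
        # guard against wild steps from near-singular information
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        s = 1.0
        accepted = False
        for _ in range(max_halvings):
            x_new = x + s * step
            if feasible is None or feasible(x_new):
                ll_new, g_new, h_new = fgh(x_new)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-13 * (1 + abs(ll)):
                    accepted = True
                    break
            s *= 0.5
        if not accepted:
            return NewtonResult(
                x, ll, g, h, False, it, "line search failed"
            )
        improvement = ll_new - ll
        x, ll, g, h = x_new, ll_new, g_new, h_new
        if improvement < tol * (1 + abs(ll)):
            converged = bool(np.max(np.abs(g)) < soft_gtol)
            return NewtonResult(
                x, ll, g, h, converged, it,
                "" if converged else "stalled with large gradient",
            )
    return NewtonResult(x, ll, g, h, False, maxiter, "maxiter reached")
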