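"""Levenberg-Marquardt fitting of the MRF term weights.

The three unary-term weights w = (w_psi, w_lam, w_rho) are fitted against
ground-truth arch parameters on a set of scenes: with residuals
f_i(w) = G_i - E_i(w) (ground truth minus pipeline estimate) and cost
F(w) = 1/2 ||f(w)||^2, each step solves the damped normal equations

    (J^T J + mu I) h = -J^T f,

accepting the step only if it lowers F (mu shrinks on acceptance, grows on
rejection). The Jacobian is obtained by central finite differences with a
deliberately large relative step, because the pipeline is a piecewise-flat
function of the weights. All pipeline randomness is frozen by seed so the
residuals are deterministic functions of w. Each arch parameter is fitted
separately (the residual units differ), yielding one weight triple per
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "LMAResult",
    "WeightOptProblem",
    "numeric_jacobian",
    "lma_optimize",
    "make_weight_problem",
    "optimize_weights_per_parameter",
]


@dataclass
class LMAResult:
    w: np.ndarray  # best weights found
    cost: float  # F(w) = 0.5 ||f||^2
    cost_trace: list[float]  # accepted-step costs, strictly decreasing
    n_iter: int
    converged: bool


def numeric_jacobian(fn: Callable[[np.ndarray], np.ndarray],
                     w: np.ndarray, h_rel: float = 1e-2) -> np.ndarray:
    """Central-difference Jacobian of a vector function at w.

    The step for component k is h_rel * max(|w_k|, 1). Exact (to rounding)
    for affine functions.
    """
    w = np.asarray(w, dtype=float)
    f0 = np.asarray(fn(w), dtype=float)
    if not np.all(np.isfinite(f0)):
        raise ValueError("function is not finite at w")
    m, n = f0.size, w.size
    J = np.empty((m, n))
    for k in range(n):
        h = h_rel * max(abs(w[k]), 1.0)
        wp, wm = w.copy(), w.copy()
        wp[k] += h
        wm[k] -= h
        fp = np.asarray(fn(wp), dtype=float)
        fm = np.asarray(fn(wm), dtype=float)
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
            raise ValueError(f"non-finite evaluation perturbing weight {k}")
        J[:, k] = (fp - fm) / (2.0 * h)
    return J


def lma_optimize(
    residual: Callable[[np.ndarray], np.ndarray],
    w0: Sequence[float],
    tol: float = 1e-10,
    max_iter: int = 50,
    mu0: float = 1e-3,
    nu: float = 10.0,
    h_rel: float = 1e-2,
    nonnegative: bool = True,
    max_rejects: int = 25,
) -> LMAResult:
    """Minimize F(w) = 0.5 ||residual(w)||^2 by Levenberg-Marquardt.

    Accepted steps strictly decrease the cost; rejected steps keep the old w
    and residual and raise the damping. Weights are projected to be
    non-negative after each accepted step (the MRF energy requires it).
    """
    w = np.asarray(w0, dtype=float).copy()
    f = np.asarray(residual(w), dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("residual is not finite at w0")
    cost = 0.5 * float(f @ f)
    trace = [cost]
    mu = mu0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        J = numeric_jacobian(residual, w, h_rel=h_rel)
        g = J.T @ f
        A = J.T @ J
        accepted = False
        for _ in range(max_rejects):
            try:
                h = np.linalg.solve(A + mu * np.eye(w.size), -g)
            except np.linalg.LinAlgError as exc:
                raise RuntimeError("singular damped normal matrix") from exc
            w_new = w + h
            if nonnegative:
                w_new = np.maximum(w_new, 0.0)
            f_new = np.asarray(residual(w_new), dtype=float)
            cost_new = 0.5 * float(f_new @ f_new)
            if np.isfinite(cost_new) and cost_new < cost:
                w, f, prev_cost, cost = w_new, f_new, cost, cost_new
                trace.append(cost)
                mu = max(mu / nu, 1e-12)
                accepted = True
                break
            mu *= nu  # reject: keep the old w and f, raise damping
        if not accepted:
            converged = True
            break
        if prev_cost - cost < tol * max(1.0, prev_cost):
            converged = True
            break
        if np.linalg.norm(h) < 1e-12:
            converged = True
            break
    return LMAResult(w=w, cost=cost, cost_trace=trace, n_iter=it,
                     converged=converged)


@dataclass
class WeightOptProblem:
    """Weights-to-arch-parameter fitting problem over m scenes."""

    ground_truth: np.ndarray  # (m,) G_i
    evaluator: Callable[[np.ndarray], np.ndarray]  # w -> (m,) E_i(w)

    def residual(self, w: np.ndarray) -> np.ndarray:
        return self.ground_truth - np.asarray(self.evaluator(w), dtype=float)

    def cost(self, w: np.ndarray) -> float:
        f = self.residual(w)
        return 0.5 * float(f @ f)


def make_weight_problem(
    scenes,
    target: str = "AI",
    seed: int = 0,
    cache: dict | None = None,
) -> WeightOptProblem:
    """Build the fitting problem for one arch parameter on synthetic scenes.

    ``scenes`` is a sequence of (frame, ground_truth) pairs from the scene
    generator; the evaluator runs the full measurement pipeline with the
    candidate weights, all stochastic stages seeded identically so E(w) is
    deterministic. Evaluations are memoized on the weight triple.
    """
    from .arch_params import PipelineConfig, measure

    attr = {"AI": "AI_true", "AW": "AW_true", "AH": "AH_true"}[target]
    gt = np.array([getattr(g, attr) for _, g in scenes], dtype=float)
    memo: dict = {} if cache is None else cache

    def evaluator(w: np.ndarray) -> np.ndarray:
        key = tuple(np.round(np.asarray(w, dtype=float), 12))
        if key not in memo:
            cfg = PipelineConfig(weights=tuple(np.maximum(w, 0.0)))
            out = []
            for frame, g in scenes:
                ap = measure(frame, g.toe2_center, config=cfg, seed=seed)
                out.append(getattr(ap, target))
            memo[key] = np.array(out)
        return memo[key]

    return WeightOptProblem(ground_truth=gt, evaluator=evaluator)


def optimize_weights_per_parameter(
    scenes,
    w0: Sequence[float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    **lma_kwargs,
) -> dict[str, LMAResult]:
    """Fit one weight triple per arch parameter, as separate LMA problems."""
    results = {}
    for target in ("AI", "AW", "AH"):
        problem = make_weight_problem(scenes, target=target, seed=seed)
        results[target] = lma_optimize(problem.residual, w0, **lma_kwargs)
    return results
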