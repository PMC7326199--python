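"""Least-squares fitting of trajectory models to expression tensors.

The fit quality of a model prediction ``xhat`` against an observed
``S x T x n`` tensor ``x`` is the root-mean-square loss

    l(x, xhat) = ( (1 / STn) * sum (x_stg - xhat_stg)^2 ) ** (1/2)

and the pooled coefficient of determination ``R^2 = 1 - SS_res / SS_tot``
with the total sum of squares taken about the grand mean of all entries.

Global optimization is basin hopping: repeated bounded least-squares local
solves from randomly kicked restarts, keeping the best solution seen.
Dynamics parameters get multiplicative log-normal kicks (which respect
positivity); initial-condition parameters are resampled uniformly within
their bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitResult", "loss", "r_squared", "fit"]


def loss(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root-mean-square difference over all ``S * T * n`` tensor entries."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"shape mismatch: {observed.shape} vs {predicted.shape}"
        )
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pooled coefficient of determination about the grand mean.

    Exactly 0 for the grand-mean predictor, 1 for a perfect fit, negative
    for predictions worse than the grand mean.  A constant observed tensor
    has no variance to explain and is rejected.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"shape mismatch: {observed.shape} vs {predicted.shape}"
        )
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed tensor is constant; R^2 is undefined")
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def r_squared_per_gene(observed: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Diagnostic per-gene R^2 (pooled over sets and times for each gene)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    out = np.empty(observed.shape[2])
    for g in range(observed.shape[2]):
        out[g] = r_squared(observed[:, :, g], predicted[:, :, g])
    return out


@dataclass(frozen=True)
class FitResult:
    """Outcome of a basin-hopping fit."""

    parameters: np.ndarray
    loss: float
    r_squared: float
    n_evaluations: int
    seed: int
    converged: bool
    budget: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameters", np.asarray(self.parameters, dtype=float))
        if self.loss < 0:
            raise ValueError("loss must be nonnegative")
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters.tolist(),
            "loss": self.loss,
            "r_squared": self.r_squared,
            "n_evaluations": self.n_evaluations,
            "seed": self.seed,
            "converged": self.converged,
            "budget": self.budget,
        }


_FAIL_RESIDUAL = 1e3  # finite stand-in so a diverged integration scores
                      # astronomically bad instead of aborting the solver


def fit(
    predict: Callable[[np.ndarray], np.ndarray],
    observed: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray],
    seed: int,
    budget: int = 10,
    x0: np.ndarray | None = None,
    ic_mask: np.ndarray | None = None,
    kick_sigma: float = 0.5,
    max_nfev: int | None = None,
) -> FitResult:
    """Minimize the RMS loss of ``predict(theta)`` against *observed*.

    Parameters
    ----------
    predict
        Maps a parameter vector to a predicted ``S x T x n`` tensor (a
        parametrized ODE solve, typically).  Exceptions are treated as
        infeasible points, not errors.
    bounds
        ``(lower, upper)`` arrays for the full parameter vector.
    seed
        Fixes every random choice (starting point and kicks); identical
        seeds give identical results.
    budget
        Number of local least-squares solves (basin-hopping iterations).
    x0
        Optional starting point; by default dynamics parameters start
        log-uniform over their bounds (floored at 1e-2) and
        initial-condition parameters uniform.
    ic_mask
        Boolean mask marking initial-condition entries of the parameter
        vector; kicked by uniform resampling instead of log-normal noise.

    The best-so-far loss is monotone nonincreasing in the budget.
    """
    observed = np.asarray(observed, dtype=float)
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    n_par = len(lo)
    if ic_mask is None:
        ic_mask = np.zeros(n_par, dtype=bool)
    ic_mask = np.asarray(ic_mask, dtype=bool)
    scale = 1.0 / np.sqrt(observed.size)
    n_eval = 0
    any_success = False

    def residuals(theta: np.ndarray) -> np.ndarray:
        nonlocal n_eval, any_success
        n_eval += 1
        try:
            pred = predict(theta)
        except (RuntimeError, ValueError, OverflowError, FloatingPointError):
            return np.full(observed.size, _FAIL_RESIDUAL)
        if not np.all(np.isfinite(pred)):
            return np.full(observed.size, _FAIL_RESIDUAL)
        any_success = True
        return ((pred - observed) * scale).ravel()

    def random_start() -> np.ndarray:
        theta = np.empty(n_par)
        dyn = ~ic_mask
        lo_d = np.maximum(lo[dyn], 1e-2)
        theta[dyn] = np.exp(rng.uniform(np.log(lo_d), np.log(hi[dyn])))
        theta[ic_mask] = rng.uniform(lo[ic_mask], hi[ic_mask])
        return np.clip(theta, lo, hi)

    def kick(theta: np.ndarray) -> np.ndarray:
        out = theta.copy()
        dyn = ~ic_mask
        out[dyn] = theta[dyn] * np.exp(rng.normal(0.0, kick_sigma, size=dyn.sum()))
        out[ic_mask] = rng.uniform(lo[ic_mask], hi[ic_mask])
        return np.clip(out, lo, hi)

    theta_start = np.clip(np.asarray(x0, dtype=float), lo, hi) if x0 is not None else random_start()
    best_theta, best_loss = None, np.inf
    for hop in range(budget):
        res = least_squares(
            residuals, theta_start, bounds=(lo, hi), method="trf",
            max_nfev=max_nfev, x_scale="jac",
        )
        cand_loss = float(np.linalg.norm(res.fun))  # residuals pre-scaled: ||r|| = RMS loss
        if cand_loss < best_loss:
            best_loss = cand_loss
            best_theta = res.x
        # every third hop restarts from scratch instead of kicking the
        # incumbent, so a deep-but-wrong basin cannot trap the whole run
        if (hop + 1) % 3 == 0 or best_theta is None:
            theta_start = random_start()
        else:
            theta_start = kick(best_theta)
    if best_theta is None or not any_success:
        raise RuntimeError("every local solve diverged; no feasible fit found")
    pred = predict(best_theta)
    return FitResult(
        parameters=best_theta,
        loss=loss(observed, pred),
        r_squared=r_squared(observed, pred),
        n_evaluations=n_eval,
        seed=seed,
        converged=best_loss < np.inf,
        budget=budget,
    )
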