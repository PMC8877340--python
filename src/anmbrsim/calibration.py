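"""Parameter estimation and model-quality metrics.

Bounded nonlinear least squares with Jacobian-based standard errors, the
mean absolute percentage error (MAPE) as the accuracy metric, relative-error
quality bands for the estimates (below 0.1 good, above 0.5 poor, moderate in
between), and a Morris elementary-effects screening to rank parameter
influence before fitting.  Identifiability staging (choosing which subset to
fit first) is left to the user: fit subsets sequentially with ``theta_subset``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitResult", "mape", "fit_parameters", "elementary_effects",
           "quality_label"]


def quality_label(rel_error: float) -> str:
    """Quality band of an estimate from its relative error sigma/theta."""
    if not np.isfinite(rel_error):
        return "poor"
    if rel_error < 0.1:
        return "good"
    if rel_error > 0.5:
        return "poor"
    return "moderate"


def mape(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Mean absolute percentage error, %.

    Zero observations are excluded (with a warning reporting how many);
    series must have equal length.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted series must have equal length")
    nonzero = obs != 0.0
    n_excl = int((~nonzero).sum())
    if n_excl:
        warnings.warn(f"mape: excluded {n_excl} zero observation(s)",
                      stacklevel=2)
    if not nonzero.any():
        raise ValueError("all observations are zero")
    return float(100.0 * np.mean(np.abs(obs[nonzero] - pred[nonzero])
                                 / np.abs(obs[nonzero])))


@dataclass
class FitResult:
    """Outcome of a least-squares parameter estimation."""

    names: list[str]
    estimates: np.ndarray
    std_errors: np.ndarray
    relative_errors: np.ndarray
    labels: list[str]
    mape: float
    residual_norm: float
    success: bool

    def as_dict(self) -> dict:
        return {
            "parameters": {
                n: {"estimate": float(e), "std_error": float(s),
                    "relative_error": float(r), "quality": lab}
                for n, e, s, r, lab in zip(self.names, self.estimates,
                                           self.std_errors,
                                           self.relative_errors, self.labels)
            },
            "mape": self.mape,
            "residual_norm": self.residual_norm,
            "success": self.success,
        }


def fit_parameters(model: Callable[[np.ndarray], np.ndarray],
                   observed: Sequence[float],
                   theta0: Sequence[float],
                   names: Sequence[str] | None = None,
                   bounds: tuple | None = None) -> FitResult:
    """Estimate parameters of ``model`` against an observed series.

    ``model(theta)`` must return the predicted series on the observation
    grid.  Standard errors come from the Gauss-Newton covariance estimate
    ``s^2 (J^T J)^-1`` at the optimum; each parameter gets a quality label
    from its relative error.
    """
    obs = np.asarray(observed, float)
    theta0 = np.asarray(theta0, float)
    names = list(names) if names is not None else [
        f"theta{i}" for i in range(theta0.size)]
    if obs.size <= theta0.size:
        raise ValueError("need more observations than parameters")

    def residuals(theta: np.ndarray) -> np.ndarray:
        return np.asarray(model(theta), float) - obs

    kwargs = {"bounds": bounds} if bounds is not None else {}
    sol = least_squares(residuals, theta0, **kwargs)
    if not sol.success:
        raise RuntimeError(
            f"least-squares fit did not converge: {sol.message}; "
            f"final cost {sol.cost:.4g}")

    dof = max(obs.size - theta0.size, 1)
    s2 = 2.0 * sol.cost / dof
    JTJ = sol.jac.T @ sol.jac
    # structurally insensitive parameters (zero Jacobian column) get an
    # infinite standard error; the rest use the reduced normal matrix
    diag = np.diag(JTJ)
    active = diag > 1e-12 * max(float(diag.max()), 1.0)
    std = np.full(theta0.size, np.inf)
    if active.any():
        try:
            cov = s2 * np.linalg.inv(JTJ[np.ix_(active, active)])
            std[active] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            pass
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(sol.x != 0, std / np.abs(sol.x), np.inf)
    labels = [quality_label(r) for r in rel]
    pred = np.asarray(model(sol.x), float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_mape = mape(obs[obs != 0], pred[obs != 0]) if (obs != 0).any() else np.nan
    return FitResult(names=names, estimates=sol.x, std_errors=std,
                     relative_errors=rel, labels=labels, mape=fit_mape,
                     residual_norm=float(np.sqrt(2.0 * sol.cost)),
                     success=True)


def elementary_effects(model: Callable[[np.ndarray], float],
                       ranges: Sequence[tuple[float, float]],
                       r: int = 10, seed: int = 0,
                       levels: int = 4) -> dict:
    """Morris elementary-effects screening over a parameter hypercube.

    For each of ``r`` trajectories a random grid point is drawn and each
    parameter perturbed once by the grid jump ``delta = levels/(2*(levels-1))``
    (in normalised units); effects are scaled back by the parameter range so
    ``mu_star`` is comparable across parameters with different units of the
    model output per unit parameter.

    Returns ``{"mu_star": ..., "sigma": ..., "ranking": ...}`` with the
    ranking from most to least influential.
    """
    if r < 4:
        raise ValueError("need at least r = 4 trajectories")
    ranges = [(float(lo), float(hi)) for lo, hi in ranges]
    k = len(ranges)
    rng = np.random.default_rng(seed)
    delta = levels / (2.0 * (levels - 1))
    grid = np.arange(levels - 1) / (levels - 1)  # points where +delta stays in [0,1]

    effects = np.zeros((r, k))
    for traj in range(r):
        x = rng.choice(grid, size=k)
        order = rng.permutation(k)
        base = model(_denorm(x, ranges))
        for idx in order:
            x_new = x.copy()
            x_new[idx] += delta
            val = model(_denorm(x_new, ranges))
            span = ranges[idx][1] - ranges[idx][0]
            # effect per unit of the physical parameter, scaled by its range
            effects[traj, idx] = (val - base) / delta
            x, base = x_new, val

    mu_star = np.abs(effects).mean(axis=0)
    sigma = effects.std(axis=0, ddof=1) if r > 1 else np.zeros(k)
    ranking = list(np.argsort(mu_star)[::-1])
    return {"mu_star": mu_star, "sigma": sigma, "ranking": ranking}


def _denorm(x: np.ndarray, ranges) -> np.ndarray:
    return np.array([lo + xi * (hi - lo) for xi, (lo, hi) in zip(x, ranges)])
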