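"""Pooled exponential decay fitting and the associated hypothesis tests.

The spatial decay of the conducted constriction is modelled as

    y = a * exp(b * x)

with ``y`` the relative constriction at upstream distance ``x`` (um),
``a`` the local constriction at the stimulation site and ``b`` (1/um) the
decay rate.  One fit is made per group over all pooled points; because
every traceable distance of every vessel contributes one point, short
distances (observed in more vessels) weigh in more heavily, which is
algebraically identical to an n-weighted fit of the per-distance means.
The length constant is lam = -1/b, the distance over which the response
falls to 1/e of its local amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .traces import PooledGroupData

__all__ = [
    "ExpFit",
    "DistanceTestResult",
    "fit_exponential",
    "length_constant",
    "predict",
    "per_distance_tests",
    "compare_local",
]

ALPHA = 0.05
# log-linear seeding needs two positive values; otherwise start from a
# decay typical of arteriolar conduction (lam = 200 um)
FALLBACK_B0 = -5e-3
XTOL = 1e-10
MAX_NFEV = 10_000


@dataclass(frozen=True)
class ExpFit:
    """Result of one pooled nonlinear least-squares fit of y = a*exp(b*x).

    Standard errors come from the Gauss-Newton curvature of the objective
    at the optimum; ``length_constant_um`` is -1/b when b < 0, else NaN.
    """

    a: float
    b: float
    se_a: float
    se_b: float
    residual_sum_squares: float
    n_points: int
    converged: bool

    @property
    def length_constant_um(self) -> float:
        return -1.0 / self.b if self.b < 0 else float("nan")


def _model(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a, b = params
    return a * np.exp(np.clip(b * x, -700.0, 700.0))


def fit_exponential(points) -> ExpFit:
    """Fit y = a*exp(b*x) to pooled (distance, constriction) points.

    ``points`` is an (N, 2) array-like of (x, y) pairs.  All points enter
    the sum of squares individually (no per-distance averaging), so the
    implicit weighting by the number of observations per distance follows
    from pooling.  ``b`` is unconstrained; a non-decaying optimum is only
    rejected later, when a length constant is derived from it.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (distance, constriction) points")
    x, y = pts[:, 0], pts[:, 1]
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct distances to fit a decay")

    a0 = float(np.mean(y[x == x.min()]))
    pos = y > 0
    if np.unique(x[pos]).size >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        b0 = float(slope)
        if a0 == 0.0:
            a0 = float(np.exp(intercept))
    else:
        b0 = FALLBACK_B0

    def residuals(p: np.ndarray) -> np.ndarray:
        return _model(p, x) - y

    def jac(p: np.ndarray) -> np.ndarray:
        e = np.exp(np.clip(p[1] * x, -700.0, 700.0))
        return np.column_stack([e, p[0] * x * e])

    res = optimize.least_squares(residuals, x0=[a0, b0], jac=jac, method="lm",
                                 xtol=XTOL, ftol=XTOL, gtol=XTOL,
                                 max_nfev=MAX_NFEV)
    a_hat, b_hat = map(float, res.x)
    rss = float(np.sum(res.fun ** 2))
    converged = bool(res.success) and np.all(np.isfinite(res.x))

    n = pts.shape[0]
    dof = n - 2
    J = jac(res.x)
    JtJ = J.T @ J
    if dof > 0:
        sigma2 = rss / dof
        try:
            cov = sigma2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            cov = sigma2 * np.linalg.pinv(JtJ)
        se_a, se_b = (float(np.sqrt(max(c, 0.0))) for c in np.diag(cov))
    else:
        se_a = se_b = 0.0

    return ExpFit(a=a_hat, b=b_hat, se_a=se_a, se_b=se_b,
                  residual_sum_squares=rss, n_points=n, converged=converged)


def length_constant(b: float) -> float:
    """Length constant lam = -1/b (um) of an exponential spatial decay."""
    if not (np.isfinite(b) and b < 0):
        raise ValueError(
            f"decay rate must be negative for a length constant, got b = {b}")
    return -1.0 / b


def predict(fit: ExpFit, x) -> float | np.ndarray:
    """Evaluate the fitted curve a*exp(b*x) at distance(s) ``x`` (um)."""
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    out = fit.a * np.exp(fit.b * np.asarray(x, dtype=float))
    return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class DistanceTestResult:
    """One-sample t-test of the per-vessel constrictions at one distance
    against 0 (two-sided).  ``testable`` is False when n < 2 or the sample
    variance is zero; then t and p are NaN and ``significant`` is False."""

    distance: float
    n: int
    mean: float
    t_statistic: float
    p_value: float
    testable: bool
    significant: bool


def per_distance_tests(pooled: PooledGroupData,
                       alpha: float = ALPHA) -> list[DistanceTestResult]:
    """Two-sided one-sample t-tests against 0 at every pooled distance."""
    results = []
    for d in pooled.per_distance["distance_um"]:
        vals = pooled.values_at(float(d))
        n = vals.size
        mean = float(np.mean(vals))
        if n < 2 or np.allclose(vals, vals[0]):
            results.append(DistanceTestResult(
                distance=float(d), n=n, mean=mean,
                t_statistic=float("nan"), p_value=float("nan"),
                testable=False, significant=False))
            continue
        t, p = stats.ttest_1samp(vals, 0.0)
        results.append(DistanceTestResult(
            distance=float(d), n=n, mean=mean, t_statistic=float(t),
            p_value=float(p), testable=True, significant=bool(p <= alpha)))
    return results


def compare_local(group_a_locals, group_b_locals) -> tuple[float, float]:
    """One-way ANOVA on the local (0 um) constrictions of two groups.

    With two groups the F statistic equals the square of the
    pooled-variance two-sample t statistic.
    """
    a = np.asarray(group_a_locals, dtype=float)
    b = np.asarray(group_b_locals, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 local-constriction values")
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)
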