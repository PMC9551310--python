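"""Model-based period analysis: project relative survival for a future period.

The cumulative k-year relative survival factorises into conditional 1-year
relative survival ratios ``r_j = p_j / p*_j``, one per follow-up year.
Computing these for several consecutive calendar periods gives a grid
``r_{j,p}`` (follow-up year j, period p).  A generalized linear model with
binomial error is fitted to the conditional *failure* probabilities
``1 - r_{j,p}``:

    link(1 - r_{j,p}) = alpha_j + gamma * p

with a categorical effect per follow-up year and a linear calendar-period
trend on the link scale, each cell weighted by its effective denominator
``n'_{j,p}``.  The default link is the complementary log-log, under which
``log(-log r) = alpha_j + gamma p`` — a log-linear trend in the annual
excess hazard; the logit link is available as an alternative.  Projection
to a future period evaluates the inverse link at ``p = target`` and
multiplies the predicted conditional survivals:

    R_k(target) = prod_{j<=k} inverse_link(alpha_j + gamma * target).

Conditional ratios above 1 (observed mortality below the population's,
possible in noisy cells) are clamped to ``1 - eps`` before fitting so the
failure probability stays in the link's domain; the clamp count is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

#: clamp for conditional relative survival >= 1, on the failure scale
CLAMP_EPS = 1e-6


class FittingError(RuntimeError):
    """The projection GLM could not be fitted."""


@dataclass
class ConditionalSurvivalGrid:
    """Conditional 1-year relative survival by follow-up year x period.

    ``r`` and ``w`` have shape (k, P); cells with ``w == 0`` or
    non-finite ``r`` are flagged and excluded from fitting.
    """

    r: np.ndarray
    w: np.ndarray
    period_labels: list[str]
    n_clamped: int = 0
    flagged: list[tuple[int, int]] = field(default_factory=list)  # (j, p) 1-based

    @property
    def k(self) -> int:
        return self.r.shape[0]

    @property
    def n_periods(self) -> int:
        return self.r.shape[1]

    def usable(self) -> np.ndarray:
        return np.isfinite(self.r) & (self.w > 0)


@dataclass
class ProjectionResult:
    """Fitted coefficients and, after prediction, the projected survival."""

    link: str
    alpha: np.ndarray  # per follow-up year, link scale
    gamma: float  # per-period trend, link scale
    deviance: float
    df_resid: int
    n_periods: int
    n_clamped: int = 0
    target_period: int | None = None
    r_hat: np.ndarray | None = None  # predicted conditional survival at target
    R_hat: float | None = None  # projected cumulative relative survival


def build_conditional_grid(estimates, period_labels=None) -> ConditionalSurvivalGrid:
    """Assemble the model's input grid from per-period survival estimates.

    ``estimates`` is a sequence of :class:`~periodsurv.engine.SurvivalEstimate`
    (one per consecutive calendar period, identical ``k``).  Cell values are
    the conditional relative survival ratios with the effective
    denominators as weights; ratios >= 1 are clamped to ``1 - eps``.
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise FittingError("need at least 2 periods to model a trend")
    k = estimates[0].k
    if any(e.k != k for e in estimates):
        raise FittingError("all periods must share the same k")
    P = len(estimates)
    r = np.full((k, P), np.nan)
    w = np.zeros((k, P))
    n_clamped = 0
    flagged: list[tuple[int, int]] = []
    for p, est in enumerate(estimates):
        r[:, p] = est.r
        w[:, p] = est.eff_n
    high = np.isfinite(r) & (r >= 1.0)
    n_clamped = int(high.sum())
    r[high] = 1.0 - CLAMP_EPS
    bad = ~(np.isfinite(r) & (w > 0))
    for j, p in zip(*np.nonzero(bad)):
        flagged.append((int(j) + 1, int(p) + 1))
    labels = (list(period_labels) if period_labels is not None
              else [f"period {p + 1}" for p in range(P)])
    return ConditionalSurvivalGrid(r=r, w=w, period_labels=labels,
                                   n_clamped=n_clamped, flagged=flagged)


def _get_link(link: str):
    if link == "cloglog":
        return sm.families.links.CLogLog()
    if link == "logit":
        return sm.families.links.Logit()
    raise ValueError(f"unknown link {link!r} (use 'cloglog' or 'logit')")


def fit_projection_model(
    grid: ConditionalSurvivalGrid, link: str = "cloglog"
) -> ProjectionResult:
    """Fit the weighted binomial GLM on the conditional failure grid."""
    k, P = grid.k, grid.n_periods
    use = grid.usable()
    periods_per_j = use.sum(axis=1)
    if np.any(periods_per_j < 2):
        j_bad = int(np.argmin(periods_per_j)) + 1
        raise FittingError(
            f"follow-up year {j_bad} has fewer than 2 usable periods"
        )

    jj, pp = np.nonzero(use)
    y = 1.0 - grid.r[use]  # conditional failure probability
    X = np.zeros((len(y), k + 1))
    X[np.arange(len(y)), jj] = 1.0  # follow-up-year indicators, no intercept
    X[:, k] = pp + 1.0  # linear period index 1..P
    weights = grid.w[use]

    family = sm.families.Binomial(link=_get_link(link))
    model = sm.GLM(y, X, family=family, var_weights=weights)
    try:
        with warnings.catch_warnings():
            # a deviance of ~0 (saturated mean structure) is a legitimate
            # outcome here, not a separation problem
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=300, tol=1e-12)
    except Exception as exc:  # non-convergence / singular design
        raise FittingError(f"projection GLM failed: {exc}") from exc
    if not res.converged:
        raise FittingError(
            f"projection GLM did not converge (deviance {res.deviance:.3g})"
        )
    return ProjectionResult(
        link=link,
        alpha=np.asarray(res.params[:k]),
        gamma=float(res.params[k]),
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        n_periods=P,
        n_clamped=grid.n_clamped,
    )


def predict_future_period(
    model: ProjectionResult, target_p: int, k: int | None = None
) -> ProjectionResult:
    """Evaluate the fitted trend at a (usually future) period index.

    Returns a completed copy of ``model`` carrying the predicted
    conditional survivals ``r_hat_j`` (capped at 1) and their product
    ``R_hat``, the projected k-year relative survival.
    """
    k = len(model.alpha) if k is None else k
    eta = model.alpha[:k] + model.gamma * target_p
    linkfun = _get_link(model.link)
    r_hat = np.minimum(1.0 - linkfun.inverse(eta), 1.0)
    return ProjectionResult(
        link=model.link, alpha=model.alpha, gamma=model.gamma,
        deviance=model.deviance, df_resid=model.df_resid,
        n_periods=model.n_periods, n_clamped=model.n_clamped,
        target_period=target_p, r_hat=r_hat, R_hat=float(np.prod(r_hat)),
    )
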