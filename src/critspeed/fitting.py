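"""(Weighted) least-squares estimation of (CS, d') for all model variants.

A *fitting procedure* is the combination of a model variant (which
variable sits on the vertical axis) and a regression method (ordinary or
weighted least squares).  The loss is always minimised along the vertical
axis:

    minimise  sum_i  w_i * (y_i - yhat_i(CS, d'))**2

with ``w_i = 1`` for LS.  For fixed-speed designs, time to exhaustion is
the error-carrying variable and its variance grows proportionally with
its magnitude, so the statistically appropriate weights are

    t(s):  w_i ~ 1 / t_i                (Var(t) ~ t)
    d(s):  w_i ~ 1 / (s_i**2 * t_i)     (Var(d) = s**2 Var(t), speed exact)

Minimisation uses the Levenberg--Marquardt algorithm.  For the two
hyperbolic variants t(s) and d(s), CS is kept strictly below the smallest
trial speed through a log-gap reparameterisation, because the model has a
genuine singularity at s = CS.  The two remaining variants are linear in
(CS, d') and need no constraint.

Fit quality is summarised by the parameter standard errors (SEE), their
combination in percent units (%SEE = 100*SEE_CS/CS + 100*SEE_d'/d') and
the residual standard error RSE = sqrt(RSS/(n-2)) in the units of the
fitted dependent variable.  RSE is computed from raw (unweighted)
residuals and is not comparable across procedures with different vertical
axes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .models import CSParameters, SubjectTrials

__all__ = [
    "ModelVariant",
    "Regression",
    "Appropriateness",
    "FittingProcedure",
    "FitResult",
    "STUDY_PROCEDURES",
    "build_weights",
    "fit",
    "standard_errors",
    "pct_see",
    "rse",
]


class ModelVariant(str, enum.Enum):
    """Which rearrangement of the two-parameter model is fitted."""

    T_OF_S = "t(s)"  # time vs speed, hyperbolic
    D_OF_S = "d(s)"  # distance vs speed, hyperbolic
    S_OF_T = "s(t)"  # speed vs time, linear in (CS, d') with regressor 1/t
    D_OF_T = "d(t)"  # distance vs time, the linear form

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Regression(str, enum.Enum):
    LS = "LS"
    WLS = "WLS"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Appropriateness(str, enum.Enum):
    """Statistical classification of a procedure for a given design.

    Assigned by :mod:`critspeed.selector`; purely informational — the
    fitter never refuses to run an inappropriate procedure, since running
    them deliberately is how their biases are measured.
    """

    APPROPRIATE = "appropriate"
    WRONG_DEPENDENT = "wrong_dependent"
    ENDOGENOUS = "endogenous"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class FittingProcedure:
    variant: ModelVariant
    regression: Regression
    appropriateness: Appropriateness = Appropriateness.UNCLASSIFIED

    @property
    def label(self) -> str:
        return f"{self.variant.value} using {self.regression.value}"

    def with_appropriateness(self, status: Appropriateness) -> "FittingProcedure":
        return replace(self, appropriateness=status)


#: The four procedures of the fixed-speed study protocol: the two
#: statistically appropriate WLS fits and the two frequently used but
#: inappropriate LS fits.
STUDY_PROCEDURES: tuple[FittingProcedure, ...] = (
    FittingProcedure(ModelVariant.T_OF_S, Regression.WLS),
    FittingProcedure(ModelVariant.D_OF_S, Regression.WLS),
    FittingProcedure(ModelVariant.S_OF_T, Regression.LS),
    FittingProcedure(ModelVariant.D_OF_T, Regression.LS),
)


@dataclass(frozen=True)
class FitResult:
    """Estimated parameters with fit-quality diagnostics.

    ``residuals`` are raw (unweighted) residuals in the units of the
    variant's vertical-axis variable.  ``see_cs``/``see_dprime`` are the
    square roots of the diagonal of s^2 (J^T W J)^-1; they are NaN when
    n <= 2 (zero residual degrees of freedom).  ``params_valid`` is False
    when the optimum is physically meaningless (CS or d' non-positive).
    """

    params: CSParameters
    see_cs: float
    see_dprime: float
    pct_see: float
    rse: float
    residuals: np.ndarray
    n_trials: int
    converged: bool
    n_iterations: int
    procedure: FittingProcedure
    params_valid: bool
    subject_id: str | None = None


# vertical-axis (y) and horizontal-axis (x) extractors per variant
def _design(trials: SubjectTrials, variant: ModelVariant):
    s, t, d = trials.speeds, trials.times, trials.distances
    if variant is ModelVariant.T_OF_S:
        return s, t
    if variant is ModelVariant.D_OF_S:
        return s, d
    if variant is ModelVariant.S_OF_T:
        return t, s
    if variant is ModelVariant.D_OF_T:
        return t, d
    raise ValueError(f"unknown variant {variant!r}")


def _predict(variant: ModelVariant, cs: float, dp: float, x: np.ndarray) -> np.ndarray:
    if variant is ModelVariant.T_OF_S:
        return dp / (x - cs)
    if variant is ModelVariant.D_OF_S:
        return x * dp / (x - cs)
    if variant is ModelVariant.S_OF_T:
        return dp / x + cs
    if variant is ModelVariant.D_OF_T:
        return dp + cs * x
    raise ValueError(f"unknown variant {variant!r}")


def _jacobian(variant: ModelVariant, cs: float, dp: float, x: np.ndarray) -> np.ndarray:
    """d yhat / d (cs, d') — an (n, 2) matrix."""
    if variant is ModelVariant.T_OF_S:
        g = x - cs
        return np.column_stack([dp / g**2, 1.0 / g])
    if variant is ModelVariant.D_OF_S:
        g = x - cs
        return np.column_stack([x * dp / g**2, x / g])
    if variant is ModelVariant.S_OF_T:
        return np.column_stack([np.ones_like(x), 1.0 / x])
    if variant is ModelVariant.D_OF_T:
        return np.column_stack([x, np.ones_like(x)])
    raise ValueError(f"unknown variant {variant!r}")


def build_weights(
    trials: SubjectTrials,
    variant: ModelVariant,
    scheme: str = "variance",
) -> np.ndarray:
    """Per-trial WLS weights for the fixed-speed design, normalised to mean 1.

    Weights are inverse dependent-variable variances: ``1/t`` for t(s)
    and, by error propagation through d = s*t with exact speed,
    ``1/(s**2 * t)`` for d(s).  ``scheme='time'`` offers ``1/t`` for d(s)
    as a sensitivity check.  Only relative weights matter; mean-1
    normalisation keeps the weighted residual variance on the same scale
    as the unweighted one across subjects.
    """
    if variant not in (ModelVariant.T_OF_S, ModelVariant.D_OF_S):
        raise ValueError(
            f"weights are defined only for the fixed-speed dependent variables "
            f"t(s) and d(s); the study fits {variant.value} with unweighted LS"
        )
    t = trials.times
    if variant is ModelVariant.T_OF_S or scheme == "time":
        w = 1.0 / t
    elif scheme == "variance":
        w = 1.0 / (trials.speeds**2 * t)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return w / w.mean()


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS slope/intercept of y on x (normal equations)."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValueError("singular design: regressor has zero variance")
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return slope, ym - slope * xm


def _default_init(trials: SubjectTrials) -> CSParameters:
    """Initial guess from the closed-form d(t) OLS line.

    Falls back to a crude through-the-origin guess when all times
    coincide (the d(t) line is then undefined but t(s)/d(s) are not).
    """
    try:
        slope, intercept = _ols_line(trials.times, trials.distances)
        return CSParameters(cs=slope, d_prime=intercept)
    except ValueError:
        return CSParameters(cs=0.0, d_prime=float(np.mean(trials.distances)))


def fit(
    trials: SubjectTrials,
    procedure: FittingProcedure,
    init: CSParameters | None = None,
    *,
    weight_scheme: str = "variance",
    xtol: float = 1e-12,
    max_iter: int = 200,
) -> FitResult:
    """Estimate (CS, d') by Levenberg--Marquardt (weighted) least squares.

    Parameters
    ----------
    trials
        The subject's exhaustive-trial data (>= 2 distinct speeds).
    procedure
        Model variant + regression method.  WLS is only defined for the
        t(s) and d(s) variants (weights on the measured/derived
        dependent variable of a fixed-speed design).
    init
        Optional starting parameters; defaults to the closed-form d(t)
        OLS solution, which always exists.
    weight_scheme
        Passed to :func:`build_weights` for WLS fits.
    xtol
        Relative parameter-change convergence threshold.
    max_iter
        Cap on function evaluations before declaring non-convergence.
    """
    variant = procedure.variant
    x, y = _design(trials, variant)
    n = len(y)

    if variant in (ModelVariant.S_OF_T, ModelVariant.D_OF_T):
        if np.unique(trials.times).size < 2:
            raise ValueError("singular design: all times to exhaustion equal")

    if procedure.regression is Regression.WLS:
        w = build_weights(trials, variant, scheme=weight_scheme)
    else:
        w = np.ones(n)
    sw = np.sqrt(w)

    p0 = init if init is not None else _default_init(trials)

    hyperbolic = variant in (ModelVariant.T_OF_S, ModelVariant.D_OF_S)
    if hyperbolic:
        # CS < min(speed): singularity of the hyperbola.  Fit in
        # theta = (log(s_lim - cs), d') so the constraint is structural.
        s_lim = trials.speeds.min() * (1.0 - 1e-6)
        gap0 = s_lim - p0.cs
        if gap0 <= 0:
            gap0 = 0.1 * s_lim  # init above the asymptote: back off
        theta0 = np.array([np.log(gap0), p0.d_prime])

        def unpack(theta):
            return s_lim - np.exp(theta[0]), theta[1]

        def resid(theta):
            cs, dp = unpack(theta)
            return sw * (y - _predict(variant, cs, dp, x))

        def jac(theta):
            cs, dp = unpack(theta)
            J = _jacobian(variant, cs, dp, x)  # wrt (cs, d')
            # chain rule: d cs / d theta0 = -exp(theta0)
            J = J.copy()
            J[:, 0] *= -np.exp(theta[0])
            return -sw[:, None] * J

    else:
        theta0 = np.array([p0.cs, p0.d_prime])

        def unpack(theta):
            return theta[0], theta[1]

        def resid(theta):
            cs, dp = unpack(theta)
            return sw * (y - _predict(variant, cs, dp, x))

        def jac(theta):
            cs, dp = unpack(theta)
            return -sw[:, None] * _jacobian(variant, cs, dp, x)

    sol = least_squares(
        resid,
        theta0,
        jac=jac,
        method="lm",
        xtol=xtol,
        ftol=xtol,
        gtol=xtol,
        max_nfev=max_iter * 10,
    )
    cs_hat, dp_hat = unpack(sol.x)
    params = CSParameters(cs=float(cs_hat), d_prime=float(dp_hat))

    yhat = _predict(variant, params.cs, params.d_prime, x)
    residuals = y - yhat

    see_cs, see_dp = _covariance_see(variant, params, x, w, residuals, n)
    rse_val = float(np.sqrt(np.sum(residuals**2) / (n - 2))) if n > 2 else np.nan
    if params.is_physical and np.isfinite(see_cs):
        pct = 100.0 * see_cs / params.cs + 100.0 * see_dp / params.d_prime
    else:
        pct = np.nan

    return FitResult(
        params=params,
        see_cs=see_cs,
        see_dprime=see_dp,
        pct_see=pct,
        rse=rse_val,
        residuals=residuals,
        n_trials=n,
        converged=sol.status > 0,
        n_iterations=int(sol.nfev),
        procedure=procedure,
        params_valid=params.is_physical,
        subject_id=trials.subject_id,
    )


def _covariance_see(variant, params, x, w, residuals, n) -> tuple[float, float]:
    if n <= 2:
        return np.nan, np.nan
    J = _jacobian(variant, params.cs, params.d_prime, x)
    JtWJ = J.T @ (w[:, None] * J)
    s2 = float(np.sum(w * residuals**2) / (n - 2))
    try:
        cov = s2 * np.linalg.inv(JtWJ)
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    diag = np.clip(np.diag(cov), 0.0, None)
    return float(np.sqrt(diag[0])), float(np.sqrt(diag[1]))


def standard_errors(fit_result: FitResult) -> tuple[float, float]:
    """Parameter SEEs (CS in m/s, d' in m) of a converged fit.

    Defined as sqrt(diag(s^2 (J^T W J)^-1)) with s^2 the weighted
    residual variance on n - 2 degrees of freedom; undefined for n <= 2.
    """
    if fit_result.n_trials <= 2:
        raise ValueError("standard errors undefined for n <= 2 (zero residual df)")
    return fit_result.see_cs, fit_result.see_dprime


def pct_see(fit_result: FitResult) -> float:
    """Combined SEE in percent: 100*SEE_CS/CS + 100*SEE_d'/d'."""
    p = fit_result.params
    if not (p.cs > 0 and p.d_prime > 0):
        raise ValueError("%SEE requires positive CS and d'")
    return 100.0 * fit_result.see_cs / p.cs + 100.0 * fit_result.see_dprime / p.d_prime


def rse(fit_result: FitResult) -> float:
    """Residual standard error sqrt(RSS/(n-2)), raw residual units.

    Not comparable between procedures with different vertical axes.
    """
    if fit_result.n_trials <= 2:
        raise ValueError("RSE undefined for n <= 2")
    return float(np.sqrt(np.sum(fit_result.residuals**2) / (fit_result.n_trials - 2)))
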