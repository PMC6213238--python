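"""Hydrothermal response surface of biodegradation.

Decomposition rate responds to temperature through a Q10 law normalised at
the optimum T_m,

    m(T) = Q10 ** ((T - T_m) / 10),        0 <= T <= T_m,

and to relative moisture W (fraction of total moisture capacity, 0..1)
through a two-exponent beta-shaped factor

    f(W) = (W / W_m)**a * ((1 - W) / (1 - W_m))**b,

which equals 1 exactly at its extremum W_m = a / (a + b) and vanishes at
both dry and waterlogged endpoints.  The combined rate is the product

    U(T, W) = U_max * m(T) * f(W).

The module also fits the exponential temperature law for decay constants,
k(T) = k0 * exp(s * T), whose implied Q10 is exp(10 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit, least_squares

from .errors import IllPosedFitError, FitConvergenceError, InvalidInputError, RangeError

__all__ = [
    "TemperatureResponse",
    "MoistureResponse",
    "ExpRateLaw",
    "temperature_factor",
    "moisture_factor",
    "combined_rate",
    "MoistureFit",
    "fit_moisture_response",
    "fit_rate_temperature",
    "SurfaceFit",
    "fit_response_surface",
]


@dataclass(frozen=True)
class TemperatureResponse:
    """Q10 temperature factor normalised to 1 at the optimum ``t_opt``."""

    q10: float = 2.0
    t_opt: float = 30.0     # deg C
    u_max: float = 1.0      # rate at the optimum, mg kg-1 h-1

    def __post_init__(self):
        if self.q10 <= 1:
            raise InvalidInputError(f"Q10 must exceed 1, got {self.q10}")
        if self.u_max <= 0:
            raise InvalidInputError("u_max must be > 0")


@dataclass(frozen=True)
class MoistureResponse:
    """Two-exponent moisture factor with extremum at w_opt = a/(a+b)."""

    a: float
    b: float
    u_max: float = 1.0
    w_opt: float | None = None  # stored redundantly; checked if supplied

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise InvalidInputError("exponents a, b must be > 0")
        if self.u_max <= 0:
            raise InvalidInputError("u_max must be > 0")
        w = self.a / (self.a + self.b)
        if self.w_opt is None:
            object.__setattr__(self, "w_opt", w)
        elif not math.isclose(self.w_opt, w, rel_tol=1e-6):
            raise InvalidInputError(
                f"w_opt {self.w_opt} inconsistent with a/(a+b) = {w:.6g}"
            )


@dataclass(frozen=True)
class ExpRateLaw:
    """Exponential temperature dependence of the decay constant.

    k(T) = k0 * exp(s * T), k0 in yr-1, s in 1/degC, T in degC.
    """

    k0: float
    s: float

    def __post_init__(self):
        if self.k0 <= 0:
            raise InvalidInputError("pre-exponential constant must be > 0")

    @property
    def q10(self) -> float:
        """Implied temperature coefficient exp(10 s)."""
        return math.exp(10.0 * self.s)

    def __call__(self, t_c):
        return self.k0 * np.exp(self.s * np.asarray(t_c, dtype=float))


def temperature_factor(t_c, resp: TemperatureResponse, extrapolate: bool = False):
    """m(T) = Q10**((T - T_opt)/10) for T in [0, T_opt].

    The law is an empirical fit over 0..T_opt; temperatures above the
    optimum (where real rates fall off) are refused unless
    ``extrapolate=True``.
    """
    t = np.asarray(t_c, dtype=float)
    if np.any(t < 0):
        raise RangeError("temperature below 0 degC is outside the model range")
    if not extrapolate and np.any(t > resp.t_opt):
        raise RangeError(
            f"temperature above the optimum {resp.t_opt} degC requires extrapolate=True"
        )
    m = resp.q10 ** ((t - resp.t_opt) / 10.0)
    return float(m) if np.isscalar(t_c) else m


def moisture_factor(w_rel, resp: MoistureResponse):
    """f(W) on relative moisture W/W_s in [0, 1]; 1 at w_opt, 0 at the ends."""
    scalar = np.isscalar(w_rel) or np.asarray(w_rel).ndim == 0
    w = np.atleast_1d(np.asarray(w_rel, dtype=float))
    if np.any((w < 0) | (w > 1)):
        raise InvalidInputError("relative moisture must lie in [0, 1]")
    wm = resp.w_opt
    f = np.zeros_like(w, dtype=float)
    interior = (w > 0) & (w < 1)
    f[interior] = (w[interior] / wm) ** resp.a * ((1.0 - w[interior]) / (1.0 - wm)) ** resp.b
    return float(f[0]) if scalar else f


def combined_rate(
    t_c,
    w_rel,
    t_resp: TemperatureResponse,
    m_resp: MoistureResponse,
    u_max: float | None = None,
    extrapolate: bool = False,
):
    """U(T, W) = U_max * m(T) * f(W); maximum U_max at (t_opt, w_opt).

    ``u_max`` defaults to ``t_resp.u_max``.
    """
    umax = t_resp.u_max if u_max is None else u_max
    return umax * temperature_factor(t_c, t_resp, extrapolate) * moisture_factor(w_rel, m_resp)


# ---------------------------------------------------------------------
# fitting


class MoistureFit(NamedTuple):
    response: MoistureResponse
    r_squared: float
    s: float                       # RMS residual of normalised rates
    stderr: dict                   # parameter standard errors
    p_values: dict                 # two-sided t-test p-values
    formula: str                   # rendered model string


def _fit_statistics(resid: np.ndarray, jac: np.ndarray, theta: np.ndarray,
                    names: Sequence[str]):
    """Standard errors and significance p-values for log-parameterised fits.

    Covariance comes from the Gauss-Newton approximation in log scale;
    natural-scale standard errors follow by the delta method
    (se = exp(theta) * se_log).  The p-value tests H0: parameter = 0 with
    the natural-scale t-statistic, the convention of nonlinear-regression
    reports.
    """
    n, p = resid.size, theta.size
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * sigma2
        se_log = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_log = np.full(p, np.nan)
    natural = np.exp(theta)
    se = se_log * natural  # d exp(x) = exp(x) dx
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, natural / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return (
        {nm: float(v) for nm, v in zip(names, se)},
        {nm: float(v) for nm, v in zip(names, pvals)},
    )


def fit_moisture_response(
    w_rel: Sequence[float],
    u: Sequence[float],
    u_max_mode: str = "normalized",
) -> MoistureFit:
    """Fit U = u_max * f(W) to (relative moisture, rate) pairs.

    Optimisation runs in (log a, log b[, log u_max]) to enforce positivity.
    Initialisation is deterministic: w_opt0 from the empirical argmax,
    a0 = 2, b0 = a0 (1 - w_opt0)/w_opt0, u_max0 = max observed rate.

    Parameters
    ----------
    u_max_mode
        ``"normalized"`` (default): u_max is pinned at the empirical maximum
        and only a, b are fitted — appropriate when the data are reported as
        dimensionless rates.  ``"fit"``: u_max is co-fitted.

    Raises
    ------
    IllPosedFitError
        If all points lie on one side of the apparent maximum (a, b are
        then unidentifiable).
    """
    w = np.asarray(w_rel, dtype=float)
    y = np.asarray(u, dtype=float)
    if w.size != y.size:
        raise InvalidInputError("w and U differ in length")
    if w.size < 5:
        raise InvalidInputError("need at least 5 points to fit the moisture response")
    if np.any((w < 0) | (w > 1)):
        raise InvalidInputError("relative moisture must lie in [0, 1]")
    if u_max_mode not in ("normalized", "fit"):
        raise InvalidInputError(f"unknown u_max_mode {u_max_mode!r}")

    interior = (w > 0) & (w < 1)
    i_max = int(np.argmax(y))
    order = np.argsort(w)
    rank_of_max = int(np.where(order == i_max)[0][0])
    if rank_of_max == 0 or rank_of_max == w.size - 1:
        raise IllPosedFitError(
            "apparent maximum sits at the edge of the moisture range; "
            "both rising and falling limbs are required"
        )

    w_opt0 = float(np.clip(w[i_max], 0.05, 0.95))
    a0, umax0 = 2.0, float(y.max())
    b0 = a0 * (1.0 - w_opt0) / w_opt0

    def model(theta):
        a, b = np.exp(theta[0]), np.exp(theta[1])
        umax = np.exp(theta[2]) if u_max_mode == "fit" else umax0
        resp = MoistureResponse(a=a, b=b, u_max=max(umax, 1e-300))
        return umax * moisture_factor(w, resp)

    def resid(theta):
        return model(theta) - y

    theta0 = [math.log(a0), math.log(b0)]
    names = ["a", "b"]
    if u_max_mode == "fit":
        theta0.append(math.log(umax0))
        names.append("u_max")

    sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=20000)
    if not sol.success:
        raise FitConvergenceError("moisture-response fit did not converge", trace=sol)

    a_hat, b_hat = float(np.exp(sol.x[0])), float(np.exp(sol.x[1]))
    umax_hat = float(np.exp(sol.x[2])) if u_max_mode == "fit" else umax0
    resp = MoistureResponse(a=a_hat, b=b_hat, u_max=umax_hat)

    fitted = umax_hat * moisture_factor(w, resp)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # standard error of approximation: RMS residual of rates normalised by u_max
    s_err = float(np.sqrt(np.mean(((y - fitted) / umax_hat) ** 2)))
    stderr, pvals = _fit_statistics(sol.fun, sol.jac, sol.x, names)
    formula = (
        f"f(W) = (W/{resp.w_opt:.2f})^{a_hat:.2f}"
        f" * ((1-W)/{1 - resp.w_opt:.2f})^{b_hat:.2f};"
        f" R2 = {r2:.2f}, s = {s_err:.2f}"
    )
    return MoistureFit(resp, r2, s_err, stderr, pvals, formula)


def fit_rate_temperature(t_c: Sequence[float], k: Sequence[float]) -> tuple[ExpRateLaw, float]:
    """Fit k(T) = k0 * exp(s T) to (temperature, decay-constant) pairs.

    Returns the law and R².  Needs >= 3 distinct temperatures; initialised
    from the log-linear regression of ln k on T.
    """
    t = np.asarray(t_c, dtype=float)
    y = np.asarray(k, dtype=float)
    if np.unique(t).size < 3:
        raise InvalidInputError("need at least 3 distinct temperatures")
    if np.any(y <= 0):
        raise InvalidInputError("decay constants must be > 0 for an exponential law")
    s0, logk0 = np.polyfit(t, np.log(y), 1)
    popt, _ = curve_fit(
        lambda tt, k0, s: k0 * np.exp(s * tt), t, y,
        p0=[math.exp(logk0), s0], maxfev=20000,
    )
    law = ExpRateLaw(k0=float(popt[0]), s=float(popt[1]))
    fitted = law(t)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return law, r2


class SurfaceFit(NamedTuple):
    temperature: TemperatureResponse
    moisture: MoistureResponse
    u_max: float
    r_squared: float


def fit_response_surface(
    t_c: Sequence[float],
    w_rel: Sequence[float],
    u: Sequence[float],
    q10: float | None = 2.0,
    t_opt: float = 30.0,
) -> SurfaceFit:
    """Joint fit of U = u_max * m(T) * f(W) on a (T, W) grid.

    ``q10=None`` co-fits the temperature coefficient; otherwise it is fixed
    (default 2, the conventional average for decomposition).
    """
    t = np.asarray(t_c, dtype=float)
    w = np.asarray(w_rel, dtype=float)
    y = np.asarray(u, dtype=float)
    if not (t.size == w.size == y.size):
        raise InvalidInputError("t, w, U must have equal length")
    if t.size < 6:
        raise InvalidInputError("need at least 6 points for a surface fit")

    i_max = int(np.argmax(y))
    w_opt0 = float(np.clip(w[i_max], 0.05, 0.95))
    a0 = 2.0
    theta0 = [math.log(a0), math.log(a0 * (1 - w_opt0) / w_opt0), math.log(float(y.max()))]
    fit_q10 = q10 is None
    if fit_q10:
        theta0.append(math.log(2.0))

    def resid(theta):
        a, b, umax = np.exp(theta[:3])
        q = np.exp(theta[3]) if fit_q10 else q10
        tr = TemperatureResponse(q10=max(q, 1 + 1e-9), t_opt=t_opt, u_max=umax)
        mr = MoistureResponse(a=a, b=b, u_max=umax)
        return combined_rate(t, w, tr, mr, extrapolate=True) - y

    sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=40000)
    if not sol.success:
        raise FitConvergenceError("response-surface fit did not converge", trace=sol)
    a_hat, b_hat, umax_hat = (float(v) for v in np.exp(sol.x[:3]))
    q_hat = float(np.exp(sol.x[3])) if fit_q10 else float(q10)
    tr = TemperatureResponse(q10=q_hat, t_opt=t_opt, u_max=umax_hat)
    mr = MoistureResponse(a=a_hat, b=b_hat, u_max=umax_hat)
    fitted = combined_rate(t, w, tr, mr, extrapolate=True)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return SurfaceFit(tr, mr, umax_hat, r2)
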