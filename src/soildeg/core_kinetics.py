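"""First-order biodegradation kinetics.

The package's central model is the linear (single-pool) organic-matter
balance

    dC/dt = L - k * C,

where ``C`` is the stock of conditioner organic matter, ``L`` an input flux
and ``k`` (per year) the biodegradation constant.  With no input the stock
decays exponentially, ``C(t) = C0 * exp(-k t)``, and two characteristic
times summarise the kinetics: the half-life ``T0.5 = ln 2 / k`` and the
95%-decay time ``T0.95 ≈ 3 / k`` (3 ≈ ln 20).

This module derives ``k`` from three independent observation routes:

* closed-vial respirometry (carbon emission rate + carbon content),
* a stated fractional annual loss,
* a retained-mass (or carbon-content) time series fitted by nonlinear
  least squares.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import InvalidInputError

__all__ = [
    "YEAR_DAYS",
    "YEAR_HOURS",
    "T95_FACTOR",
    "CO2_TO_C",
    "KineticEstimate",
    "MassLossSeries",
    "StockBalance",
    "k_from_respiration",
    "k_from_co2_respiration",
    "k_from_annual_loss",
    "characteristic_times",
    "decay_curve",
    "fit_decay_constant",
    "steady_state_input",
]

#: Days per model year (fixed conversion, not a tunable).
YEAR_DAYS = 365.0
#: Hours per model year.
YEAR_HOURS = 8760.0
#: Numerator of the 95%-decay time: T0.95 = 3/k (the conventional rounding of ln 20).
T95_FACTOR = 3.0
#: Molar-mass ratio converting a CO2 flux into a carbon flux.
CO2_TO_C = 12.0 / 44.0

_SOURCES = ("respiration", "annual_loss", "series_fit")


@dataclass(frozen=True)
class KineticEstimate:
    """A first-order decay constant with its derived characteristic times.

    Parameters
    ----------
    k
        Biodegradation constant, per year.  ``k == 0`` encodes "no
        measurable decay" (characteristic times are infinite).
    t_bio
        Period of biological activity used in the derivation, days per
        year (1..365).  365 for potential (optimum-condition) rates.
    source
        Observation route: ``"respiration"``, ``"annual_loss"`` or
        ``"series_fit"``.
    r_squared
        Coefficient of determination when the estimate comes from a fit.
    """

    k: float
    t_bio: float = YEAR_DAYS
    source: str = "series_fit"
    r_squared: float | None = None

    def __post_init__(self):
        if not (self.k >= 0.0) or not math.isfinite(self.k):
            raise InvalidInputError(f"decay constant must be finite and >= 0, got {self.k}")
        if not (0.0 < self.t_bio <= YEAR_DAYS):
            raise InvalidInputError(f"t_bio must lie in (0, 365] days, got {self.t_bio}")
        if self.source not in _SOURCES:
            raise InvalidInputError(f"unknown source tag {self.source!r}")

    @property
    def t_half(self) -> float:
        """Half-life ln2/k, years (inf when k == 0)."""
        return math.log(2.0) / self.k if self.k > 0 else math.inf

    @property
    def t_95(self) -> float:
        """95%-decay time 3/k, years (inf when k == 0)."""
        return T95_FACTOR / self.k if self.k > 0 else math.inf

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "t_half": self.t_half,
                "t_95": self.t_95,
                "t_bio": self.t_bio,
                "source": self.source,
                "r_squared": self.r_squared,
            },
            sort_keys=True,
        )


@dataclass(frozen=True)
class MassLossSeries:
    """A retained-mass (D% = 100*m_t/m0) or carbon-content time series.

    ``kind="mass"`` series start at 100 (percent retained); ``kind="carbon"``
    series start at the applied dose in carbon-percent units.
    """

    times: tuple[float, ...]
    retained_percent: tuple[float, ...]
    kind: Literal["mass", "carbon"] = "mass"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.retained_percent, dtype=float)
        if t.size != y.size:
            raise InvalidInputError("times and values differ in length")
        if t.size and np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(y < 0):
            raise InvalidInputError("retained values must be non-negative")
        if self.kind == "mass" and t.size and not math.isclose(y[0], 100.0, rel_tol=1e-9):
            raise InvalidInputError(
                f"a mass series must start at 100% retained, got {y[0]}"
            )
        object.__setattr__(self, "times", tuple(float(v) for v in t))
        object.__setattr__(self, "retained_percent", tuple(float(v) for v in y))

    # -- delimited-text round trip ------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "mass") -> "MassLossSeries":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        missing = {"time_years", "value_percent"} - set(df.columns)
        if missing:
            raise InvalidInputError(f"missing columns: {sorted(missing)}")
        return cls(tuple(df["time_years"]), tuple(df["value_percent"]), kind=kind)

    def to_csv(self, path: str | Path) -> None:
        buf = io.StringIO()
        buf.write("time_years,value_percent\n")
        for t, y in zip(self.times, self.retained_percent):
            buf.write(f"{t:.10g},{y:.10g}\n")
        Path(path).write_text(buf.getvalue())


@dataclass(frozen=True)
class StockBalance:
    """A stock C and its input flux L; steady state satisfies L = k*C."""

    stock: float
    input_flux: float

    def steady_state_k(self) -> float:
        if self.stock <= 0:
            raise InvalidInputError("stock must be positive to infer k")
        return self.input_flux / self.stock


def k_from_respiration(u_carbon: float, c_percent: float, t_bio: float = YEAR_DAYS) -> KineticEstimate:
    """Biodegradation constant from a carbon emission rate.

    A respiring sample loses ``p = 24e-2 * u_carbon / c_percent`` percent of
    its organic carbon per day; compounded over ``t_bio`` active days per
    year this gives

        k = (t_bio / T0) * (ln 100 - ln(100 - p)),   T0 = 1 year.

    Parameters
    ----------
    u_carbon
        Carbon emission rate, mg C per kg dry sample per hour.  Use
        :func:`k_from_co2_respiration` for a CO2-mass flux.
    c_percent
        Organic-carbon content of the dry sample, percent (0 < C% <= 100).
    t_bio
        Period of biological activity, days per year.
    """
    if u_carbon < 0:
        raise InvalidInputError(f"emission rate must be >= 0, got {u_carbon}")
    if not (0 < c_percent <= 100):
        raise InvalidInputError(f"carbon content must be in (0, 100] %, got {c_percent}")
    p = 24e-2 * u_carbon / c_percent  # % of carbon stock lost per day
    if p >= 100:
        raise InvalidInputError(
            f"daily loss {p:.1f}% >= 100%: sample would vanish within a day"
        )
    k = t_bio * (math.log(100.0) - math.log(100.0 - p))
    return KineticEstimate(k=k, t_bio=t_bio, source="respiration")


def k_from_co2_respiration(u_co2: float, c_percent: float, t_bio: float = YEAR_DAYS) -> KineticEstimate:
    """As :func:`k_from_respiration` but for a CO2-mass flux (mg CO2 kg-1 h-1).

    Applies the 12/44 molar-mass factor to convert the CO2 flux to a carbon
    flux before the kinetic conversion.
    """
    return k_from_respiration(u_co2 * CO2_TO_C, c_percent, t_bio)


def k_from_annual_loss(loss_fraction: float) -> KineticEstimate:
    """Decay constant equivalent to losing ``loss_fraction`` of stock per year.

    Inverts C(1)/C0 = 1 - loss = exp(-k): k = -ln(1 - loss_fraction).
    """
    if not (0 <= loss_fraction < 1):
        raise InvalidInputError(
            f"annual loss fraction must be in [0, 1), got {loss_fraction}"
        )
    return KineticEstimate(k=-math.log1p(-loss_fraction), source="annual_loss")


def characteristic_times(k: float) -> tuple[float, float]:
    """Return (half-life, 95%-decay time) = (ln2/k, 3/k) in years."""
    if not (k > 0):
        raise InvalidInputError(f"decay constant must be > 0, got {k}")
    return math.log(2.0) / k, T95_FACTOR / k


def decay_curve(c0: float, k: float, t):
    """Remaining amount c0*exp(-k*t) after t years (t may be an array)."""
    if c0 < 0:
        raise InvalidInputError("initial amount must be >= 0")
    if k < 0:
        raise InvalidInputError("decay constant must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("time must be >= 0")
    out = c0 * np.exp(-k * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


class DecayFit(NamedTuple):
    estimate: KineticEstimate
    y0: float
    residuals: np.ndarray
    r_squared: float


def fit_decay_constant(
    series: MassLossSeries,
    fix_initial: bool = True,
    log_linear: bool = False,
) -> DecayFit:
    """Fit y(t) = y0 * exp(-k t) to a retained-mass/carbon series.

    The fit runs in natural scale by nonlinear least squares, matching how
    exponential regressions are conventionally reported for such series; a
    log-linear fallback (ordinary regression of ln y on t) is available via
    ``log_linear=True``.

    Parameters
    ----------
    series
        At least three strictly-increasing time points.
    fix_initial
        If True (default) the intercept y0 is pinned to the first observed
        value; otherwise y0 is co-fitted.

    Returns
    -------
    DecayFit
        The kinetic estimate (k clipped at >= 0), the intercept used,
        residuals and R².
    """
    t = np.asarray(series.times, dtype=float)
    y = np.asarray(series.retained_percent, dtype=float)
    if t.size < 3:
        raise InvalidInputError("need at least 3 time points to fit a decay constant")

    if np.all(np.diff(y) >= 0) and not np.all(y == y[0]):
        warnings.warn("series shows no net loss; k will be clipped at 0", stacklevel=2)

    if np.all(y == y[0]):
        est = KineticEstimate(k=0.0, source="series_fit", r_squared=1.0)
        return DecayFit(est, float(y[0]), np.zeros_like(y), 1.0)

    # starting value from a crude log-linear slope on positive values
    pos = y > 0
    if pos.sum() >= 2:
        slope = np.polyfit(t[pos], np.log(y[pos]), 1)[0]
        k0 = max(-slope, 1e-6)
    else:
        k0 = 0.5

    if log_linear:
        if np.any(y <= 0):
            raise InvalidInputError("log-linear fit requires strictly positive values")
        if fix_initial:
            k_hat = float(-np.sum(t * (np.log(y) - np.log(y[0]))) / np.sum(t * t))
            y0_hat = float(y[0])
        else:
            b, a = np.polyfit(t, np.log(y), 1)
            k_hat, y0_hat = float(-b), float(np.exp(a))
        k_hat = max(k_hat, 0.0)
    elif fix_initial:
        y0_hat = float(y[0])
        popt, _ = curve_fit(
            lambda tt, k: y0_hat * np.exp(-k * tt), t, y,
            p0=[k0], bounds=([0.0], [np.inf]), maxfev=10000,
        )
        k_hat = float(popt[0])
    else:
        popt, _ = curve_fit(
            lambda tt, y0, k: y0 * np.exp(-k * tt), t, y,
            p0=[y[0], k0], bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
        )
        y0_hat, k_hat = float(popt[0]), float(popt[1])

    fitted = y0_hat * np.exp(-k_hat * t)
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    est = KineticEstimate(k=k_hat, source="series_fit", r_squared=r2)
    return DecayFit(est, y0_hat, resid, r2)


def steady_state_input(k: float, stock: float) -> float:
    """Input flux L = k * stock balancing annual decomposition at steady state."""
    if k < 0:
        raise InvalidInputError("decay constant must be >= 0")
    if stock < 0:
        raise InvalidInputError("stock must be >= 0")
    return k * stock
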