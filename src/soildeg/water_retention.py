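"""Water-retention curves and capacity metrics.

Tracks how conditioner biodegradation degrades the water-holding
properties of a substrate.  Retention data — (pressure, water content)
pairs from centrifugation over 0..1000 kPa — are fitted with the van
Genuchten model in its Mualem-constrained form (m = 1 - 1/n):

    theta(psi) = theta_r + (theta_s - theta_r) / (1 + (alpha*psi)**n)**m.

Capacity metrics derived from the fitted curve: total moisture capacity
W_s = theta_s (saturation) and field capacity, the water content at a
conventional drainage potential.  No universally accepted potential
exists for field capacity; this package defaults to 33 kPa (a common
agronomic convention) and treats the threshold as fully configurable.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitConvergenceError, IllPosedFitError, InvalidInputError

__all__ = [
    "DEFAULT_FIELD_CAPACITY_PRESSURE",
    "VanGenuchtenParams",
    "RetentionDataset",
    "vg_water_content",
    "fit_wrc",
    "capacity_metrics",
]

#: Drainage potential (kPa) at which field capacity is read by default —
#: a package convention, overridable everywhere it is used.
DEFAULT_FIELD_CAPACITY_PRESSURE = 33.0


@dataclass(frozen=True)
class VanGenuchtenParams:
    """Mualem-constrained van Genuchten parameters (water content in %)."""

    theta_r: float    # residual water content, %
    theta_s: float    # saturated water content, %
    alpha: float      # inverse-pressure scale, kPa-1
    n_shape: float    # shape exponent, > 1

    def __post_init__(self):
        if not (0 <= self.theta_r < self.theta_s <= 100):
            raise InvalidInputError(
                f"need 0 <= theta_r < theta_s <= 100, got ({self.theta_r}, {self.theta_s})"
            )
        if self.alpha <= 0:
            raise InvalidInputError("alpha must be > 0")
        if self.n_shape <= 1:
            raise InvalidInputError("n must exceed 1")

    @property
    def m_shape(self) -> float:
        return 1.0 - 1.0 / self.n_shape

    def to_json(self) -> str:
        return json.dumps(
            {"theta_r": self.theta_r, "theta_s": self.theta_s,
             "alpha": self.alpha, "n_shape": self.n_shape, "m_shape": self.m_shape},
            sort_keys=True,
        )


@dataclass(frozen=True)
class RetentionDataset:
    """(pressure kPa, water content %) pairs; content should fall with pressure."""

    pressure: tuple[float, ...]
    water_content: tuple[float, ...]

    def __post_init__(self):
        p = np.asarray(self.pressure, dtype=float)
        th = np.asarray(self.water_content, dtype=float)
        if p.size != th.size:
            raise InvalidInputError("pressure and water content differ in length")
        if np.any(p < 0):
            raise InvalidInputError("pressures must be >= 0")
        order = np.argsort(p)
        # tolerate instrument noise: flag only gross non-monotonicity
        rises = np.diff(th[order])
        spread = th.max() - th.min() if th.size else 0.0
        if spread > 0 and np.any(rises > 0.25 * spread):
            warnings.warn(
                "water content rises substantially with pressure; check data",
                stacklevel=2,
            )
        object.__setattr__(self, "pressure", tuple(float(v) for v in p))
        object.__setattr__(self, "water_content", tuple(float(v) for v in th))


def vg_water_content(pressure, params: VanGenuchtenParams):
    """theta(psi); theta_s at zero pressure, theta_r in the dry limit."""
    p = np.asarray(pressure, dtype=float)
    if np.any(p < 0):
        raise InvalidInputError("pressure must be >= 0")
    theta = params.theta_r + (params.theta_s - params.theta_r) / (
        1.0 + (params.alpha * p) ** params.n_shape
    ) ** params.m_shape
    return float(theta) if np.isscalar(pressure) else theta


class WrcFit(NamedTuple):
    params: VanGenuchtenParams
    r_squared: float


def fit_wrc(data: RetentionDataset) -> WrcFit:
    """Constrained least-squares fit of the van Genuchten curve.

    Needs >= 5 pressure levels including a near-zero point (theta_s is
    initialised from the lowest-pressure observation).  A flat curve
    (range below 0.5% water content) cannot identify alpha and n and
    raises :class:`IllPosedFitError`.
    """
    p = np.asarray(data.pressure, dtype=float)
    th = np.asarray(data.water_content, dtype=float)
    if p.size < 5:
        raise InvalidInputError("need at least 5 pressure levels")
    if p.min() > 5.0:
        raise InvalidInputError("dataset must include a near-zero pressure point")
    if th.max() - th.min() < 0.5:
        raise IllPosedFitError("flat retention curve: shape parameters unidentifiable")

    order = np.argsort(p)
    p, th = p[order], th[order]
    theta_s0 = float(th[0])
    theta_r0 = max(float(th[-1]) * 0.5, 0.0)
    alpha0 = 1.0 / max(float(np.median(p[p > 0])), 1e-3)

    def model(pp, theta_r, theta_s, alpha, n):
        m = 1.0 - 1.0 / n
        return theta_r + (theta_s - theta_r) / (1.0 + (alpha * pp) ** n) ** m

    try:
        popt, _ = curve_fit(
            model, p, th,
            p0=[theta_r0, theta_s0, alpha0, 1.5],
            bounds=([0.0, 0.0, 1e-8, 1.0 + 1e-6], [100.0, 100.0, 1e3, 15.0]),
            maxfev=40000,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"WRC fit failed: {exc}") from exc
    params = VanGenuchtenParams(
        theta_r=float(popt[0]), theta_s=float(popt[1]),
        alpha=float(popt[2]), n_shape=float(popt[3]),
    )
    fitted = vg_water_content(p, params)
    ss_tot = float(np.sum((th - th.mean()) ** 2))
    r2 = 1.0 - float(np.sum((th - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return WrcFit(params, r2)


class CapacityMetrics(NamedTuple):
    total_capacity: float    # W_s = theta_s, %
    field_capacity: float    # theta at the drainage potential, %


def capacity_metrics(
    params: VanGenuchtenParams,
    field_capacity_pressure: float = DEFAULT_FIELD_CAPACITY_PRESSURE,
) -> CapacityMetrics:
    """Total moisture capacity (theta_s) and field capacity from a fitted curve."""
    if field_capacity_pressure <= 0:
        raise InvalidInputError("field-capacity pressure must be > 0")
    return CapacityMetrics(
        total_capacity=params.theta_s,
        field_capacity=vg_water_content(field_capacity_pressure, params),
    )
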