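"""Depth attenuation of biological activity and burial-depth nomographs.

Aerobic microbial activity falls off roughly exponentially with soil depth
h (cm):

    U_m(h) = U_inf + a * exp(-b h),

with an asymptotic floor U_inf, surface excess a and attenuation b (cm-1;
0.1-1 for most mineral soils).  By analogy with kinetic characteristic
times, H0.5 = ln2/b and H0.95 = 3/b bound the layer holding half, resp.
95%, of the surface-excess activity — H0.95 is a proxy for the biogenic
(humus) horizon thickness.  Burying a conditioner below the surface slows
its decay by the same exponential factor, so the depth achieving an
n-fold reduction is

    H = ln(n) / b.

Nomograph tables precompute H over ranges of b (or of H0.95, for users who
only know the biogenic-horizon thickness, via b = 3/H0.95) and a list of
reduction factors n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core_kinetics import T95_FACTOR
from .errors import FitConvergenceError, InvalidInputError

__all__ = [
    "DepthProfile",
    "NomographSpec",
    "depth_activity",
    "fit_depth_profile",
    "characteristic_depths",
    "burial_depth",
    "nomograph_table",
]


@dataclass(frozen=True)
class DepthProfile:
    """Exponential depth profile of respiration, U(h) = u_inf + amplitude*exp(-attenuation*h)."""

    u_inf: float          # asymptotic deep activity, mg kg-1 h-1
    amplitude: float      # surface excess, mg kg-1 h-1
    attenuation: float    # b, cm-1

    def __post_init__(self):
        if self.amplitude <= 0:
            raise InvalidInputError("amplitude must be > 0")
        if self.attenuation <= 0:
            raise InvalidInputError("attenuation must be > 0")
        if self.u_inf < 0:
            raise InvalidInputError("asymptotic activity must be >= 0")


def depth_activity(h, profile: DepthProfile):
    """Activity at depth h (cm): u_inf + amplitude * exp(-attenuation*h)."""
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise InvalidInputError("depth must be >= 0")
    out = profile.u_inf + profile.amplitude * np.exp(-profile.attenuation * h_arr)
    return float(out) if np.isscalar(h) else out


class DepthFit(NamedTuple):
    profile: DepthProfile
    r_squared: float
    monotone_warning: bool


def fit_depth_profile(h: Sequence[float], u_m: Sequence[float]) -> DepthFit:
    """Nonlinear least-squares fit of the exponential depth profile.

    Requires >= 4 depths spanning near-surface and deep points; the floor
    u_inf is constrained non-negative.  A profile whose observed activity
    rises with depth beyond ~2x noise is flagged (``monotone_warning``)
    but still fitted.
    """
    hh = np.asarray(h, dtype=float)
    yy = np.asarray(u_m, dtype=float)
    if hh.size != yy.size:
        raise InvalidInputError("depths and activities differ in length")
    if hh.size < 4:
        raise InvalidInputError("need at least 4 depths")
    if np.any(hh < 0):
        raise InvalidInputError("depths must be >= 0")

    order = np.argsort(hh)
    hh, yy = hh[order], yy[order]
    increase = float(np.max(np.maximum.accumulate(yy[::-1])[::-1] - yy))
    spread = float(yy.max() - yy.min())
    monotone_warning = spread > 0 and (np.diff(yy) > 0.25 * spread).any()

    u_inf0 = max(float(yy.min()), 0.0)
    a0 = max(float(yy[0] - u_inf0), 1e-6)
    # crude slope from the two shallowest distinct depths
    b0 = 0.3
    try:
        popt, _ = curve_fit(
            lambda x, u_inf, a, b: u_inf + a * np.exp(-b * x),
            hh, yy, p0=[u_inf0, a0, b0],
            bounds=([0.0, 1e-12, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - solver failure path
        raise FitConvergenceError(f"depth-profile fit failed: {exc}") from exc
    profile = DepthProfile(u_inf=float(popt[0]), amplitude=float(popt[1]),
                           attenuation=float(popt[2]))
    fitted = depth_activity(hh, profile)
    ss_tot = float(np.sum((yy - yy.mean()) ** 2))
    r2 = 1.0 - float(np.sum((yy - fitted) ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return DepthFit(profile, r2, bool(monotone_warning))


def characteristic_depths(attenuation: float) -> tuple[float, float]:
    """(H0.5, H0.95) = (ln2/b, 3/b) in cm."""
    if not (attenuation > 0):
        raise InvalidInputError(f"attenuation must be > 0, got {attenuation}")
    return math.log(2.0) / attenuation, T95_FACTOR / attenuation


def burial_depth(
    n: float,
    attenuation: float | None = None,
    active_layer: float | None = None,
    profile: DepthProfile | None = None,
) -> float:
    """Depth H (cm) reducing biodegradation n-fold relative to the surface.

    Pure-exponential attenuation gives H = ln(n)/b.  Supply exactly one of

    * ``attenuation``: b directly, cm-1;
    * ``active_layer``: the biogenic-horizon thickness H0.95, converted by
      b = 3/H0.95;
    * ``profile``: a floor-aware variant solving
      u_inf + a*exp(-b H) = (u_inf + a)/n — with a nonzero floor an n-fold
      total reduction may be unattainable at any depth, which raises.
    """
    if n < 1:
        raise InvalidInputError(f"reduction factor must be >= 1, got {n}")
    supplied = sum(x is not None for x in (attenuation, active_layer, profile))
    if supplied != 1:
        raise InvalidInputError(
            "supply exactly one of attenuation, active_layer, profile"
        )
    if profile is not None:
        target = (profile.u_inf + profile.amplitude) / n
        excess = target - profile.u_inf
        if excess <= 0:
            raise InvalidInputError(
                f"an {n}-fold reduction is unattainable: the deep floor "
                f"{profile.u_inf} already exceeds the target {target:.4g}"
            )
        return math.log(profile.amplitude / excess) / profile.attenuation
    if active_layer is not None:
        if active_layer <= 0:
            raise InvalidInputError("active layer thickness must be > 0")
        attenuation = T95_FACTOR / active_layer
    if attenuation <= 0:
        raise InvalidInputError("attenuation must be > 0")
    return math.log(n) / attenuation


#: Reduction-factor curves drawn on the standard nomograph.
DEFAULT_REDUCTION_FACTORS = (2.0, 3.0, 4.0, 6.0, 8.0, 16.0, 32.0)


@dataclass(frozen=True)
class NomographSpec:
    """Layout of a burial-depth nomograph table.

    ``mode="attenuation"`` sweeps b over ``x_range`` (default 0.1-1 cm-1,
    the span typical of mineral soils); ``mode="active-layer"`` sweeps
    H0.95 (default 6-30 cm, the usual biogenic-horizon range).
    """

    mode: Literal["attenuation", "active-layer"] = "attenuation"
    x_range: tuple[float, float] | None = None
    n_points: int = 50
    reduction_factors: tuple[float, ...] = DEFAULT_REDUCTION_FACTORS

    def __post_init__(self):
        if self.mode not in ("attenuation", "active-layer"):
            raise InvalidInputError(f"unknown nomograph mode {self.mode!r}")
        if self.x_range is None:
            default = (0.1, 1.0) if self.mode == "attenuation" else (6.0, 30.0)
            object.__setattr__(self, "x_range", default)
        lo, hi = self.x_range
        if not (0 < lo < hi):
            raise InvalidInputError("x_range must be positive and increasing")
        if self.n_points < 2:
            raise InvalidInputError("need at least 2 grid points")
        if not self.reduction_factors:
            raise InvalidInputError("reduction factor list must not be empty")
        if any(n <= 1 for n in self.reduction_factors):
            raise InvalidInputError("all reduction factors must exceed 1")


def nomograph_table(spec: NomographSpec) -> pd.DataFrame:
    """Burial depths H over the spec's grid, one column per reduction factor.

    Values are analytic (H = ln(n)/b), so the table carries no
    interpolation error; every cell satisfies exp(b*H) = n exactly.
    """
    lo, hi = spec.x_range
    x = np.linspace(lo, hi, spec.n_points)
    if spec.mode == "attenuation":
        b = x
        index_name = "b_per_cm"
    else:
        b = T95_FACTOR / x
        index_name = "h95_cm"
    data = {f"n={n:g}": np.log(n) / b for n in spec.reduction_factors}
    df = pd.DataFrame(data, index=pd.Index(x, name=index_name))
    return df
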