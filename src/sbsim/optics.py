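"""Refraction arithmetic, per-bandwidth statistics and the tightening power law.

The eye is treated as a reduced optical system: the induced myopic change of
a case is computed from its pre- and post-operative axial lengths as

    dD = -n1 (1/AL_pre - 1/AL_pos)    [AL in metres]

with ``n1 = 1.336`` the aqueous refractive index, so axial elongation gives a
negative (myopic) shift.  The thick-lens system power
``D0 = D1 + D2 - D1 D2 d / n1`` is also available when corneal and lens
powers are supplied.  The myopia-versus-tightening trend is summarised by a
power law ``dD(x) = a x^b + c`` fitted by nonlinear least squares, where
``x`` is the tightening percentage.

Diopter values are kept at full precision internally; :func:`round_reported`
(half away from zero) is applied only when printing/reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "OpticsConfig",
    "RefractionResult",
    "TighteningFit",
    "FitError",
    "round_reported",
    "eye_power",
    "myopic_change",
    "summarize_by_bandwidth",
    "fit_power_law",
    "evaluate_fit",
    "relative_increment",
    "load_reference_cases",
]


def load_reference_cases() -> "pd.DataFrame":
    """Bundled nine-case reference table (band width x IOP study).

    Columns: case id, IOP (mmHg), band width (mm), pre/post axial lengths
    (mm), axial elongation, and the induced myopia at the three tightening
    levels.  The full-tightening myopia is reproducible from the axial
    lengths via :func:`myopic_change`.
    """
    from importlib.resources import files

    with files("sbsim.data").joinpath("reference_cases.csv").open() as fh:
        return pd.read_csv(fh)


class FitError(RuntimeError):
    """Raised when the power-law fit cannot be determined from the data."""


@dataclass(frozen=True)
class OpticsConfig:
    """Optical constants: refractive index and (optional) component powers.

    ``D1``/``D2`` are corneal and lens powers in diopters, ``d`` the distance
    from corneal apex to mid-lens in mm.  ``D1`` may be derived from the
    anterior apical radius R (mm) as (n1 - 1)/R with R in metres.
    """

    n1: float = 1.336
    D1: float | None = None
    D2: float | None = None
    d: float | None = None

    def __post_init__(self) -> None:
        if not self.n1 > 1.0:
            raise ValueError("refractive index must exceed 1")


@dataclass(frozen=True)
class RefractionResult:
    D0: float
    D0f: float
    delta_D: float


@dataclass(frozen=True)
class TighteningFit:
    """Coefficients of dD(x) = a x^b + c with x the tightening percent."""

    a: float
    b: float
    c: float
    rmse: float


def round_reported(value: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention used for reported diopters."""
    scale = 10.0**decimals
    return math.copysign(math.floor(abs(value) * scale + 0.5), value) / scale


def eye_power(cfg: OpticsConfig) -> float:
    """Thick-lens system power D0 = D1 + D2 - D1 D2 d / n1 (d in mm)."""
    if cfg.D1 is None or cfg.D2 is None or cfg.d is None:
        raise ValueError("eye_power requires D1, D2 and d")
    return cfg.D1 + cfg.D2 - cfg.D1 * cfg.D2 * (cfg.d / 1000.0) / cfg.n1


def myopic_change(AL_pre: float, AL_pos: float, n1: float = 1.336) -> float:
    """Induced myopic change (D) from axial lengths in mm; negative = myopic."""
    if AL_pre <= 0.0 or AL_pos <= 0.0:
        raise ValueError("axial lengths must be positive")
    return -n1 * (1000.0 / AL_pre - 1000.0 / AL_pos)


def summarize_by_bandwidth(cases: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD (n-1 denominator) of dAL and dD per bandwidth.

    Expects columns ``bandwidth_mm`` and any of ``dAL_mm`` / ``dD_D``;
    returns one row per bandwidth (descending width, the case-table order).
    """
    cols = [c for c in ("dAL_mm", "dD_D") if c in cases.columns]
    if not cols:
        raise ValueError("no dAL_mm or dD_D column to summarise")
    g = cases.groupby("bandwidth_mm")[cols]
    out = pd.concat({"mean": g.mean(), "sd": g.std(ddof=1)}, axis=1)
    out.columns = [f"{stat}_{col}" for stat, col in out.columns]
    return out.sort_index(ascending=False)


#: fitted tightening-curve coefficient sets accompanying the bundled
#: nine-case reference table, keyed by band width (mm)
REFERENCE_TIGHTENING_FITS: dict[float, TighteningFit] = {
    1.0: TighteningFit(a=-4.80e-11, b=4.899, c=-0.1387, rmse=0.0),
    2.0: TighteningFit(a=-1.12e-6, b=2.901, c=-0.1716, rmse=0.0),
    2.5: TighteningFit(a=-1.051e-6, b=2.96, c=-0.1972, rmse=0.0),
}


def _power(x, a, b, c):
    return a * np.power(x, b) + c


def fit_power_law(x, dD) -> TighteningFit:
    """Nonlinear least-squares fit of dD(x) = a x^b + c.

    Deterministic initialisation: b0 = 3, c0 = dD at the smallest x, a0 from
    the largest-x point; bounds a <= 0, 0 < b <= 10.
    """
    x = np.asarray(x, float)
    dD = np.asarray(dD, float)
    if x.size < 3 or np.unique(x).size < 3:
        raise FitError("need at least 3 distinct tightening levels for a 3-parameter fit")
    if np.ptp(dD) == 0.0:
        raise FitError("degenerate (constant) myopia data")
    order = np.argsort(x)
    x, dD = x[order], dD[order]
    c0 = dD[0]
    a0 = (dD[-1] - c0) / x[-1] ** 3.0
    if not a0 < 0.0:
        a0 = -1e-9
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-residual fits have no covariance
            popt, _ = curve_fit(
                _power,
                x,
                dD,
                p0=(a0, 3.0, c0),
                bounds=([-np.inf, 1e-9, -np.inf], [0.0, 10.0, np.inf]),
                maxfev=20000,
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"power-law fit failed: {exc}") from exc
    if not np.all(np.isfinite(popt)):
        raise FitError("power-law fit did not produce finite coefficients")
    resid = _power(x, *popt) - dD
    return TighteningFit(float(popt[0]), float(popt[1]), float(popt[2]), float(np.sqrt(np.mean(resid**2))))


def evaluate_fit(fit: TighteningFit, x: float) -> float:
    """Evaluate a x^b + c at tightening percent x."""
    return fit.a * x**fit.b + fit.c


def relative_increment(dD_100: float, dD_125: float) -> float:
    """Percent growth of |dD| from 100% to 125% tightening."""
    if dD_100 == 0.0:
        raise ValueError("reference myopic change is zero")
    return 100.0 * (abs(dD_125) - abs(dD_100)) / abs(dD_100)
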