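"""Sensor constitutive law: stress-strain calibration and its inversion.

Polyacrylamide microbeads are calibrated by osmotic compression: dextran at
known concentration applies a known isotropic pressure P (kPa) and the bead
volumetric strain s = |V(P)-V0|/V0 is measured.  Below ~15% compression the
response is linear with bulk modulus K (P = K*s); beyond it the empirical
curve stiffens and is captured by a zero-intercept monotone polynomial

    P(s) = K*s + c2*s^2 + ... + cd*s^d

whose linear coefficient is tied to the independently fitted K.  Inversion
(strain -> pressure and back) is restricted to the calibrated strain range;
no silent extrapolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import NonMonotoneFitError, OutOfRangeError

__all__ = [
    "ConstitutiveFit",
    "fit_constitutive",
    "pressure_to_strain",
    "strain_to_pressure",
    "linear_fit",
    "PAA_5_0225",
]

_ROOT_TOL = 1e-12
_RANGE_RTOL = 1e-9


@dataclass(frozen=True)
class ConstitutiveFit:
    """A bead sensor's calibrated stress-strain law.

    Attributes
    ----------
    bulk_modulus : float
        K in kPa, the slope at the origin of P(s) (linear-regime fit).
    bulk_modulus_se : float
        Standard error of K, kPa.
    poly_coeffs : tuple of float
        (c1, c2, ..., cd) of P(s) = sum_k c_k s^k, with c1 == K and no
        intercept (P(0) = 0 by construction).
    strain_range : tuple of float
        (0, s_max): the strain interval over which the law is calibrated
        and invertible.
    linear_limit : float
        Upper strain bound of the linear regime used for the K fit.
    """

    bulk_modulus: float
    bulk_modulus_se: float = 0.0
    poly_coeffs: tuple[float, ...] = field(default=())
    strain_range: tuple[float, float] = (0.0, 0.15)
    linear_limit: float = 0.15

    def __post_init__(self) -> None:
        if self.bulk_modulus <= 0:
            raise ValueError("bulk modulus must be positive")
        if not self.poly_coeffs:
            object.__setattr__(self, "poly_coeffs", (self.bulk_modulus,))
        if abs(self.poly_coeffs[0] - self.bulk_modulus) > 1e-9 * self.bulk_modulus:
            raise ValueError("first polynomial coefficient must equal the bulk modulus")
        _check_monotone(np.asarray(self.poly_coeffs), self.strain_range[1])

    @property
    def s_max(self) -> float:
        return self.strain_range[1]

    @property
    def p_max(self) -> float:
        """Largest calibrated pressure, P(s_max), kPa."""
        return _poly_eval(np.asarray(self.poly_coeffs), self.s_max)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "bulk_modulus_kPa": self.bulk_modulus,
            "bulk_modulus_se_kPa": self.bulk_modulus_se,
            "poly_coeffs": list(self.poly_coeffs),
            "strain_range": list(self.strain_range),
            "linear_limit": self.linear_limit,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ConstitutiveFit":
        d = json.loads(Path(path).read_text())
        return cls(
            bulk_modulus=d["bulk_modulus_kPa"],
            bulk_modulus_se=d["bulk_modulus_se_kPa"],
            poly_coeffs=tuple(d["poly_coeffs"]),
            strain_range=tuple(d["strain_range"]),
            linear_limit=d["linear_limit"],
        )


def _poly_eval(coeffs: np.ndarray, s) -> np.ndarray | float:
    """Evaluate P(s) = sum_k coeffs[k-1] * s^k (zero intercept)."""
    return np.polyval(np.concatenate([coeffs[::-1], [0.0]]), s)


def _check_monotone(coeffs: np.ndarray, s_max: float, n_grid: int = 2001) -> None:
    grid = np.linspace(0.0, s_max, n_grid)
    deriv_coeffs = coeffs * np.arange(1, coeffs.size + 1)
    deriv = np.polyval(deriv_coeffs[::-1], grid)
    if np.any(deriv <= 0):
        raise NonMonotoneFitError(
            f"P(s) is not strictly increasing on [0, {s_max:g}]"
        )


def linear_fit(pressure: np.ndarray, strain: np.ndarray) -> tuple[float, float]:
    """Zero-intercept least-squares slope of P versus s, with standard error."""
    s = np.asarray(strain, dtype=float)
    p = np.asarray(pressure, dtype=float)
    ss = float(np.sum(s * s))
    if ss == 0:
        raise ValueError("all strains are zero; slope undefined")
    k = float(np.sum(s * p) / ss)
    resid = p - k * s
    dof = max(s.size - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / ss))
    return k, se


def fit_constitutive(
    data: pd.DataFrame,
    degree: int = 3,
    linear_limit: float = 0.15,
) -> ConstitutiveFit:
    """Fit the sensor law from an osmotic-compression table.

    Parameters
    ----------
    data : DataFrame with columns ``pressure_kPa`` and ``strain``.
    degree : polynomial degree of the full-range law (>= 1).
    linear_limit : strain cut below which points define the bulk modulus.

    The bulk modulus K is the zero-intercept slope of P on s restricted to
    s <= linear_limit; the full-range polynomial is then least-squares
    fitted with its linear coefficient constrained to K.  The fitted law is
    verified to be strictly increasing over the observed strain range.
    """
    p = np.asarray(data["pressure_kPa"], dtype=float)
    s = np.asarray(data["strain"], dtype=float)
    if np.any(s < 0) or np.any(p < 0):
        raise ValueError("pressures and strains must be non-negative")
    lin = s <= linear_limit
    if np.count_nonzero(s[lin] > 0) < 2:
        raise ValueError(
            f"need >= 2 non-zero strain points below linear_limit={linear_limit}"
        )
    k, k_se = linear_fit(p[lin], s[lin])

    if degree < 1:
        raise ValueError("degree must be >= 1")
    if p.size < degree + 1:
        raise ValueError(f"need >= {degree + 1} points for a degree-{degree} fit")
    if degree == 1:
        coeffs = np.array([k])
    else:
        # residual pressure after the constrained linear term
        design = np.vstack([s**m for m in range(2, degree + 1)]).T
        target = p - k * s
        higher, *_ = np.linalg.lstsq(design, target, rcond=None)
        coeffs = np.concatenate([[k], higher])

    s_max = float(np.max(s))
    if s_max <= 0:
        raise ValueError("all strains are zero; no calibrated range")
    _check_monotone(coeffs, s_max)
    return ConstitutiveFit(
        bulk_modulus=k,
        bulk_modulus_se=k_se,
        poly_coeffs=tuple(float(c) for c in coeffs),
        strain_range=(0.0, s_max),
        linear_limit=linear_limit,
    )


def strain_to_pressure(fit: ConstitutiveFit, strain) -> np.ndarray | float:
    """Local pressure (kPa) at a measured volumetric strain.

    Errors on strains outside the calibrated range rather than
    extrapolating the polynomial.
    """
    s = np.asarray(strain, dtype=float)
    if np.any(s < 0) or np.any(s > fit.s_max * (1 + _RANGE_RTOL)):
        raise OutOfRangeError(
            f"strain outside calibrated range [0, {fit.s_max:g}]"
        )
    out = _poly_eval(np.asarray(fit.poly_coeffs), np.minimum(s, fit.s_max))
    return float(out) if np.isscalar(strain) else np.asarray(out)


def pressure_to_strain(fit: ConstitutiveFit, pressure) -> np.ndarray | float:
    """Invert the calibrated law: the unique strain with P(s) = pressure.

    Bracketing root-finding on [0, s_max]; monotonicity of the fitted
    polynomial guarantees uniqueness.
    """
    p_arr = np.atleast_1d(np.asarray(pressure, dtype=float))
    p_max = fit.p_max
    if np.any(p_arr < 0) or np.any(p_arr > p_max * (1 + _RANGE_RTOL)):
        raise OutOfRangeError(
            f"pressure outside calibrated range [0, {p_max:g}] kPa"
        )
    coeffs = np.asarray(fit.poly_coeffs)
    out = np.empty_like(p_arr)
    for i, p in enumerate(p_arr):
        p = min(p, p_max)
        if p == 0:
            out[i] = 0.0
        else:
            out[i] = brentq(
                lambda s: _poly_eval(coeffs, s) - p, 0.0, fit.s_max, xtol=_ROOT_TOL
            )
    return float(out[0]) if np.isscalar(pressure) else out


#: Convenience preset for the 5/0.225 acrylamide/bisacrylamide bead batch:
#: published bulk modulus 15 +/- 0.4 kPa, used here as a purely linear law
#: over strains up to 0.4.
PAA_5_0225 = ConstitutiveFit(
    bulk_modulus=15.0,
    bulk_modulus_se=0.4,
    poly_coeffs=(15.0,),
    strain_range=(0.0, 0.4),
    linear_limit=0.15,
)
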