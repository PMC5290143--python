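"""Radial profiles of strain and pressure, and the power-law fit.

Bead observations that pass QC are binned along the normalized radius
(fixed-width or equal-count bins); each reported bin carries the mean
position, mean value, s.e.m. (sample sd over sqrt(n); flagged rather than
fabricated for single-point bins) and count.  Strains convert to pressures
per observation *before* re-binning, because the constitutive curve is
nonlinear.  The stress power law sigma = P1 * r^beta is fitted by weighted
least squares of log(P) on log(r) with bin counts as weights; core bins can
be excluded explicitly (mirroring the omitted near-centre point in the
original analysis) but never automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import ConstitutiveFit, strain_to_pressure

__all__ = [
    "RadialProfile",
    "PowerLawFit",
    "bin_radial",
    "strain_profile_to_pressure",
    "fit_power_law",
    "linear_trend",
]


@dataclass
class RadialProfile:
    """Binned radial profile of a per-bead quantity.

    ``bins`` has columns r_norm (mean position), value (mean), sem (NaN
    when n == 1), n.  The raw per-observation points are retained so a
    nonlinear conversion can re-bin from scratch.
    """

    bins: pd.DataFrame
    kind: str  # "strain" or "pressure_kPa"
    scheme: str
    n_bins: int
    observations: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of P = amplitude * r^beta on binned pressures (log-log WLS)."""

    amplitude: float  # stress at r_norm = 1, kPa
    beta: float
    beta_se: float
    excluded_bins: tuple[int, ...]
    residual_norm: float
    n_bins_used: int


def _bin_edges(r: np.ndarray, scheme: str, n_bins: int) -> np.ndarray:
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if scheme == "fixed_width":
        return np.linspace(r.min(), r.max(), n_bins + 1)
    if scheme == "equal_count":
        return np.quantile(r, np.linspace(0, 1, n_bins + 1))
    raise ValueError(f"unknown binning scheme {scheme!r}")


def bin_radial(
    values: pd.DataFrame, scheme: str = "equal_count", n_bins: int = 7,
    kind: str = "strain",
) -> RadialProfile:
    """Group (r_norm, value) points into radial bins.

    ``values`` needs columns r_norm and value.  Empty bins are omitted;
    the rightmost edge is inclusive.
    """
    df = values[["r_norm", "value"]].dropna()
    if df.empty:
        raise ValueError("no observations to bin")
    r = df["r_norm"].to_numpy(dtype=float)
    v = df["value"].to_numpy(dtype=float)
    edges = _bin_edges(r, scheme, n_bins)
    idx = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        sem = float(np.std(v[sel], ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
        rows.append(
            {
                "bin": b,
                "r_norm": float(r[sel].mean()),
                "value": float(v[sel].mean()),
                "sem": sem,
                "n": n,
            }
        )
    return RadialProfile(
        bins=pd.DataFrame(rows),
        kind=kind,
        scheme=scheme,
        n_bins=n_bins,
        observations=df.reset_index(drop=True),
    )


def strain_profile_to_pressure(
    profile: RadialProfile, fit: ConstitutiveFit
) -> RadialProfile:
    """Convert a strain profile to a pressure profile (kPa).

    Each raw observation is converted through the calibrated law first and
    the converted points are re-binned with the same scheme; averaging
    before conversion would bias the means wherever the law is nonlinear.
    Out-of-range strains raise, reporting the offending observations.
    """
    if profile.kind != "strain":
        raise ValueError("input profile must hold strains")
    obs = profile.observations.copy()
    s_max = fit.strain_range[1]
    bad = obs.index[(obs["value"] < 0) | (obs["value"] > s_max)]
    if len(bad) > 0:
        raise ValueError(
            f"{len(bad)} strain(s) outside calibrated range [0, {s_max:g}]: "
            f"rows {list(bad[:10])}"
        )
    obs["value"] = [strain_to_pressure(fit, s) for s in obs["value"]]
    return bin_radial(obs, profile.scheme, profile.n_bins, kind="pressure_kPa")


def fit_power_law(
    profile: RadialProfile, exclude: tuple[int, ...] = ()
) -> PowerLawFit:
    """Weighted log-log fit of P = amplitude * r^beta on binned pressures.

    Weights are bin counts; ``exclude`` removes bins by their index in
    ``profile.bins`` (explicit user choice, e.g. a contaminated core bin).
    Requires >= 3 included bins with positive mean pressure and position.
    """
    bins = profile.bins.drop(index=list(exclude), errors="raise")
    if len(bins) < 3:
        raise ValueError("need >= 3 included bins for a power-law fit")
    r = bins["r_norm"].to_numpy(dtype=float)
    p = bins["value"].to_numpy(dtype=float)
    w = bins["n"].to_numpy(dtype=float)
    if np.any(p <= 0) or np.any(r <= 0):
        raise ValueError("power-law fit needs positive bin pressures and radii")
    x, y = np.log(r), np.log(p)
    sw = np.sqrt(w)
    design = np.column_stack([sw, sw * x])
    coef, *_ = np.linalg.lstsq(design, sw * y, rcond=None)
    intercept, slope = coef
    resid = sw * y - design @ coef
    dof = len(bins) - 2
    if dof > 0:
        s2 = float(resid @ resid) / dof
        sxx = float(np.sum(w * (x - np.average(x, weights=w)) ** 2))
        slope_se = float(np.sqrt(s2 / sxx)) if sxx > 0 else np.nan
    else:
        slope_se = np.nan
    return PowerLawFit(
        amplitude=float(np.exp(intercept)),
        beta=float(slope),
        beta_se=slope_se,
        excluded_bins=tuple(exclude),
        residual_norm=float(np.linalg.norm(resid)),
        n_bins_used=len(bins),
    )


def linear_trend(values: pd.DataFrame) -> dict:
    """OLS trend of raw (unbinned) strain against r_norm.

    Returns slope, its standard error, intercept and the one-sided p-value
    that the slope is negative (strain increasing toward the core).
    """
    r = values["r_norm"].to_numpy(dtype=float)
    v = values["value"].to_numpy(dtype=float)
    if r.size < 3:
        raise ValueError("need >= 3 points for a trend")
    if np.ptp(r) == 0:
        raise ValueError("degenerate radial spread")
    res = stats.linregress(r, v)
    if res.stderr and res.stderr > 0:
        p_neg = float(stats.t.cdf(res.slope / res.stderr, df=r.size - 2))
    else:
        p_neg = np.nan
    return {
        "slope": float(res.slope),
        "slope_se": float(res.stderr),
        "intercept": float(res.intercept),
        "p_slope_negative": p_neg,
    }
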