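"""End-to-end orchestration: scene -> observations -> profiles -> model fit.

`run_full_pipeline` takes a scene (in-memory `ScenePair` or a directory in
the same layout), segments every bead before/after pair, computes strains
and radial positions, applies QC, converts strains to pressures through a
calibrated constitutive law, bins the radial profiles, fits the stress
power law and inverts it into a cell stiffness ratio.  Failures on single
beads mark those beads rejected instead of aborting the run.  `report`
writes the result as JSON, CSV tables and figures with fixed filenames.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ConstitutiveFit
from .errors import NoBeadsError
from .imaging import (
    QC_SEGMENTATION,
    BeadObservation,
    Rect,
    SpheroidGeometry,
    auto_roi,
    bead_radial_position,
    bead_strain_from_areas,
    isodata_threshold,
    qc_filter,
    segment_bead,
    spheroid_geometry,
)
from .mechanics import stiffness_ratio_from_beta
from .profile import (
    PowerLawFit,
    RadialProfile,
    bin_radial,
    fit_power_law,
    linear_trend,
    strain_profile_to_pressure,
)
from .synthetic import ScenePair, load_scene

__all__ = ["PipelineOptions", "PipelineResult", "measure_scene", "run_full_pipeline", "report"]

log = logging.getLogger("beadstress.pipeline")


@dataclass(frozen=True)
class PipelineOptions:
    """Tunable stages of the full analysis.

    ``roi_halfwidth_px`` switches from automatic blob-derived ROIs to
    fixed squares centred on the metadata bead position.
    """

    n_bins: int = 7
    scheme: str = "equal_count"
    exclude_bins: tuple[int, ...] = ()
    surface_margin: float = 10.0  # um
    ellipticity_max: float = 1.15
    roi_halfwidth_px: int | None = None


@dataclass
class PipelineResult:
    observations: pd.DataFrame
    strain_profile: RadialProfile | None
    pressure_profile: RadialProfile | None
    power_law: PowerLawFit | None
    stiffness_ratio: float | None
    strain_trend: dict | None
    qc_summary: dict
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _measure_one_bead(
    sid: str,
    bid: str,
    before: np.ndarray,
    after: np.ndarray,
    meta: pd.Series,
    geom: SpheroidGeometry,
    options: PipelineOptions,
    pixel_size: float,
) -> BeadObservation:
    if options.roi_halfwidth_px is not None:
        hw = options.roi_halfwidth_px
        x, y = int(round(meta["x_px"])), int(round(meta["y_px"]))
        roi_b = roi_a = Rect(x - hw, y - hw, x + hw + 1, y + hw + 1)
    else:
        roi_b, roi_a = auto_roi(before), auto_roi(after)
    area_b_px, centroid_b, ell_b = segment_bead(
        before, roi_b, isodata_threshold(before, roi_b)
    )
    area_a_px, _, _ = segment_bead(after, roi_a, isodata_threshold(after, roi_a))
    a0 = area_b_px * pixel_size**2
    a1 = area_a_px * pixel_size**2
    v0, v1, strain = bead_strain_from_areas(a0, a1)
    center = (
        centroid_b[0] * pixel_size,
        centroid_b[1] * pixel_size,
        float(meta["z_um"]),
    )
    obs = BeadObservation(
        spheroid_id=sid,
        bead_id=bid,
        area_before=a0,
        area_after=a1,
        volume_before=v0,
        volume_after=v1,
        strain=strain,
        center=center,
        ellipticity=ell_b,
    )
    obs.r_norm = bead_radial_position(center, geom)
    return obs


def measure_scene(
    scene: ScenePair, options: PipelineOptions = PipelineOptions()
) -> tuple[list[BeadObservation], list[BeadObservation], dict[str, SpheroidGeometry]]:
    """Segment every bead in a scene and apply QC.

    Returns (kept, rejected, spheroid geometries); beads whose
    segmentation fails are rejected with reason ``segmentation_failed``.
    """
    sph_z = dict(zip(scene.spheroids["spheroid_id"], scene.spheroids["z_um"]))
    geoms = {
        sid: spheroid_geometry(mask, scene.pixel_size, z=sph_z.get(sid, 0.0))
        for sid, mask in scene.contours.items()
    }
    kept_all: list[BeadObservation] = []
    rejected_all: list[BeadObservation] = []
    for _, meta in scene.metadata.iterrows():
        sid, bid = meta["spheroid_id"], meta["bead_id"]
        before, after = scene.images[(sid, bid)]
        geom = geoms[sid]
        try:
            obs = _measure_one_bead(
                sid, bid, before, after, meta, geom, options, scene.pixel_size
            )
        except Exception as exc:  # one bad bead never aborts the run
            log.debug("bead %s/%s failed segmentation: %s", sid, bid, exc)
            rejected_all.append(
                BeadObservation(
                    spheroid_id=sid, bead_id=bid,
                    area_before=np.nan, area_after=np.nan,
                    volume_before=np.nan, volume_after=np.nan,
                    strain=np.nan, center=(np.nan, np.nan, np.nan),
                    ellipticity=np.nan, qc=QC_SEGMENTATION,
                )
            )
            continue
        kept, rejected = qc_filter(
            [obs], geom, margin=options.surface_margin,
            ellipticity_max=options.ellipticity_max,
        )
        kept_all.extend(kept)
        rejected_all.extend(rejected)
    return kept_all, rejected_all, geoms


def _observations_frame(observations: list[BeadObservation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        d = asdict(o)
        x, y, z = d.pop("center")
        d.update(x_um=x, y_um=y, z_um=z)
        rows.append(d)
    return pd.DataFrame(rows)


def run_full_pipeline(
    scene: ScenePair | str | Path,
    constitutive: ConstitutiveFit,
    options: PipelineOptions = PipelineOptions(),
    seed: int | None = None,
) -> PipelineResult:
    """Full analysis of one scene: observations, profiles, power-law fit.

    Deterministic given its inputs (no stage is stochastic); ``seed`` is
    recorded in provenance for scenes that were generated from one.
    """
    if not isinstance(scene, ScenePair):
        scene = load_scene(scene)
    if scene.metadata.empty:
        raise NoBeadsError("scene contains no beads")
    kept, rejected, _ = measure_scene(scene, options)
    if not kept:
        raise NoBeadsError("no bead passed quality control")

    obs_df = _observations_frame(kept + rejected)
    qc_counts = obs_df["qc"].value_counts().to_dict()
    warnings: list[str] = []

    strain_points = pd.DataFrame(
        {"r_norm": [o.r_norm for o in kept], "value": [o.strain for o in kept]}
    )
    strain_prof = bin_radial(
        strain_points, scheme=options.scheme, n_bins=options.n_bins, kind="strain"
    )
    trend = linear_trend(strain_points) if len(strain_points) >= 3 else None

    pressure_prof: RadialProfile | None = None
    power_law: PowerLawFit | None = None
    rho_hat: float | None = None
    try:
        pressure_prof = strain_profile_to_pressure(strain_prof, constitutive)
        power_law = fit_power_law(pressure_prof, exclude=options.exclude_bins)
        rho_hat = stiffness_ratio_from_beta(power_law.beta)
    except Exception as exc:
        warnings.append(f"power-law stage skipped: {exc}")
        log.warning("power-law stage skipped: %s", exc)

    from . import __version__ as pkg_version

    prov = {
        "package_version": pkg_version,
        "seed": seed,
        "options": asdict(options),
        "calibration": {
            "bulk_modulus_kPa": constitutive.bulk_modulus,
            "poly_coeffs": list(constitutive.poly_coeffs),
            "strain_range": list(constitutive.strain_range),
        },
    }
    prov["config_hash"] = hashlib.sha256(
        json.dumps(prov, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    return PipelineResult(
        observations=obs_df,
        strain_profile=strain_prof,
        pressure_profile=pressure_prof,
        power_law=power_law,
        stiffness_ratio=rho_hat,
        strain_trend=trend,
        qc_summary={"kept": len(kept), "rejected": len(rejected), "by_reason": qc_counts},
        warnings=warnings,
        provenance=prov,
    )


def _result_json(result: PipelineResult) -> dict:
    return {
        "power_law": asdict(result.power_law) if result.power_law else None,
        "anisotropy_ratio": result.stiffness_ratio,
        "strain_trend": result.strain_trend,
        "qc_summary": result.qc_summary,
        "warnings": result.warnings,
        "provenance": result.provenance,
    }


def report(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write JSON, CSV tables and figures for a pipeline result.

    Fixed filenames; JSON is byte-identical across reruns on the same
    inputs (no timestamps).  Empty profiles produce a report with an
    explicit warning rather than an error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "result.json").write_text(
        json.dumps(_result_json(result), indent=2, sort_keys=True, default=float) + "\n"
    )
    result.observations.to_csv(out / "observations.csv", index=False)
    if result.strain_profile is not None:
        result.strain_profile.bins.to_csv(out / "strain_profile.csv", index=False)
    if result.pressure_profile is not None:
        result.pressure_profile.bins.to_csv(out / "pressure_profile.csv", index=False)
    _plot_report(result, out)
    return out


def _plot_report(result: PipelineResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    if result.strain_profile is not None and not result.strain_profile.bins.empty:
        b = result.strain_profile.bins
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.errorbar(b["r_norm"], b["value"], yerr=b["sem"], fmt="o", capsize=3)
        ax.set_xlabel("r / R0")
        ax.set_ylabel("volumetric strain |V-V0|/V0")
        fig.tight_layout()
        fig.savefig(out / "strain_profile.png", dpi=150)
        plt.close(fig)
    if result.pressure_profile is not None and not result.pressure_profile.bins.empty:
        b = result.pressure_profile.bins
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        ax.errorbar(b["r_norm"], b["value"], yerr=b["sem"], fmt="o", capsize=3)
        if result.power_law is not None:
            rr = np.linspace(b["r_norm"].min(), b["r_norm"].max(), 100)
            ax.plot(
                rr,
                result.power_law.amplitude * rr**result.power_law.beta,
                "-",
                label=f"P1*r^beta, beta={result.power_law.beta:.2f}",
            )
            ax.legend()
        ax.set_xlabel("r / R0")
        ax.set_ylabel("pressure (kPa)")
        fig.tight_layout()
        fig.savefig(out / "pressure_profile.png", dpi=150)
        plt.close(fig)
    # regime schematic: the three qualitative stress profiles
    from .mechanics import AnisotropyModel, radial_stress

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    rr = np.linspace(0.05, 1.0, 200)
    for rho, lab in ((0.8, "softer radial"), (1.0, "isotropic"), (1.12, "stiffer radial")):
        m = AnisotropyModel(stiffness_ratio=rho, surface_stress=1.0)
        ax.plot(rr, radial_stress(m, rr), label=f"rho={rho} ({lab})")
    ax.set_xlabel("r / R0")
    ax.set_ylabel("sigma_rr / P_s")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "regimes.png", dpi=150)
    plt.close(fig)
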