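"""Seeded synthetic data emulating the bead-in-spheroid experiments.

Three generators cover the analysis inputs:

* `make_calibration_dataset` - osmotic-compression stress-strain tables for
  the sensor calibration (known constitutive law plus Gaussian strain noise).
* `make_spheroid_scene` - cohorts of spheroids (radius 120 +/- 10 um) with
  3-4 embedded beads each.  The local compressive stress follows the
  anisotropic-sphere power law sigma(r) = eta * dP0 * (r/R0)^beta with beta
  set by the stiffness ratio; eta models the observed screening of the
  applied 5 kPa osmotic step to ~1 kPa of tissue stress at the surface.
  Each bead is rendered at its own equatorial focal plane as an
  anti-aliased disk, blurred by a Gaussian PSF, with additive Gaussian
  noise; the after image shrinks the bead so its volumetric strain matches
  the constitutive law at the local stress.
* `make_cell_field` - ellipse cell fields with tangential orientation and
  high aspect ratio (2.25) outside a transition radius (default R0/3) and
  rounder, randomly oriented cells (1.5) inside, mirroring the observed
  anisotropy zones.

All generators are bit-reproducible for a fixed seed.  Compressive stress
is positive; strain is the unsigned relative volume change |V - V0| / V0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import gaussian_filter

from .calibration import ConstitutiveFit, pressure_to_strain
from .errors import PlacementError
from .mechanics import beta_from_stiffness_ratio

__all__ = [
    "SceneConfig",
    "ScenePair",
    "make_calibration_dataset",
    "make_spheroid_scene",
    "make_cell_field",
    "render_disk",
    "write_scene",
    "load_scene",
]


@dataclass(frozen=True)
class SceneConfig:
    """Generation parameters for a synthetic spheroid cohort.

    Defaults reproduce the study conditions: spheroids of radius
    120 +/- 10 um with 3-4 beads (radius 8-18 um), an applied osmotic step
    of 5 kPa transmitted at eta = 0.2 into the tissue, and a stiffness
    ratio of 1.12 (radially stiffer cells, stress rising toward the core).
    """

    n_spheroids: int = 1
    spheroid_radius_mean: float = 120.0  # um
    spheroid_radius_sd: float = 10.0  # um
    beads_per_spheroid: tuple[int, int] = (3, 4)  # inclusive uniform range
    bead_radius_range: tuple[float, float] = (8.0, 18.0)  # um, < 20
    applied_pressure: float = 5.0  # kPa, external osmotic step dP0
    surface_transmission: float = 0.2  # eta in (0, 1]
    stiffness_ratio: float = 1.12  # rho = E_r / E_t
    pixel_size: float = 1.0  # um / px
    psf_sigma: float = 2.0  # px
    background_level: float = 100.0  # a.u.
    bead_intensity: float = 1000.0  # a.u.
    noise_sd: float = 20.0  # a.u. (2% of bead intensity)
    surface_clearance: bool = True  # keep bead surface >= 1 radius from surface
    core_drop: bool = False  # taper stress linearly to 0 inside r_norm < 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.spheroid_radius_mean, self.pixel_size) <= 0:
            raise ValueError("lengths must be positive")
        if not (0 < self.surface_transmission <= 1):
            raise ValueError("surface_transmission must lie in (0, 1]")
        if self.stiffness_ratio <= 0:
            raise ValueError("stiffness_ratio must be positive")
        lo, hi = self.bead_radius_range
        if not (0 < lo <= hi < 20):
            raise ValueError("bead radii must lie in (0, 20) um")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SceneConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("beads_per_spheroid", "bead_radius_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ScenePair:
    """Synthetic before/after images plus ground truth for one cohort.

    ``images`` maps (spheroid_id, bead_id) to a (before, after) pair of 2D
    float arrays; ``contours`` maps spheroid_id to a binary equatorial
    mask of the same frame.  ``metadata`` carries per-bead pixel positions
    and stage z; ``spheroids`` the per-spheroid frame info; ``truth`` the
    generator's ground-truth table.
    """

    images: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]]
    contours: dict[str, np.ndarray]
    metadata: pd.DataFrame
    spheroids: pd.DataFrame
    truth: pd.DataFrame
    pixel_size: float
    config: SceneConfig | None = field(default=None, repr=False)


def make_calibration_dataset(
    truth: ConstitutiveFit,
    pressures,
    replicates: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated osmotic-compression table (pressure_kPa, strain).

    Each replicate's strain is the truth law's strain at that pressure plus
    Gaussian noise of sd ``noise_sd``, truncated at zero (strains are
    unsigned volume changes).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    p = np.asarray(list(pressures), dtype=float)
    if np.any(p < 0):
        raise ValueError("pressures must be non-negative")
    rng = np.random.default_rng(seed)
    clean = np.array([pressure_to_strain(truth, pi) for pi in p])
    p_all = np.repeat(p, replicates)
    s_all = np.repeat(clean, replicates)
    if noise_sd > 0:
        s_all = np.maximum(s_all + rng.normal(0.0, noise_sd, s_all.size), 0.0)
    return pd.DataFrame({"pressure_kPa": p_all, "strain": s_all})


def render_disk(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    intensity: float,
    background: float = 0.0,
    supersample: int = 8,
) -> np.ndarray:
    """Anti-aliased disk on a flat background.

    Edge pixels get fractional intensity proportional to the area covered,
    estimated on a ``supersample x supersample`` subpixel grid, so that the
    integrated disk area is accurate to well under a percent for radii of a
    few pixels and up.  ``center`` is (x, y) in pixel units.
    """
    h, w = shape
    cx, cy = center
    img = np.full(shape, float(background))
    x0 = max(int(np.floor(cx - radius - 1)), 0)
    x1 = min(int(np.ceil(cx + radius + 2)), w)
    y0 = max(int(np.floor(cy - radius - 1)), 0)
    y1 = min(int(np.ceil(cy + radius + 2)), h)
    if x0 >= x1 or y0 >= y1:
        return img
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    ys = (np.arange(y0, y1)[:, None] + offs[None, :]).ravel()  # row samples
    xs = (np.arange(x0, x1)[:, None] + offs[None, :]).ravel()
    inside = (
        (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= radius**2
    ).astype(float)
    cov = inside.reshape(y1 - y0, supersample, x1 - x0, supersample).mean(axis=(1, 3))
    img[y0:y1, x0:x1] += (intensity - background) * cov
    return img


def _local_stress(cfg: SceneConfig, r_norm: np.ndarray) -> np.ndarray:
    """Ground-truth compressive stress at normalized radius r_norm."""
    beta = beta_from_stiffness_ratio(cfg.stiffness_ratio)
    sigma = cfg.surface_transmission * cfg.applied_pressure * np.power(r_norm, beta)
    if cfg.core_drop:
        taper = np.where(r_norm < 0.25, r_norm / 0.25, 1.0)
        sigma = sigma * taper
    return sigma


def _sample_bead_centers(
    rng: np.random.Generator,
    n: int,
    spheroid_radius: float,
    bead_radii: np.ndarray,
    surface_clearance: bool,
    max_attempts: int = 1000,
) -> np.ndarray:
    """Bead centres uniform in the spheroid volume (density ~ r^2 in r)."""
    centers = np.empty((n, 3))
    for i, rb in enumerate(bead_radii):
        clearance = 2.0 * rb if surface_clearance else rb
        r_max = spheroid_radius - clearance
        if r_max <= 0:
            raise PlacementError(
                f"bead radius {rb:.1f} um cannot fit inside spheroid "
                f"radius {spheroid_radius:.1f} um with the requested clearance"
            )
        for _ in range(max_attempts):
            u = rng.uniform(-1.0, 1.0, 3)
            if np.dot(u, u) <= 1.0 and np.dot(u, u) > 0:
                centers[i] = u * r_max  # uniform in the ball of radius r_max
                break
        else:  # pragma: no cover - acceptance probability ~0.52 per draw
            raise PlacementError("bead placement failed after bounded attempts")
    return centers


def make_spheroid_scene(cfg: SceneConfig, truth: ConstitutiveFit) -> ScenePair:
    """Render a seeded cohort of spheroids with embedded bead sensors.

    Every bead gets one before/after image pair at its own equatorial
    focal plane (other beads are out of focus and not rendered); the
    after-image radius is shrunk so the bead's volumetric strain equals
    the truth constitutive law evaluated at the local power-law stress.
    """
    rng = np.random.default_rng(cfg.seed)
    images: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    contours: dict[str, np.ndarray] = {}
    meta_rows, sph_rows, truth_rows = [], [], []

    for si in range(cfg.n_spheroids):
        sid = f"sph{si:03d}"
        r0 = rng.normal(cfg.spheroid_radius_mean, cfg.spheroid_radius_sd)
        r0 = float(np.clip(r0, 0.5 * cfg.spheroid_radius_mean, None))
        frame_um = 2.0 * (r0 + 15.0)
        npx = int(np.ceil(frame_um / cfg.pixel_size))
        c_px = npx / 2.0  # spheroid centre, both axes

        contour = (
            render_disk((npx, npx), (c_px, c_px), r0 / cfg.pixel_size, 1.0, 0.0) > 0.5
        )
        contours[sid] = contour
        sph_rows.append(
            {"spheroid_id": sid, "z_um": 0.0, "frame_px": npx, "R0_true_um": r0}
        )

        lo, hi = cfg.beads_per_spheroid
        n_beads = int(rng.integers(lo, hi + 1))
        bead_radii = rng.uniform(*cfg.bead_radius_range, n_beads)
        centers = _sample_bead_centers(
            rng, n_beads, r0, bead_radii, cfg.surface_clearance
        )
        r_norm = np.linalg.norm(centers, axis=1) / r0
        sigma = _local_stress(cfg, r_norm)
        strain = np.array([pressure_to_strain(truth, s) for s in sigma])
        radii_after = bead_radii * np.cbrt(1.0 - strain)

        for bi in range(n_beads):
            bid = f"bead{bi}"
            x_px = c_px + centers[bi, 0] / cfg.pixel_size
            y_px = c_px + centers[bi, 1] / cfg.pixel_size
            pair = []
            for radius in (bead_radii[bi], radii_after[bi]):
                img = render_disk(
                    (npx, npx),
                    (x_px, y_px),
                    radius / cfg.pixel_size,
                    cfg.bead_intensity,
                    cfg.background_level,
                )
                if cfg.psf_sigma > 0:
                    img = gaussian_filter(img, cfg.psf_sigma)
                if cfg.noise_sd > 0:
                    img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
                pair.append(np.maximum(img, 0.0))
            images[(sid, bid)] = (pair[0], pair[1])
            meta_rows.append(
                {
                    "spheroid_id": sid,
                    "bead_id": bid,
                    "x_px": x_px,
                    "y_px": y_px,
                    "z_um": centers[bi, 2],
                    "pixel_size_um": cfg.pixel_size,
                }
            )
            truth_rows.append(
                {
                    "spheroid_id": sid,
                    "bead_id": bid,
                    "x_um": centers[bi, 0],
                    "y_um": centers[bi, 1],
                    "z_um": centers[bi, 2],
                    "true_radius_before_um": bead_radii[bi],
                    "true_radius_after_um": radii_after[bi],
                    "true_local_stress_kPa": sigma[bi],
                    "true_strain": strain[bi],
                    "r_norm": r_norm[bi],
                }
            )

    return ScenePair(
        images=images,
        contours=contours,
        metadata=pd.DataFrame(meta_rows),
        spheroids=pd.DataFrame(sph_rows),
        truth=pd.DataFrame(truth_rows),
        pixel_size=cfg.pixel_size,
        config=cfg,
    )


def _rasterize_ellipse(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    semi_major_px: float,
    semi_minor_px: float,
    orientation: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel (rows, cols) inside an ellipse; orientation CCW from +x (columns)."""
    h, w = shape
    cx, cy = center_px
    ext = semi_major_px + 1
    y0, y1 = max(int(cy - ext), 0), min(int(cy + ext) + 1, h)
    x0, x1 = max(int(cx - ext), 0), min(int(cx + ext) + 1, w)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(orientation) + dy * np.sin(orientation)
    v = -dx * np.sin(orientation) + dy * np.cos(orientation)
    inside = (u / semi_major_px) ** 2 + (v / semi_minor_px) ** 2 <= 1.0
    rows, cols = np.nonzero(inside)
    return rows + y0, cols + x0


def make_cell_field(
    R0: float,
    n_cells: int,
    ar_outer: float = 2.25,
    ar_core: float = 1.5,
    transition_rnorm: float = 1.0 / 3.0,
    seed: int = 0,
    pixel_size: float = 1.0,
    cell_equiv_radius: float = 5.0,
    max_attempts: int = 500,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Label image of ellipse cells in an equatorial spheroid section.

    Outside ``transition_rnorm`` the cells are elongated (aspect ratio
    ``ar_outer``) with the major axis perpendicular to the radius
    (tangential); inside they are rounder (``ar_core``) with random
    orientation.  Placement is random sequential with pixel-exact overlap
    rejection (best effort; raises PlacementError if a cell cannot be
    placed within ``max_attempts`` tries).

    Returns (label image with cells labelled 1..n, truth table with
    positions, r_norm, aspect ratio and orientation).  Orientation is CCW
    from the +x (column) axis in image coordinates.
    """
    if not (ar_outer >= 1 and ar_core >= 1):
        raise ValueError("aspect ratios must be >= 1")
    if not (0 < transition_rnorm < 1):
        raise ValueError("transition_rnorm must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    npx = int(np.ceil(2.0 * (R0 + 5.0) / pixel_size))
    c_px = npx / 2.0
    labels = np.zeros((npx, npx), dtype=np.int32)
    rows_out = []
    r_eq_px = cell_equiv_radius / pixel_size
    r_max = R0 - cell_equiv_radius * np.sqrt(max(ar_outer, ar_core))

    for cid in range(1, n_cells + 1):
        for _ in range(max_attempts):
            r = np.sqrt(rng.uniform()) * r_max  # uniform in section area
            theta = rng.uniform(0, 2 * np.pi)
            r_norm = r / R0
            if r_norm > transition_rnorm:
                ar = ar_outer
                orientation = theta + np.pi / 2  # tangential major axis
            else:
                ar = ar_core
                orientation = rng.uniform(-np.pi / 2, np.pi / 2)
            a = r_eq_px * np.sqrt(ar)
            b = r_eq_px / np.sqrt(ar)
            cx = c_px + (r / pixel_size) * np.cos(theta)
            cy = c_px + (r / pixel_size) * np.sin(theta)
            rr, cc = _rasterize_ellipse((npx, npx), (cx, cy), a, b, orientation)
            if rr.size == 0 or labels[rr, cc].any():
                continue
            labels[rr, cc] = cid
            orientation = (orientation + np.pi / 2) % np.pi - np.pi / 2
            rows_out.append(
                {
                    "cell_id": cid,
                    "x_um": cx * pixel_size,
                    "y_um": cy * pixel_size,
                    "r_norm": r_norm,
                    "aspect_ratio": ar,
                    "orientation": orientation,
                }
            )
            break
        else:
            raise PlacementError(
                f"could not place cell {cid}/{n_cells} after {max_attempts} attempts"
            )
    return labels, pd.DataFrame(rows_out)


# ---------------------------------------------------------------------------
# scene serialization (per-bead TIFF pairs + CSV tables)

def write_scene(scene: ScenePair, out_dir: str | Path) -> Path:
    """Write a scene as 16-bit TIFFs and CSVs under ``out_dir``.

    Layout: ``{spheroid}/{bead}_before.tif`` / ``_after.tif``,
    ``{spheroid}/contour.tif``, plus ``metadata.csv``, ``spheroids.csv``
    and ``ground_truth.csv`` at the top level.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (sid, bid), (before, after) in scene.images.items():
        d = out / sid
        d.mkdir(exist_ok=True)
        for tag, img in (("before", before), ("after", after)):
            tifffile.imwrite(
                d / f"{bid}_{tag}.tif",
                np.clip(img, 0, 65535).astype(np.uint16),
            )
    for sid, contour in scene.contours.items():
        tifffile.imwrite(
            out / sid / "contour.tif", contour.astype(np.uint16) * 65535
        )
    scene.metadata.to_csv(out / "metadata.csv", index=False)
    scene.spheroids.to_csv(out / "spheroids.csv", index=False)
    scene.truth.to_csv(out / "ground_truth.csv", index=False)
    return out


def load_scene(scene_dir: str | Path) -> ScenePair:
    """Load a scene written by `write_scene` (or real data in that layout)."""
    d = Path(scene_dir)
    metadata = pd.read_csv(d / "metadata.csv")
    spheroids = pd.read_csv(d / "spheroids.csv")
    truth_path = d / "ground_truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame()
    images = {}
    contours = {}
    for _, row in metadata.iterrows():
        sid, bid = row["spheroid_id"], row["bead_id"]
        images[(sid, bid)] = (
            tifffile.imread(d / sid / f"{bid}_before.tif").astype(float),
            tifffile.imread(d / sid / f"{bid}_after.tif").astype(float),
        )
    for sid in metadata["spheroid_id"].unique():
        contours[sid] = tifffile.imread(d / sid / "contour.tif") > 0
    return ScenePair(
        images=images,
        contours=contours,
        metadata=metadata,
        spheroids=spheroids,
        truth=truth,
        pixel_size=float(metadata["pixel_size_um"].iloc[0]),
    )
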