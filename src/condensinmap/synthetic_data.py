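"""Ground-truth-labeled synthetic inputs for the whole pipeline.

Each generator emulates the statistical structure one downstream stage
assumes: two-compartment cells with known bound and free protein pools
under photon noise (FCS-calibrated counting), exchange-model recovery
trajectories (FRAP), tube-like chromatids decorated with point-emitter
Condensin spots under an anisotropic PSF (STED), and two-color spot
fields with a controlled overlap fraction (colocalization).

Coordinate convention: all coordinate arrays are ``(z, y, x)`` in nm,
matching array index order; CSV export reorders to x, y, z columns.
Noise model: Poisson photon noise on expected counts plus Gaussian read
noise, qualitatively matching photon-counting APD detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .frap import FrapSeries, exchange_model
from .stack import ImageStack
from .units import conc_from_molecules

# PSF defaults (separable Gaussian sigmas, nm): STED has ~30-nm lateral
# resolving power but diffraction-limited z; confocal is ~100 nm lateral.
STED_PSF_SIGMA_XY = 30.0
CONFOCAL_PSF_SIGMA_XY = 100.0
PSF_SIGMA_Z = 250.0

#: STED acquisition voxel size (z, y, x) nm: 20-nm xy pixels, 140-nm z interval
STED_VOXEL_NM = (140.0, 20.0, 20.0)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson photon noise plus Gaussian read noise.

    ``photons_per_unit`` converts intensity units to expected photon
    counts (None disables shot noise); ``read_sd`` is additive Gaussian
    noise in intensity units.
    """

    photons_per_unit: float | None = 5.0
    read_sd: float = 0.0

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(expected, dtype=float)
        if self.photons_per_unit is not None:
            lam = np.clip(out * self.photons_per_unit, 0, None)
            out = rng.poisson(lam).astype(float) / self.photons_per_unit
        if self.read_sd > 0:
            out = out + rng.normal(0.0, self.read_sd, size=out.shape)
        return out


# ---------------------------------------------------------------------------
# confocal two-compartment cell
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CellGeometry:
    """Nested cell/chromatin ellipsoids on a voxel grid."""

    shape: tuple[int, int, int] = (48, 64, 64)
    voxel_size_nm: tuple[float, float, float] = (500.0, 500.0, 500.0)
    cell_radii_nm: tuple[float, float, float] = (9000.0, 12000.0, 12000.0)
    chromatin_radii_nm: tuple[float, float, float] = (4000.0, 6000.0, 6000.0)

    def __post_init__(self) -> None:
        if any(c >= r for c, r in zip(self.chromatin_radii_nm, self.cell_radii_nm)):
            raise ValueError("chromatin ellipsoid must nest strictly inside the cell")

    def masks(self) -> tuple[np.ndarray, np.ndarray]:
        grids = [
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.shape, self.voxel_size_nm)
        ]
        zz, yy, xx = np.meshgrid(*grids, indexing="ij")

        def ellipsoid(radii):
            rz, ry, rx = radii
            return (zz / rz) ** 2 + (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0

        return ellipsoid(self.cell_radii_nm), ellipsoid(self.chromatin_radii_nm)


@dataclass
class SyntheticCellTruth:
    """Ground truth behind a synthetic confocal cell."""

    bound_count: float
    free_concentration_nM: float
    chromatin_mask: np.ndarray
    cell_mask: np.ndarray
    calibration_slope: float  # nM per intensity unit
    calibration_offset: float  # intensity units (background)
    voxel_volume_um3: float

    def __post_init__(self) -> None:
        if self.bound_count < 0:
            raise ValueError("bound_count must be >= 0")
        if self.calibration_slope <= 0:
            raise ValueError("calibration_slope must be > 0")
        if np.any(self.chromatin_mask & ~self.cell_mask):
            raise ValueError("chromatin mask must be a subset of the cell mask")

    @property
    def chromatin_volume_um3(self) -> float:
        return float(self.chromatin_mask.sum()) * self.voxel_volume_um3

    @property
    def cell_volume_um3(self) -> float:
        return float(self.cell_mask.sum()) * self.voxel_volume_um3

    @property
    def bound_concentration_nM(self) -> float:
        if self.bound_count == 0:
            return 0.0
        return conc_from_molecules(self.bound_count, self.chromatin_volume_um3)


def gen_confocal_cell(
    bound_count: float,
    free_conc_nM: float,
    geometry: CellGeometry | None = None,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
    calibration_slope: float = 2.0,
    calibration_offset: float = 100.0,
) -> tuple[ImageStack, SyntheticCellTruth]:
    """Render a two-compartment cell with known bound and free pools.

    The free pool at ``free_conc_nM`` fills the whole cell (the nuclear
    envelope is open in the emulated mitotic regime); ``bound_count``
    molecules are distributed uniformly over the chromatin volume.
    Voxel intensity = offset + concentration/slope (+ noise).
    """
    geometry = geometry or CellGeometry()
    cell_mask, chromatin_mask = geometry.masks()
    voxel_vol = float(np.prod(geometry.voxel_size_nm)) * 1e-9
    truth = SyntheticCellTruth(
        bound_count=bound_count,
        free_concentration_nM=free_conc_nM,
        chromatin_mask=chromatin_mask,
        cell_mask=cell_mask,
        calibration_slope=calibration_slope,
        calibration_offset=calibration_offset,
        voxel_volume_um3=voxel_vol,
    )
    conc = np.zeros(geometry.shape, dtype=float)
    conc[cell_mask] = free_conc_nM
    conc[chromatin_mask] += truth.bound_concentration_nM
    expected = calibration_offset + conc / calibration_slope
    if noise_model is not None:
        rng = np.random.default_rng(seed)
        expected = noise_model.apply(expected, rng)
    stack = ImageStack(expected, geometry.voxel_size_nm)
    return stack, truth


# ---------------------------------------------------------------------------
# FRAP trajectories and image series
# ---------------------------------------------------------------------------


def gen_frap_series(
    immobile_a: float,
    rate_per_min: float,
    n_frames: int = 40,
    dt_s: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FrapSeries, dict]:
    """Normalized-difference trajectory from the exchange model plus noise.

    Defaults match the acquisition protocol: 20-s frames, 30-45 frames.
    """
    if not 0.0 <= immobile_a <= 1.0:
        raise ValueError("immobile fraction must be in [0, 1]")
    if rate_per_min <= 0:
        raise ValueError("rate must be > 0")
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    t_s = np.arange(n_frames) * dt_s
    curve = exchange_model(t_s / 60.0, immobile_a, rate_per_min)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        curve = curve + rng.normal(0.0, noise_sd, size=curve.shape)
    truth = {"a": immobile_a, "rate_per_min": rate_per_min, "tau_min": 1.0 / rate_per_min}
    return FrapSeries(t_s=t_s, norm_diff=curve), truth


def render_frap_movie(
    immobile_a: float,
    rate_per_min: float,
    n_frames: int = 40,
    dt_s: float = 20.0,
    shape: tuple[int, int] = (60, 100),
    photobleach_rate_per_min: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Render a half-bleach FRAP experiment as (t, y, x) image series.

    Chromatin is a centered rectangle elongated along x; the bleach ROI
    is the right half.  The bleached half starts at zero and recovers
    such that the normalized difference follows the exchange model; an
    optional common photobleaching decay multiplies both channels (it
    must cancel in the normalized difference).

    Returns (protein_stack, dna_stack, bleach_roi, truth).
    """
    ny, nx = shape
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=bool)
    mask[ny // 4 : 3 * ny // 4, nx // 8 : 7 * nx // 8] = True
    roi = np.zeros(shape, dtype=bool)
    roi[:, nx // 2 :] = True

    t_min = np.arange(n_frames) * dt_s / 60.0
    diff = exchange_model(t_min, immobile_a, rate_per_min)
    decay = np.exp(-photobleach_rate_per_min * t_min)

    protein = np.zeros((n_frames, ny, nx))
    dna = np.zeros((n_frames, ny, nx))
    for ti in range(n_frames):
        frame = np.zeros(shape)
        # exchange redistributes the surviving fluorophores: the
        # unbleached half decays toward the common level while the
        # bleached half recovers; the total is conserved
        frame[mask & ~roi] = 0.5 + 0.5 * diff[ti]
        frame[mask & roi] = 0.5 - 0.5 * diff[ti]
        # acquisition photobleaching acts multiplicatively on everything
        protein[ti] = (frame + 0.05) * decay[ti]
        dna[ti] = (mask.astype(float) + 0.05) * decay[ti]
    if noise_sd > 0:
        protein += rng.normal(0.0, noise_sd, size=protein.shape)
        dna += rng.normal(0.0, noise_sd * 0.2, size=dna.shape)
    truth = {"a": immobile_a, "rate_per_min": rate_per_min, "norm_diff": diff}
    return protein, dna, roi, truth


# ---------------------------------------------------------------------------
# STED chromatids with point-emitter spots
# ---------------------------------------------------------------------------


def straight_axis(length_nm: float, step_nm: float = 10.0, z_nm: float = 0.0) -> np.ndarray:
    """Straight centerline along x, (n, 3) array of (z, y, x) nm."""
    x = np.arange(0.0, length_nm + step_nm / 2, step_nm)
    pts = np.zeros((len(x), 3))
    pts[:, 2] = x
    pts[:, 0] = z_nm
    return pts


def arc_axis(
    radius_nm: float, angle_rad: float = np.pi / 2, step_nm: float = 10.0
) -> np.ndarray:
    """Circular-arc centerline in the xy plane (quarter circle by default)."""
    n = max(int(np.ceil(radius_nm * angle_rad / step_nm)) + 1, 2)
    theta = np.linspace(0.0, angle_rad, n)
    pts = np.zeros((n, 3))
    pts[:, 2] = radius_nm * np.sin(theta)
    pts[:, 1] = radius_nm * (1.0 - np.cos(theta))
    return pts


def _arc_length(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _tangents(points: np.ndarray) -> np.ndarray:
    tan = np.gradient(points, axis=0)
    return tan / np.linalg.norm(tan, axis=1, keepdims=True)


@dataclass
class SyntheticChromatidTruth:
    """Ground truth for a synthetic STED chromatid."""

    axis_points: np.ndarray  # (n, 3) (z, y, x) nm
    spot_positions: np.ndarray  # retained (rendered) spots, (m, 3) nm
    spot_multiplicities: np.ndarray
    spot_arc_positions: np.ndarray  # arc length of each retained spot, nm
    tube_radius_sigma: float
    psf_sigma_xy: float
    psf_sigma_z: float
    n_spots_placed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.psf_sigma_z < self.psf_sigma_xy:
            raise ValueError("psf_sigma_z must be >= psf_sigma_xy (2D depletion beam)")
        if _arc_length(self.axis_points)[-1] <= 0:
            raise ValueError("axis arc length must be > 0")

    @property
    def axis_length_nm(self) -> float:
        return float(_arc_length(self.axis_points)[-1])


def _render_gaussians(
    shape: tuple[int, int, int],
    voxel_size_nm: tuple[float, float, float],
    positions_nm: np.ndarray,
    totals: np.ndarray,
    sigma_nm: tuple[float, float, float],
) -> np.ndarray:
    """Sum of separable Gaussians; each spot integrates to its total."""
    img = np.zeros(shape, dtype=float)
    voxel = np.asarray(voxel_size_nm)
    sigma_vox = np.asarray(sigma_nm) / voxel
    half = np.maximum((4 * sigma_vox).astype(int), 1)
    norm = float(np.prod(voxel)) / ((2 * np.pi) ** 1.5 * float(np.prod(sigma_nm)))
    for pos, total in zip(np.atleast_2d(positions_nm), np.atleast_1d(totals)):
        center = pos / voxel
        lo = np.maximum(np.floor(center - half).astype(int), 0)
        hi = np.minimum(np.ceil(center + half).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        axes = [
            np.exp(-0.5 * ((np.arange(lo[d], hi[d]) - center[d]) / sigma_vox[d]) ** 2)
            for d in range(3)
        ]
        img[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += (
            total * norm * axes[0][:, None, None] * axes[1][None, :, None] * axes[2][None, None, :]
        )
    return img


def render_tube(
    axis_points: np.ndarray,
    sigma_nm: float,
    shape: tuple[int, int, int],
    voxel_size_nm: tuple[float, float, float],
    intensity_per_nm: float = 100.0,
    step_nm: float = 5.0,
) -> ImageStack:
    """Render a centerline as a tube with a radial Gaussian profile.

    The radial Gaussian makes the lateral FWHM analytically checkable
    (2 sqrt(2 ln 2) sigma = 2.355 sigma).  The centerline is painted at
    sub-voxel steps and blurred with a separable Gaussian, so intensity
    per unit axis length is constant.
    """
    voxel = np.asarray(voxel_size_nm, dtype=float)
    s = _arc_length(axis_points)
    stations = np.arange(0.0, s[-1] + step_nm / 2, step_nm)
    pts = np.column_stack(
        [np.interp(stations, s, axis_points[:, d]) for d in range(3)]
    )
    img = np.zeros(shape, dtype=float)
    idx = np.round(pts / voxel).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(shape)), axis=1)
    np.add.at(img, tuple(idx[ok].T), intensity_per_nm * step_nm)
    img = ndimage.gaussian_filter(img, sigma_nm / voxel)
    return ImageStack(img, voxel_size_nm)


def tube_mask(
    axis_points: np.ndarray,
    radius_nm: float,
    shape: tuple[int, int, int],
    voxel_size_nm: tuple[float, float, float],
    step_nm: float = 10.0,
) -> np.ndarray:
    """Boolean flat-ended tube: voxels within ``radius_nm`` of the axis.

    Voxels whose nearest axis station is an endpoint are only included
    when they lie on the cutting plane side (flat caps, no hemispheres),
    so the mask extent equals the axis arc length.
    """
    from scipy.spatial import cKDTree

    s = _arc_length(axis_points)
    stations = np.arange(0.0, s[-1] + step_nm / 2, step_nm)
    pts = np.column_stack([np.interp(stations, s, axis_points[:, d]) for d in range(3)])
    tan = _tangents(pts)
    grids = [np.arange(n) * v for n, v in zip(shape, voxel_size_nm)]
    zz, yy, xx = np.meshgrid(*grids, indexing="ij")
    vox = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    d, nearest = cKDTree(pts).query(vox)
    mask = d <= radius_nm
    # flat caps: drop voxels projecting beyond the first/last station
    end0 = nearest == 0
    proj0 = (vox - pts[0]) @ tan[0]
    mask &= ~(end0 & (proj0 < 0))
    endn = nearest == len(pts) - 1
    projn = (vox - pts[-1]) @ tan[-1]
    mask &= ~(endn & (projn > 0))
    return mask.reshape(shape)


def gen_sted_chromatid(
    axis_points: np.ndarray,
    spot_spacing_nm: float,
    multiplicity_dist: dict[int, float] | None = None,
    psf_sigma_xy: float = STED_PSF_SIGMA_XY,
    psf_sigma_z: float = PSF_SIGMA_Z,
    tube_radius_sigma: float = 150.0,
    detection_efficiency: float = 1.0,
    intensity_unit: float = 3000.0,
    lateral_jitter_sigma: float = 0.0,
    voxel_size_nm: tuple[float, float, float] = STED_VOXEL_NM,
    margin_nm: float = 600.0,
    noise_model: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[ImageStack, SyntheticChromatidTruth]:
    """Decorate a chromatid axis with Condensin spots and render STED data.

    Spots are placed at equidistant arc-length stations (count =
    floor(L/spacing) + 1), optionally displaced perpendicular to the
    local tangent (``lateral_jitter_sigma``, truncated at 3 sigma so the
    spot stays within 3 sigma of the axis when the jitter equals the
    tube radius).  Each spot renders as an anisotropic Gaussian whose
    integrated intensity is multiplicity x ``intensity_unit`` AU; a
    binomial thinning with ``detection_efficiency`` emulates incomplete
    labeling/detection.  The DNA channel is a diffraction-limited tube.

    Returns a two-channel stack (``condensin``, ``dna``) and the truth.
    """
    if spot_spacing_nm <= 0:
        raise ValueError("spot spacing must be > 0")
    if not 0 < detection_efficiency <= 1:
        raise ValueError("detection_efficiency must be in (0, 1]")
    rng = np.random.default_rng(seed)
    axis_points = np.asarray(axis_points, dtype=float)
    s = _arc_length(axis_points)
    stations = np.arange(0.0, s[-1] + 1e-9, spot_spacing_nm)
    pos = np.column_stack([np.interp(stations, s, axis_points[:, d]) for d in range(3)])
    tangents_axis = _tangents(axis_points)
    tan = np.column_stack(
        [np.interp(stations, s, tangents_axis[:, d]) for d in range(3)]
    )
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)

    if lateral_jitter_sigma > 0:
        # orthonormal frame perpendicular to the local tangent
        ref = np.tile([1.0, 0.0, 0.0], (len(tan), 1))
        swap = np.abs(tan[:, 0]) > 0.9
        ref[swap] = [0.0, 1.0, 0.0]
        u = np.cross(tan, ref)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(tan, u)
        r1 = np.clip(rng.normal(0, lateral_jitter_sigma, len(pos)), -3 * lateral_jitter_sigma, 3 * lateral_jitter_sigma)
        r2 = np.clip(rng.normal(0, lateral_jitter_sigma, len(pos)), -3 * lateral_jitter_sigma, 3 * lateral_jitter_sigma)
        pos = pos + u * r1[:, None] + v * r2[:, None]

    n_placed = len(pos)
    keep = rng.random(n_placed) < detection_efficiency
    if detection_efficiency >= 1.0:
        keep[:] = True
    pos, stations = pos[keep], stations[keep]

    if multiplicity_dist is None:
        mult = np.ones(len(pos), dtype=int)
    else:
        ks = np.array(sorted(multiplicity_dist))
        ps = np.array([multiplicity_dist[k] for k in ks], dtype=float)
        mult = rng.choice(ks, size=len(pos), p=ps / ps.sum())

    # shift everything into the positive octant with a margin
    lo = axis_points.min(axis=0) - margin_nm
    axis_shifted = axis_points - lo
    pos_shifted = pos - lo
    extent = axis_points.max(axis=0) - lo + margin_nm
    shape = tuple(int(np.ceil(e / v)) + 1 for e, v in zip(extent, voxel_size_nm))

    condensin = _render_gaussians(
        shape, voxel_size_nm, pos_shifted, mult * intensity_unit,
        (psf_sigma_z, psf_sigma_xy, psf_sigma_xy),
    )
    dna = render_tube(
        axis_shifted, tube_radius_sigma, shape, voxel_size_nm
    ).data
    if noise_model is not None:
        condensin = noise_model.apply(condensin, rng)
        dna = noise_model.apply(dna, rng)
    stack = ImageStack(
        np.stack([condensin, dna]), voxel_size_nm, channels=("condensin", "dna")
    )
    truth = SyntheticChromatidTruth(
        axis_points=axis_shifted,
        spot_positions=pos_shifted,
        spot_multiplicities=mult,
        spot_arc_positions=stations,
        tube_radius_sigma=tube_radius_sigma,
        psf_sigma_xy=psf_sigma_xy,
        psf_sigma_z=psf_sigma_z,
        n_spots_placed=n_placed,
        meta={"intensity_unit": intensity_unit, "origin_shift_nm": -lo},
    )
    return stack, truth


# ---------------------------------------------------------------------------
# whole-cell chromatid field (length-estimator ground truth)
# ---------------------------------------------------------------------------


def gen_chromatid_field(
    n_tubes: int = 128,
    length_range_um: tuple[float, float] = (3.0, 6.0),
    voxel_nm: float = 100.0,
    tube_sigma_nm: float = 150.0,
    dna_sigma_nm: float = 250.0,
    background_au: float = 10.0,
    n_regions: int = 4,
    region_radius_nm: float = 450.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ImageStack, ImageStack, list[np.ndarray], dict]:
    """Whole-cell field of straight chromatid tubes with known lengths.

    Tubes are laid out on a grid (one per grid cell, centered, along x)
    with lengths drawn uniformly from ``length_range_um``; Condensin
    intensity per unit axis length is constant, so the intensity-ratio
    length estimator is unbiased by construction.  ``n_regions`` tubes
    get a truth region mask (a flat-ended cylinder of
    ``region_radius_nm`` around the tube axis, emulating a manual
    segmentation of a clearly recognizable Condensin stretch).

    Returns (dna_stack, condensin_stack, region_masks, truth) where
    truth carries per-tube lengths (nm), the sampled region indices and
    the total length in µm.
    """
    rng = np.random.default_rng(seed)
    n_cols = 8
    n_rows = int(np.ceil(n_tubes / n_cols))
    cell_x = int(np.ceil((length_range_um[1] * 1000 + 1200) / voxel_nm))
    cell_y = int(np.ceil(1600 / voxel_nm))
    nz = int(np.ceil(1600 / voxel_nm))
    shape = (nz, n_rows * cell_y, n_cols * cell_x)
    voxel = (voxel_nm, voxel_nm, voxel_nm)

    lengths = rng.uniform(*length_range_um, size=n_tubes) * 1000.0  # nm
    cond = np.zeros(shape, dtype=np.float32)
    axes = []
    step = voxel_nm / 4.0
    z0 = nz / 2.0 * voxel_nm
    for i, L in enumerate(lengths):
        row, col = divmod(i, n_cols)
        y0 = (row + 0.5) * cell_y * voxel_nm
        xc = (col + 0.5) * cell_x * voxel_nm
        xs = np.arange(xc - L / 2, xc + L / 2 + step / 2, step)
        idx_z = np.full(len(xs), z0 / voxel_nm)
        idx_y = np.full(len(xs), y0 / voxel_nm)
        idx_x = xs / voxel_nm
        np.add.at(
            cond,
            (
                np.round(idx_z).astype(int),
                np.round(idx_y).astype(int),
                np.clip(np.round(idx_x).astype(int), 0, shape[2] - 1),
            ),
            1.0,
        )
        axes.append((np.array([z0, y0, xc - L / 2]), np.array([z0, y0, xc + L / 2])))
    cond = ndimage.gaussian_filter(cond, tube_sigma_nm / voxel_nm) * 1e4
    dna = ndimage.gaussian_filter(cond, dna_sigma_nm / voxel_nm)
    cond = cond + background_au
    dna = dna + background_au
    if noise_sd > 0:
        cond = cond + rng.normal(0, noise_sd, cond.shape)
        dna = dna + rng.normal(0, noise_sd, dna.shape)

    region_idx = rng.choice(n_tubes, size=n_regions, replace=False)
    region_masks = []
    for ri in region_idx:
        p0, p1 = axes[ri]
        lo = np.maximum(((np.minimum(p0, p1) - 2 * region_radius_nm) / voxel_nm).astype(int), 0)
        hi = np.minimum(
            ((np.maximum(p0, p1) + 2 * region_radius_nm) / voxel_nm).astype(int) + 2,
            shape,
        )
        sub_axis = np.vstack([p0, p1]) - lo * voxel_nm
        sub_shape = tuple(int(h - l) for h, l in zip(hi, lo))
        sub = tube_mask(sub_axis, region_radius_nm, sub_shape, voxel)
        full = np.zeros(shape, dtype=bool)
        full[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = sub
        region_masks.append(full)
    truth = {
        "lengths_nm": lengths,
        "total_length_um": float(lengths.sum() / 1000.0),
        "region_tube_indices": region_idx,
        "background_au": background_au,
    }
    return (
        ImageStack(dna, voxel),
        ImageStack(cond, voxel),
        region_masks,
        truth,
    )


# ---------------------------------------------------------------------------
# two-color STED spot fields
# ---------------------------------------------------------------------------


def gen_two_channel_sted(
    overlap_fraction: float,
    counts: int,
    seed: int = 0,
    shape: tuple[int, int, int] = (9, 256, 256),
    voxel_size_nm: tuple[float, float, float] = STED_VOXEL_NM,
    psf_sigma_xy: float = STED_PSF_SIGMA_XY,
    psf_sigma_z: float = PSF_SIGMA_Z,
    intensity_unit: float = 3000.0,
    noise_model: NoiseModel | None = None,
) -> tuple[ImageStack, ImageStack, dict]:
    """Two spot channels with a controlled coincidence fraction.

    Exactly round(overlap_fraction x counts) channel-B spots sit at
    channel-A positions; the rest are placed at least 3 lateral PSF
    widths (FWHM) from every A spot.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if counts < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    extent = np.array(shape) * np.array(voxel_size_nm)
    margin = np.array([psf_sigma_z, 3 * psf_sigma_xy, 3 * psf_sigma_xy]) * 2

    def draw(n):
        return margin + rng.random((n, 3)) * (extent - 2 * margin)

    pos_a = draw(counts)
    n_over = int(round(overlap_fraction * counts))
    pos_b = [pos_a[rng.permutation(counts)[:n_over]]] if n_over else []
    min_sep = 3 * 2.355 * psf_sigma_xy
    placed = 0
    attempts = 0
    extra = []
    while placed < counts - n_over:
        cand = draw(1)[0]
        d = np.linalg.norm((pos_a - cand)[:, 1:], axis=1)  # lateral distance
        if d.min() >= min_sep:
            extra.append(cand)
            placed += 1
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not place non-overlapping spots; lower counts")
    if extra:
        pos_b.append(np.array(extra))
    pos_b = np.concatenate(pos_b) if pos_b else np.empty((0, 3))

    sig = (psf_sigma_z, psf_sigma_xy, psf_sigma_xy)
    totals_a = np.full(len(pos_a), intensity_unit)
    totals_b = np.full(len(pos_b), intensity_unit)
    img_a = _render_gaussians(shape, voxel_size_nm, pos_a, totals_a, sig)
    img_b = _render_gaussians(shape, voxel_size_nm, pos_b, totals_b, sig)
    if noise_model is not None:
        img_a = noise_model.apply(img_a, rng)
        img_b = noise_model.apply(img_b, rng)
    truth = {
        "positions_a": pos_a,
        "positions_b": pos_b,
        "n_coincident": n_over,
        "overlap_fraction": overlap_fraction,
    }
    return (
        ImageStack(img_a, voxel_size_nm),
        ImageStack(img_b, voxel_size_nm),
        truth,
    )
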