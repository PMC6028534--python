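"""Chromatid/Condensin axis tracing and width statistics from STED stacks.

The segmented Condensin volume is sliced orthogonally to its principal
eigenvector at 100-nm spacing; the resulting centroids define local
tangents that drive a second, curvature-adaptive slicing at 20 nm.  The
centroids of the fine cross sections are the Condensin axis.  Widths
are the FWHM of z-projected lateral intensity profiles accumulated in a
2-µm sliding window shifted by 200 nm; radial intensity distributions
are symmetrized 1D profiles through a reference point, reconstructed as
radially symmetric distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stack import ImageStack


@dataclass
class ChromatidAxis:
    """Ordered 3D centerline with cumulative arc length (all nm)."""

    points: np.ndarray  # (n, 3) (z, y, x) nm
    tangents: np.ndarray  # (n, 3) unit vectors
    spacing_nm: float  # nominal fine-step spacing

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if len(self.points) < 2:
            raise ValueError("axis needs >= 2 points")

    @property
    def cumulative_length(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length_nm(self) -> float:
        return float(self.cumulative_length[-1])


@dataclass
class WidthProfile:
    window_centers_nm: np.ndarray
    fwhm_per_window_nm: np.ndarray
    flags: list[str] = field(default_factory=list)

    @property
    def mean_fwhm_nm(self) -> float:
        return float(np.mean(self.fwhm_per_window_nm))


@dataclass
class RadialProfile:
    radius_nm: np.ndarray
    intensity: np.ndarray  # peak-normalized

    def containment_radius(self, q: float) -> float:
        """Radius containing fraction ``q`` of the radially symmetric mass."""
        if not 0 < q < 1:
            raise ValueError("q must be in (0, 1)")
        mass = np.cumsum(self.intensity * self.radius_nm)
        if mass[-1] <= 0:
            raise ValueError("profile has no mass")
        mass = mass / mass[-1]
        return float(np.interp(q, mass, self.radius_nm))


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def preprocess_stack(
    stack: ImageStack,
    drift_correct: bool = True,
    smooth_sigma_vox: float = 0.5,
    protein_channel: str = "condensin",
) -> ImageStack:
    """Drift-correct, interpolate z to isotropic voxels, smooth protein.

    Slice-to-slice rigid drift is estimated on the protein channel by
    subpixel phase correlation and removed; the z dimension is linearly
    interpolated to the lateral voxel size; a 3D Gaussian filter
    (sigma = 0.5 voxels) is applied to the protein channel only.
    """
    from skimage.registration import phase_cross_correlation

    vz, vy, vx = stack.voxel_size_nm
    if abs(vy - vx) > 1e-9:
        raise ValueError("expected square xy pixels")
    multi = stack.data.ndim == 4
    if multi:
        names = stack.channels or tuple(f"ch{i}" for i in range(stack.data.shape[0]))
        ref_idx = names.index(protein_channel) if protein_channel in names else 0
        channels = [stack.data[i].astype(float) for i in range(stack.data.shape[0])]
    else:
        names = None
        ref_idx = 0
        channels = [stack.data.astype(float)]

    n_z = channels[ref_idx].shape[0]
    if drift_correct:
        if n_z < 2:
            warnings.warn("single-slice stack: drift correction skipped", stacklevel=2)
        else:
            ref = channels[ref_idx]
            shifts = np.zeros((n_z, 2))
            for zi in range(1, n_z):
                shift, _, _ = phase_cross_correlation(
                    ref[zi - 1], ref[zi], upsample_factor=20, normalization=None
                )
                shifts[zi] = shifts[zi - 1] + shift
            for ch in channels:
                for zi in range(1, n_z):
                    ch[zi] = ndimage.shift(ch[zi], shifts[zi], order=1, mode="nearest")

    # linear z interpolation to isotropic voxels
    factor = vz / vx
    if abs(factor - 1.0) > 1e-9:
        old_z = np.arange(n_z) * vz
        new_z = np.arange(0.0, old_z[-1] + 1e-9, vx)
        out = []
        for ch in channels:
            interp = np.empty((len(new_z),) + ch.shape[1:])
            idx = np.clip(np.searchsorted(old_z, new_z, side="right") - 1, 0, n_z - 2)
            frac = ((new_z - old_z[idx]) / vz)[:, None, None]
            interp[:] = ch[idx] * (1 - frac) + ch[idx + 1] * frac
            out.append(interp)
        channels = out

    channels[ref_idx] = ndimage.gaussian_filter(channels[ref_idx], smooth_sigma_vox)
    voxel = (vx, vy, vx)
    if multi:
        return ImageStack(np.stack(channels), voxel, channels=names, meta=dict(stack.meta))
    return ImageStack(channels[0], voxel, meta=dict(stack.meta))


# ---------------------------------------------------------------------------
# axis tracing
# ---------------------------------------------------------------------------


def trace_axis(
    mask: np.ndarray,
    voxel_size_nm: float | tuple[float, float, float],
    coarse_step_nm: float = 100.0,
    fine_step_nm: float = 20.0,
    end_trim_nm: float = 0.0,
    min_aspect: float = 2.0,
    smooth_window: int = 5,
    max_radius_nm: float = 1000.0,
) -> ChromatidAxis:
    """Trace the centerline of a tube-like binary volume.

    First pass: cut orthogonally to the principal eigenvector of the
    voxel-coordinate covariance at ``coarse_step_nm``.  Second pass:
    local tangents from neighboring coarse centroids drive an adaptive
    slicing at ``fine_step_nm`` compatible with the local curvature.
    The fine centroid polyline is smoothed with a short moving average
    (``smooth_window`` points) to suppress voxel-quantization zigzag,
    which would otherwise inflate the arc length; ``end_trim_nm`` of
    axis is excluded from each end.
    """
    mask = np.asarray(mask, dtype=bool)
    if np.isscalar(voxel_size_nm):
        voxel = np.array([voxel_size_nm] * 3, dtype=float)
    else:
        voxel = np.asarray(voxel_size_nm, dtype=float)
    coords = np.argwhere(mask).astype(float) * voxel
    if len(coords) < 10:
        raise ValueError("mask too small to trace")
    center = coords.mean(axis=0)
    cov = np.cov((coords - center).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    aspect = np.sqrt(evals[0] / max(evals[1], 1e-12))
    if aspect < min_aspect:
        raise ValueError(
            f"no dominant axis (aspect ratio {aspect:.2f} < {min_aspect}): not tube-like"
        )
    e1 = evecs[:, 0]
    pts, tans = _centroid_axis(
        coords, e1, coarse_step_nm, fine_step_nm, smooth_window, max_radius_nm
    )

    if end_trim_nm > 0:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        keep = (cum >= end_trim_nm) & (cum <= cum[-1] - end_trim_nm)
        if keep.sum() < 2:
            raise ValueError("end trim removed the whole axis")
        pts, tans = pts[keep], tans[keep]
    return ChromatidAxis(points=pts, tangents=tans, spacing_nm=fine_step_nm)


def _centroid_axis(
    coords: np.ndarray,
    e1: np.ndarray,
    coarse_step_nm: float,
    fine_step_nm: float,
    smooth_window: int,
    max_radius_nm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pass centroid axis of a voxel point cloud along direction e1."""
    center = coords.mean(axis=0)

    # pass 1: coarse orthogonal cuts along the initial direction
    s = (coords - center) @ e1
    edges = np.arange(s.min(), s.max() + coarse_step_nm, coarse_step_nm)
    which = np.digitize(s, edges)
    coarse = np.array(
        [coords[which == b].mean(axis=0) for b in np.unique(which) if (which == b).sum() > 0]
    )
    if len(coarse) < 2:
        raise ValueError("coarse slicing produced < 2 centroids")

    # pass 2: curvature-adaptive fine cuts along the coarse polyline
    seg = np.linalg.norm(np.diff(coarse, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    tan_coarse = np.gradient(coarse, arc, axis=0)
    tan_coarse /= np.linalg.norm(tan_coarse, axis=1, keepdims=True)
    # extend beyond the coarse centroids so the axis reaches the tube caps
    stations = np.arange(-coarse_step_nm, arc[-1] + coarse_step_nm + 1e-9, fine_step_nm)
    pts, tans, counts = [], [], []
    for st in stations:
        if st < 0:
            p = coarse[0] + tan_coarse[0] * st
            t = tan_coarse[0].copy()
        elif st > arc[-1]:
            p = coarse[-1] + tan_coarse[-1] * (st - arc[-1])
            t = tan_coarse[-1].copy()
        else:
            p = np.array([np.interp(st, arc, coarse[:, d]) for d in range(3)])
            t = np.array([np.interp(st, arc, tan_coarse[:, d]) for d in range(3)])
        t /= np.linalg.norm(t)
        d = coords - p
        proj = d @ t
        lateral = d - proj[:, None] * t
        # bounded cut: a laterally unbounded plane could intersect a
        # distant bend of the same tube
        sel = (np.abs(proj) <= fine_step_nm / 2.0) & (
            np.linalg.norm(lateral, axis=1) <= max_radius_nm
        )
        if not sel.any():
            continue
        c = coords[sel].mean(axis=0)
        # keep the centroid on the cutting plane through the station
        c = c - ((c - p) @ t) * t
        pts.append(c)
        tans.append(t)
        counts.append(int(sel.sum()))
    pts = np.asarray(pts)
    tans = np.asarray(tans)
    counts = np.asarray(counts)
    if len(pts) < 2:
        raise ValueError("fine slicing produced < 2 centroids")
    # partial cap cuts at the ends drag centroids along the tube rim;
    # trim stations whose section holds < half the median voxel count
    full = counts >= 0.5 * np.median(counts)
    first, last = np.argmax(full), len(full) - 1 - np.argmax(full[::-1])
    pts, tans = pts[first : last + 1], tans[first : last + 1]
    if len(pts) < 2:
        raise ValueError("fine slicing produced < 2 centroids")
    if smooth_window > 1 and len(pts) > smooth_window:
        kernel = np.ones(smooth_window) / smooth_window
        sm = np.column_stack(
            [np.convolve(pts[:, d], kernel, mode="valid") for d in range(3)]
        )
        half = (smooth_window - 1) // 2
        pts = np.vstack([pts[:half], sm, pts[len(pts) - (smooth_window - 1 - half):]])
    return pts, tans


# ---------------------------------------------------------------------------
# cross-section sampling
# ---------------------------------------------------------------------------


def _lateral_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point orthonormal frame: u in the xy plane, v completing it."""
    ez = np.array([1.0, 0.0, 0.0])  # (z, y, x) order: unit z
    u = np.cross(tangents, ez)
    norms = np.linalg.norm(u, axis=1, keepdims=True)
    # tangent parallel to z: fall back to the y direction
    bad = norms[:, 0] < 1e-6
    u[bad] = np.array([0.0, 1.0, 0.0])
    norms[bad] = 1.0
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(tangents, u)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return u, v


def _sample_cross_sections(
    data: np.ndarray,
    voxel_size_nm,
    axis: ChromatidAxis,
    lateral_extent_nm: float,
    sample_step_nm: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the (u, v) cross-section plane at every axis point.

    Returns (planes, offsets): planes is (n_points, nu, nv), offsets the
    lateral coordinate grid in nm (shared by u and v).
    """
    voxel = np.asarray(voxel_size_nm, dtype=float)
    offs = np.arange(-lateral_extent_nm, lateral_extent_nm + sample_step_nm / 2, sample_step_nm)
    u, v = _lateral_frames(axis.tangents)
    planes = np.empty((len(axis.points), len(offs), len(offs)))
    uu, vv = np.meshgrid(offs, offs, indexing="ij")
    for i, (p, ui, vi) in enumerate(zip(axis.points, u, v)):
        sample_nm = p[None, None, :] + uu[..., None] * ui + vv[..., None] * vi
        coords_vox = (sample_nm / voxel).transpose(2, 0, 1)
        planes[i] = ndimage.map_coordinates(data, coords_vox, order=1, mode="constant")
    return planes, offs


def _fwhm_linear(profile: np.ndarray, step_nm: float) -> float | None:
    """FWHM by linear interpolation of the half-maximum crossings."""
    imax = int(np.argmax(profile))
    peak = profile[imax]
    if peak <= 0:
        return None
    half = peak / 2.0
    left = right = None
    for i in range(imax, 0, -1):
        if profile[i - 1] <= half <= profile[i]:
            frac = (profile[i] - half) / max(profile[i] - profile[i - 1], 1e-30)
            left = i - frac
            break
    for i in range(imax, len(profile) - 1):
        if profile[i + 1] <= half <= profile[i]:
            frac = (profile[i] - half) / max(profile[i] - profile[i + 1], 1e-30)
            right = i + frac
            break
    if left is None or right is None:
        return None
    return float((right - left) * step_nm)


def compute_fwhm_profile(
    stack: ImageStack,
    axis: ChromatidAxis,
    window_nm: float = 2000.0,
    step_nm: float = 200.0,
    lateral_extent_nm: float = 1500.0,
    background: str = "tail_median",
) -> WidthProfile:
    """Sliding-window FWHM of the z-projected lateral intensity profile.

    Within each 2-µm window the cross sections are accumulated, summed
    along the v (axial/z-like) direction to a 1D lateral profile, the
    profile's tail median is subtracted (background), and the FWHM is
    measured by linear interpolation at the half-maximum crossings.
    """
    data = stack.data if stack.data.ndim == 3 else stack.data[0]
    sample_step = min(stack.voxel_size_nm)
    planes, offs = _sample_cross_sections(
        data, stack.voxel_size_nm, axis, lateral_extent_nm, sample_step
    )
    profiles = planes.sum(axis=2)  # project along v -> (n_points, nu)
    arc = axis.cumulative_length
    if arc[-1] < window_nm:
        raise ValueError("axis shorter than one window")
    centers = np.arange(window_nm / 2, arc[-1] - window_nm / 2 + 1e-9, step_nm)
    n_tail = max(int(0.1 * len(offs)), 2)
    fwhms, used_centers, flags = [], [], []
    for c in centers:
        sel = np.abs(arc - c) <= window_nm / 2
        prof = profiles[sel].sum(axis=0)
        if background == "tail_median":
            tail = np.concatenate([prof[:n_tail], prof[-n_tail:]])
            prof = prof - np.median(tail)
        w = _fwhm_linear(prof, sample_step)
        if w is None:
            flags.append(f"window@{c:.0f}nm: no half-max crossing, skipped")
            continue
        fwhms.append(w)
        used_centers.append(c)
    if not fwhms:
        raise ValueError("no window yielded a measurable FWHM")
    return WidthProfile(
        window_centers_nm=np.asarray(used_centers),
        fwhm_per_window_nm=np.asarray(fwhms),
        flags=flags,
    )


def compute_radial_profile(
    stack: ImageStack,
    axis: ChromatidAxis,
    chromatid_width_nm: float,
    lateral_extent_nm: float = 1500.0,
) -> RadialProfile:
    """Symmetrized radial intensity distribution around the chromatid axis.

    All cross sections are accumulated into one (u, v) image; the
    reference point maximizes the total intensity within a window of
    0.4x and 0.6x the mean chromatid width in u and v; the 1D profile
    through the reference point along u is symmetrized (left side
    reflected onto the right and averaged); intensities beyond the
    chromatid radius are excluded.
    """
    data = stack.data if stack.data.ndim == 3 else stack.data[0]
    sample_step = min(stack.voxel_size_nm)
    planes, offs = _sample_cross_sections(
        data, stack.voxel_size_nm, axis, lateral_extent_nm, sample_step
    )
    image = planes.sum(axis=0)  # (u, v)
    wu = max(int(round(0.4 * chromatid_width_nm / sample_step)), 1)
    wv = max(int(round(0.6 * chromatid_width_nm / sample_step)), 1)
    if wu > image.shape[0] or wv > image.shape[1]:
        raise ValueError("reference window larger than the sampled image")
    boxsum = ndimage.uniform_filter(image, size=(wu, wv))
    iu, iv = np.unravel_index(np.argmax(boxsum), image.shape)
    profile = image[:, iv]

    # symmetrize about the reference point
    n = len(offs)
    rmax_idx = min(iu, n - 1 - iu)
    r = np.arange(rmax_idx + 1) * sample_step
    left = profile[iu::-1][: rmax_idx + 1]
    right = profile[iu:][: rmax_idx + 1]
    sym = 0.5 * (left + right)
    keep = r <= chromatid_width_nm / 2.0
    r, sym = r[keep], sym[keep]
    if sym[0] <= 0:
        raise ValueError("empty profile at the reference point")
    return RadialProfile(radius_nm=r, intensity=sym / sym[0])
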