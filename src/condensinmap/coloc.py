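"""Two-channel high-density segmentation and colocalization statistics.

The nonoverlap percentage of two segmented channels is the number of
nonoverlapping voxels (symmetric difference) divided by the geometric
mean of the per-channel positive-voxel counts, times 100; 0% means the
masks are identical and values above 100% occur for disjoint masks.
The intensity correlation is a normalized cross-correlation (per-channel
mean subtraction) over the union of positive voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stack import ImageStack


@dataclass(frozen=True)
class ColocResult:
    nonoverlap_percent: float
    ncc: float
    n_voxels_a: int
    n_voxels_b: int
    n_overlap: int
    #: alternative per-channel reading: mean of |A\B|/|A| and |B\A|/|B| x 100
    nonoverlap_percent_per_channel: float = float("nan")


def segment_high_density(
    stack: ImageStack | np.ndarray, local_window: int = 9, sensitivity: float = 1.0
) -> np.ndarray:
    """Segment high-density voxels: global Otsu AND local-mean threshold.

    The local threshold is the mean within an in-plane ``local_window``
    x ``local_window`` neighborhood scaled by ``sensitivity``; combining
    it with the global Otsu threshold reduces over/undersegmentation.
    Operates slice-by-slice on the 2D planes of a 3D stack.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, dtype=float)
    if data.ndim == 2:
        data = data[None]
    if np.ptp(data) == 0:
        warnings.warn("constant image: empty segmentation", stacklevel=2)
        return np.zeros_like(data, dtype=bool)
    from skimage.filters import threshold_otsu

    global_thr = threshold_otsu(data)
    mask = np.zeros_like(data, dtype=bool)
    for zi in range(data.shape[0]):
        local_mean = ndimage.uniform_filter(data[zi], size=local_window)
        mask[zi] = (data[zi] > global_thr) & (data[zi] > sensitivity * local_mean)
    return mask


def coloc_stats(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    stack_a: ImageStack | np.ndarray,
    stack_b: ImageStack | np.ndarray,
) -> ColocResult:
    """Nonoverlap percentage and normalized cross-correlation.

    Masks must already be aligned (channel offsets corrected upstream
    via bead calibration).
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must have equal shape")
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("colocalization undefined for an empty mask")
    n_overlap = int((mask_a & mask_b).sum())
    nonoverlap = 100.0 * (n_a + n_b - 2 * n_overlap) / np.sqrt(n_a * n_b)
    per_channel = 50.0 * ((n_a - n_overlap) / n_a + (n_b - n_overlap) / n_b)

    data_a = stack_a.data if isinstance(stack_a, ImageStack) else np.asarray(stack_a, float)
    data_b = stack_b.data if isinstance(stack_b, ImageStack) else np.asarray(stack_b, float)
    union = mask_a | mask_b
    xa = data_a[union].astype(float)
    xb = data_b[union].astype(float)
    xa -= xa.mean()
    xb -= xb.mean()
    denom = np.sqrt((xa**2).sum() * (xb**2).sum())
    ncc = float((xa * xb).sum() / denom) if denom > 0 else 0.0
    return ColocResult(
        nonoverlap_percent=float(nonoverlap),
        ncc=ncc,
        n_voxels_a=n_a,
        n_voxels_b=n_b,
        n_overlap=n_overlap,
        nonoverlap_percent_per_channel=float(per_channel),
    )
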