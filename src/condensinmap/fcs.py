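"""FCS-calibrated protein counting with bound/soluble correction.

An experiment-specific calibration line maps fluorescence intensity to
concentration, concentration maps are integrated over cell and
chromatin masks, and the chromatin-bound pool is separated from the
freely diffusing pool.  While the nuclear envelope is open (NEBD to end
of anaphase) the free concentration inside the chromatin volume equals
the cytoplasmic concentration:

    [Chr]_c = [Chr] - [Cyt]                      (bound concentration)
    N_Chr^c = [Chr]_c * V_Chr * N_A              (bound copies)
    N_Cyt   = ([Cyt] V_Cyt + [Cyt] V_Chr) * N_A  (soluble copies)

Before NEBD (prophase) a binding equilibrium with constant Kd,
estimated from metaphase concentrations Kd = [Cyt]/[Chr]_c, gives

    [Chr]_bg = Kd/(1+Kd) [Chr],   [Chr]_c = [Chr]/(1+Kd).

After nuclear envelope reformation only the total nuclear count is
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .stack import ImageStack
from .units import NM_UM3_TO_MOLECULES

PHASES = ("prophase", "NEBD_to_anaphase", "post_reformation")


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine intensity-to-concentration map: C = slope * (I - background)."""

    slope: float  # nM per intensity unit
    background_intensity: float
    fit_residual_scale: float
    n_points: int

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be > 0")
        if self.n_points < 2:
            raise ValueError("calibration needs >= 2 points")


def fit_calibration(pairs) -> CalibrationCurve:
    """Robust line fit of concentration against intensity.

    ``pairs`` is an iterable of (intensity, concentration_nM).  Uses an
    iteratively reweighted robust regression (Huber M-estimator), so a
    minority of gross outliers does not bias the calibration.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need >= 2 (intensity, concentration) pairs")
    intensity, conc = arr[:, 0], arr[:, 1]
    if np.ptp(intensity) == 0:
        raise ValueError("all intensities identical: singular calibration fit")
    X = sm.add_constant(intensity)
    res = sm.RLM(conc, X, M=sm.robust.norms.HuberT()).fit()
    intercept, slope = res.params
    if slope <= 0:
        raise ValueError(f"non-positive calibration slope ({slope:.3g})")
    return CalibrationCurve(
        slope=float(slope),
        background_intensity=float(-intercept / slope),
        fit_residual_scale=float(res.scale),
        n_points=len(arr),
    )


def intensity_to_concentration(stack: ImageStack, curve: CalibrationCurve) -> ImageStack:
    """Voxelwise affine transform to nM; negative values floored at 0."""
    if stack.data.ndim != 3:
        raise ValueError("expected a single-channel (z, y, x) stack")
    conc = curve.slope * (stack.data.astype(float) - curve.background_intensity)
    np.clip(conc, 0.0, None, out=conc)
    return ImageStack(conc, stack.voxel_size_nm, meta={**stack.meta, "units": "nM"})


@dataclass
class CompartmentQuant:
    """Per-timepoint compartment volumes, concentrations and copy numbers."""

    V_Chr_um3: float
    V_Cyt_um3: float
    conc_Chr_nM: float
    conc_Cyt_nM: float
    N_total: float
    phase_label: str | None = None
    conc_Chr_bound_nM: float | None = None
    conc_Chr_bg_nM: float | None = None
    N_Chr_bound: float | None = None
    N_Cyt: float | None = None
    N_nuclear: float | None = None
    Kd: float | None = None
    flags: list[str] = field(default_factory=list)


def quantify_compartments(
    conc_map: ImageStack, cell_mask: np.ndarray, chromatin_mask: np.ndarray
) -> CompartmentQuant:
    """Volumes, mean concentrations and total count from a concentration map.

    The cytoplasmic region is the cell mask minus the chromatin region
    (XOR); volumes come from voxel counts times the voxel volume.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    chromatin_mask = np.asarray(chromatin_mask, dtype=bool)
    if not cell_mask.any() or not chromatin_mask.any():
        raise ValueError("empty cell or chromatin mask")
    if np.any(chromatin_mask & ~cell_mask):
        raise ValueError("chromatin mask must be a subset of the cell mask")
    cyto_mask = cell_mask & ~chromatin_mask
    if not cyto_mask.any():
        raise ValueError("cytoplasmic region is empty")
    vol = conc_map.voxel_volume_um3
    conc = conc_map.data
    V_Chr = float(chromatin_mask.sum()) * vol
    V_Cyt = float(cyto_mask.sum()) * vol
    return CompartmentQuant(
        V_Chr_um3=V_Chr,
        V_Cyt_um3=V_Cyt,
        conc_Chr_nM=float(conc[chromatin_mask].mean()),
        conc_Cyt_nM=float(conc[cyto_mask].mean()),
        N_total=float(conc[cell_mask].sum()) * vol * NM_UM3_TO_MOLECULES,
    )


def kd_from_metaphase(quant: CompartmentQuant) -> float:
    """Equilibrium constant Kd = [Cyt]/([Chr] - [Cyt]) from a metaphase cell."""
    bound = quant.conc_Chr_nM - quant.conc_Cyt_nM
    if bound <= 0:
        raise ValueError("metaphase chromatin concentration must exceed cytoplasmic")
    return quant.conc_Cyt_nM / bound


def correct_bound_fraction(
    quant: CompartmentQuant, phase_label: str, Kd: float | None = None
) -> CompartmentQuant:
    """Separate chromatin-bound from freely diffusing copies.

    ``phase_label`` selects the regime; for ``prophase`` a Kd estimated
    from a metaphase cell of the same experiment must be supplied.
    """
    if phase_label not in PHASES:
        raise ValueError(f"phase_label must be one of {PHASES}")
    q = CompartmentQuant(**{**quant.__dict__})
    q.phase_label = phase_label
    q.flags = list(quant.flags)
    conv = NM_UM3_TO_MOLECULES

    if phase_label == "NEBD_to_anaphase":
        q.conc_Chr_bg_nM = q.conc_Cyt_nM
        bound = q.conc_Chr_nM - q.conc_Cyt_nM
        if bound < 0:
            bound = 0.0
            q.flags.append("negative_bound_concentration_floored")
        q.conc_Chr_bound_nM = bound
        q.N_Chr_bound = bound * q.V_Chr_um3 * conv
        q.N_Cyt = q.conc_Cyt_nM * (q.V_Cyt_um3 + q.V_Chr_um3) * conv
    elif phase_label == "prophase":
        if Kd is None:
            raise ValueError("prophase correction requires a metaphase-derived Kd")
        q.Kd = Kd
        q.conc_Chr_bg_nM = Kd / (1.0 + Kd) * q.conc_Chr_nM
        q.conc_Chr_bound_nM = q.conc_Chr_nM / (1.0 + Kd)
        q.N_Chr_bound = q.conc_Chr_bound_nM * q.V_Chr_um3 * conv
        q.N_Cyt = q.conc_Cyt_nM * q.V_Cyt_um3 * conv + q.conc_Chr_bg_nM * q.V_Chr_um3 * conv
    else:  # post_reformation: bound/free split not identifiable
        q.N_nuclear = q.conc_Chr_nM * q.V_Chr_um3 * conv
        q.conc_Chr_bound_nM = None
        q.conc_Chr_bg_nM = None
        q.N_Chr_bound = None
        q.N_Cyt = None
    return q
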