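"""FRAP analysis of Condensin exchange on metaphase chromosomes.

A half-plate bleach of the chromatin region yields bleached and
unbleached signals whose DNA-weighted means are

    F_b(t)  = sum_x P_b(x,t) D_b(x,t) / sum_x D_b(x,t)      (and F_ub alike)

The normalized difference (F_ub - F_b)/(F_ub(0) - F_b(0)) cancels all
photobleaching terms and, for a binding equilibrium with constant total
protein, follows the single-exponential exchange model

    f(t) = a + (1 - a) exp(-(kappa + k_off) t)

with immobile fraction ``a`` and combined rate kappa + k_off (kappa =
k_on * B is the forward rate constant times the number of binding
sites; only the combination is identifiable here).  The residence time
is tau = 1/(kappa + k_off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize


def exchange_model(t_min: np.ndarray, a: float, rate_per_min: float) -> np.ndarray:
    """Normalized unbleached-bleached difference at time ``t_min`` (minutes)."""
    t_min = np.asarray(t_min, dtype=float)
    return a + (1.0 - a) * np.exp(-rate_per_min * t_min)


def exchanged_fraction(a: float, rate_per_min: float, t_min: float) -> float:
    """Fraction of the initially bound pool exchanged after ``t_min`` minutes."""
    return (1.0 - a) * (1.0 - np.exp(-rate_per_min * t_min))


@dataclass
class FrapSeries:
    """One cell's bleach/unbleach trajectory.

    ``t_s`` are acquisition times in seconds (t=0 is the first
    post-bleach frame); ``norm_diff`` is anchored to 1 at t=0 when
    produced by :func:`extract_frap_profiles`.
    """

    t_s: np.ndarray
    norm_diff: np.ndarray
    F_b: np.ndarray | None = None
    F_ub: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.norm_diff = np.asarray(self.norm_diff, dtype=float)
        if self.t_s.shape != self.norm_diff.shape:
            raise ValueError("t and norm_diff must have equal length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def t_min(self) -> np.ndarray:
        return self.t_s / 60.0


@dataclass
class FrapFit:
    """Fitted exchange-model parameters for one cell or a pooled set."""

    a: float
    rate_per_min: float
    flags: list[str] = field(default_factory=list)
    bootstrap_a: np.ndarray | None = None
    bootstrap_rate: np.ndarray | None = None

    @property
    def tau_min(self) -> float:
        return 1.0 / self.rate_per_min

    def exchanged_frac(self, t_min: float) -> float:
        return exchanged_fraction(self.a, self.rate_per_min, t_min)


def extract_frap_profiles(
    protein_stack: np.ndarray,
    dna_stack: np.ndarray,
    bleach_roi: np.ndarray,
    dt_s: float,
    gap_px: int = 14,
    prefilter_sigma: float = 1.0,
) -> FrapSeries:
    """Extract the normalized difference trajectory from a 2D time series.

    ``protein_stack``/``dna_stack`` are ``(t, y, x)``; ``bleach_roi`` is a
    boolean ``(y, x)`` mask of the bleached region.  Pixels are split into
    bleached/unbleached chromatin along the chromatin's major 2D axis
    (principal axis of the mask's second moments); a central gap of
    ``gap_px`` pixels around the bleach boundary is excluded to avoid
    boundary effects.  A Gaussian prefilter denoises both channels before
    profile extraction.
    """
    protein_stack = np.asarray(protein_stack, dtype=float)
    dna_stack = np.asarray(dna_stack, dtype=float)
    bleach_roi = np.asarray(bleach_roi, dtype=bool)
    if protein_stack.shape != dna_stack.shape or protein_stack.ndim != 3:
        raise ValueError("protein and DNA stacks must be (t, y, x) with equal shape")

    from skimage.filters import threshold_otsu

    dna_ref = dna_stack.mean(axis=0)
    mask = dna_ref > threshold_otsu(dna_ref)
    if not mask.any():
        raise ValueError("chromatin segmentation produced an empty mask")

    # principal axis of the chromatin mask's second moments
    yy, xx = np.nonzero(mask)
    coords = np.column_stack([yy, xx]).astype(float)
    coords -= coords.mean(axis=0)
    cov = coords.T @ coords / len(coords)
    evals, evecs = np.linalg.eigh(cov)
    axis_vec = evecs[:, np.argmax(evals)]
    s = coords @ axis_vec  # 1D coordinate along the major axis

    in_roi = bleach_roi[yy, xx]
    if not in_roi.any() or in_roi.all():
        raise ValueError("bleach ROI must cover part (not all) of the chromatin")
    # boundary between bleached and unbleached halves along the axis
    s_bleach, s_rest = s[in_roi], s[~in_roi]
    s0 = 0.5 * (
        (s_bleach.max() + s_rest.min())
        if s_bleach.mean() < s_rest.mean()
        else (s_rest.max() + s_bleach.min())
    )
    keep = np.abs(s - s0) > gap_px / 2.0
    sel_b = in_roi & keep
    sel_ub = ~in_roi & keep
    if not sel_b.any() or not sel_ub.any():
        raise ValueError("gap exclusion removed all pixels from one side")

    n_t = protein_stack.shape[0]
    F_b = np.empty(n_t)
    F_ub = np.empty(n_t)
    for ti in range(n_t):
        P = ndimage.gaussian_filter(protein_stack[ti], prefilter_sigma)
        D = ndimage.gaussian_filter(dna_stack[ti], prefilter_sigma)
        Pm, Dm = P[yy, xx], D[yy, xx]
        F_b[ti] = np.sum(Pm[sel_b] * Dm[sel_b]) / np.sum(Dm[sel_b])
        F_ub[ti] = np.sum(Pm[sel_ub] * Dm[sel_ub]) / np.sum(Dm[sel_ub])

    denom = F_ub[0] - F_b[0]
    if denom == 0:
        raise ZeroDivisionError("F_ub(0) == F_b(0): normalization undefined")
    # The half-bleach protocol conserves F_ub + F_b under exchange, so
    # dividing the difference by the per-frame total is a no-op without
    # photobleaching and cancels any common acquisition decay exactly.
    total = F_ub + F_b
    norm_diff = (F_ub - F_b) / total * (total[0] / denom)
    t = np.arange(n_t) * dt_s
    return FrapSeries(t_s=t, norm_diff=norm_diff, F_b=F_b, F_ub=F_ub)


def fit_recovery(series: FrapSeries | list[FrapSeries]) -> FrapFit:
    """Least-squares fit of the exchange model to normalized differences.

    Accepts one series or a list (pooled fit).  Initialization a=0.5,
    rate=1/min; bounds a in [0, 1], rate > 0.
    """
    if isinstance(series, FrapSeries):
        series = [series]
    t = np.concatenate([s.t_min for s in series])
    y = np.concatenate([s.norm_diff for s in series])
    if len(t) < 10:
        raise ValueError("need >= 10 frames to fit the exchange model")

    try:
        popt, _ = optimize.curve_fit(
            exchange_model,
            t,
            y,
            p0=(0.5, 1.0),
            bounds=([0.0, 1e-9], [1.0, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"exchange-model fit did not converge: {exc}") from exc
    a, rate = popt
    flags = []
    if not 0.0 <= a <= 1.0:  # defensive: bounds should prevent this
        a = float(np.clip(a, 0.0, 1.0))
        flags.append("immobile_fraction_clipped")
    return FrapFit(a=float(a), rate_per_min=float(rate), flags=flags)


def bootstrap_fit(
    series_collection: list[FrapSeries], n: int = 300, seed: int | None = None
) -> FrapFit:
    """Bootstrap over cells: resample with replacement, refit, n times.

    Returns the pooled fit with per-resample parameter distributions
    attached; medians/IQRs are available via :func:`bootstrap_summary`.
    Resamples whose fit fails are recorded in ``flags`` and excluded.
    """
    if len(series_collection) < 3:
        raise ValueError("bootstrap needs >= 3 cells")
    rng = np.random.default_rng(seed)
    boot_a, boot_rate = [], []
    n_failed = 0
    for _ in range(n):
        idx = rng.integers(0, len(series_collection), size=len(series_collection))
        sample = [series_collection[i] for i in idx]
        try:
            fit = fit_recovery(sample)
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        boot_a.append(fit.a)
        boot_rate.append(fit.rate_per_min)
    pooled = fit_recovery(series_collection)
    pooled.bootstrap_a = np.array(boot_a)
    pooled.bootstrap_rate = np.array(boot_rate)
    if n_failed:
        pooled.flags.append(f"bootstrap_failures:{n_failed}")
    return pooled


def bootstrap_summary(fit: FrapFit) -> dict:
    """Medians and interquartile ranges of the bootstrap distributions."""
    if fit.bootstrap_a is None or fit.bootstrap_rate is None:
        raise ValueError("fit has no bootstrap distributions")
    tau = 1.0 / fit.bootstrap_rate
    q = lambda x: tuple(np.percentile(x, [25, 50, 75]))  # noqa: E731
    a25, a50, a75 = q(fit.bootstrap_a)
    t25, t50, t75 = q(tau)
    return {
        "a_median": a50,
        "a_iqr": (a25, a75),
        "tau_median_min": t50,
        "tau_iqr_min": (t25, t75),
    }
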