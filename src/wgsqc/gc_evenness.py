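"""GC-bias correction and the FWHM evenness measure.

Sequencing efficiency depends on fragment GC content, so raw windowed
coverage shows a GC-dependent trend, and copy-number aberrations add
discrete coverage clouds on top of it.  The procedure here estimates the
bias with a two-step lowess fit: a first curve through all windows
(normalized coverage vs. window GC) identifies the *main copy-number
state* — the windows whose residuals fall inside the half-maximum
interval of the tallest residual-density peak — and a second curve,
fitted to those windows only, becomes the correction function.  Dividing
normalized coverage by the correction flattens the GC trend without
letting aberrant segments distort it.

The residual spread of the corrected main-state cloud is then summarised
as the full width at half maximum (FWHM) of its kernel density: small
FWHM means even coverage, and the construction makes the statistic
insensitive to both GC bias and copy-number aberrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .alignment_io import DEFAULT_POLICY, FilterPolicy, ReferenceIndex
from .coverage_metrics import CoverageProfile, bin_coverage, build_grid, median_over_mean

__all__ = [
    "GcBiasModel",
    "EvennessMetrics",
    "fit_gc_bias",
    "correct_coverage",
    "fwhm_of_main_state",
    "evenness_metrics",
]

# lowess span and robustifying iterations for both fits; 0.3 is smooth
# enough for a monotone-ish bias curve while tracking its curvature
LOWESS_FRAC = 0.3
LOWESS_IT = 3

MIN_WINDOWS = 200
MIN_GC_RANGE = 0.05
MIN_MASK_FRACTION = 0.10
MIN_MASKED_WINDOWS = 100

KDE_GRIDSIZE = 2048

WINDOW_SIZE_FWHM = 10_000
WINDOW_SIZE_MOM_WIDE = 5_000_000


def _silverman_bandwidth(values: np.ndarray) -> float:
    n = len(values)
    sd = values.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale == 0:
        scale = max(abs(values).max(), 1.0) * 1e-6  # degenerate point mass
    return 0.9 * scale * n ** (-0.2)


def kde_on_grid(values: np.ndarray, gridsize: int = KDE_GRIDSIZE):
    """Gaussian KDE with Silverman bandwidth on a fixed evaluation grid.

    The grid spans the data range extended by 3 bandwidths on each side.
    Returns (grid, density, bandwidth).
    """
    values = np.asarray(values, dtype=float)
    bw = _silverman_bandwidth(values)
    lo, hi = values.min() - 3 * bw, values.max() + 3 * bw
    grid = np.linspace(lo, hi, gridsize)
    # chunked to bound memory on large window counts
    dens = np.zeros(gridsize)
    step = 50_000
    for i in range(0, len(values), step):
        chunk = values[i:i + step]
        z = (grid[:, None] - chunk[None, :]) / bw
        dens += np.exp(-0.5 * z * z).sum(axis=1)
    dens /= len(values) * bw * np.sqrt(2 * np.pi)
    return grid, dens, bw


def _cross(grid, dens, i_lo, i_hi, level):
    """Linear interpolation of the level crossing between two grid points."""
    x0, x1 = grid[i_lo], grid[i_hi]
    y0, y1 = dens[i_lo], dens[i_hi]
    if y1 == y0:
        return x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def half_max_interval(grid: np.ndarray, dens: np.ndarray):
    """Half-maximum interval around the global density peak.

    Walks outward from the tallest peak to the nearest crossings below
    half its height; crossings are interpolated linearly between grid
    points.  If other peaks rise above the half-max level outside the
    bracket (multimodal density), the nearest crossings are still used
    and a warning is emitted.
    """
    peak = int(np.argmax(dens))
    half = dens[peak] / 2.0
    i = peak
    while i > 0 and dens[i] >= half:
        i -= 1
    left = _cross(grid, dens, i, i + 1, half) if dens[i] < half else grid[0]
    j = peak
    while j < len(dens) - 1 and dens[j] >= half:
        j += 1
    right = _cross(grid, dens, j - 1, j, half) if dens[j] < half else grid[-1]
    outside = np.zeros(len(dens), dtype=bool)
    outside[: i + 1] = True
    outside[j:] = True
    if (dens[outside] > half).any():
        warnings.warn(
            "density is multimodal above half maximum; using the crossings "
            "nearest the main peak",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(left), float(right)


@dataclass
class GcBiasModel:
    """Two-step lowess GC-bias model on a window grid.

    ``fit1`` (all retained windows) locates the main copy-number state;
    ``fit2`` (main-state windows only) is the correction function,
    evaluated by interpolation and clamped to its end values outside the
    fitted GC range.
    """

    fit1_gc: np.ndarray
    fit1_values: np.ndarray
    main_state_mask: np.ndarray  # over retained windows, in grid order
    fit2_gc: np.ndarray
    fit2_values: np.ndarray
    residual_half_max: tuple

    def trend(self, gc) -> np.ndarray:
        return np.interp(gc, self.fit1_gc, self.fit1_values)

    def correction(self, gc) -> np.ndarray:
        return np.interp(gc, self.fit2_gc, self.fit2_values)


def _lowess_curve(x: np.ndarray, y: np.ndarray):
    fitted = lowess(y, x, frac=LOWESS_FRAC, it=LOWESS_IT, return_sorted=True)
    gx, gy = fitted[:, 0], fitted[:, 1]
    # collapse ties in x so np.interp sees strictly increasing abscissae
    ux, inv = np.unique(gx, return_inverse=True)
    uy = np.zeros(len(ux))
    counts = np.zeros(len(ux))
    np.add.at(uy, inv, gy)
    np.add.at(counts, inv, 1)
    return ux, uy / counts


def fit_gc_bias(profile: CoverageProfile) -> GcBiasModel:
    """Fit the two-step lowess GC-bias model to a 10 kb coverage profile."""
    gc = profile.grid.gc_fraction[profile.retained]
    norm = profile.normalized[profile.retained]
    if len(gc) < MIN_WINDOWS:
        raise ValueError(
            f"GC-bias fit needs at least {MIN_WINDOWS} retained windows, got {len(gc)}"
        )
    if gc.max() - gc.min() <= MIN_GC_RANGE:
        raise ValueError("degenerate GC range across windows")
    f1x, f1y = _lowess_curve(gc, norm)
    residuals = norm - np.interp(gc, f1x, f1y)
    grid, dens, _ = kde_on_grid(residuals)
    lo, hi = half_max_interval(grid, dens)
    mask = (residuals >= lo) & (residuals <= hi)
    if mask.sum() < MIN_MASK_FRACTION * len(gc):
        raise ValueError("main copy-number state holds <10% of retained windows")
    f2x, f2y = _lowess_curve(gc[mask], norm[mask])
    if np.interp(gc, f2x, f2y).min() <= 0:
        raise ValueError("GC correction is non-positive on the observed GC range")
    return GcBiasModel(
        fit1_gc=f1x, fit1_values=f1y,
        main_state_mask=mask,
        fit2_gc=f2x, fit2_values=f2y,
        residual_half_max=(lo, hi),
    )


def correct_coverage(profile: CoverageProfile, model: GcBiasModel) -> np.ndarray:
    """GC-corrected normalized coverage over retained windows.

    Divides each retained window's normalized coverage by the correction
    function at its GC; main-state windows then centre on 1.
    """
    gc = profile.grid.gc_fraction[profile.retained]
    if len(gc) != len(model.main_state_mask):
        raise ValueError("model was fitted on a different grid")
    corr = model.correction(gc)
    if np.min(corr) <= 0:
        raise ValueError("non-positive correction at some window's GC")
    return profile.normalized[profile.retained] / corr


def fwhm_of_main_state(corrected: np.ndarray, mask: np.ndarray) -> float:
    """FWHM of the corrected coverage density over main-state windows."""
    values = np.asarray(corrected)[np.asarray(mask, dtype=bool)]
    if len(values) < MIN_MASKED_WINDOWS:
        raise ValueError(
            f"FWHM needs at least {MIN_MASKED_WINDOWS} main-state windows, got {len(values)}"
        )
    grid, dens, _ = kde_on_grid(values)
    lo, hi = half_max_interval(grid, dens)
    return hi - lo


@dataclass
class EvennessMetrics:
    """The evenness summary of one sample: MoM on both grids, and FWHM."""

    mom_10kb: float
    mom_5mb: float
    fwhm: float


def evenness_metrics(bam_path, policy: FilterPolicy = DEFAULT_POLICY,
                     ref: ReferenceIndex = None) -> EvennessMetrics:
    """Full evenness pipeline for one BAM.

    Bins coverage on the 10 kb and 5 Mb grids, fits and applies the
    GC-bias correction on the 10 kb grid, and computes FWHM of the
    corrected main-state coverage plus MoM on both grids.  The pass/fail
    decision downstream uses the 10 kb MoM; the 5 Mb value is reported
    for diagnostics.
    """
    if ref is None:
        raise ValueError("a ReferenceIndex is required")
    grid10 = build_grid(ref, WINDOW_SIZE_FWHM)
    grid5m = build_grid(ref, WINDOW_SIZE_MOM_WIDE)
    prof10 = bin_coverage(bam_path, policy, grid10)
    prof5m = bin_coverage(bam_path, policy, grid5m)
    model = fit_gc_bias(prof10)
    corrected = correct_coverage(prof10, model)
    fwhm = fwhm_of_main_state(corrected, model.main_state_mask)
    return EvennessMetrics(
        mom_10kb=median_over_mean(prof10),
        mom_5mb=median_over_mean(prof5m),
        fwhm=fwhm,
    )
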