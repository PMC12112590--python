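"""Wave-profile spline fitting and elongation-rate estimation.

A cubic smoothing spline is fitted to each TSS-anchored profile. Two
landmarks are extracted:

* **peak** — the argmax of the fitted curve beyond an exclusion zone (the
  zone skips residual pause-site signal; it is disabled at t = 0, where the
  pause peak *is* the wave origin). Ties break to the smallest coordinate.
* **front** — the most distal position at which the fitted curve drops
  below a fraction (default 10%) of the peak height, searching downstream
  of the peak. Under pulse-release kinetics with whole-interval labeling
  the labeled-RNA profile is a plateau that ends at the wave front, so the
  front is the landmark that moves at the elongation speed; the peak is
  kept for profiles with an interior mode.

The elongation rate is the ordinary-least-squares slope of landmark
position (bp) against time (min), reported in kb/min — either on metagene
profiles or per gene with the across-gene dispersion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline

from .coverage import CoverageMatrix, MetageneProfile, metagene
from .errors import EstimationError, ParameterError

logger = logging.getLogger(__name__)

FEATURES = ("peak", "front")


@dataclass
class WaveFit:
    """A smoothed wave profile with located landmarks."""

    timepoint_min: float
    bin_centers_bp: np.ndarray
    smoothed: np.ndarray
    peak_pos_bp: float | None
    peak_height: float
    front_pos_bp: float | None
    smoothing_parameter: float
    exclusion_zone_bp: float
    has_peak: bool = True

    def landmark(self, feature: str) -> float | None:
        if feature not in FEATURES:
            raise ParameterError(f"unknown wave feature {feature!r}")
        return self.peak_pos_bp if feature == "peak" else self.front_pos_bp


@dataclass
class RateEstimate:
    """Elongation rate from landmark positions across timepoints."""

    rate_kb_per_min: float
    intercept_bp: float
    timepoints_used: list[float]
    feature: str = "peak"
    per_gene_rates: np.ndarray | None = None
    sd_across_genes: float | None = None
    n_genes: int = 0
    n_excluded: int = 0


def _default_smoothing(y: np.ndarray) -> float:
    """Noise-proportional smoothing: n * sigma^2 with sigma estimated
    robustly from first differences (median absolute difference), so sharp
    genuine structure such as a promoter spike does not inflate the
    smoothing. Scale-equivariant: depth rescaling cannot move the argmax."""
    n = len(y)
    if n < 3:
        return 0.0
    # second differences cancel smooth trend, so a noiseless curve gets
    # (near-)zero smoothing while iid noise contributes variance 6*sigma^2
    d2 = np.diff(y, n=2)
    sigma = float(np.median(np.abs(d2))) / (0.6745 * np.sqrt(6.0))
    return n * sigma**2


def fit_wave(
    profile: MetageneProfile | tuple[np.ndarray, np.ndarray],
    timepoint_min: float = 0.0,
    smoothing: float | None = None,
    exclusion_zone_bp: float = 500.0,
    front_fraction: float = 0.1,
    grid_per_bin: int = 20,
) -> WaveFit:
    """Fit a cubic smoothing spline and locate the wave peak and front.

    ``profile`` is a :class:`MetageneProfile` or a ``(bin_centers, values)``
    pair (e.g. one gene's matrix row). A flat-zero profile yields a flagged
    no-peak fit rather than an exception.
    """
    if isinstance(profile, MetageneProfile):
        x = np.asarray(profile.bin_centers_bp, dtype=float)
        y = np.asarray(profile.mean_signal, dtype=float)
    else:
        x, y = (np.asarray(a, dtype=float) for a in profile)
    if len(x) != len(y):
        raise ParameterError("bin centers and values must align")
    if len(x) < 10:
        raise ParameterError("need at least 10 bins to fit a wave")
    if np.any(y < 0):
        raise ParameterError("wave profiles must be non-negative")
    if exclusion_zone_bp < 0:
        raise ParameterError("exclusion_zone_bp must be non-negative")
    s = _default_smoothing(y) if smoothing is None else float(smoothing)
    # A tiny positive s makes FITPACK's knot search unstable; a profile that
    # is noiseless to working precision is better interpolated exactly.
    if smoothing is None and y.max() > 0 and s < 1e-10 * len(y) * y.max() ** 2:
        s = 0.0
    if y.max() <= 0:
        return WaveFit(
            timepoint_min=timepoint_min,
            bin_centers_bp=x,
            smoothed=np.zeros_like(y),
            peak_pos_bp=None,
            peak_height=0.0,
            front_pos_bp=None,
            smoothing_parameter=s,
            exclusion_zone_bp=exclusion_zone_bp,
            has_peak=False,
        )
    spline = UnivariateSpline(x, y, k=3, s=s)
    smoothed = np.clip(spline(x), 0.0, None)
    grid = np.linspace(x[0], x[-1], grid_per_bin * len(x))
    curve = np.clip(spline(grid), 0.0, None)
    search = grid > exclusion_zone_bp
    if not search.any():
        raise ParameterError("exclusion zone covers the whole window")
    region = np.where(search, curve, -np.inf)
    peak_idx = int(np.argmax(region))  # first max -> smallest coordinate
    peak_height = float(curve[peak_idx])
    if peak_height <= 0:
        return WaveFit(
            timepoint_min=timepoint_min,
            bin_centers_bp=x,
            smoothed=smoothed,
            peak_pos_bp=None,
            peak_height=0.0,
            front_pos_bp=None,
            smoothing_parameter=s,
            exclusion_zone_bp=exclusion_zone_bp,
            has_peak=False,
        )
    peak_pos = float(grid[peak_idx])
    # front: last crossing below front_fraction * peak, downstream of peak
    thr = front_fraction * peak_height
    tail = curve[peak_idx:]
    below = tail < thr
    if not below.any():
        front_pos = float(grid[-1])  # clamped at window end
    else:
        above = ~below
        crossings = np.flatnonzero(above[:-1] & below[1:])
        if len(crossings) == 0:  # below from the start of the tail
            front_pos = float(grid[peak_idx])
        else:
            front_pos = float(grid[peak_idx + crossings[-1] + 1])
    return WaveFit(
        timepoint_min=timepoint_min,
        bin_centers_bp=x,
        smoothed=smoothed,
        peak_pos_bp=peak_pos,
        peak_height=peak_height,
        front_pos_bp=front_pos,
        smoothing_parameter=s,
        exclusion_zone_bp=exclusion_zone_bp,
        has_peak=True,
    )


def fit_wave_at_timepoint(
    profile,
    timepoint_min: float,
    exclusion_zone_bp: float = 500.0,
    **kwargs,
) -> WaveFit:
    """fit_wave with the exclusion zone disabled at t = 0, where the
    pause-site peak is the legitimate wave origin."""
    zone = 0.0 if timepoint_min == 0 else exclusion_zone_bp
    return fit_wave(profile, timepoint_min=timepoint_min, exclusion_zone_bp=zone, **kwargs)


def estimate_rate(
    fits: Sequence[WaveFit],
    timepoints: Sequence[float] | None = None,
    feature: str = "peak",
) -> RateEstimate:
    """OLS of landmark position (bp) on time (min); rate in kb/min.

    With exactly two timepoints this reduces to the two-point slope.
    """
    if feature not in FEATURES:
        raise ParameterError(f"unknown wave feature {feature!r}")
    pts = []
    for fit in fits:
        if timepoints is not None and fit.timepoint_min not in timepoints:
            continue
        pos = fit.landmark(feature)
        if fit.has_peak and pos is not None:
            pts.append((fit.timepoint_min, pos))
    times = sorted({t for t, _ in pts})
    if len(times) < 2:
        raise EstimationError(
            f"need valid fits at >=2 distinct timepoints, got {len(times)}"
        )
    t_arr = np.array([t for t, _ in pts], dtype=float)
    p_arr = np.array([p for _, p in pts], dtype=float)
    slope, intercept = np.polyfit(t_arr, p_arr, 1)
    return RateEstimate(
        rate_kb_per_min=float(slope) / 1000.0,
        intercept_bp=float(intercept),
        timepoints_used=times,
        feature=feature,
    )


def metagene_rate(
    matrices: Mapping[float, CoverageMatrix],
    timepoints: Sequence[float] | None = None,
    feature: str = "peak",
    smoothing: float | None = None,
    exclusion_zone_bp: float = 500.0,
    front_fraction: float = 0.1,
) -> tuple[RateEstimate, list[WaveFit]]:
    """Fit the metagene profile at each timepoint and regress the landmark."""
    fits = []
    for tp in sorted(matrices):
        if timepoints is not None and tp not in timepoints:
            continue
        prof = metagene(matrices[tp])
        fits.append(
            fit_wave_at_timepoint(
                prof,
                tp,
                smoothing=smoothing,
                exclusion_zone_bp=exclusion_zone_bp,
                front_fraction=front_fraction,
            )
        )
    est = estimate_rate(fits, timepoints=timepoints, feature=feature)
    return est, fits


def per_gene_rates(
    matrices: Mapping[float, CoverageMatrix],
    timepoints: Sequence[float] | None = None,
    feature: str = "peak",
    smoothing: float | None = None,
    exclusion_zone_bp: float = 500.0,
    front_fraction: float = 0.1,
) -> RateEstimate:
    """Per-gene landmark regression; genes lacking a peak at any timepoint
    are excluded and counted."""
    tps = sorted(tp for tp in matrices if timepoints is None or tp in timepoints)
    if len(tps) < 2:
        raise EstimationError("need matrices at >=2 timepoints")
    gene_ids = matrices[tps[0]].gene_ids
    for tp in tps[1:]:
        if matrices[tp].gene_ids != gene_ids:
            raise ParameterError("matrices must share one gene set")
    positions = np.full((len(gene_ids), len(tps)), np.nan)
    for j, tp in enumerate(tps):
        mat = matrices[tp]
        centers = mat.bin_centers_bp
        for i in range(len(gene_ids)):
            fit = fit_wave_at_timepoint(
                (centers, mat.values[i]),
                tp,
                smoothing=smoothing,
                exclusion_zone_bp=exclusion_zone_bp,
                front_fraction=front_fraction,
            )
            pos = fit.landmark(feature) if fit.has_peak else None
            if pos is not None:
                positions[i, j] = pos
    valid = ~np.isnan(positions).any(axis=1)
    n_excluded = int((~valid).sum())
    if not valid.any():
        raise EstimationError("every gene was excluded (no valid peaks)")
    t_arr = np.array(tps, dtype=float)
    design = np.vstack([t_arr, np.ones_like(t_arr)]).T
    coef, *_ = np.linalg.lstsq(design, positions[valid].T, rcond=None)
    rates = coef[0] / 1000.0
    mean_rate = float(rates.mean())
    sd = float(rates.std(ddof=1)) if len(rates) > 1 else None
    intercept = float(coef[1].mean())
    return RateEstimate(
        rate_kb_per_min=mean_rate,
        intercept_bp=intercept,
        timepoints_used=list(tps),
        feature=feature,
        per_gene_rates=rates,
        sd_across_genes=sd,
        n_genes=int(valid.sum()),
        n_excluded=n_excluded,
    )
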