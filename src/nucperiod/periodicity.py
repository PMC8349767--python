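"""Lomb-Scargle quantification of nucleosome mutational periodicity.

The per-offset count (or normalized rate) series is treated as a signal
sampled at integer dyad offsets.  A least-squares (Lomb-Scargle) periodogram
is used rather than an FFT because normalization can leave undefined
positions, making the effective sampling uneven.  Periodicity strength is
summarized as a signal-to-noise ratio: power at the peak period divided by
the median power at periods outside a +/-0.5 bp exclusion zone around the
peak.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
from scipy.signal import lombscargle as _scipy_lombscargle

from .counting import DyadRelativeCounts, require_minimum_mapped
from .errors import NucperiodError
from .normalization import NormalizedCounts

logger = logging.getLogger(__name__)

_MIN_POINTS = 8


@dataclass
class AnalysisConfig:
    """Parameters of one periodicity analysis.

    mode "rotational" scans periods 5-25 bp within a single nucleosome
    (radius 73); "translational" scans 50-250 bp across nucleosome arrays
    (radius 1000).  The frequency grid spacing is 1/(oversampling * span);
    smoothing_window applies to display only, never before SNR/period
    computation.
    """

    mode: str
    radius: int
    period_min: float
    period_max: float
    oversampling: int = 100
    snr_exclusion_halfwidth: float = 0.5
    min_mutations: int = 5000
    smoothing_window: int = 11

    def __post_init__(self):
        if self.mode not in ("rotational", "translational", "custom"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.period_min < self.period_max <= 2 * self.radius:
            raise ValueError(
                "periods must satisfy 0 < period_min < period_max <= 2*radius"
            )
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        if self.snr_exclusion_halfwidth <= 0:
            raise ValueError("snr_exclusion_halfwidth must be positive")
        if self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd")

    @classmethod
    def rotational(cls, **overrides) -> "AnalysisConfig":
        cfg = cls(mode="rotational", radius=73, period_min=5.0, period_max=25.0)
        return replace(cfg, **overrides) if overrides else cfg

    @classmethod
    def translational(cls, **overrides) -> "AnalysisConfig":
        cfg = cls(mode="translational", radius=1000, period_min=50.0, period_max=250.0)
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class Periodogram:
    """Normalized Lomb-Scargle powers over a period grid, with peak and SNR.

    periods increase (frequencies decrease) along the grid; power is the
    standard least-squares power in [0, 1] relative to the series variance.
    """

    periods: np.ndarray
    power: np.ndarray
    peak_period: float
    peak_power: float
    snr: float | None = None
    n_mutations_mapped: int | None = None
    config: AnalysisConfig | None = field(default=None, repr=False)

    @property
    def grid_step_frequency(self) -> float:
        """Spacing of the underlying frequency grid (cycles/bp)."""
        f = 1.0 / self.periods
        return float(abs(f[0] - f[1]))


def lomb_scargle(
    offsets: np.ndarray, values: np.ndarray, config: AnalysisConfig
) -> Periodogram:
    """Normalized Lomb-Scargle periodogram of a dyad-offset series.

    NaN values (offsets where normalization was undefined) are omitted from
    the fit.  The series is mean-subtracted; power uses the standard
    least-squares normalization (fraction of variance explained by the best
    sinusoid at each trial frequency).  Ties in maximum power break toward
    the longer period.
    """
    offsets = np.asarray(offsets, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = ~np.isnan(values)
    x, y = offsets[keep], values[keep]
    if len(x) < _MIN_POINTS:
        raise NucperiodError(
            f"only {len(x)} defined positions; at least {_MIN_POINTS} needed for a periodogram"
        )
    span = x.max() - x.min()
    df = 1.0 / (config.oversampling * span)
    freqs = np.arange(1.0 / config.period_max, 1.0 / config.period_min + 0.5 * df, df)
    periods = 1.0 / freqs[::-1]  # ascending periods = descending frequencies

    y_centered = y - y.mean()
    if np.allclose(y_centered, 0.0):
        logger.warning("constant series: periodogram is identically zero")
        power = np.zeros_like(periods)
    else:
        power = _scipy_lombscargle(x, y_centered, 2.0 * np.pi * freqs, normalize=True)[::-1]
        power = np.clip(power, 0.0, None)

    peak_power = float(power.max())
    peak_candidates = np.nonzero(power == peak_power)[0]
    peak_idx = int(peak_candidates[-1])  # tie -> longer period
    return Periodogram(
        periods=periods,
        power=power,
        peak_period=float(periods[peak_idx]),
        peak_power=peak_power,
        config=config,
    )


def compute_snr(periodogram: Periodogram, exclusion_halfwidth: float = 0.5) -> float:
    """Peak power divided by the median power at off-peak periods.

    Periods within +/-exclusion_halfwidth bp of the peak period are excluded
    from the noise estimate.  A perfectly flat periodogram yields SNR 1.
    """
    off_peak = np.abs(periodogram.periods - periodogram.peak_period) > exclusion_halfwidth
    if off_peak.sum() < 3:
        raise NucperiodError(
            "fewer than 3 periods outside the exclusion zone; cannot estimate noise"
        )
    noise = float(np.median(periodogram.power[off_peak]))
    if noise == 0.0:
        return 1.0 if periodogram.peak_power == 0.0 else float("inf")
    return float(periodogram.peak_power / noise)


def smooth_for_display(values: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges.

    Display-only: SNR and peak period are always computed on the unsmoothed
    series.  NaN entries are ignored within each window (a window of all
    NaNs stays NaN).
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    filled = np.where(finite, values, 0.0)
    kernel = np.ones(window)
    sums = np.convolve(filled, kernel, mode="same")
    counts = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = sums / counts
    out[counts == 0] = np.nan
    return out


SeriesInput = Union[DyadRelativeCounts, NormalizedCounts]


def extract_series(data: SeriesInput) -> tuple[np.ndarray, np.ndarray]:
    """Offset/value series for the periodogram (normalized values when present)."""
    if isinstance(data, NormalizedCounts):
        return data.offsets, data.normalized
    return data.offsets, data.counts.astype(float)


def run_periodicity_analysis(data: SeriesInput, config: AnalysisConfig) -> Periodogram:
    """Gate, fit, and score a dyad-relative series.

    Refuses inputs with fewer dyad-mapped mutations than config.min_mutations,
    then runs the Lomb-Scargle fit and attaches the SNR.
    """
    if data.radius != config.radius:
        warnings.warn(
            f"series radius {data.radius} differs from config radius {config.radius}",
            stacklevel=2,
        )
    require_minimum_mapped(data, config.min_mutations)
    offsets, values = extract_series(data)
    pg = lomb_scargle(offsets, values, config)
    pg.snr = compute_snr(pg, config.snr_exclusion_halfwidth)
    pg.n_mutations_mapped = data.n_mutations_mapped
    return pg
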