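"""Lagged correlation between membrane-localized fluorescence and tension.

The fluorescence abundance proxy is a band-filtered pixel count: pixels
whose intensity lies within a fixed band around the first peak of the
frame's intensity distribution (membrane-proximal signal, excluding the
small bright internal structures).  The per-frame pixel count and the mean
tension over those pixels are max-1 normalized and correlated with the
tension series lagged by one frame, matching the ~1 min acquisition offset
between the tension and fluorescence channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d


@dataclass(frozen=True)
class BandFilter:
    """Intensity band around the first (membrane) peak of the histogram."""

    mode_intensity: float
    half_width: float

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")


@dataclass
class PairedTrajectory:
    """Max-1-normalized, lag-aligned pixel-count and tension series."""

    times: np.ndarray
    norm_pixel_count: np.ndarray
    norm_tension: np.ndarray
    lag_frames: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times,
                             "norm_pixel_count": self.norm_pixel_count,
                             "norm_tension": self.norm_tension,
                             "lag_frames": self.lag_frames})


def find_first_peak(image_or_values: np.ndarray, bins: int = 256,
                    smooth_sigma: float = 2.0,
                    min_prominence: float = 0.05) -> float:
    """Lowest-intensity prominent maximum of the smoothed histogram.

    The histogram is Gaussian-smoothed (``smooth_sigma`` in bins) and
    searched with a prominence threshold of ``min_prominence`` times the
    histogram maximum, so sampling wiggles in the tails are not mistaken
    for the membrane peak.  Deterministic for fixed smoothing.  If no
    prominent peak exists (monotone/uniform histogram) the global mode is
    returned with a warning.
    """
    from scipy.signal import find_peaks

    values = np.asarray(image_or_values, dtype=float).ravel()
    if values.size < 100:
        raise ValueError("need >= 100 pixels to locate the intensity mode")
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = gaussian_filter1d(counts.astype(float), smooth_sigma)
    peaks, _ = find_peaks(smooth, prominence=min_prominence * smooth.max())
    if len(peaks) == 0:
        warnings.warn("histogram has no interior peak; returning the "
                      "global mode")
        return float(centers[np.argmax(smooth)])
    return float(centers[peaks[0]])


def default_band(image: np.ndarray, band_fraction: float = 0.1,
                 **peak_kwargs) -> BandFilter:
    """Band around the first histogram peak, half-width a fixed fraction
    (default 10%) of the frame's dynamic range."""
    values = np.asarray(image, dtype=float)
    mode = find_first_peak(values, **peak_kwargs)
    half = band_fraction * (values.max() - values.min())
    return BandFilter(mode_intensity=mode, half_width=half)


def band_pixel_count(frame: np.ndarray, band: BandFilter,
                     tension_map: np.ndarray | None = None
                     ) -> tuple[int, float]:
    """Count pixels within the band; optionally their mean tension.

    Returns ``(count, mean_tension)``; the mean tension is NaN when no
    map is supplied or the band is empty (flagged with a warning).
    """
    frame = np.asarray(frame, dtype=float)
    in_band = np.abs(frame - band.mode_intensity) <= band.half_width
    count = int(in_band.sum())
    mean_tension = float("nan")
    if tension_map is not None:
        if tension_map.shape != frame.shape:
            raise ValueError("tension map and frame shapes differ")
        if count == 0:
            warnings.warn("empty intensity band: mean tension undefined")
        else:
            vals = np.asarray(tension_map, dtype=float)[in_band]
            vals = vals[np.isfinite(vals)]
            mean_tension = float(vals.mean()) if len(vals) else float("nan")
    return count, mean_tension


def normalize_max1(series: np.ndarray) -> np.ndarray:
    """Divide by the series maximum so that max equals exactly 1."""
    series = np.asarray(series, dtype=float)
    m = np.nanmax(series)
    if not m > 0:
        raise ValueError("series maximum must be > 0 for max-1 "
                         "normalization")
    return series / m


def lagged_correlation(pixel_counts, tensions, times=None,
                       lag_frames: int = 1, method: str = "pearson"
                       ) -> tuple[float, float, PairedTrajectory]:
    """Correlate normalized pixel count with tension at preceding frames.

    Both series are max-1 normalized; pairs are
    ``(count_t, tension_{t-lag})``.  ``lag_frames=0`` reduces to the
    ordinary synchronous correlation.  Returns (r, two-sided p, paired
    trajectory); Spearman is available via ``method``.
    """
    counts = normalize_max1(np.asarray(pixel_counts, dtype=float))
    tens = normalize_max1(np.asarray(tensions, dtype=float))
    if len(counts) != len(tens):
        raise ValueError("series lengths differ")
    if lag_frames < 0:
        raise ValueError("lag_frames must be >= 0")
    c = counts[lag_frames:]
    t = tens[:len(tens) - lag_frames]
    if len(c) < 4:
        raise ValueError("need >= 4 paired points after lag alignment")
    if np.std(c) == 0 or np.std(t) == 0:
        raise ValueError("zero variance in a series; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(c, t)
    elif method == "spearman":
        r, p = stats.spearmanr(c, t)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    if times is None:
        times = np.arange(len(counts), dtype=float)
    traj = PairedTrajectory(times=np.asarray(times, float)[lag_frames:],
                            norm_pixel_count=c, norm_tension=t,
                            lag_frames=lag_frames)
    return float(r), float(p), traj
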