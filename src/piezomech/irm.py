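"""IRM fluctuation analysis: interferograms -> heights -> PSD -> mechanics.

The analysis chain mirrors the standard fluctuation-tension methodology:

1.  calibrate the interference extrema and keep only first-branch-region
    (FBR) tiles, where intensity is a monotone function of height;
2.  invert the cosine interference relation to per-pixel height series;
3.  estimate the one-sided PSD of each series, by Welch FFT and by the
    autoregressive covariance ("pcov") method with the order chosen to
    best match the FFT estimate;
4.  fit the Helfrich model spectrum in log-log space for
    (sigma, eta_eff, gamma, A) with the bending rigidity kappa held fixed
    at 15 kB*T, yielding tension maps, R^2 maps and SD_time maps;
5.  summarize tension trajectories over time with Mann-Whitney U tests
    against baseline, Bonferroni corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

from piezomech.model import (
    MechanicalParams,
    N_PER_M_TO_PN_PER_UM,
    SpectralGrid,
    helfrich_psd,
    sampled_psd,
)
from piezomech.optics import IRMOptics
from piezomech.stacks import HeightMapStack, ImageStack

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "sigma": (1e-9, 1e-3),      # N/m
    "eta_eff": (1e-3, 1e2),     # Pa*s
    "gamma": (1e0, 1e12),       # N/m^3 (lower bound ~ unconfined)
    "A": (0.1, 100.0),
}


@dataclass
class FluctuationSpectrum:
    """One-sided PSD of a height series, in nm^2/Hz."""

    freqs: np.ndarray
    psd: np.ndarray
    method: str
    fs: float
    n_frames: int
    ar_order: int | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.psd < 0):
            raise ValueError("psd must be >= 0")
        if self.freqs[-1] > self.fs / 2 + 1e-9:
            raise ValueError("freqs exceed Nyquist")

    def band(self, f_lo: float, f_hi: float) -> tuple[np.ndarray, np.ndarray]:
        m = (self.freqs >= f_lo) & (self.freqs <= f_hi) & (self.psd > 0)
        return self.freqs[m], self.psd[m]

    def total_power(self) -> float:
        """Trapezoid-integrated power, nm^2 (Parseval companion of the
        series variance)."""
        return float(np.trapezoid(self.psd, self.freqs))


@dataclass
class FitResult:
    params: MechanicalParams
    r_squared: float
    fit_band: tuple[float, float]
    converged: bool
    residual_rms: float


@dataclass
class FluctuationMap:
    """Per-pixel (or per-tile) maps of fluctuation amplitude and mechanics.

    ``tension`` is in pN/um; failed or excluded entries are NaN and
    flagged in ``mask`` (True = valid).
    """

    sd_time: np.ndarray
    tension: np.ndarray | None = None
    eta_eff: np.ndarray | None = None
    gamma: np.ndarray | None = None
    A: np.ndarray | None = None
    r_squared: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.isfinite(self.sd_time)

    def valid_tensions(self) -> np.ndarray:
        if self.tension is None:
            return np.array([])
        return self.tension[self.mask & np.isfinite(self.tension)]


def calibrate_extrema(stack: ImageStack, lo_pct: float = 0.5,
                      hi_pct: float = 99.5) -> tuple[float, float]:
    """Robust percentile estimate of the interference extrema (i_min, i_max).

    Assumes the stack spans most of the first branch somewhere in the
    field of view.  Raises on a degenerate (flat) stack.
    """
    data = stack.intensity
    i_min, i_max = np.percentile(data, [lo_pct, hi_pct])
    if not i_max > i_min:
        raise ValueError("degenerate stack: intensity extrema coincide")
    return float(i_min), float(i_max)


def select_fbr_regions(stack: ImageStack, optics: IRMOptics,
                       roi_px: int = 4, central_band: float = 0.6
                       ) -> list[tuple[slice, slice]]:
    """Non-overlapping roi_px x roi_px tiles inside the first branch region.

    A tile qualifies when its time-and-space mean intensity lies within
    the central ``central_band`` fraction of [i_min, i_max]; tiles whose
    mean sits near either extreme are too close to an interference
    extremum (membrane at the substrate, or beyond ~100 nm) for the
    cosine inversion to be reliable, mirroring the stringent FBR
    selection of the methodology.
    """
    mean_img = stack.mean_image()
    lo = optics.i_min + (1 - central_band) / 2 * (optics.i_max - optics.i_min)
    hi = optics.i_max - (1 - central_band) / 2 * (optics.i_max - optics.i_min)
    tiles = []
    H, W = mean_img.shape
    for r in range(0, H - roi_px + 1, roi_px):
        for c in range(0, W - roi_px + 1, roi_px):
            sl = (slice(r, r + roi_px), slice(c, c + roi_px))
            m = mean_img[sl].mean()
            if lo <= m <= hi:
                tiles.append(sl)
    if not tiles:
        warnings.warn("no tile passed the FBR selection criterion")
    return tiles


def intensity_to_height(stack: ImageStack, optics: IRMOptics) -> HeightMapStack:
    """Invert the first-branch cosine relation per pixel; heights in nm."""
    h = optics.height_from_intensity(stack.intensity)
    return HeightMapStack(heights=h, dt=stack.dt, pixel_nm=stack.pixel_nm)


def sd_time_map(heights: HeightMapStack) -> FluctuationMap:
    """Per-pixel temporal standard deviation of height (SD_time), nm.

    Sample standard deviation with ddof=1; requires >= 8 frames.
    """
    if heights.n_frames < 8:
        raise ValueError("need >= 8 frames for SD_time")
    sd = heights.heights.std(axis=0, ddof=1)
    return FluctuationMap(sd_time=sd)


def estimate_psd_fft(series: np.ndarray, fs: float) -> FluctuationSpectrum:
    """One-sided Welch PSD of a height series (nm -> nm^2/Hz).

    Mean-detrended Hann-windowed Welch estimate with segment length n/8
    and 50% overlap; the zero-frequency bin is dropped.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be 1D")
    if np.any(~np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    n = len(series)
    if n < 64:
        raise ValueError("need >= 64 frames for a Welch PSD")
    nperseg = max(16, n // 8)
    freqs, psd = signal.welch(series, fs=fs, window="hann", nperseg=nperseg,
                              noverlap=nperseg // 2, detrend="constant")
    return FluctuationSpectrum(freqs=freqs[1:], psd=psd[1:], method="fft",
                               fs=fs, n_frames=n)


def _ar_covariance_fit(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Covariance-method (least-squares, no windowing) AR fit.

    Solves the forward linear prediction problem over t = order..n-1 by
    ordinary least squares; returns (coefficients a_1..a_p, residual
    variance).
    """
    n = len(x)
    X = np.column_stack([x[order - k:n - k] for k in range(1, order + 1)])
    y = x[order:]
    a, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ a
    sigma2 = float(np.mean(resid ** 2))
    return a, sigma2


def ar_psd(a: np.ndarray, sigma2: float, freqs: np.ndarray,
           fs: float) -> np.ndarray:
    """One-sided PSD of an AR process at the given frequencies."""
    _, h = signal.freqz(b=[1.0], a=np.r_[1.0, -a], worN=freqs, fs=fs)
    return 2.0 * sigma2 / fs * np.abs(h) ** 2


def estimate_psd_ar(series: np.ndarray, fs: float,
                    order_range: range = range(4, 41, 2),
                    fit_band: tuple[float, float] | None = None
                    ) -> FluctuationSpectrum:
    """Autoregressive ("pcov") PSD with FFT-matched order selection.

    AR coefficients are estimated by the covariance (least-squares, no
    windowing) method for each candidate order; the returned order
    minimizes the RMS difference of log10 PSD against the Welch estimate
    over the fit band.  The PSD is evaluated on the Welch frequency grid.
    """
    series = np.asarray(series, dtype=float)
    if np.any(~np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    if len(series) <= 2 * max(order_range):
        raise ValueError("series too short for the requested AR orders")
    x = series - series.mean()
    welch = estimate_psd_fft(series, fs)
    if fit_band is None:
        fit_band = (welch.freqs[0], 0.8 * fs / 2)
    f_band, p_band = welch.band(*fit_band)
    best = None
    for order in order_range:
        try:
            a, sigma2 = _ar_covariance_fit(x, order)
            if sigma2 <= 0 or not np.all(np.isfinite(a)):
                continue
            psd_band = ar_psd(a, sigma2, f_band, fs)
            if np.any(psd_band <= 0) or np.any(~np.isfinite(psd_band)):
                continue
            rms = float(np.sqrt(np.mean(
                (np.log10(psd_band) - np.log10(p_band)) ** 2)))
        except np.linalg.LinAlgError:
            continue
        if best is None or rms < best[0]:
            best = (rms, order, a, sigma2)
    if best is None:
        raise ValueError("all AR orders failed")
    _, order, a, sigma2 = best
    psd = ar_psd(a, sigma2, welch.freqs, fs)
    psd = np.clip(psd, 0.0, None)
    return FluctuationSpectrum(freqs=welch.freqs, psd=psd, method="ar",
                               fs=fs, n_frames=len(series), ar_order=order)


_GRID_POINTS = {"sigma": 7, "eta_eff": 6, "gamma": 4, "A": 4}


def _grid_starts(model_fn, f: np.ndarray, log_psd: np.ndarray,
                 kappa: float, temperature_K: float,
                 bounds: dict[str, tuple[float, float]],
                 free: tuple[str, ...], fixed: dict[str, float],
                 n_starts: int) -> list[np.ndarray]:
    """Coarse log-spaced grid search returning the best starting points
    (in log10 space over the free parameters)."""
    axes = []
    for k in free:
        lo, hi = bounds[k]
        if k == "gamma":
            lo = max(lo, 1e2)
        axes.append(np.geomspace(lo, hi, _GRID_POINTS[k]))
    scored = []
    for combo in np.stack(np.meshgrid(*axes, indexing="ij"),
                          axis=-1).reshape(-1, len(free)):
        kw = dict(zip(free, combo))
        kw.update(fixed)
        p = MechanicalParams(kappa=kappa, temperature_K=temperature_K, **kw)
        model = model_fn(f, p, n_q_nodes=64)
        cost = float(np.mean((np.log10(model) - log_psd) ** 2))
        scored.append((cost, np.log10(combo)))
    scored.sort(key=lambda t: t[0])
    return [x for _, x in scored[:n_starts]]


def fit_helfrich(spectrum: FluctuationSpectrum,
                 grid: SpectralGrid | None = None,
                 kappa_kbt: float = 15.0,
                 temperature_K: float = 300.0,
                 bounds: dict[str, tuple[float, float]] | None = None,
                 init: MechanicalParams | None = None,
                 fit_band: tuple[float, float] | None = None,
                 n_starts: int = 5,
                 fix: dict[str, float] | None = None,
                 exposure: float | None = None) -> FitResult:
    """Fit the Helfrich model spectrum for (sigma, eta_eff, gamma, A).

    The fit minimizes log10(model) - log10(PSD) residuals over the fit
    band (default 0.2 Hz to 0.8 * Nyquist, excluding low-frequency drift
    and the camera-noise floor), with kappa held fixed at ``kappa_kbt``
    (default 15 kB*T).  Parameters are optimized in log space within
    bounds, from multiple starting points found by a coarse grid search
    (plus ``init`` if given); the best residual wins.  Fitting in log-log
    space keeps the ~3-decade span of the PSD from being dominated by its
    lowest frequencies.

    ``fix`` holds additional parameters at known values, e.g.
    ``fix={"A": 1.0}`` for a purely thermal drive.  The full
    four-parameter fit has a nearly flat likelihood direction along which
    (sigma, eta_eff, A) trade off against the fixed bending term, so
    per-ROI parameter values from it carry order-of-magnitude
    uncertainties even when the fitted curve is excellent; fixing A
    restores quantitative identifiability of sigma (see the methods
    notes).

    ``exposure`` (fraction of the frame interval the camera integrates,
    typically 1.0) switches the comparison curve to the exposure-averaged,
    alias-folded sampled spectrum, which is the correct model for camera
    data when mode relaxation times approach the frame interval.
    """
    from piezomech.model import kbt_joule

    if grid is None:
        grid = SpectralGrid.from_pixel(fs=spectrum.fs,
                                       n_frames=spectrum.n_frames)
    if bounds is None:
        bounds = DEFAULT_BOUNDS
    if fit_band is None:
        fit_band = (0.2, 0.8 * spectrum.fs / 2)
    fixed = dict(fix) if fix else {}
    keys = tuple(k for k in ("sigma", "eta_eff", "gamma", "A")
                 if k not in fixed)
    if not keys:
        raise ValueError("at least one parameter must be free")
    kappa = kappa_kbt * kbt_joule(temperature_K)
    f, p = spectrum.band(*fit_band)
    if len(f) < 5:
        raise ValueError("fewer than 5 spectral points in the fit band")
    # thin dense grids for speed; the model is smooth in log f
    if len(f) > 80:
        idx = np.unique(np.round(np.geomspace(1, len(f), 80)).astype(int)) - 1
        f, p = f[idx], p[idx]
    log_psd = np.log10(p)

    lo = np.log10([bounds[k][0] for k in keys])
    hi = np.log10([bounds[k][1] for k in keys])

    def make_params(x: np.ndarray) -> MechanicalParams:
        kw = {k: 10.0 ** xi for k, xi in zip(keys, x)}
        kw.update(fixed)
        return MechanicalParams(kappa=kappa, temperature_K=temperature_K,
                                **kw)

    if exposure is None:
        def model_fn(ff, pp, n_q_nodes=200):
            return helfrich_psd(ff, pp, grid, n_q_nodes=n_q_nodes)
    else:
        def model_fn(ff, pp, n_q_nodes=200):
            return sampled_psd(ff, pp, grid, fs=spectrum.fs,
                               exposure=exposure, n_q_nodes=n_q_nodes)

    def residuals(x: np.ndarray) -> np.ndarray:
        return np.log10(model_fn(f, make_params(x))) - log_psd

    starts = _grid_starts(model_fn, f, log_psd, kappa, temperature_K,
                          bounds, keys, fixed, n_starts)
    if init is not None:
        starts.insert(0, np.log10([getattr(init, k) for k in keys]))
    best = None
    any_success = False
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                         method="trf", xtol=1e-10,
                                         ftol=1e-10, max_nfev=400)
        except Exception:
            continue
        any_success = any_success or res.success
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("Helfrich fit failed from every starting point")
    params = make_params(best.x)
    resid = best.fun
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((log_psd - log_psd.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)
    return FitResult(params=params, r_squared=r2, fit_band=fit_band,
                     converged=bool(any_success),
                     residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def fit_height_series(series: np.ndarray, fs: float, method: str = "fft",
                      **fit_kwargs) -> FitResult:
    """PSD estimation plus Helfrich fit of one height series (nm)."""
    if method == "fft":
        spec = estimate_psd_fft(series, fs)
    elif method == "ar":
        spec = estimate_psd_ar(series, fs)
    else:
        raise ValueError("method must be 'fft' or 'ar'")
    return fit_helfrich(spec, **fit_kwargs)


def tile_spectrum(tile_series: np.ndarray, fs: float) -> FluctuationSpectrum:
    """ROI spectrum: per-pixel Welch PSDs averaged over the tile.

    Averaging periodograms over the ROI pixels reduces the spectral
    estimation noise by ~sqrt(n_pixels) without altering the expected
    spectrum, which per-series averaging would do for weakly correlated
    pixels.
    """
    specs = [estimate_psd_fft(s, fs) for s in tile_series]
    psd = np.mean([s.psd for s in specs], axis=0)
    return FluctuationSpectrum(freqs=specs[0].freqs, psd=psd, method="fft",
                               fs=fs, n_frames=specs[0].n_frames)


def tension_map(heights: HeightMapStack, mode: str = "pixel",
                roi_px: int = 4, method: str = "fft",
                mask: np.ndarray | None = None,
                r2_threshold: float = 0.0,
                **fit_kwargs) -> FluctuationMap:
    """Map mechanical parameters over a height stack.

    ``mode='pixel'`` fits every pixel's PSD (the tension-map convention);
    ``mode='tile'`` fits the tile-averaged PSD of non-overlapping
    roi_px x roi_px tiles (the ROI-statistics convention; FFT spectra
    only) and returns tile-resolution maps.  Failing pixels (excluded by
    ``mask``, non-convergent, or with R^2 below ``r2_threshold``) are
    masked, never fatal.  Tension is reported in pN/um.
    """
    h = heights.heights
    if mode not in ("pixel", "tile"):
        raise ValueError("mode must be 'pixel' or 'tile'")
    if mode == "tile" and method != "fft":
        raise ValueError("tile mode averages periodograms and supports "
                         "only method='fft'")
    if mode == "tile":
        T, Hf, Wf = h.shape
        H, W = Hf // roi_px, Wf // roi_px
        if mask is not None:
            tm = mask[:H * roi_px, :W * roi_px]
            mask = tm.reshape(H, roi_px, W, roi_px).all(axis=(1, 3))
    else:
        T, H, W = h.shape
    sd_px = h.std(axis=0, ddof=1)
    if mode == "tile":
        sd = sd_px[:H * roi_px, :W * roi_px].reshape(
            H, roi_px, W, roi_px).mean(axis=(1, 3))
    else:
        sd = sd_px
    maps = {k: np.full((H, W), np.nan) for k in
            ("tension", "eta_eff", "gamma", "A", "r_squared")}
    valid = np.zeros((H, W), dtype=bool)
    for r in range(H):
        for c in range(W):
            if mask is not None and not mask[r, c]:
                continue
            try:
                if mode == "tile":
                    tile = h[:, r * roi_px:(r + 1) * roi_px,
                             c * roi_px:(c + 1) * roi_px]
                    spec = tile_spectrum(tile.reshape(T, -1).T, heights.fs)
                    fit = fit_helfrich(spec, **fit_kwargs)
                else:
                    fit = fit_height_series(h[:, r, c], heights.fs,
                                            method=method, **fit_kwargs)
            except Exception:
                continue
            if not fit.converged or fit.r_squared < r2_threshold:
                continue
            maps["tension"][r, c] = fit.params.sigma * N_PER_M_TO_PN_PER_UM
            maps["eta_eff"][r, c] = fit.params.eta_eff
            maps["gamma"][r, c] = fit.params.gamma
            maps["A"][r, c] = fit.params.A
            maps["r_squared"][r, c] = fit.r_squared
            valid[r, c] = True
    return FluctuationMap(sd_time=sd, tension=maps["tension"],
                          eta_eff=maps["eta_eff"], gamma=maps["gamma"],
                          A=maps["A"], r_squared=maps["r_squared"],
                          mask=valid)


def tension_trajectory(measurements: list[tuple[float, FluctuationMap]],
                       baseline_index: int = 0,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Summarize tension over time and test each point against baseline.

    Returns one row per time point with the median tension over valid
    entries, the IQR, and (for non-baseline points) the two-sided
    Mann-Whitney U p-value against the baseline map, Bonferroni-corrected
    over the number of comparisons.
    """
    if len(measurements) < 2:
        raise ValueError("need >= 2 time points")
    usable = []
    for t, fmap in measurements:
        vals = fmap.valid_tensions()
        if len(vals) == 0:
            warnings.warn(f"time point {t} has no valid ROIs; dropped")
            continue
        usable.append((t, vals))
    base_t, base_vals = usable[baseline_index]
    m = len(usable) - 1
    rows = []
    for i, (t, vals) in enumerate(usable):
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        if i == baseline_index:
            p_raw = p_adj = np.nan
        else:
            p_raw = float(stats.mannwhitneyu(vals, base_vals,
                                             alternative="two-sided").pvalue)
            p_adj = min(1.0, p_raw * m)
        rows.append({"time_min": t, "n_rois": len(vals),
                     "median_tension_pn_um": med, "iqr_pn_um": q3 - q1,
                     "p_raw": p_raw, "p_adj": p_adj,
                     "significant": bool(p_adj < alpha)
                     if np.isfinite(p_adj) else False})
    return pd.DataFrame(rows)


def analyze_irm_stack(stack: ImageStack, optics: IRMOptics,
                      roi_px: int = 4, method: str = "fft",
                      **fit_kwargs) -> pd.DataFrame:
    """FBR tile selection + height inversion + per-tile Helfrich fits.

    Returns one row per selected tile: position, SD_time, fitted
    mechanical parameters and fit quality.
    """
    tiles = select_fbr_regions(stack, optics, roi_px=roi_px)
    heights = intensity_to_height(stack, optics)
    T = heights.n_frames
    rows = []
    for sl in tiles:
        tile = heights.heights[:, sl[0], sl[1]].reshape(T, -1)
        sd = float(tile.std(axis=0, ddof=1).mean())
        try:
            if method == "fft":
                spec = tile_spectrum(tile.T, heights.fs)
                fit = fit_helfrich(spec, **fit_kwargs)
            else:
                fit = fit_height_series(tile.mean(axis=1), heights.fs,
                                        method=method, **fit_kwargs)
        except Exception:
            continue
        rows.append({"row": sl[0].start, "col": sl[1].start,
                     "sd_time_nm": sd,
                     "sigma_pN_per_um":
                         fit.params.sigma * N_PER_M_TO_PN_PER_UM,
                     "eta_eff": fit.params.eta_eff,
                     "gamma": fit.params.gamma, "A": fit.params.A,
                     "r2": fit.r_squared, "converged": fit.converged})
    return pd.DataFrame(rows)
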