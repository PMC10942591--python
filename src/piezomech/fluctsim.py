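"""Synthetic-data generators with known ground truth.

Every input consumed by the analysis pipeline can be generated here:

* membrane height fluctuation movies whose one-sided PSD equals the
  Helfrich model spectrum (sum of per-wavenumber Ornstein-Uhlenbeck
  modes, exact discrete updates);
* IRM interferogram movies obtained from those heights through the
  first-branch cosine interference relation plus Gaussian camera noise;
* fluorescence movies of translating elliptical cells with an exactly
  controlled front/back intensity skew;
* Brownian and persistent random-walk track tables;
* two-channel puncta fields with a controlled co-located fraction.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from piezomech import coloc as _coloc
from piezomech.model import (
    MechanicalParams,
    SpectralGrid,
    mode_relaxation_times,
    mode_variances,
)
from piezomech.motility import TRACK_COLUMNS, TrackTable
from piezomech.optics import IRMOptics
from piezomech.stacks import HeightMapStack, ImageStack


def simulate_height_series(params: MechanicalParams, grid: SpectralGrid,
                           n_pixels: int | tuple[int, int] = 64,
                           seed: int | np.random.Generator = 0,
                           mean_height_nm: float = 51.3,
                           exposure_substeps: int = 4) -> HeightMapStack:
    """Simulate membrane height movies as sums of independent OU modes.

    Each pixel is an independent sum over the ``grid.n_q`` wavenumber bins
    of Ornstein-Uhlenbeck processes with relaxation time
    ``tau_q = 4 eta_eff / E(q)`` and stationary variance
    ``s_q^2 = A kB T dq / (4 pi E(q))``, so the summed process has
    one-sided PSD equal to the discretized Helfrich model spectrum.
    Updates use the exact discrete OU transition (mean decay
    ``exp(-dt/tau)``, matched stationary variance), not an Euler scheme,
    so there is no time-step bias even for fast modes.

    Pixels are statistically independent (no spatial correlation); the
    per-pixel/per-ROI fitting downstream never uses cross-pixel
    covariance, so this suffices for validation.

    Each recorded frame is the average of ``exposure_substeps`` exact OU
    substeps, emulating the camera integrating over its exposure; set
    ``exposure_substeps=1`` for instantaneous point sampling.  Frame
    integration low-passes the fast modes the way a real detector does
    and keeps fold-back of above-Nyquist power from biasing the sampled
    spectrum.

    Returns heights in nm offset to ``mean_height_nm`` (default is the
    middle of the IRM first branch).
    """
    rng = np.random.default_rng(seed)
    if isinstance(n_pixels, int):
        shape = (1, n_pixels)
    else:
        shape = tuple(n_pixels)
    npx = int(np.prod(shape))
    tau = mode_relaxation_times(params, grid)           # (n_q,)
    s2 = mode_variances(params, grid)                   # m^2
    if exposure_substeps < 1:
        raise ValueError("exposure_substeps must be >= 1")
    dt = grid.dt / exposure_substeps
    undersampled = int(np.sum(tau < 2.0 / grid.fs))
    if undersampled:
        warnings.warn(
            f"{undersampled}/{grid.n_q} modes have relaxation times "
            "shorter than two frame intervals; their dynamics are "
            "undersampled at this frame rate")
    a = np.exp(-dt / tau)[:, None]                      # (n_q, 1)
    s = np.sqrt(s2)[:, None]
    innov_sd = s * np.sqrt(1.0 - a ** 2)
    state = s * rng.standard_normal((grid.n_q, npx))    # stationary start
    out = np.empty((grid.n_frames, npx))
    frame_acc = state.sum(axis=0)
    for sub in range(1, exposure_substeps):
        state = a * state + innov_sd * rng.standard_normal((grid.n_q, npx))
        frame_acc += state.sum(axis=0)
    out[0] = frame_acc / exposure_substeps
    for t in range(1, grid.n_frames):
        frame_acc = np.zeros(npx)
        for _ in range(exposure_substeps):
            state = a * state + innov_sd * rng.standard_normal(
                (grid.n_q, npx))
            frame_acc += state.sum(axis=0)
        out[t] = frame_acc / exposure_substeps
    heights_nm = out.reshape((grid.n_frames,) + shape) * 1e9 + mean_height_nm
    pixel_nm = np.pi / grid.q_max * 1e9
    return HeightMapStack(heights=heights_nm, dt=dt, pixel_nm=pixel_nm)


def heights_to_irm(heights: HeightMapStack, optics: IRMOptics,
                   seed: int | np.random.Generator = 0) -> ImageStack:
    """Convert a height movie to an IRM interferogram movie.

    Applies the first-branch cosine interference relation and adds
    Gaussian camera noise of standard deviation ``optics.noise_sd``.
    Heights outside the first branch are clipped to it (with a warning
    reporting the count) since the forward relation is no longer
    invertible there.
    """
    rng = np.random.default_rng(seed)
    h = heights.heights
    span = optics.branch_span_nm
    n_out = int(np.sum((h < 0) | (h > span)))
    if n_out:
        warnings.warn(f"{n_out} height samples outside the first branch "
                      "were clipped")
        h = np.clip(h, 0.0, span)
    intensity = optics.intensity_from_height(h)
    if optics.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, optics.noise_sd, h.shape)
    return ImageStack(intensity=intensity, dt=heights.dt,
                      pixel_nm=heights.pixel_nm, channel="irm")


def simulate_tracks(model: str = "brownian", D: float = 0.5,
                    speed: float = 0.1, persistence_s: float = 120.0,
                    n_tracks: int = 50, n_steps: int = 30, dt: float = 30.0,
                    seed: int | np.random.Generator = 0,
                    pixel_um: float = 1.0) -> TrackTable:
    """Generate Brownian or persistent random-walk tracks.

    Brownian: per-step displacements N(0, 2 D dt) per axis (D in um^2/s).
    Persistent: constant ``speed`` (um/s) with the heading decorrelating
    by rotational diffusion over ``persistence_s`` seconds, so the
    velocity autocorrelation decays as exp(-t/persistence_s) and the MSD
    is ballistic, (speed*t)^2, at lags much shorter than the persistence
    time.
    """
    if model not in ("brownian", "persistent"):
        raise ValueError("model must be 'brownian' or 'persistent'")
    if D < 0:
        raise ValueError("D must be >= 0")
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for tid in range(n_tracks):
        if model == "brownian":
            steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), (n_steps - 1, 2))
        else:
            theta = np.empty(n_steps - 1)
            theta[0] = rng.uniform(0, 2 * np.pi)
            dtheta_sd = np.sqrt(2.0 * dt / persistence_s)
            for i in range(1, n_steps - 1):
                theta[i] = theta[i - 1] + rng.normal(0.0, dtheta_sd)
            steps = speed * dt * np.column_stack([np.cos(theta),
                                                  np.sin(theta)])
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) / pixel_um
        for f in range(n_steps):
            rows.append((tid, f, xy[f, 0], xy[f, 1]))
    df = pd.DataFrame(rows, columns=list(TRACK_COLUMNS))
    return TrackTable(data=df, dt=dt, pixel_um=pixel_um)


def _ellipse_pixels(center_xy: np.ndarray, axes: tuple[float, float],
                    heading_rad: float, shape: tuple[int, int]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of pixel centers inside a rotated ellipse."""
    a, b = axes
    cx, cy = center_xy
    r0 = max(0, int(np.floor(cy - a - 1)))
    r1 = min(shape[0], int(np.ceil(cy + a + 2)))
    c0 = max(0, int(np.floor(cx - a - 1)))
    c1 = min(shape[1], int(np.ceil(cx + a + 2)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx, dy = cc - cx, rr - cy
    u = dx * np.cos(heading_rad) + dy * np.sin(heading_rad)
    v = -dx * np.sin(heading_rad) + dy * np.cos(heading_rad)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def simulate_polarized_cell_movie(
        n_cells: int = 4, skew_fraction: float = 0.75,
        step_px: float = 2.0, ellipse_axes: tuple[float, float] = (14.0, 9.0),
        n_frames: int = 8, seed: int | np.random.Generator = 0,
        skew_angle_deg: float = 0.0, total_intensity: float = 1.0e4,
        margin_px: int = 6) -> tuple[ImageStack, pd.DataFrame]:
    """Movie of translating elliptical cells with exact front/back skew.

    Each cell is an ellipse with its long axis along a random per-cell
    heading, translating by ``step_px`` per frame along that heading.  In
    every frame the total intensity is split between the two ellipse
    halves (bisected perpendicular to the skew direction, which is the
    heading rotated by ``skew_angle_deg``) at exactly ``skew_fraction`` in
    the front half.  Cells are laid out on a grid sized so trajectories
    can never overlap.

    Returns the movie and a ground-truth table with per-frame centroid,
    heading and skew.
    """
    if not 0.5 <= skew_fraction <= 1.0:
        raise ValueError("skew_fraction must be in [0.5, 1.0]")
    rng = np.random.default_rng(seed)
    a = max(ellipse_axes)
    cell_box = int(np.ceil(2 * a + (n_frames - 1) * step_px + 2 * margin_px))
    n_side = int(np.ceil(np.sqrt(n_cells)))
    H = W = n_side * cell_box
    movie = np.zeros((n_frames, H, W))
    truth = []
    for cid in range(n_cells):
        gy, gx = divmod(cid, n_side)
        heading = rng.uniform(0, 2 * np.pi)
        skew_dir = heading + np.deg2rad(skew_angle_deg)
        # start so that the full trajectory stays inside the cell box
        box_c = np.array([gx * cell_box + cell_box / 2,
                          gy * cell_box + cell_box / 2])
        travel = (n_frames - 1) * step_px
        start = box_c - 0.5 * travel * np.array([np.cos(heading),
                                                 np.sin(heading)])
        for f in range(n_frames):
            center = start + f * step_px * np.array([np.cos(heading),
                                                     np.sin(heading)])
            rr, cc = _ellipse_pixels(center, ellipse_axes, heading, (H, W))
            if len(rr) == 0:
                raise RuntimeError("cell left the field of view")
            d = ((cc - center[0]) * np.cos(skew_dir) +
                 (rr - center[1]) * np.sin(skew_dir))
            front = d > 0
            n_f, n_b = int(front.sum()), int((~front).sum())
            vals = np.empty(len(rr))
            if n_b == 0 or skew_fraction == 1.0:
                vals[:] = 0.0
                vals[front] = total_intensity / max(n_f, 1)
            else:
                vals[front] = skew_fraction * total_intensity / n_f
                vals[~front] = (1 - skew_fraction) * total_intensity / n_b
            movie[f, rr, cc] += vals
            truth.append((cid, f, center[0], center[1],
                          np.rad2deg(heading) % 360.0, skew_fraction))
    stack = ImageStack(intensity=movie, dt=30.0, pixel_nm=320.0,
                       channel="fluor")
    gt = pd.DataFrame(truth, columns=["cell_id", "frame", "cx_px", "cy_px",
                                      "heading_deg", "skew_fraction"])
    return stack, gt


def simulate_puncta_field(mask: np.ndarray, n_ref: int = 40,
                          n_query: int = 40, coloc_fraction: float = 0.5,
                          area_range_px: tuple[int, int] = (50, 350),
                          seed: int | np.random.Generator = 0
                          ) -> tuple[_coloc.PunctaSet, _coloc.PunctaSet]:
    """Two-channel puncta field with a controlled co-located fraction.

    Reference objects (disks with areas uniform in ``area_range_px``) are
    placed uniformly at random in ``mask`` without mutual overlap.  A
    fraction ``coloc_fraction`` of the query objects is centered on
    randomly chosen reference objects (guaranteeing overlap); the rest
    are placed uniformly in the mask.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = np.asarray(mask, dtype=bool)
    lo, hi = area_range_px
    ref_areas = rng.uniform(lo, hi, n_ref)
    ref_labels = _coloc.place_disk_objects(mask, ref_areas, rng)
    ref = _coloc._label_to_punctaset(ref_labels, channel="reference")

    n_col = int(round(coloc_fraction * n_query))
    query_areas = rng.uniform(lo, hi, n_query)
    H, W = mask.shape
    labels = np.zeros((H, W), dtype=np.int32)
    yy, xx = np.mgrid[0:H, 0:W]
    # co-located objects: centered on reference centroids
    chosen = rng.choice(ref.n_objects, size=n_col,
                        replace=n_col > ref.n_objects)
    lab = 0
    for i in range(n_col):
        cy, cx = ref.centroids[chosen[i]]
        r = max(1.0, np.sqrt(query_areas[i] / np.pi))
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        disk &= ~(labels > 0)
        lab += 1
        labels[disk] = lab
    # independent objects: uniform in the mask, avoiding existing query
    if n_query - n_col > 0:
        free = _coloc.place_disk_objects(mask, query_areas[n_col:], rng)
        # merge, avoiding collision with co-located query objects
        add = (free > 0) & (labels == 0)
        labels[add] = free[add] + lab
    query = _coloc._label_to_punctaset(labels, channel="query")
    return ref, query
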