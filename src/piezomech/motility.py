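"""Track-level motility quantification: MSD curves and transwell migration.

Trajectories live in a :class:`TrackTable` (a thin wrapper over a tidy
DataFrame with ``track_id, frame, x_px, y_px`` and an optional ``group``
column).  The mean-squared displacement at lag ``n`` frames is the
time-averaged squared displacement over all sliding origins within each
track, then averaged across tracks; the literal fixed-origin variant
``(x_n - x_0)^2 + (y_n - y_0)^2`` is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

TRACK_COLUMNS = ("track_id", "frame", "x_px", "y_px")


@dataclass
class TrackTable:
    """Linked 2D trajectories with calibration."""

    data: pd.DataFrame
    dt: float
    pixel_um: float = 1.0

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        if self.dt <= 0 or self.pixel_um <= 0:
            raise ValueError("dt and pixel_um must be > 0")
        by_track = self.data.groupby("track_id")["frame"]
        if (by_track.diff().dropna() <= 0).any():
            raise ValueError("frames must be strictly increasing per track")

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def groups(self) -> list[str]:
        if "group" in self.data.columns:
            return sorted(self.data["group"].unique())
        return ["all"]


@dataclass
class MSDCurve:
    """Ensemble MSD versus lag time for one track group."""

    lag_s: np.ndarray
    msd_um2: np.ndarray
    sem_um2: np.ndarray
    n_tracks: np.ndarray
    group: str = "all"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_s": self.lag_s, "msd_um2": self.msd_um2,
                             "sem_um2": self.sem_um2,
                             "n_tracks": self.n_tracks,
                             "group": self.group})


def _track_msd(xy_um: np.ndarray, max_lag: int,
               time_average: bool) -> np.ndarray:
    """Per-track MSD at lags 1..max_lag (nan where undefined)."""
    n = len(xy_um)
    out = np.full(max_lag, np.nan)
    for lag in range(1, min(max_lag + 1, n)):
        if time_average:
            d = xy_um[lag:] - xy_um[:-lag]
            out[lag - 1] = (d ** 2).sum(axis=1).mean()
        else:
            # fixed-origin variant: displacement from the first frame only
            out[lag - 1] = ((xy_um[lag] - xy_um[0]) ** 2).sum()
    return out


def compute_msd(tracks: TrackTable, max_lag_fraction: float = 0.5,
                min_tracks: int = 3,
                time_average: bool = True) -> dict[str, MSDCurve]:
    """Ensemble-averaged MSD per group.

    Lags are capped at ``max_lag_fraction`` of the longest track in the
    group to limit estimator variance; lags supported by fewer than
    ``min_tracks`` tracks are dropped, and groups with fewer than
    ``min_tracks`` tracks are omitted with a warning.
    """
    df = tracks.data
    if "group" not in df.columns:
        df = df.assign(group="all")
    curves: dict[str, MSDCurve] = {}
    for group, gdf in df.groupby("group"):
        track_lengths = gdf.groupby("track_id").size()
        if len(track_lengths) < min_tracks:
            warnings.warn(f"group {group!r} has fewer than {min_tracks} "
                          "tracks; omitted")
            continue
        max_lag = max(1, int(track_lengths.max() * max_lag_fraction))
        per_track = []
        for _, tdf in gdf.groupby("track_id"):
            xy = tdf.sort_values("frame")[["x_px", "y_px"]].to_numpy()
            per_track.append(_track_msd(xy * tracks.pixel_um, max_lag,
                                        time_average))
        arr = np.vstack(per_track)
        n_per_lag = np.sum(np.isfinite(arr), axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(arr, axis=0)
            sem = np.nanstd(arr, axis=0, ddof=1) / np.sqrt(n_per_lag)
        keep = n_per_lag >= min_tracks
        lags = (np.arange(1, max_lag + 1) * tracks.dt)[keep]
        curves[group] = MSDCurve(
            lag_s=np.concatenate([[0.0], lags]),
            msd_um2=np.concatenate([[0.0], mean[keep]]),
            sem_um2=np.concatenate([[0.0], sem[keep]]),
            n_tracks=np.concatenate([[len(per_track)], n_per_lag[keep]]),
            group=str(group))
    return curves


def estimate_diffusion(curve: MSDCurve, n_lags: int = 5) -> float:
    """Diffusion coefficient (um^2/s) from a through-origin linear fit
    of the first ``n_lags`` MSD points, slope / 4."""
    t = curve.lag_s[1:n_lags + 1]
    m = curve.msd_um2[1:n_lags + 1]
    slope = float(np.sum(t * m) / np.sum(t * t))
    return slope / 4.0


def link_centroids(stack, threshold: float, min_area: int = 50,
                   max_disp_px: float = 15.0) -> TrackTable:
    """Detect per-frame blob centroids and link them greedily.

    Frames are binarized at ``threshold``; connected components smaller
    than ``min_area`` px^2 (debris) are dropped.  Detections are linked to
    the nearest active track end within ``max_disp_px``, closest pairs
    first (ties broken by lowest label index); unmatched detections start
    new tracks.  Greedy nearest-neighbor linking is adequate for sparse
    fields but will not resolve dense crossings.
    """
    rows = []
    next_id = 0
    active: dict[int, np.ndarray] = {}
    for t in range(stack.n_frames):
        labels, n = ndimage.label(stack.intensity[t] > threshold)
        cents = []
        if n:
            idx = np.arange(1, n + 1)
            areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
            for lab in idx[areas >= min_area]:
                cy, cx = ndimage.center_of_mass(labels == lab)
                cents.append((cx, cy))
        cents = np.asarray(cents, dtype=float).reshape(-1, 2)
        assigned_det: set[int] = set()
        assigned_trk: set[int] = set()
        if len(cents) and active:
            trk_ids = sorted(active)
            ends = np.array([active[i] for i in trk_ids])
            dist = np.linalg.norm(ends[:, None, :] - cents[None, :, :],
                                  axis=2)
            order = sorted(
                ((dist[i, j], trk_ids[i], j)
                 for i in range(len(trk_ids)) for j in range(len(cents))
                 if dist[i, j] <= max_disp_px))
            for _, trk, det in order:
                if trk in assigned_trk or det in assigned_det:
                    continue
                assigned_trk.add(trk)
                assigned_det.add(det)
                active[trk] = cents[det]
                rows.append((trk, t, cents[det, 0], cents[det, 1]))
        # tracks unmatched this frame are terminated
        active = {k: v for k, v in active.items() if k in assigned_trk}
        for det in range(len(cents)):
            if det not in assigned_det:
                active[next_id] = cents[det]
                rows.append((next_id, t, cents[det, 0], cents[det, 1]))
                next_id += 1
    df = pd.DataFrame(rows, columns=list(TRACK_COLUMNS))
    df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return TrackTable(data=df, dt=stack.dt,
                      pixel_um=stack.pixel_nm / 1000.0)


def percent_migration(n_lower: int, n_seeded: int) -> float:
    """Transwell percent migration, 100 * n_lower / n_seeded."""
    if n_seeded <= 0:
        raise ValueError("n_seeded must be > 0")
    if n_lower < 0 or n_lower > n_seeded:
        raise ValueError("require 0 <= n_lower <= n_seeded")
    return 100.0 * n_lower / n_seeded
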