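"""Front/back fluorescence asymmetry of migrating cells.

Cells are segmented into polygon ROIs, fitted with an ellipse from the
second image moments of their binary mask, and bisected by the line
through the ellipse center perpendicular to a reference direction: the
per-frame migration direction for live cells, or the cell's long axis for
fixed cells.  From the half intensities A (front) and B (back):

* F/B ratio               = A / B
* unsigned polarity index = |A - B| / (A + B)  in [0, 1]
* signed polarity index   = (A - B) / (A + B)  in [-1, 1], with the half
  ordering chosen so a reference channel (e.g. CD44, a uropod marker) is
  positive, so that an anti-polar query channel is negative.

The polarization direction of a channel is the vector from the geometric
centroid to the intensity-weighted center of mass; its angle relative to
the displacement vector is summarized in polar histograms.

Pixel coordinates are 0-based (x = column, y = row, y increasing
downward); all angle comparisons are relative, so the absolute angle
convention cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import find_contours

MIN_DISPLACEMENT_PX = 0.5


@dataclass
class CellROI:
    """A segmented cell: mask pixels, polygon boundary and fitted ellipse."""

    pixels_rc: np.ndarray           # (N, 2) int rows/cols of the mask
    centroid_xy: np.ndarray         # geometric centroid of the mask
    ellipse_center_xy: np.ndarray
    semi_axes: tuple[float, float]  # (major, minor)
    orientation_rad: float          # long-axis direction, atan2(dy, dx)
    polygon_xy: np.ndarray | None = None
    displacement_xy: np.ndarray | None = None

    @property
    def area_px(self) -> int:
        return len(self.pixels_rc)

    def long_axis_vector(self) -> np.ndarray:
        return np.array([np.cos(self.orientation_rad),
                         np.sin(self.orientation_rad)])


def _fit_ellipse(pixels_rc: np.ndarray) -> tuple[np.ndarray,
                                                 tuple[float, float], float]:
    """Ellipse (center, semi-axes, orientation) from second moments.

    For a filled ellipse the pixel-coordinate covariance eigenvalues are
    (a/2)^2 and (b/2)^2, so semi-axes are 2*sqrt(eigenvalues).
    """
    xy = pixels_rc[:, ::-1].astype(float)   # -> (x, y)
    center = xy.mean(axis=0)
    cov = np.cov(xy.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    a, b = 2.0 * np.sqrt(np.maximum(evals, 1e-12))
    major = evecs[:, 0]
    return center, (float(a), float(b)), float(np.arctan2(major[1],
                                                          major[0]))


def segment_cells(image: np.ndarray,
                  threshold_method: str | float = "otsu",
                  min_area: int = 50) -> list[CellROI]:
    """Threshold, label, and fit each cell with a polygon ROI and ellipse.

    ROIs are ordered deterministically by centroid (row-major).
    """
    image = np.asarray(image, dtype=float)
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError("threshold_method must be 'otsu' or a number")
        if image.max() == image.min():
            return []
        thr = threshold_otsu(image)
    else:
        thr = float(threshold_method)
    labels, n = ndimage.label(image > thr)
    rois = []
    for lab in range(1, n + 1):
        mask = labels == lab
        if mask.sum() < min_area:
            continue
        pixels = np.argwhere(mask)
        center, axes, orient = _fit_ellipse(pixels)
        contours = find_contours(mask.astype(float), 0.5)
        poly = contours[0][:, ::-1] if contours else None
        centroid = pixels[:, ::-1].mean(axis=0)
        rois.append(CellROI(pixels_rc=pixels, centroid_xy=centroid,
                            ellipse_center_xy=center, semi_axes=axes,
                            orientation_rad=orient, polygon_xy=poly))
    rois.sort(key=lambda r: (round(r.centroid_xy[1], 3),
                             round(r.centroid_xy[0], 3)))
    return rois


def ellipse_interior(roi: CellROI, shape: tuple[int, int]) -> np.ndarray:
    """(N, 2) rows/cols of pixel centers inside the fitted ellipse."""
    a, b = roi.semi_axes
    cx, cy = roi.ellipse_center_xy
    r0 = max(0, int(np.floor(cy - a - 1)))
    r1 = min(shape[0], int(np.ceil(cy + a + 2)))
    c0 = max(0, int(np.floor(cx - a - 1)))
    c1 = min(shape[1], int(np.ceil(cx + a + 2)))
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx, dy = cc - cx, rr - cy
    th = roi.orientation_rad
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return np.column_stack([rr[inside], cc[inside]])


def split_halves(roi: CellROI, direction: np.ndarray,
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Partition the ellipse interior by the bisector perpendicular to
    ``direction`` through the ellipse center.

    Front = pixels whose offset from the center has positive dot product
    with the direction.  Raises on a zero direction (caller policy
    decides how to handle stationary frames).
    """
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("zero direction vector")
    d = direction / norm
    pix = ellipse_interior(roi, shape)
    offs = pix[:, ::-1] - roi.ellipse_center_xy
    t = offs @ d
    # pixels exactly on the bisector are tie-broken by the perpendicular
    # component so that reversing the direction swaps the halves exactly;
    # a pixel exactly at the center lies on every bisector and is dropped
    s = offs @ np.array([-d[1], d[0]])
    center = (t == 0) & (s == 0)
    front = ((t > 0) | ((t == 0) & (s > 0))) & ~center
    back = ~front & ~center
    return pix[front], pix[back]


def _half_sums(image: np.ndarray, roi: CellROI,
               direction: np.ndarray) -> tuple[float, float]:
    front, back = split_halves(roi, direction, image.shape)
    sa = float(image[front[:, 0], front[:, 1]].sum()) if len(front) else 0.0
    sb = float(image[back[:, 0], back[:, 1]].sum()) if len(back) else 0.0
    return sa, sb


def front_back_ratio(image: np.ndarray, roi: CellROI,
                     direction: np.ndarray) -> float:
    """Leading-half / trailing-half total intensity ratio (F/B)."""
    sa, sb = _half_sums(np.asarray(image, float), roi, direction)
    if sb == 0:
        warnings.warn("zero back-half intensity: F/B undefined")
        return float("nan")
    return sa / sb


def polarity_index(image: np.ndarray, roi: CellROI,
                   direction: np.ndarray | None = None,
                   signed: bool = False) -> float:
    """Polarity index of one cell: |A-B|/(A+B), or (A-B)/(A+B) if signed.

    With no ``direction`` the cell's long axis is used (the fixed-cell
    convention); 0 means uniform, magnitude 1 complete skew to one half.
    """
    if direction is None:
        direction = roi.long_axis_vector()
    sa, sb = _half_sums(np.asarray(image, float), roi, direction)
    if sa + sb == 0:
        warnings.warn("zero total intensity: polarity index undefined")
        return float("nan")
    p = (sa - sb) / (sa + sb)
    return p if signed else abs(p)


def paired_signed_polarity(image_ref: np.ndarray, image_query: np.ndarray,
                           roi: CellROI) -> tuple[float, float]:
    """Signed polarity of two channels with the half order set by the
    reference channel.

    The long-axis half labeling is flipped if needed so the reference
    index is positive; the query index is computed with the same order,
    so a channel polarizing to the opposite pole comes out negative.
    """
    direction = roi.long_axis_vector()
    p_ref = polarity_index(image_ref, roi, direction, signed=True)
    if np.isnan(p_ref):
        warnings.warn("reference channel has zero intensity")
        return float("nan"), float("nan")
    if p_ref == 0:
        warnings.warn("reference channel exactly unpolarized; keeping "
                      "long-axis positive side as front")
    if p_ref < 0:
        direction = -direction
        p_ref = -p_ref
    p_query = polarity_index(image_query, roi, direction, signed=True)
    return p_ref, p_query


def signed_angle_deg(v: np.ndarray, reference: np.ndarray) -> float:
    """Signed angle from ``reference`` to ``v`` in degrees, in [-180, 180)."""
    cross = reference[0] * v[1] - reference[1] * v[0]
    dot = float(np.dot(reference, v))
    ang = np.degrees(np.arctan2(cross, dot))
    return float(-180.0 if np.isclose(ang, 180.0) else ang)


def polarization_angle(image: np.ndarray, roi: CellROI,
                       displacement: np.ndarray,
                       eps: float = 1e-6) -> float:
    """Angle between the polarization vector (center of mass - centroid)
    and the displacement vector, degrees in [-180, 180).

    NaN when the polarization vector is shorter than ``eps`` pixels.
    """
    image = np.asarray(image, dtype=float)
    pix = roi.pixels_rc
    w = image[pix[:, 0], pix[:, 1]]
    if w.sum() <= 0:
        return float("nan")
    com_xy = (pix[:, ::-1] * w[:, None]).sum(axis=0) / w.sum()
    v = com_xy - roi.centroid_xy
    if np.linalg.norm(v) < eps or np.linalg.norm(displacement) == 0:
        return float("nan")
    return signed_angle_deg(v, np.asarray(displacement, float))


def polar_histogram(angles_deg, bin_deg: float = 20.0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of angles over [-180, 180) in ``bin_deg`` bins; skips NaN."""
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    edges = np.arange(-180.0, 180.0 + bin_deg / 2, bin_deg)
    counts, _ = np.histogram(a, bins=edges)
    return counts, edges


def _link_rois(frames_rois: list[list[CellROI]],
               max_disp_px: float = 25.0) -> dict[int, list[tuple[int, CellROI]]]:
    """Greedy nearest-centroid linking of per-frame ROIs into cells."""
    cells: dict[int, list[tuple[int, CellROI]]] = {}
    active: dict[int, np.ndarray] = {}
    next_id = 0
    for f, rois in enumerate(frames_rois):
        pairs = []
        for j, roi in enumerate(rois):
            for cid, last in active.items():
                d = float(np.linalg.norm(roi.centroid_xy - last))
                if d <= max_disp_px:
                    pairs.append((d, cid, j))
        pairs.sort()
        used_c, used_j = set(), set()
        new_active = {}
        for d, cid, j in pairs:
            if cid in used_c or j in used_j:
                continue
            used_c.add(cid)
            used_j.add(j)
            cells[cid].append((f, rois[j]))
            new_active[cid] = rois[j].centroid_xy
        for j, roi in enumerate(rois):
            if j not in used_j:
                cells[next_id] = [(f, roi)]
                new_active[next_id] = roi.centroid_xy
                next_id += 1
        active = new_active
    return cells


def fb_timeseries(stacks: dict[str, "np.ndarray"],
                  segment_channel: str,
                  threshold_method: str | float = "otsu",
                  min_area: int = 50,
                  max_disp_px: float = 25.0) -> pd.DataFrame:
    """Per-frame F/B ratio and polarity index for each channel of tracked
    cells.

    ``stacks`` maps channel name to a (T, H, W) array sharing geometry;
    cells are segmented on ``segment_channel`` each frame and linked by
    nearest centroid.  The front direction is the frame-to-frame centroid
    displacement; frames moving less than 0.5 px reuse the last valid
    direction and are dropped if none exists yet.  Returns a tidy frame
    (cell_id, frame, channel, fb_ratio, polarity_index); average over
    frames per cell for per-cell summaries.
    """
    seg = stacks[segment_channel]
    frames_rois = [segment_cells(seg[t], threshold_method, min_area)
                   for t in range(seg.shape[0])]
    cells = _link_rois(frames_rois, max_disp_px)
    rows = []
    for cid, seq in sorted(cells.items()):
        last_dir = None
        for k, (f, roi) in enumerate(seq):
            if k + 1 < len(seq):
                disp = seq[k + 1][1].centroid_xy - roi.centroid_xy
            elif k > 0:
                disp = roi.centroid_xy - seq[k - 1][1].centroid_xy
            else:
                disp = np.zeros(2)
            if np.linalg.norm(disp) < MIN_DISPLACEMENT_PX:
                if last_dir is None:
                    continue
                disp = last_dir
            else:
                last_dir = disp
            for channel, stack in stacks.items():
                rows.append({
                    "cell_id": cid, "frame": f, "channel": channel,
                    "fb_ratio": front_back_ratio(stack[f], roi, disp),
                    "polarity_index": polarity_index(stack[f], roi, disp),
                })
    return pd.DataFrame(rows)
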