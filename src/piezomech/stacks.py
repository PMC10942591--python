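"""Time-resolved image and height-map containers plus TIFF plumbing.

Stacks are plain (T, H, W) numpy arrays with acquisition metadata.  TIFF
files carry the pixel data; a JSON sidecar (``<name>.json``) carries frame
interval, pixel size and channel label so that round trips are lossless.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.registration import phase_cross_correlation


@dataclass
class ImageStack:
    """(T, H, W) intensity stack in camera counts."""

    intensity: np.ndarray
    dt: float
    pixel_nm: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be a (T, H, W) array")
        if self.dt <= 0 or self.pixel_nm <= 0:
            raise ValueError("dt and pixel_nm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    def mean_image(self) -> np.ndarray:
        return self.intensity.mean(axis=0)


@dataclass
class HeightMapStack:
    """(T, H, W) membrane height above the substrate, in nm."""

    heights: np.ndarray
    dt: float
    pixel_nm: float

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 3:
            raise ValueError("heights must be a (T, H, W) array")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.dt <= 0 or self.pixel_nm <= 0:
            raise ValueError("dt and pixel_nm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.heights.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.dt

    @property
    def fs(self) -> float:
        return 1.0 / self.dt


def write_stack(path: str | Path, stack: ImageStack,
                scale_to_uint16: bool = True) -> Path:
    """Write a stack as TIFF plus JSON metadata sidecar.

    Intensities are stored as uint16 after clipping to [0, 65535] (the
    native EMCCD count range); pass ``scale_to_uint16=False`` to keep
    float32.
    """
    path = Path(path)
    data = stack.intensity
    if scale_to_uint16:
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    else:
        data = data.astype(np.float32)
    tifffile.imwrite(path, data)
    sidecar = {"dt": stack.dt, "pixel_nm": stack.pixel_nm,
               "channel": stack.channel}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))
    return path


def read_stack(path: str | Path) -> ImageStack:
    """Read a TIFF stack; metadata comes from the JSON sidecar if present."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = {"dt": 1.0, "pixel_nm": 180.0, "channel": ""}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))
    return ImageStack(intensity=data.astype(float), dt=float(meta["dt"]),
                      pixel_nm=float(meta["pixel_nm"]),
                      channel=str(meta.get("channel", "")))


def align_stack(stack: ImageStack, reference_frame: int = 0) -> ImageStack:
    """Integer-pixel rigid drift correction against one reference frame.

    Each frame is phase-correlated with the reference and rolled by the
    estimated integer shift.  Sub-pixel registration is deliberately not
    attempted; this utility only removes stage drift before fluctuation
    analysis.
    """
    ref = stack.intensity[reference_frame]
    out = np.empty_like(stack.intensity)
    large = 0
    for t in range(stack.n_frames):
        shift, _, _ = phase_cross_correlation(ref, stack.intensity[t],
                                              upsample_factor=1,
                                              normalization=None)
        shift = np.rint(shift).astype(int)
        if np.any(np.abs(shift) > min(stack.shape[1:]) // 4):
            large += 1
        out[t] = np.roll(stack.intensity[t], shift, axis=(0, 1))
    if large:
        warnings.warn(f"{large} frames had suspiciously large drift shifts")
    return ImageStack(intensity=out, dt=stack.dt, pixel_nm=stack.pixel_nm,
                      channel=stack.channel)
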