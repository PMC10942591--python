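"""IRM interference optics: cosine relation between membrane height and
reflected intensity, restricted to the first branch.

Within the first branch region (FBR, heights 0 to lambda/(4 n) ~ 100 nm)
the reflected intensity is a monotone function of the membrane-substrate
distance h:

    I(h) = i_min + (i_max - i_min)/2 * (1 - cos(4 pi n h / lambda))

and can be inverted unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class IRMOptics:
    """Interference imaging parameters.

    ``wavelength_nm`` defaults to the 546 nm Hg line; ``n_medium`` to the
    aqueous-medium refractive index 1.33, which gives a first-branch span
    of ~103 nm.  ``i_min``/``i_max`` are the destructive/constructive
    interference extrema in camera counts; ``noise_sd`` is additive
    Gaussian camera noise in counts.
    """

    wavelength_nm: float = 546.0
    n_medium: float = 1.33
    i_min: float = 2000.0
    i_max: float = 10000.0
    noise_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be > 0")
        if self.n_medium <= 0:
            raise ValueError("n_medium must be > 0")
        if self.i_max <= self.i_min:
            raise ValueError("require i_max > i_min")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def branch_span_nm(self) -> float:
        """Height span of the first branch, lambda / (4 n_medium)."""
        return self.wavelength_nm / (4.0 * self.n_medium)

    def intensity_from_height(self, heights_nm: np.ndarray) -> np.ndarray:
        """Noise-free intensity for height(s) in nm (cosine relation)."""
        h = np.asarray(heights_nm, dtype=float)
        phase = 4.0 * np.pi * self.n_medium * h / self.wavelength_nm
        return self.i_min + 0.5 * (self.i_max - self.i_min) * (1.0 - np.cos(phase))

    def height_from_intensity(self, intensity: np.ndarray) -> np.ndarray:
        """Invert the cosine relation on the first branch; result in nm.

        The arccos argument is clipped to [-1, 1] so that intensities
        slightly outside [i_min, i_max] (noise) map to the branch ends.
        """
        i = np.asarray(intensity, dtype=float)
        arg = 1.0 - 2.0 * (i - self.i_min) / (self.i_max - self.i_min)
        arg = np.clip(arg, -1.0, 1.0)
        return self.wavelength_nm / (4.0 * np.pi * self.n_medium) * np.arccos(arg)
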