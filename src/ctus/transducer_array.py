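"""Multi-element integration, radial blur, and 8-bit scaling.

A real probe sums the echoes received by a small aperture of neighboring
transducer elements.  Element ``i`` (signed index from the aperture center)
sees the sample under an angle ``theta_i = arctan(|i| d / d0)`` and its
physical contribution ``cos(theta_i) * exp(-2 alpha d0 / cos(theta_i))``
falls off monotonically with ``|i|`` — a bell-shaped taper that is
approximated by a Kaiser window (Bessel-I0 based, shape parameter alpha).
Integration is therefore a lateral Kaiser-weighted sum over the
``n_elements`` neighboring scanlines of the already-propagated echo grid,
followed by a short box blur along depth (the element's pulse extent), and
a linear stretch of the result onto the 8-bit display scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0 as bessel_i0

__all__ = [
    "ArrayParams",
    "element_angle",
    "physical_weight",
    "kaiser_weights",
    "integrate_elements",
    "radial_blur",
    "linear_scale_256",
]


@dataclass
class ArrayParams:
    """Aperture description.

    n_elements : active elements per output scanline (odd so the aperture
        centers on the scanline; 1 disables integration).
    element_pitch : spacing d between adjacent elements, mm.
    d0 : minimum element-to-sample distance, mm.
    kaiser_alpha : Kaiser shape parameter (0 = uniform taper).
    radial_blur_len : odd box-kernel length along depth (1 = off).
    """

    n_elements: int = 7
    element_pitch: float = 0.4
    d0: float = 10.0
    kaiser_alpha: float = 2.0
    radial_blur_len: int = 3

    def __post_init__(self):
        if self.n_elements < 1 or self.n_elements % 2 == 0:
            raise ValueError("n_elements must be odd and >= 1")
        if self.element_pitch <= 0 or self.d0 <= 0:
            raise ValueError("element_pitch and d0 must be > 0")
        if self.radial_blur_len < 1 or self.radial_blur_len % 2 == 0:
            raise ValueError("radial_blur_len must be odd and >= 1")


def element_angle(i: int, params: ArrayParams) -> float:
    """theta_i = arctan(|i| * pitch / d0); symmetric in +-i, 0 at center."""
    return float(np.arctan(abs(i) * params.element_pitch / params.d0))


def physical_weight(theta: float, alpha_ref: float, d0: float) -> float:
    """cos(theta) * exp(-2 alpha_ref d0 / cos(theta)); decreasing on [0, pi/2)."""
    if not 0 <= theta < np.pi / 2:
        raise ValueError("theta must lie in [0, pi/2)")
    c = np.cos(theta)
    return float(c * np.exp(-2.0 * alpha_ref * d0 / c))


def kaiser_weights(length: int, alpha: float) -> np.ndarray:
    """Kaiser window of ``length`` taps, normalized to sum 1.

    ``w(m) = I0(pi alpha sqrt(1 - (2m/M - 1)^2)) / I0(pi alpha)`` for
    ``0 <= m <= M`` with ``M = length - 1``; symmetric with its peak at the
    center; ``alpha = 0`` degenerates to a uniform window.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if length == 1:
        return np.array([1.0])
    M = length - 1
    m = np.arange(length)
    arg = np.pi * alpha * np.sqrt(np.clip(1.0 - (2.0 * m / M - 1.0) ** 2, 0.0, None))
    w = bessel_i0(arg) / bessel_i0(np.pi * alpha)
    return w / w.sum()


def integrate_elements(echo_image: np.ndarray, params: ArrayParams) -> np.ndarray:
    """Kaiser-weighted lateral sum over the aperture around each scanline.

    Edge scanlines use the truncated part of the window renormalized to sum
    1 (no wraparound, no zero padding).
    """
    echo_image = np.asarray(echo_image, float)
    m, n = echo_image.shape
    k = params.n_elements
    if k > n:
        raise ValueError(f"aperture of {k} elements is wider than {n} scanlines")
    if k == 1:
        return echo_image.copy()
    w = kaiser_weights(k, params.kaiser_alpha)
    half = k // 2
    out = np.zeros_like(echo_image)
    for j in range(n):
        lo = max(0, j - half)
        hi = min(n, j + half + 1)
        ww = w[lo - (j - half) : k - ((j + half + 1) - hi)]
        ww = ww / ww.sum()
        out[:, j] = echo_image[:, lo:hi] @ ww
    return out


def radial_blur(image: np.ndarray, radial_blur_len: int) -> np.ndarray:
    """Normalized box blur along the depth axis (per column); 1 = identity."""
    if radial_blur_len % 2 == 0 or radial_blur_len < 1:
        raise ValueError("radial blur length must be odd and >= 1")
    image = np.asarray(image, float)
    if radial_blur_len == 1:
        return image.copy()
    kernel = np.full(radial_blur_len, 1.0 / radial_blur_len)
    from scipy.ndimage import convolve1d

    return convolve1d(image, kernel, axis=0, mode="nearest")


def linear_scale_256(image: np.ndarray) -> np.ndarray:
    """Affine stretch of [min, max] onto [0, 255], rounded half-up, uint8.

    A constant image maps to all zeros (degenerate range).
    """
    image = np.asarray(image, float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.uint8)
    scaled = (image - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)
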