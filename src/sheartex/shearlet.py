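"""Band-limited cone-adapted complex shearlet decomposition.

The system is built entirely in the frequency domain.  A Meyer-type radial
window splits the spectrum into one low-pass band and ``scales`` dyadic
band-pass rings; a smooth angular window splits each ring into
``directions_per_scale`` wedges whose centres are evenly spaced over 180
degrees of orientation.  The squared windows form an exact partition of unity
on the discrete frequency grid, so the filter bank is a Parseval-type frame
and forward/inverse round-trips are exact to machine precision.

Complex ("analytic") coefficients are obtained by restricting each
directional filter to the half-plane containing its orientation vector, the
2-D analogue of the analytic signal: the real part of a coefficient equals
the classical real-valued subband, and the magnitude/phase pair is the
envelope and local phase of that subband.

Orientation indexing follows the cone convention used throughout the
package: directions ``k = 1..K/2`` tile the horizontal-frequency cone
(orientations within 45 degrees of the x-frequency axis) and directions
``k = K/2+1..K`` tile the vertical cone.  Subbands are ordered scales
ascending (coarse to fine) and directions ascending within each scale.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.fft

from .errors import (
    CompletenessError,
    DimensionError,
    FormatError,
    SizingError,
)

__all__ = [
    "ShearletSystem",
    "CoefficientStack",
    "build_shearlet_system",
    "shearlet_transform",
    "inverse_shearlet_transform",
    "relative_phase",
    "to_grayscale",
    "wrap_angle",
]

# Rec. 601 luminance weights.
_LUMA = np.array([0.299, 0.587, 0.114])


def _meyer_step(x: np.ndarray) -> np.ndarray:
    """Smooth monotone step: 0 for x <= 0, 1 for x >= 1, C^3 in between."""
    t = np.clip(x, 0.0, 1.0)
    return t**4 * (35.0 - 84.0 * t + 70.0 * t**2 - 20.0 * t**3)


@dataclasses.dataclass(frozen=True)
class ShearletSystem:
    """Frequency-domain filter bank for one image shape.

    Attributes
    ----------
    shape
        (rows, cols) of the images this system decomposes.
    scales, directions_per_scale
        S and K.  There are exactly ``S * K`` directional subbands plus one
        low-pass band.
    filters
        Real array of shape (S*K, rows, cols); the symmetric frequency
        window of each directional subband.
    analytic
        Half-plane weights in {0, 1/2, 1}, same shape as ``filters``;
        the one-sided factor is ``2 * analytic``.
    lowpass
        Real (rows, cols) low-pass frequency window.
    subband_index
        Ordered tuple of (scale, direction) pairs, 1-based, coarse to fine.
    """

    shape: tuple[int, int]
    scales: int
    directions_per_scale: int
    filters: np.ndarray
    analytic: np.ndarray
    lowpass: np.ndarray
    subband_index: tuple[tuple[int, int], ...]

    @property
    def n_subbands(self) -> int:
        return self.scales * self.directions_per_scale

    def subband_position(self, scale: int, direction: int) -> int:
        """Flat index of subband (scale, direction), both 1-based."""
        return self.subband_index.index((scale, direction))


@dataclasses.dataclass
class CoefficientStack:
    """Complex shearlet coefficients of one image plus derived real stacks.

    ``coeffs`` has shape (S*K, rows, cols); ``magnitude``, ``phase`` and
    ``rp`` (relative phase) share that shape and indexing.  The low-pass
    band is stored separately and excluded from descriptor extraction.
    """

    coeffs: np.ndarray
    lowpass: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray
    rp: np.ndarray
    subband_index: tuple[tuple[int, int], ...]
    directions_per_scale: int

    def component(self, name: str) -> np.ndarray:
        if name in ("magnitude", "mag"):
            return self.magnitude
        if name == "rp":
            return self.rp
        if name == "phase":
            return self.phase
        raise KeyError(f"unknown component {name!r}")


def build_shearlet_system(
    rows: int,
    cols: int,
    scales: int = 4,
    directions_per_scale: int = 8,
) -> ShearletSystem:
    """Construct the cone-adapted band-limited system for an image shape.

    Parameters use the defaults adopted throughout the package: S = 4
    scales and K = 8 directions per scale, i.e. 32 directional subbands.

    Raises
    ------
    SizingError
        If the image cannot resolve the coarsest band: both dimensions
        must be at least ``max(32, 2**(scales + 1))``.
    """
    scales = int(scales)
    directions = int(directions_per_scale)
    if scales < 1:
        raise ValueError("scales must be >= 1")
    if directions < 2 or directions % 2:
        raise ValueError("directions_per_scale must be even and >= 2")
    min_size = max(32, 2 ** (scales + 1))
    if rows < min_size or cols < min_size:
        raise SizingError(
            f"image {rows}x{cols} too small for {scales} scales: both "
            f"dimensions must be at least {min_size}"
        )

    fy = np.fft.fftfreq(rows)[:, None]  # row frequency (vertical)
    fx = np.fft.fftfreq(cols)[None, :]  # column frequency (horizontal)
    r = np.hypot(fx, fy)
    # Log-radial coordinate: l = 0 at the Nyquist ring r = 1/2.
    with np.errstate(divide="ignore"):
        lg = np.where(r > 0, np.log2(np.maximum(r, 1e-300) * 2.0), -np.inf)

    # Radial partition: squared windows telescope from smooth octave steps.
    # G_s rises over [s - scales - 1, s - scales]; lowpass^2 = 1 - G_1,
    # band_s^2 = G_s - G_{s+1}, band_S^2 = G_S (covers grid corners).
    G = [_meyer_step(lg - (s - scales - 1)) for s in range(1, scales + 1)]
    low_sq = 1.0 - G[0]
    band_sq = [G[s] - G[s + 1] for s in range(scales - 1)] + [G[-1]]

    # Angular partition with period pi (orientation).  Wedge centres are
    # evenly spaced so directions 1..K/2 fall in the horizontal cone.
    delta = np.pi / directions
    phi = np.arctan2(fy, fx)
    # wrap orientation into [-pi/4, 3pi/4)
    phi_o = np.mod(phi + np.pi / 4.0, np.pi) - np.pi / 4.0
    centers = [-np.pi / 4.0 + (k - 0.5) * delta for k in range(1, directions + 1)]

    def _rev(a: np.ndarray) -> np.ndarray:
        # a[(-i) % rows, (-j) % cols]: the grid's frequency-negation map.
        return np.roll(a[::-1, ::-1], 1, axis=(0, 1))

    wedge_sq = []
    halfplane = []
    for c in centers:
        d = np.mod(phi_o - c + np.pi / 2.0, np.pi) - np.pi / 2.0
        w = np.where(np.abs(d) < delta, np.cos(np.pi * d / (2.0 * delta)) ** 2, 0.0)
        # Nyquist rows/columns alias +1/2 and -1/2 cycles per sample, so the
        # raw window is not symmetric under frequency negation there.
        # Symmetrising restores exact Hermitian pairing; the wedges still sum
        # to one because the negated windows are a partition of unity too.
        wedge_sq.append(0.5 * (w + _rev(w)))
        sgn = np.sign(fx * np.cos(c) + fy * np.sin(c))
        # exactly antisymmetric under frequency negation -> H(xi) + H(-xi) = 1
        halfplane.append(0.5 + 0.25 * (sgn - _rev(sgn)))

    index = []
    filters = np.empty((scales * directions, rows, cols))
    analytic = np.empty_like(filters)
    pos = 0
    for s in range(1, scales + 1):
        for k in range(1, directions + 1):
            filters[pos] = np.sqrt(np.maximum(band_sq[s - 1] * wedge_sq[k - 1], 0.0))
            analytic[pos] = halfplane[k - 1]
            index.append((s, k))
            pos += 1
    lowpass = np.sqrt(np.maximum(low_sq, 0.0))

    return ShearletSystem(
        shape=(rows, cols),
        scales=scales,
        directions_per_scale=directions,
        filters=filters,
        analytic=analytic,
        lowpass=lowpass,
        subband_index=tuple(index),
    )


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 1- or 3-channel raster to a float image in [0, 1].

    Integer inputs are rescaled by their dtype range; RGB is collapsed with
    Rec. 601 luminance weights (0.299 R + 0.587 G + 0.114 B).
    """
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim not in (2, 3):
        raise FormatError(f"expected a 2-D or (h, w, 3) raster, got shape {arr.shape}")
    if arr.ndim == 3 and arr.shape[-1] != 3:
        raise FormatError(
            f"unsupported channel count {arr.shape[-1]}; expected 1 or 3"
        )
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = arr.astype(np.float64) / float(info.max)
    else:
        arr = arr.astype(np.float64)
    if arr.ndim == 3:
        arr = arr @ _LUMA
    if not np.all(np.isfinite(arr)):
        raise FormatError("image contains non-finite values")
    return np.clip(arr, 0.0, 1.0)


def wrap_angle(angle: np.ndarray) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    wrapped = angle - 2.0 * np.pi * np.round(angle / (2.0 * np.pi))
    return np.where(wrapped <= -np.pi, wrapped + 2.0 * np.pi, wrapped)


def relative_phase(
    phase: np.ndarray,
    directions_per_scale: int,
    subband_index: Sequence[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Relative phase: wrapped difference against the adjacent coefficient.

    For directions in the horizontal cone (k <= K/2) the neighbour is the
    next column (j + 1); for the vertical cone (k > K/2) it is the next row
    (i + 1).  The neighbour at the last column/row wraps around circularly so
    the output keeps the full subband shape.  Differences are wrapped to
    (-pi, pi].
    """
    phase = np.asarray(phase, dtype=np.float64)
    if phase.ndim == 2:
        phase = phase[None]
        squeeze = True
    else:
        squeeze = False
    k_half = directions_per_scale // 2
    if subband_index is None:
        n_scales = phase.shape[0] // directions_per_scale
        subband_index = [
            (s, k)
            for s in range(1, n_scales + 1)
            for k in range(1, directions_per_scale + 1)
        ]
    if len(subband_index) != phase.shape[0]:
        raise DimensionError(
            f"{phase.shape[0]} phase subbands but {len(subband_index)} index entries"
        )
    out = np.empty_like(phase)
    for pos, (_, k) in enumerate(subband_index):
        theta = phase[pos]
        if k <= k_half:
            diff = theta - np.roll(theta, -1, axis=1)
        else:
            diff = theta - np.roll(theta, -1, axis=0)
        out[pos] = wrap_angle(diff)
    return out[0] if squeeze else out


def _check_image(image: np.ndarray, system: ShearletSystem) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.shape != system.shape:
        raise DimensionError(
            f"image shape {arr.shape} does not match system shape {system.shape}"
        )
    return arr


def shearlet_transform(image: np.ndarray, system: ShearletSystem) -> CoefficientStack:
    """Decompose an image into complex directional subbands.

    Returns a :class:`CoefficientStack` holding one complex matrix per
    (scale, direction) with the same shape as the input, plus the derived
    magnitude, phase and relative-phase stacks and the low-pass band.
    """
    arr = _check_image(image, system)
    fhat = scipy.fft.fft2(arr)
    onesided = system.filters * (2.0 * system.analytic)
    coeffs = scipy.fft.ifft2(fhat[None, :, :] * onesided, axes=(-2, -1))
    low = scipy.fft.ifft2(fhat * system.lowpass).real
    magnitude = np.abs(coeffs)
    phase = np.arctan2(coeffs.imag, coeffs.real)
    phase = np.where(phase <= -np.pi, np.pi, phase)
    rp = relative_phase(phase, system.directions_per_scale, system.subband_index)
    return CoefficientStack(
        coeffs=coeffs,
        lowpass=low,
        magnitude=magnitude,
        phase=phase,
        rp=rp,
        subband_index=system.subband_index,
        directions_per_scale=system.directions_per_scale,
    )


def inverse_shearlet_transform(
    coeffs: CoefficientStack, system: ShearletSystem
) -> np.ndarray:
    """Reconstruct the image from a coefficient stack.

    Exact (to floating-point round-off) for stacks produced by
    :func:`shearlet_transform` with the same system, because the squared
    frequency windows sum to one.
    """
    if coeffs.lowpass is None:
        raise CompletenessError("coefficient stack is missing the low-pass band")
    if coeffs.coeffs.shape[0] != system.n_subbands:
        raise CompletenessError(
            f"expected {system.n_subbands} directional subbands, "
            f"got {coeffs.coeffs.shape[0]}"
        )
    if coeffs.coeffs.shape[1:] != system.shape:
        raise DimensionError(
            f"coefficient shape {coeffs.coeffs.shape[1:]} does not match "
            f"system shape {system.shape}"
        )
    # Real part of the analytic coefficient is the symmetric-filter subband.
    fhat = np.sum(
        scipy.fft.fft2(coeffs.coeffs.real, axes=(-2, -1)) * system.filters, axis=0
    )
    fhat += scipy.fft.fft2(np.asarray(coeffs.lowpass).real) * system.lowpass
    return scipy.fft.ifft2(fhat).real
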