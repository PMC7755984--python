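"""Binary edge primitives from the masked raster: Canny or phase congruency.

Both detectors run on a single band rescaled to the 0-255 intensity range
within the AOI (DSMs are min-max rescaled the same way), so hysteresis
thresholds are always expressed on a fixed scale. Detection runs on the full
cropped array; the AOI mask is applied afterwards and edges within 2 px of the
mask boundary are dropped, because the AOI outline itself is a strong false
edge.

The phase-congruency detector follows Kovesi's log-Gabor formulation: phase
agreement across ``nscale`` filter scales and ``norient`` orientations yields a
contrast-invariant edge-strength map (the maximum moment of the per-orientation
covariance), which is thinned by non-maximum suppression and hysteresis to a
single-pixel edge set, exactly as the Canny output is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny as _skimage_canny
from skimage.filters import apply_hysteresis_threshold

from .geo_io import FieldImage, FieldMask


@dataclass(frozen=True)
class CannyParams:
    """Canny parameters: Gaussian envelope and hysteresis thresholds.

    Thresholds apply to the Sobel gradient magnitude of the 0-255 rescaled
    band. When only ``upper`` is given the lower threshold is upper/2 (the
    classic 2:1 hysteresis ratio); when neither is given both are derived from
    the gradient maximum (upper = 0.2 max, lower = 0.1 max).
    """

    sigma: float = 2.0
    upper: Optional[float] = None
    lower: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lower is not None and self.upper is None:
            raise ValueError("lower threshold given without upper")
        if self.upper is not None:
            low = self.upper / 2 if self.lower is None else self.lower
            if not 0 < low <= self.upper:
                raise ValueError("thresholds must satisfy 0 < lower <= upper")
            object.__setattr__(self, "lower", low)

    def resolve(self, gradient_max: float) -> tuple[float, float]:
        """Concrete (lower, upper) for a given gradient magnitude maximum."""
        if self.upper is None:
            return 0.1 * gradient_max, 0.2 * gradient_max
        return float(self.lower), float(self.upper)


@dataclass(frozen=True)
class PCParams:
    """Phase-congruency parameters (Kovesi log-Gabor parameterization).

    ``sigma`` keeps parameter parity with :class:`CannyParams` but acts in the
    frequency domain: it scales the smallest log-Gabor wavelength
    (``min_wavelength * max(1, sigma)``) so fine scales are simply not
    sampled. Low-passing the input instead would concentrate all amplitude in
    the coarsest filter and defeat the frequency-spread weighting. ``k``
    scales the estimated noise energy threshold; ``upper`` is the hysteresis
    threshold on the phase-congruency moment map (lower = upper/2). When
    ``upper`` is unset the thresholds are relative to the moment maximum
    (upper = 0.3 max), which keeps the detector contrast-invariant.
    """

    sigma: float = 2.0
    nscale: int = 4
    norient: int = 6
    min_wavelength: float = 3.0
    mult: float = 2.1
    sigma_onf: float = 0.55
    k: float = 2.0
    upper: Optional[float] = None
    lower: Optional[float] = None

    def __post_init__(self) -> None:
        if self.nscale < 2 or self.norient < 3:
            raise ValueError("need nscale >= 2 and norient >= 3")
        for name in ("sigma", "min_wavelength", "mult", "sigma_onf", "k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lower is not None and self.upper is None:
            raise ValueError("lower threshold given without upper")
        if self.upper is not None:
            low = self.upper / 2 if self.lower is None else self.lower
            if not 0 < low <= self.upper:
                raise ValueError("thresholds must satisfy 0 < lower <= upper")
            object.__setattr__(self, "lower", low)

    @property
    def effective_min_wavelength(self) -> float:
        return self.min_wavelength * max(1.0, self.sigma)

    def resolve(self, moment_max: float) -> tuple[float, float]:
        if self.upper is None:
            return 0.15 * moment_max, 0.3 * moment_max
        return float(self.lower), float(self.upper)


@dataclass
class EdgeMap:
    """Boolean edge raster plus the parameters that produced it."""

    bits: np.ndarray
    params: CannyParams | PCParams
    axis_tag: str = "both"  # both | major | minor

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)

    @property
    def n_edges(self) -> int:
        return int(self.bits.sum())


# ---------------------------------------------------------------------------


def rescale_255(image: FieldImage, mask: FieldMask) -> np.ndarray:
    """Min-max rescale the band to [0, 255] using AOI statistics."""
    px = np.asarray(image.pixels, dtype=float)
    if px.ndim != 2:
        raise ValueError("edge detection needs a single-band image; use to_grayscale")
    vals = px[mask.bits]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros_like(px)
    return np.clip((px - lo) / (hi - lo) * 255.0, 0.0, 255.0)


def _interior(mask: FieldMask, border_px: int = 2) -> np.ndarray:
    """AOI mask eroded so edges hugging the mask outline are discarded."""
    return ndi.binary_erosion(mask.bits, iterations=border_px, border_value=0)


def canny_edges(image: FieldImage, params: CannyParams, mask: FieldMask) -> EdgeMap:
    """Canny edge primitives: Gaussian smoothing, Sobel gradient, NMS, hysteresis."""
    scaled = rescale_255(image, mask)
    smoothed = ndi.gaussian_filter(scaled, params.sigma)
    grad = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
    gmax = float(grad.max())
    if gmax == 0:
        return EdgeMap(np.zeros(image.shape, dtype=bool), params)
    low, high = params.resolve(gmax)
    bits = _skimage_canny(scaled, sigma=params.sigma, low_threshold=low, high_threshold=high)
    bits &= _interior(mask)
    return EdgeMap(bits, params)


# ---------------------------------------------------------------------------
# phase congruency (log-Gabor filter bank)


def _filter_grids(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0  # avoid log(0) at DC; the DC gain is zeroed anyway
    theta = np.arctan2(-fy, fx)  # y negated: angles measured with y up
    return radius, np.sin(theta), np.cos(theta)


def _lowpass(radius: np.ndarray, cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def phase_congruency(img: np.ndarray, params: PCParams) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-moment phase congruency map and per-pixel edge normal angle.

    Returns ``(M, phi)`` where ``M`` is the edge strength (unitless, ~[0, 1])
    and ``phi`` is the normal direction of the local feature in radians
    (array convention: x = col, y = row increasing downwards).
    """
    rows, cols = img.shape
    min_wl = params.effective_min_wavelength
    max_wavelength = min_wl * params.mult ** (params.nscale - 1)
    if min(rows, cols) < max_wavelength:
        raise ValueError(
            f"image ({rows}x{cols}) is smaller than the largest filter wavelength "
            f"({max_wavelength:.1f} px); reduce sigma/nscale/mult or supply a larger window"
        )
    imf = np.fft.fft2(img)
    radius, sintheta, costheta = _filter_grids(rows, cols)
    lp = _lowpass(radius)
    log_gabors = []
    for s in range(params.nscale):
        wavelength = min_wl * params.mult**s
        fo = 1.0 / wavelength
        lg = np.exp(-(np.log(radius / fo) ** 2) / (2 * np.log(params.sigma_onf) ** 2))
        lg *= lp
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    theta_sigma = np.pi / params.norient / 1.3
    eps = 1e-4
    per_orient: list[tuple[np.ndarray, np.ndarray, np.ndarray, float]] = []
    for o in range(params.norient):
        angl = o * np.pi / params.norient
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2 * theta_sigma**2))
        sumE = np.zeros((rows, cols))
        sumO = np.zeros((rows, cols))
        sumAn = np.zeros((rows, cols))
        maxAn = np.zeros((rows, cols))
        responses = []
        tau = 0.0
        for s, lg in enumerate(log_gabors):
            eo = np.fft.ifft2(imf * lg * spread)
            responses.append(eo)
            an = np.abs(eo)
            sumE += eo.real
            sumO += eo.imag
            sumAn += an
            np.maximum(maxAn, an, out=maxAn)
            if s == 0:
                tau = float(np.median(an)) / np.sqrt(np.log(4))
        x_energy = np.sqrt(sumE**2 + sumO**2) + eps
        mean_e, mean_o = sumE / x_energy, sumO / x_energy
        # energy: amplitude-weighted phase agreement (Kovesi's formulation)
        energy = np.zeros((rows, cols))
        for eo in responses:
            e, od = eo.real, eo.imag
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)
        # expected noise energy from the smallest-scale amplitude statistics
        total_tau = tau * (1 - (1 / params.mult) ** params.nscale) / (1 - 1 / params.mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2)
        noise_sigma = total_tau * np.sqrt((4 - np.pi) / 2)
        T = noise_mean + params.k * noise_sigma
        # frequency-spread weighting penalizes narrowband (ringing) responses
        width = (sumAn / (maxAn + eps) - 1) / (params.nscale - 1)
        weight = 1.0 / (1.0 + np.exp(10.0 * (0.5 - width)))
        per_orient.append((energy, sumAn, weight, T))

    # On (near-)noise-free imagery the Rayleigh noise estimate collapses and
    # orientations with negligible amplitude report spuriously perfect phase
    # agreement; floor the threshold at a small fraction of the peak energy.
    # The floor scales linearly with image contrast, so PC stays
    # contrast-invariant.
    energy_max = max(float(e.max()) for e, _, _, _ in per_orient)
    covx2 = np.zeros((rows, cols))
    covy2 = np.zeros((rows, cols))
    covxy = np.zeros((rows, cols))
    for o, (energy, sumAn, weight, T) in enumerate(per_orient):
        T = max(T, 0.02 * energy_max)
        pc_o = weight * np.maximum(energy - T, 0.0) / (sumAn + eps)
        angl = o * np.pi / params.norient
        # angl is measured y-up; flip the sine back to array coords
        c, s_ = np.cos(angl), -np.sin(angl)
        covx2 += (pc_o * c) ** 2
        covy2 += (pc_o * s_) ** 2
        covxy += pc_o**2 * c * s_

    covx2 *= 2.0 / params.norient
    covy2 *= 2.0 / params.norient
    covxy *= 4.0 / params.norient
    denom = np.sqrt((covx2 - covy2) ** 2 + covxy**2)
    M = (covy2 + covx2 + denom) / 2.0
    phi = 0.5 * np.arctan2(covxy, covx2 - covy2)
    return M, phi


def _nms(strength: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Quantized non-maximum suppression along the per-pixel normal direction."""
    out = np.zeros_like(strength)
    ang = np.mod(np.rad2deg(normal), 180.0)
    sector = ((ang + 22.5) // 45).astype(int) % 4  # 0:E-W, 1:NE-SW, 2:N-S, 3:NW-SE
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    padded = np.pad(strength, 1, mode="constant")
    for sec, (dr, dc) in offsets.items():
        n1 = padded[1 + dr : 1 + dr + strength.shape[0], 1 + dc : 1 + dc + strength.shape[1]]
        n2 = padded[1 - dr : 1 - dr + strength.shape[0], 1 - dc : 1 - dc + strength.shape[1]]
        keep = (sector == sec) & (strength >= n1) & (strength > n2)
        out[keep] = strength[keep]
    return out


def pc_edges(image: FieldImage, params: PCParams, mask: FieldMask) -> EdgeMap:
    """Phase-congruency edge primitives, thinned to single-pixel width."""
    scaled = rescale_255(image, mask)
    if not np.any(scaled != scaled.flat[0]):
        return EdgeMap(np.zeros(image.shape, dtype=bool), params)
    M, phi = phase_congruency(scaled, params)
    thin = _nms(M, phi)
    # crop to the AOI interior before thresholding so FFT wrap-around
    # artifacts at the array border cannot set the relative threshold
    thin[~_interior(mask)] = 0.0
    tmax = float(thin.max())
    if tmax == 0:
        return EdgeMap(np.zeros(image.shape, dtype=bool), params)
    low, high = params.resolve(tmax)
    bits = apply_hysteresis_threshold(thin, low, high)
    return EdgeMap(bits, params)


def dual_axis_edges(
    image: FieldImage,
    params_major: CannyParams | PCParams,
    params_minor: CannyParams | PCParams,
    mask: FieldMask,
) -> tuple[EdgeMap, EdgeMap]:
    """Independent edge maps for the field's major and minor axes.

    Useful when the frequency of plot divisions differs per axis, e.g. long
    narrow plots where heavy smoothing is needed along one direction only.
    Each map is later paired only with Hough detection along its own axis.
    """

    def detect(params: CannyParams | PCParams) -> EdgeMap:
        if isinstance(params, CannyParams):
            return canny_edges(image, params, mask)
        return pc_edges(image, params, mask)

    em_major = detect(params_major)
    em_major.axis_tag = "major"
    em_minor = detect(params_minor)
    em_minor.axis_tag = "minor"
    return em_major, em_minor
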