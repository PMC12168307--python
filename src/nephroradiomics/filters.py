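"""Derived-image bank for texture feature extraction.

The default bank yields 15 image types per input volume: the original,
Laplacian-of-Gaussian responses at 1 mm and 2 mm, the 8 subbands of a
single-level stationary (undecimated) 3D wavelet decomposition, and four
stochastic/smoothing filters (shot noise, binomial blur, speckle noise,
additive Gaussian noise). All outputs preserve the input shape; noise
filters are pure functions of (volume, seed, params).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from .errors import ConfigurationError, RangeError

WAVELET_SUBBAND_NAMES = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def log_filter(volume, spacing, sigma_mm, normalize=True):
    """Laplacian of Gaussian with physical-units sigma.

    Sigma is converted to voxels per axis via the spacing. ``normalize``
    applies the sigma^2 scale normalization so responses are comparable
    across scales (the blob-detection convention).
    """
    if sigma_mm <= 0:
        raise RangeError("sigma_mm must be > 0")
    if sigma_mm < min(spacing) / 2:
        warnings.warn(
            f"LoG sigma {sigma_mm} mm is below half the smallest voxel "
            f"spacing {min(spacing)} mm; the scale is degenerate",
            stacklevel=2,
        )
    sigma_vox = [sigma_mm / s for s in spacing]
    vol = np.asarray(volume, dtype=np.float64)
    out = ndimage.gaussian_laplace(vol, sigma_vox, mode="reflect")
    # the truncated kernel does not sum exactly to zero; remove the DC
    # response so constants are annihilated exactly
    k = float(ndimage.gaussian_laplace(np.ones((1, 1, 1)), sigma_vox, mode="reflect")[0, 0, 0])
    out -= k * vol
    if normalize:
        out *= sigma_mm**2
    return out


def wavelet_decompose(volume, wavelet="coif1"):
    """Single-level stationary 3D wavelet decomposition into 8 subbands.

    Returns a dict keyed 'LLL'..'HHH' (axis-ordered low/high string). The
    normalized stationary transform is energy-preserving, and the input is
    recoverable from the 8 subbands (see :func:`wavelet_reconstruct`).
    Odd-length axes are periodically padded by one voxel and cropped back.
    """
    w = pywt.Wavelet(wavelet)
    vol = np.asarray(volume, dtype=np.float64)
    if any(n < w.dec_len for n in vol.shape):
        raise ConfigurationError(
            f"every dimension must be >= the filter length {w.dec_len}; got {vol.shape}"
        )
    pad = [(0, n % 2) for n in vol.shape]
    padded = np.pad(vol, pad, mode="wrap") if any(p[1] for p in pad) else vol
    coeffs = pywt.swtn(padded, w, level=1, norm=True)[0]
    out = {}
    crop = tuple(slice(0, n) for n in vol.shape)
    for key, arr in coeffs.items():
        name = "".join("L" if c == "a" else "H" for c in key)
        out[name] = arr[crop]
    return {name: out[name] for name in WAVELET_SUBBAND_NAMES}


def wavelet_reconstruct(subbands, wavelet="coif1"):
    """Invert :func:`wavelet_decompose` (even-length axes only)."""
    coeffs = {
        "".join("a" if c == "L" else "d" for c in name): np.asarray(arr, dtype=np.float64)
        for name, arr in subbands.items()
    }
    return pywt.iswtn([coeffs], pywt.Wavelet(wavelet), norm=True)


def binomial_blur(volume, iterations=1):
    """Separable [1,2,1]/4 binomial smoothing, ``iterations`` passes per axis."""
    if iterations < 1:
        raise RangeError("iterations must be >= 1")
    out = np.asarray(volume, dtype=np.float64)
    kernel = np.array([0.25, 0.5, 0.25])
    for _ in range(iterations):
        for axis in range(out.ndim):
            out = ndimage.convolve1d(out, kernel, axis=axis, mode="reflect")
    return out


def shot_noise(volume, seed, scale=1.0):
    """Poisson (shot) noise: voxelwise Poisson(I/scale) * scale.

    Smaller ``scale`` means more photons per unit intensity and hence less
    relative noise; requires a nonnegative volume.
    """
    vol = np.asarray(volume, dtype=np.float64)
    if scale <= 0:
        raise RangeError("scale must be > 0")
    if vol.min() < 0:
        raise RangeError("shot noise requires nonnegative intensities; shift first")
    rng = np.random.default_rng(seed)
    return rng.poisson(vol / scale).astype(np.float64) * scale


def speckle_noise(volume, seed, sigma=0.1):
    """Multiplicative Gaussian speckle: I * (1 + sigma*N(0,1))."""
    vol = np.asarray(volume, dtype=np.float64)
    rng = np.random.default_rng(seed)
    return vol * (1.0 + sigma * rng.standard_normal(vol.shape))


def additive_gaussian_noise(volume, seed, sigma=0.1):
    """Additive Gaussian noise with SD = sigma * SD(volume)."""
    vol = np.asarray(volume, dtype=np.float64)
    rng = np.random.default_rng(seed)
    return vol + sigma * vol.std() * rng.standard_normal(vol.shape)


@dataclass(frozen=True)
class FilterBankConfig:
    include_original: bool = True
    log_sigmas_mm: tuple[float, ...] = (1.0, 2.0)
    wavelet: str | None = "coif1"
    include_noise_filters: bool = True
    shot_noise_scale: float = 1.0
    binomial_iterations: int = 4
    speckle_sigma: float = 0.1
    gaussian_sigma: float = 0.1

    def image_type_names(self) -> list[str]:
        names = []
        if self.include_original:
            names.append("original")
        for s in self.log_sigmas_mm:
            names.append(_log_name(s))
        if self.wavelet:
            names += [f"wavelet-{b}" for b in WAVELET_SUBBAND_NAMES]
        if self.include_noise_filters:
            names += ["shotnoise", "binomialblur", "specklenoise", "gaussiannoise"]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate image-type names in filter bank")
        return names


def _log_name(sigma_mm: float) -> str:
    return f"log-sigma-{sigma_mm:.1f}".replace(".", "-") + "-mm-3D"


DEFAULT_FILTER_BANK = FilterBankConfig()


def derive_image_types(volume, spacing, cfg: FilterBankConfig = DEFAULT_FILTER_BANK, seed=0):
    """Compute the named bank of derived images (default: exactly 15).

    Noise-filter substreams are derived deterministically from ``seed``.
    """
    vol = np.asarray(volume, dtype=np.float64)
    names = cfg.image_type_names()
    out: dict[str, np.ndarray] = {}
    if cfg.include_original:
        out["original"] = vol
    for s in cfg.log_sigmas_mm:
        out[_log_name(s)] = log_filter(vol, spacing, s)
    if cfg.wavelet:
        for band, arr in wavelet_decompose(vol, cfg.wavelet).items():
            out[f"wavelet-{band}"] = arr
    if cfg.include_noise_filters:
        shifted = vol - min(vol.min(), 0.0)
        out["shotnoise"] = shot_noise(shifted, [seed, 0], cfg.shot_noise_scale)
        out["binomialblur"] = binomial_blur(vol, cfg.binomial_iterations)
        out["specklenoise"] = speckle_noise(vol, [seed, 1], cfg.speckle_sigma)
        out["gaussiannoise"] = additive_gaussian_noise(vol, [seed, 2], cfg.gaussian_sigma)
    assert list(out) == names
    return out
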