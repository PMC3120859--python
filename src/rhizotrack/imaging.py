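"""PSF measurement from bead stacks and EM (Richardson–Lucy) deconvolution.

The deconvolution is the classical multiplicative expectation-maximization
scheme for Poisson noise with a known, shift-invariant PSF.  A constant
background (low-percentile estimate) is subtracted before iterating, the
stack is padded reflectively so frequency-domain convolution does not wrap
around, and a fixed iteration count (default 30) is used instead of a
convergence tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve
from skimage.feature import peak_local_max

from .types import ImageStack, PSF

__all__ = [
    "measure_psf",
    "em_deconvolve",
    "poisson_log_likelihood",
    "profile_fwhm",
]

_EPS = 1e-12


def profile_fwhm(profile: np.ndarray, spacing: float) -> float:
    """Full width at half maximum of a 1D profile, by linear interpolation
    of the half-height crossings around the global maximum."""
    profile = np.asarray(profile, dtype=float)
    i_max = int(np.argmax(profile))
    half = profile[i_max] / 2.0
    # walk left
    left = float(i_max)
    for i in range(i_max, 0, -1):
        if profile[i - 1] < half:
            frac = (profile[i] - half) / (profile[i] - profile[i - 1])
            left = i - frac
            break
    else:
        left = 0.0
    right = float(i_max)
    for i in range(i_max, len(profile) - 1):
        if profile[i + 1] < half:
            frac = (profile[i] - half) / (profile[i] - profile[i + 1])
            right = i + frac
            break
    else:
        right = float(len(profile) - 1)
    return (right - left) * spacing


def _kernel_fwhm(kernel: np.ndarray, voxel_sizes) -> tuple[float, float, float]:
    zc, yc, xc = np.unravel_index(np.argmax(kernel), kernel.shape)
    dx, dy, dz = voxel_sizes
    return (
        profile_fwhm(kernel[zc, yc, :], dx),
        profile_fwhm(kernel[zc, :, xc], dy),
        profile_fwhm(kernel[:, yc, xc], dz),
    )


def measure_psf(
    bead_stack: ImageStack,
    threshold: float | None = None,
    window_um: float = 12.0,
) -> PSF:
    """Average aligned bead sub-volumes into a normalized PSF kernel.

    Local maxima above ``threshold`` (default: background plus half the
    dynamic range) are treated as beads; a window of ``window_um`` µm
    half-width is extracted around each, background-subtracted using the
    window border median, averaged and normalized to unit sum.
    """
    data = bead_stack.voxels
    if threshold is None:
        threshold = float(np.percentile(data, 10) + 0.5 * np.ptp(data))
    dx, dy, dz = bead_stack.voxel_sizes
    half = np.maximum(
        1, np.round(window_um / np.array([dz, dy, dx])).astype(int)
    )
    peaks = peak_local_max(
        data, min_distance=int(max(half)), threshold_abs=threshold, exclude_border=False
    )
    # keep peaks whose window fits inside the stack
    shape = np.array(data.shape)
    peaks = peaks[np.all((peaks - half >= 0) & (peaks + half + 1 <= shape), axis=1)]
    if len(peaks) == 0:
        raise ValueError("no beads found above threshold")
    acc = np.zeros(2 * half + 1)
    for p in peaks:
        sub = data[
            p[0] - half[0] : p[0] + half[0] + 1,
            p[1] - half[1] : p[1] + half[1] + 1,
            p[2] - half[2] : p[2] + half[2] + 1,
        ].astype(float)
        border = np.concatenate(
            [sub[0].ravel(), sub[-1].ravel(), sub[:, 0].ravel(), sub[:, -1].ravel()]
        )
        acc += np.clip(sub - np.median(border), 0.0, None)
    kernel = acc / acc.sum()
    return PSF(
        kernel=kernel,
        voxel_sizes=bead_stack.voxel_sizes,
        fwhm=_kernel_fwhm(kernel, bead_stack.voxel_sizes),
    )


def _convolve(a: np.ndarray, k: np.ndarray) -> np.ndarray:
    return fftconvolve(a, k, mode="same")


def em_deconvolve(
    stack: ImageStack,
    psf: PSF,
    n_iter: int = 30,
    background: float | None = None,
) -> ImageStack:
    """Richardson–Lucy (Poisson EM) deconvolution.

    ``background`` defaults to the stack's 1st intensity percentile; it is
    subtracted (clamped at zero) before the EM iterations, which assume
    signal-only Poisson counts.  Reflective padding by the PSF half-width
    precedes the frequency-domain convolutions.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if not np.allclose(stack.voxel_sizes, psf.voxel_sizes, rtol=1e-6):
        raise ValueError(
            f"voxel sizes differ between stack {stack.voxel_sizes} "
            f"and PSF {psf.voxel_sizes}"
        )
    kernel = psf.kernel
    if background is None:
        background = float(np.percentile(stack.voxels, 1.0))
    data = np.clip(stack.voxels - background, 0.0, None)
    pad = [(s // 2, s // 2) for s in kernel.shape]
    padded = np.pad(data, pad, mode="reflect")
    kernel_t = kernel[::-1, ::-1, ::-1]
    est = np.full_like(padded, max(padded.mean(), _EPS))
    for _ in range(n_iter):
        blurred = _convolve(est, kernel)
        ratio = padded / np.clip(blurred, _EPS, None)
        est = est * _convolve(ratio, kernel_t)
        np.clip(est, 0.0, None, out=est)
    sl = tuple(slice(lo, est.shape[i] - hi) for i, (lo, hi) in enumerate(pad))
    return ImageStack(
        voxels=est[sl],
        voxel_sizes=stack.voxel_sizes,
        time=stack.time,
        origin=stack.origin,
    )


def poisson_log_likelihood(
    data: np.ndarray, estimate: np.ndarray, kernel: np.ndarray
) -> float:
    """Poisson log-likelihood of ``data`` under a blurred estimate, up to
    the data-dependent constant: sum(d * log(mu) - mu)."""
    mu = np.clip(_convolve(estimate, kernel), _EPS, None)
    return float(np.sum(data * np.log(mu) - mu))
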