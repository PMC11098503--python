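"""Feature-space handling.

Latent and feature matrices are the two in-memory currencies of the
analysis: a :class:`LatentMatrix` holds per-stimulus generative latents
(z-, w- or clip-like spaces), a :class:`FeatureMatrix` holds per-stimulus
feature vectors from some extraction stage (a latent kind or a layer of
the toy hierarchy).  This module also implements the latent-space linear
operations used to probe the decoder (interpolation, vector arithmetic)
and the Gaussian-smooth-then-subsample downsampling applied to large
activation maps before encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "LatentMatrix",
    "FeatureMatrix",
    "downsample_activation",
    "interpolate_latents",
    "latent_arithmetic",
]


@dataclass
class LatentMatrix:
    """Stimuli x latent-dim matrix tagged with its latent kind.

    Parameters
    ----------
    values : ndarray, shape (n_stimuli, d)
    kind : str
        One of ``"z"``, ``"w"`` or ``"clip-like"``.
    """

    values: np.ndarray
    kind: str = "z"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("latent matrix must be 2-D (stimuli x dims)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("latent matrix contains non-finite values")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureMatrix:
    """Stimuli x feature-dim design matrix with provenance metadata."""

    values: np.ndarray
    kind: str = "layer-1"
    downsample_factor: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("feature matrix must be 2-D with >= 1 column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def _gaussian_kernel(size: int) -> np.ndarray:
    """Normalized 1-D Gaussian kernel with ``size`` taps and sigma = size/2.

    The kernel is centred on the tap grid (half-sample offsets for even
    sizes) and renormalized to sum to one so constants pass unchanged.
    """
    offsets = np.arange(size, dtype=float) - (size - 1) / 2.0
    sigma = size / 2.0
    k = np.exp(-0.5 * (offsets / sigma) ** 2)
    return k / k.sum()


def downsample_activation(activation: np.ndarray, factor: int) -> np.ndarray:
    """Smooth each channel with a Gaussian and subsample by ``factor``.

    Per channel the H x W map is filtered with a separable Gaussian whose
    kernel size equals the downsampling factor (sigma = factor/2, reflect
    padding), then subsampled with stride ``factor`` starting at index 0.
    Factor 1 is the identity.

    Parameters
    ----------
    activation : ndarray, shape (channels, H, W)
    factor : int >= 1
        H and W must be divisible by ``factor``.
    """
    if factor < 1:
        raise ValueError("downsampling factor must be >= 1")
    act = np.asarray(activation, dtype=float)
    if act.ndim != 3:
        raise ValueError("activation must be (channels, H, W)")
    _, h, w = act.shape
    if h % factor or w % factor:
        raise ValueError(f"spatial dims ({h}, {w}) not divisible by factor {factor}")
    if factor == 1:
        return act.copy()
    kernel = _gaussian_kernel(factor)
    smoothed = ndimage.correlate1d(act, kernel, axis=1, mode="reflect")
    smoothed = ndimage.correlate1d(smoothed, kernel, axis=2, mode="reflect")
    return smoothed[:, ::factor, ::factor]


def interpolate_latents(w1: np.ndarray, w2: np.ndarray, steps: int) -> np.ndarray:
    """Linearly interpolate two latent vectors in ``steps`` equal steps.

    Returns the ordered stack w(a_k) = (1 - a_k) w1 + a_k w2 with a_k
    equally spaced in [0, 1]; the endpoints are returned exactly.
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.shape != w2.shape:
        raise ValueError("latent dimensions do not match")
    if steps < 2:
        raise ValueError("need at least 2 interpolation steps")
    alphas = np.linspace(0.0, 1.0, steps)
    out = (1.0 - alphas)[:, None] * w1[None, :] + alphas[:, None] * w2[None, :]
    out[0] = w1
    out[-1] = w2
    return out


def latent_arithmetic(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Analogy-style vector arithmetic a - b + c in latent space."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    if not (a.shape == b.shape == c.shape):
        raise ValueError("latent dimensions do not match")
    return a - b + c
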