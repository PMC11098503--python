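"""Synthetic world generator.

The analysis pipeline was designed for recordings of macaque visual
cortex responding to GAN-synthesized stimuli.  This module builds a
fully known stand-in for that world so every downstream stage can be
tested against ground truth:

* Gaussian latents with StyleGAN-style psi-truncation toward the mean;
* a fixed invertible mixing standing in for the z-to-w mapping network;
* a deterministic blob renderer standing in for the image generator
  (each latent dimension controls exactly one blob parameter, so the
  latent space is feature-disentangled by construction);
* a pooling-pyramid feature hierarchy standing in for layer activations
  of a discriminative network (coarse-to-fine complexity gradient);
* a linear-Gaussian response simulator producing trial-resolved
  multi-electrode recordings with region-specific temporal profiles
  locked to stimulus onset, 1 ms bins, and configurable repetition
  structure (1 repetition for training stimuli, 20 for test stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix, LatentMatrix
from .responses import RegionMap, ResponseRecording, build_region_map

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "gen_latents",
    "make_mixing",
    "map_z_to_w",
    "render_toy_images",
    "latent_to_blob_params",
    "extract_toy_features",
    "temporal_profile",
    "make_ground_truth",
    "simulate_responses",
]

#: default region layout: (name, n_arrays, channels_per_array)
DEFAULT_REGIONS: tuple[tuple[str, int, int], ...] = (
    ("V1", 2, 16),
    ("V4", 2, 16),
    ("IT", 2, 16),
)

#: region response peaks in ms after stimulus onset
DEFAULT_PEAKS: dict[str, float] = {"V1": 75.0, "V4": 100.0, "IT": 125.0}

#: feature-forward time windows per region, ms after stimulus onset
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "V1": (25.0, 125.0),
    "V4": (50.0, 150.0),
    "IT": (75.0, 175.0),
}


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    Defaults are the desk-scale conditions used throughout the test
    suite: 1000 training stimuli presented once, 100 test stimuli
    presented 20 times, 32 latent dimensions, and 96 channels split over
    V1/V4/IT.  ``recording_scale`` returns the structural configuration of
    the original recordings (4000/100 stimuli, 512-dim latents, 7/4/4
    arrays of 64 channels = 960 channels); it is used for structural
    counts only — materializing its response tensors is never required.
    """

    n_train: int = 1000
    n_test: int = 100
    latent_dim: int = 32
    truncation_psi: float = 0.7
    regions: tuple[tuple[str, int, int], ...] = DEFAULT_REGIONS
    trial_ms: int = 300
    onset_ms: int = 100
    peak_ms: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PEAKS))
    windows: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    noise_sigma: float = 0.5
    n_reps_train: int = 1
    n_reps_test: int = 20
    image_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")
        if not 0.0 <= self.truncation_psi <= 1.0:
            raise ValueError("truncation_psi must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        for name in (n for n, *_ in self.regions):
            if name not in self.peak_ms:
                raise ValueError(f"no response peak specified for region {name!r}")
            if self.peak_ms[name] + self.onset_ms > self.trial_ms:
                raise ValueError(f"peak for {name!r} falls outside the trial")
        for name, (lo, hi) in self.windows.items():
            if not (0 <= lo < hi and hi + self.onset_ms <= self.trial_ms):
                raise ValueError(f"window for {name!r} outside the recorded trial")

    @property
    def n_channels(self) -> int:
        return sum(a * c for _, a, c in self.regions)

    def region_map(self) -> RegionMap:
        return build_region_map(self.regions, self.windows)

    @classmethod
    def recording_scale(cls) -> "SyntheticConfig":
        """Structural configuration of the original recordings."""
        return cls(
            n_train=4000,
            n_test=100,
            latent_dim=512,
            regions=(("V1", 7, 64), ("V4", 4, 64), ("IT", 4, 64)),
        )


@dataclass
class GroundTruth:
    """The synthetic world's true stimulus-response mapping.

    ``weights[region]`` is the (feature-dim x region-channels) linear map
    from that region's driving feature space to its channels; responses
    unfold in time along ``profiles[region]`` (nonnegative, unit peak)
    and are corrupted by i.i.d. Gaussian noise per (stimulus, repetition,
    channel, bin).
    """

    weights: dict[str, np.ndarray]
    bias: np.ndarray
    profiles: dict[str, np.ndarray]
    noise_sigma: float
    seed: int

    def __post_init__(self) -> None:
        for name, w in self.weights.items():
            if not np.all(np.isfinite(w)):
                raise ValueError(f"non-finite weights for region {name!r}")
        for name, p in self.profiles.items():
            if p.min() < 0 or not np.isclose(p.max(), 1.0):
                raise ValueError(
                    f"temporal profile for {name!r} must be nonnegative with unit peak"
                )
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")


def gen_latents(n: int, d: int, psi: float, seed: int, kind: str = "z") -> LatentMatrix:
    """Sample ``n`` i.i.d. standard-normal latents and psi-truncate them.

    Truncation interpolates every sample toward the latent-space center
    mu (the origin for z-space): w' = mu + psi * (w - mu).  psi = 1
    leaves the samples untouched; psi = 0 collapses them onto the mean.
    """
    if n < 1 or d < 1:
        raise ValueError("n and d must be >= 1")
    if not 0.0 <= psi <= 1.0:
        raise ValueError("psi must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((n, d))
    return LatentMatrix(values=psi * raw, kind=kind)


def make_mixing(d: int, seed: int) -> np.ndarray:
    """Fixed random orthogonal d x d mixing (toy z-to-w mapping network)."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    # fix signs so the factorization (hence the mixing) is unique
    return q * np.sign(np.diag(r))


def map_z_to_w(
    z: LatentMatrix, mixing: np.ndarray, curvature: float = 0.0
) -> LatentMatrix:
    """Map z-latents through a fixed mixing to the w-latent space.

    ``mixing`` has shape (w_dim, z_dim); rows of the output are
    ``mixing @ z_row``.  For an invertible mixing the map is bijective.
    A positive ``curvature`` c adds the strictly monotone elementwise
    bend y -> y + c*y^3 after mixing — a stand-in for the mapping
    network's nonlinearity, so that w carries structure no linear model
    of z can reproduce while staying bijective.
    """
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 2 or mixing.shape[1] != z.dim:
        raise ValueError(
            f"mixing columns ({mixing.shape[-1]}) must equal z dim ({z.dim})"
        )
    if curvature < 0:
        raise ValueError("curvature must be nonnegative")
    values = z.values @ mixing.T
    if curvature:
        values = values + curvature * values**3
    return LatentMatrix(values=values, kind="w")


# ---------------------------------------------------------------------------
# toy image generator: additive Gaussian blobs
# ---------------------------------------------------------------------------

_PARAMS_PER_BLOB = 4  # (x, y, log-width, amplitude)


def latent_to_blob_params(w: np.ndarray, size: int) -> np.ndarray:
    """Deterministic map from one latent vector to blob parameters.

    Latent dimensions are consumed in groups of four: (center x,
    center y, log-width, amplitude) for one blob; missing trailing
    parameters default to zero.  Returns an array (n_blobs, 4) with
    centers in pixel units, widths in pixels and signed amplitudes.
    """
    w = np.asarray(w, dtype=float).ravel()
    n_blobs = -(-w.size // _PARAMS_PER_BLOB)  # ceil division
    padded = np.zeros(n_blobs * _PARAMS_PER_BLOB)
    padded[: w.size] = w
    raw = padded.reshape(n_blobs, _PARAMS_PER_BLOB)
    params = np.empty_like(raw)
    params[:, 0] = size * (0.5 + 0.35 * np.tanh(raw[:, 0]))
    params[:, 1] = size * (0.5 + 0.35 * np.tanh(raw[:, 1]))
    params[:, 2] = (size / 8.0) * np.exp(0.5 * np.tanh(raw[:, 2]))
    params[:, 3] = raw[:, 3]
    return params


def render_toy_images(w: LatentMatrix | np.ndarray, size: int = 64) -> np.ndarray:
    """Render one grayscale image per latent row as additive Gaussian blobs.

    The renderer is a deterministic stand-in for a generative model's
    synthesis network: each group of four latent dimensions sets the
    position, width and amplitude of one isotropic blob, so equal
    latents give bit-identical images and each dimension controls a
    single visual attribute.  The all-zero latent renders the canonical
    baseline image (all blobs at the center with zero amplitude, i.e. a
    blank image).
    """
    if size < 8:
        raise ValueError("image size must be >= 8 to place blobs")
    values = w.values if isinstance(w, LatentMatrix) else np.asarray(w, dtype=float)
    if values.ndim == 1:
        values = values[None, :]
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    images = np.zeros((values.shape[0], size, size))
    for i, row in enumerate(values):
        for cx, cy, width, amp in latent_to_blob_params(row, size):
            if amp == 0.0:
                continue
            images[i] += amp * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * width**2)
            )
    return images


# ---------------------------------------------------------------------------
# toy feature hierarchy: pooling pyramid + fixed random projection
# ---------------------------------------------------------------------------

_PROJECTION_ROOT_SEED = 7  # package constant; fixes all projection matrices


def _feature_dim(pooled_dim: int, level: int) -> int:
    return min(pooled_dim, max(pooled_dim // 8, 2 ** (6 - level)))


def extract_toy_features(images: np.ndarray, level: int) -> FeatureMatrix:
    """Multi-scale features: block-mean pooling then a fixed random projection.

    Level k pools the image with non-overlapping 2^k blocks and projects
    the flattened pooled map through a fixed seeded Gaussian matrix.
    Higher levels therefore have coarser spatial support and strictly
    lower feature dimension, emulating the complexity gradient of a deep
    hierarchy.  The projection dimension stays below the pooled pixel
    count at every level, so no level's feature space linearly contains
    another's — levels are mutually identifiable by encoding quality.
    """
    if not 1 <= level <= 5:
        raise ValueError("level must lie in 1..5")
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None, :, :]
    n, h, w = images.shape
    scale = 2**level
    if h < scale or w < scale:
        raise ValueError(f"image ({h}x{w}) smaller than pooling scale {scale}")
    if h % scale or w % scale:
        raise ValueError(f"image dims must be divisible by pooling scale {scale}")
    pooled = images.reshape(n, h // scale, scale, w // scale, scale).mean(axis=(2, 4))
    flat = pooled.reshape(n, -1)
    p = flat.shape[1]
    out_dim = _feature_dim(p, level)
    rng = np.random.default_rng(
        np.random.SeedSequence([_PROJECTION_ROOT_SEED, level, p, out_dim])
    )
    projection = rng.standard_normal((p, out_dim)) / np.sqrt(p)
    return FeatureMatrix(values=flat @ projection, kind=f"layer-{level}")


# ---------------------------------------------------------------------------
# response simulation
# ---------------------------------------------------------------------------


def temporal_profile(
    trial_ms: int, onset_ms: int, peak_ms: float, width_ms: float = 25.0
) -> np.ndarray:
    """Onset-locked Gaussian response profile over 1 ms bins, unit peak.

    The profile is zero before stimulus onset and rises to 1 at
    ``onset_ms + peak_ms``; ``width_ms`` is the Gaussian sd of the bump.
    """
    t = np.arange(trial_ms, dtype=float)
    center = onset_ms + peak_ms
    profile = np.exp(-0.5 * ((t - center) / width_ms) ** 2)
    profile[t < onset_ms] = 0.0
    peak = profile.max()
    if peak <= 0:
        raise ValueError("profile peak falls outside the trial")
    return profile / peak


def make_ground_truth(
    features_by_region: dict[str, FeatureMatrix | np.ndarray],
    region_map: RegionMap,
    cfg: SyntheticConfig,
    seed: int | None = None,
) -> GroundTruth:
    """Draw random linear weights per region, scaled to unit signal variance.

    Weights are i.i.d. Gaussian, rescaled per channel so the noiseless
    windowed signal has unit standard deviation over the supplied
    (training) stimuli; ``cfg.noise_sigma`` is then directly the
    per-bin noise-to-signal ratio.  Biases are small random offsets.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 91]))
    weights: dict[str, np.ndarray] = {}
    profiles: dict[str, np.ndarray] = {}
    n_channels = region_map.n_channels
    bias = 0.1 * rng.standard_normal(n_channels)
    for name in region_map.region_names:
        feats = features_by_region[name]
        values = feats.values if isinstance(feats, FeatureMatrix) else np.asarray(feats)
        n_ch = len(region_map.channels(name))
        w = rng.standard_normal((values.shape[1], n_ch))
        signal = values @ w
        sd = signal.std(axis=0)
        if np.any(sd == 0):
            raise ValueError(f"degenerate feature space for region {name!r}")
        weights[name] = w / sd
        profiles[name] = temporal_profile(
            cfg.trial_ms, cfg.onset_ms, cfg.peak_ms[name]
        )
    return GroundTruth(
        weights=weights,
        bias=bias,
        profiles=profiles,
        noise_sigma=cfg.noise_sigma,
        seed=seed,
    )


def simulate_responses(
    features_by_region: dict[str, FeatureMatrix | np.ndarray],
    gt: GroundTruth,
    cfg: SyntheticConfig,
    n_reps: int,
    seed: int,
) -> ResponseRecording:
    """Simulate a trial-resolved multi-electrode recording.

    Channel c of region r at time bin t responds with
    ``profile_r[t] * (features_r @ weights_r)[:, c] + bias[c]`` plus
    i.i.d. Gaussian noise of sd ``gt.noise_sigma`` per (stimulus,
    repetition, channel, bin).  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("need at least one repetition")
    region_map = cfg.region_map()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    n_stim: int | None = None
    for name in region_map.region_names:
        feats = features_by_region[name]
        values = feats.values if isinstance(feats, FeatureMatrix) else np.asarray(feats)
        if n_stim is None:
            n_stim = values.shape[0]
        elif values.shape[0] != n_stim:
            raise ValueError("feature matrices disagree on stimulus count")
        if values.shape[1] != gt.weights[name].shape[0]:
            raise ValueError(f"weights do not conform to features for {name!r}")
    assert n_stim is not None
    out = np.empty((n_stim, n_reps, region_map.n_channels, cfg.trial_ms))
    for name in region_map.region_names:
        feats = features_by_region[name]
        values = feats.values if isinstance(feats, FeatureMatrix) else np.asarray(feats)
        chans = region_map.channels(name)
        signal = values @ gt.weights[name]  # (n_stim, n_ch)
        trace = (
            signal[:, :, None] * gt.profiles[name][None, None, :]
            + gt.bias[chans][None, :, None]
        )
        out[:, :, chans, :] = trace[:, None, :, :]
    if gt.noise_sigma > 0:
        out += gt.noise_sigma * rng.standard_normal(out.shape)
    return ResponseRecording(values=out, onset_ms=cfg.onset_ms, bin_ms=1)
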