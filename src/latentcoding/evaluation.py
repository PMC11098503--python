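"""Reconstruction-quality metrics and the permutation null.

Decoding quality is scored per stimulus by cosine similarity, either
directly between predicted and ground-truth latent vectors (latent
similarity) or between hierarchical feature representations of the
rendered images at each level of the toy feature pyramid (perceptual
similarity, the stand-in for comparing deep-network activations of
stimulus and reconstruction).  Significance comes from a permutation
null: random latents drawn from the test distribution are scored
against the true stimuli, and the observed mean similarity is ranked
against the null means with an add-one estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import extract_toy_features, render_toy_images

__all__ = [
    "cosine_similarity",
    "rowwise_cosine",
    "latent_similarity",
    "perceptual_similarity",
    "make_latent_evaluator",
    "make_full_evaluator",
    "summarize",
    "permutation_test",
    "PermutationResult",
]


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vector dimensions do not match")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def rowwise_cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cosine similarity per matching row pair of two matrices."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrix shapes do not match")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    bad = (na == 0) | (nb == 0)
    if np.any(bad):
        raise ValueError(
            f"cosine similarity undefined for zero row(s) {np.flatnonzero(bad).tolist()}"
        )
    return np.clip(np.sum(a * b, axis=1) / (na * nb), -1.0, 1.0)


def latent_similarity(w_true: np.ndarray, w_pred: np.ndarray) -> np.ndarray:
    """Per-stimulus cosine similarity between true and predicted latents."""
    return rowwise_cosine(w_true, w_pred)


def perceptual_similarity(
    stim_images: np.ndarray,
    recon_images: np.ndarray,
    levels: tuple[int, ...] = (1, 2, 3, 4, 5),
) -> dict[str, np.ndarray]:
    """Per-level cosine similarity between hierarchical image features.

    Both image stacks are run through the toy feature pyramid; at each
    level the flattened whole-level feature vectors of stimulus and
    reconstruction are compared per pair.  Early levels weight fine
    spatial structure, deep levels coarse content.
    """
    stim_images = np.asarray(stim_images, dtype=float)
    recon_images = np.asarray(recon_images, dtype=float)
    if stim_images.shape != recon_images.shape:
        raise ValueError("stimulus/reconstruction counts (or sizes) do not match")
    out: dict[str, np.ndarray] = {}
    for level in levels:
        f_stim = extract_toy_features(stim_images, level).values
        f_recon = extract_toy_features(recon_images, level).values
        out[f"level-{level}"] = rowwise_cosine(f_stim, f_recon)
    return out


def make_latent_evaluator(latents_true: np.ndarray):
    """Evaluator computing only latent similarity against fixed truth."""
    latents_true = np.asarray(latents_true, dtype=float)

    def evaluator(latents_pred: np.ndarray) -> dict[str, np.ndarray]:
        return {"latent": latent_similarity(latents_true, latents_pred)}

    return evaluator


def make_full_evaluator(
    latents_true: np.ndarray,
    image_size: int = 64,
    levels: tuple[int, ...] = (1, 2, 3, 4, 5),
):
    """Evaluator computing the full similarity battery against fixed truth.

    Predicted latents are rendered to toy images and compared to the
    true stimuli at every feature level (perceptual similarity) and in
    latent space, mirroring the six-metric reconstruction report.
    """
    latents_true = np.asarray(latents_true, dtype=float)
    stim_images = render_toy_images(latents_true, size=image_size)

    def evaluator(latents_pred: np.ndarray) -> dict[str, np.ndarray]:
        recon = render_toy_images(np.asarray(latents_pred, dtype=float), size=image_size)
        sims = perceptual_similarity(stim_images, recon, levels=levels)
        sims["latent"] = latent_similarity(latents_true, latents_pred)
        return sims

    return evaluator


def summarize(similarities: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean and standard error per metric from per-stimulus vectors."""
    rows = []
    for metric, vec in similarities.items():
        vec = np.asarray(vec, dtype=float)
        rows.append(
            {
                "metric": metric,
                "mean": float(vec.mean()),
                "sem": float(vec.std(ddof=1) / np.sqrt(vec.size)),
                "n": vec.size,
            }
        )
    return pd.DataFrame.from_records(rows).set_index("metric")


@dataclass
class PermutationResult:
    """Per-metric permutation p-values and the underlying null means."""

    p_values: dict[str, float]
    observed: dict[str, float]
    null_means: dict[str, np.ndarray]
    n_iter: int

    def percentile(self, metric: str, q: float) -> float:
        return float(np.percentile(self.null_means[metric], q))


def permutation_test(
    pred_similarities: dict[str, np.ndarray],
    latent_sampler,
    evaluator,
    n_iter: int = 999,
    seed: int = 0,
) -> PermutationResult:
    """Rank observed mean similarity against random-latent nulls.

    Per iteration a fresh set of latents is drawn from the test
    distribution via ``latent_sampler(rng)`` and scored against the
    true stimuli by ``evaluator``; the p-value per metric is the
    add-one estimator (1 + #{null mean >= observed mean}) / (1 +
    n_iter), which can never return zero.
    """
    if n_iter < 1:
        raise ValueError("need at least one permutation iteration")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    observed = {
        metric: float(np.asarray(vec, dtype=float).mean())
        for metric, vec in pred_similarities.items()
    }
    null_means: dict[str, list[float]] = {metric: [] for metric in observed}
    for _ in range(n_iter):
        random_latents = latent_sampler(rng)
        sims = evaluator(random_latents)
        for metric in observed:
            null_means[metric].append(float(np.asarray(sims[metric]).mean()))
    p_values = {}
    null_arrays = {}
    for metric in observed:
        null = np.array(null_means[metric])
        null_arrays[metric] = null
        p_values[metric] = float(
            (1 + np.sum(null >= observed[metric])) / (1 + n_iter)
        )
    return PermutationResult(
        p_values=p_values, observed=observed, null_means=null_arrays, n_iter=n_iter
    )
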