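"""Multivariate linear decoding of latents from population responses.

A single ordinary-least-squares decoder maps the z-scored population
response vector to the latent vector of the stimulus.  Region
contributions are measured by occlusion: the decoder trained on all
channels is evaluated on test responses where the channels of the other
regions are replaced by an information-free fill (their per-channel
mean over the test set), keeping the decoder itself fixed.
Time-resolved decoding slides a window over the trial and refits (or
re-applies) the decoder per window to trace when stimulus information
becomes available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .responses import (
    RegionMap,
    ResponseRecording,
    average_repetitions,
    normalize_channels,
    sliding_windows,
)

__all__ = [
    "DecodingModel",
    "fit_decoder",
    "decode",
    "occlude",
    "region_contribution",
    "time_resolved_decode",
    "TimeResolvedResult",
]


@dataclass
class DecodingModel:
    """Linear decoder: latents ~ responses @ weights + intercept."""

    weights: np.ndarray  # (channels, latent_dim)
    intercept: np.ndarray  # (latent_dim,)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("decoder weights are not finite")

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.weights.shape[1]


def fit_decoder(responses: np.ndarray, latents: np.ndarray) -> DecodingModel:
    """Ordinary least squares from responses to every latent dimension.

    Solved through the SVD pseudoinverse (rank tolerance 1e-10 relative
    to the largest singular value), which gives the minimum-norm
    solution when channels outnumber stimuli.  The intercept comes from
    centering both sides.
    """
    responses = np.asarray(responses, dtype=float)
    latents = np.asarray(latents, dtype=float)
    if responses.ndim != 2 or latents.ndim != 2:
        raise ValueError("responses and latents must be 2-D")
    if responses.shape[0] != latents.shape[0]:
        raise ValueError("responses and latents disagree on stimulus count")
    if responses.shape[0] < 2:
        raise ValueError("need at least 2 training stimuli")
    x_mean = responses.mean(axis=0)
    y_mean = latents.mean(axis=0)
    xc = responses - x_mean
    yc = latents - y_mean
    weights, *_ = np.linalg.lstsq(xc, yc, rcond=1e-10)
    intercept = y_mean - x_mean @ weights
    return DecodingModel(weights=weights, intercept=intercept)


def decode(model: DecodingModel, responses: np.ndarray) -> np.ndarray:
    """Predict latents for test responses (no truncation applied)."""
    responses = np.asarray(responses, dtype=float)
    if responses.ndim == 1:
        responses = responses[None, :]
    if responses.shape[1] != model.n_channels:
        raise ValueError(
            f"decoder expects {model.n_channels} channels, got {responses.shape[1]}"
        )
    return responses @ model.weights + model.intercept


def occlude(
    responses: np.ndarray,
    keep_regions: str | list[str] | tuple[str, ...],
    region_map: RegionMap,
    fill: np.ndarray | None = None,
) -> np.ndarray:
    """Replace channels outside ``keep_regions`` with an uninformative fill.

    The default fill is each channel's mean over the supplied test
    stimuli — a constant placeholder at the channel's operating point
    that carries no stimulus information.  Kept channels are untouched.
    ``keep_regions`` may be a single region name, a list of names, or an
    empty list (every channel filled).
    """
    responses = np.asarray(responses, dtype=float)
    if isinstance(keep_regions, str):
        keep_regions = [keep_regions]
    for name in keep_regions:
        if name not in region_map.region_names:
            raise KeyError(f"unknown region {name!r}")
    if fill is None:
        fill = responses.mean(axis=0)
    fill = np.asarray(fill, dtype=float)
    keep = np.zeros(region_map.n_channels, dtype=bool)
    for name in keep_regions:
        keep[region_map.channels(name)] = True
    out = np.broadcast_to(fill, responses.shape).copy()
    out[:, keep] = responses[:, keep]
    return out


def region_contribution(
    model: DecodingModel,
    responses_test: np.ndarray,
    region_map: RegionMap,
    evaluator,
) -> pd.DataFrame:
    """Per-region similarity table from occlusion analysis.

    ``evaluator`` maps predicted latents (n_test x d) to a dict of
    per-stimulus similarity vectors, one per metric.  The returned
    table has one row per condition ('all' plus each region, the 'all'
    row using unoccluded responses) and, per metric, mean and standard
    error columns over test stimuli.
    """
    rows: dict[str, dict[str, float]] = {}
    conditions: list[tuple[str, np.ndarray]] = [("all", np.asarray(responses_test))]
    for name in region_map.region_names:
        conditions.append((name, occlude(responses_test, name, region_map)))
    for label, resp in conditions:
        predicted = decode(model, resp)
        sims = evaluator(predicted)
        row: dict[str, float] = {}
        for metric, vec in sims.items():
            vec = np.asarray(vec, dtype=float)
            row[f"{metric}_mean"] = float(vec.mean())
            row[f"{metric}_sem"] = float(vec.std(ddof=1) / np.sqrt(vec.size))
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index")


@dataclass
class TimeResolvedResult:
    """Per-window decoded latents and similarity curves."""

    windows: list[tuple[int, int]]
    predicted: list[np.ndarray]  # one (n_test, d) matrix per window
    curves: pd.DataFrame  # window_start, metric, mean, sem


def time_resolved_decode(
    rec_train: ResponseRecording,
    rec_test: ResponseRecording,
    latents_train: np.ndarray,
    latents_test: np.ndarray,
    evaluator,
    window_ms: int = 100,
    stride_ms: int = 25,
    refit: bool = True,
    model: DecodingModel | None = None,
) -> TimeResolvedResult:
    """Decode latents from each position of a sliding time window.

    For every window: all channels are averaged over the same window
    (no region-specific offsets), repetitions are averaged, channels
    are z-scored with that window's training statistics, a decoder is
    fit on training stimuli (or, with ``refit=False``, the supplied
    fixed ``model`` is reused) and applied to the test stimuli.  The
    similarity curves report mean and standard error per metric per
    window.
    """
    if not refit and model is None:
        raise ValueError("refit=False requires a fitted model")
    windows = sliding_windows(rec_train.trial_ms, window_ms, stride_ms)
    latents_train = np.asarray(latents_train, dtype=float)
    latents_test = np.asarray(latents_test, dtype=float)
    predicted: list[np.ndarray] = []
    records: list[dict[str, float]] = []
    for start, end in windows:
        wtrain = average_repetitions(rec_train.values[:, :, :, start:end].mean(axis=3))
        wtest = average_repetitions(rec_test.values[:, :, :, start:end].mean(axis=3))
        (ntrain, ntest), _, _ = normalize_channels(wtrain, wtest)
        decoder = fit_decoder(ntrain, latents_train) if refit else model
        pred = decode(decoder, ntest)
        predicted.append(pred)
        for metric, vec in evaluator(pred).items():
            vec = np.asarray(vec, dtype=float)
            records.append(
                {
                    "window_start": start,
                    "window_end": end,
                    "metric": metric,
                    "mean": float(vec.mean()),
                    "sem": float(vec.std(ddof=1) / np.sqrt(vec.size)),
                }
            )
    return TimeResolvedResult(
        windows=windows, predicted=predicted, curves=pd.DataFrame.from_records(records)
    )
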