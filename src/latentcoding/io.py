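"""HDF5 container and CSV side-files for simulated studies.

One HDF5 file holds a complete simulated experiment:

* ``/latents/{z,w}/{train,test}`` — latent matrices;
* ``/features/<kind>/{train,test}`` — feature matrices (toy layer
  levels), kind names with ``/`` are not used;
* ``/responses/{train,test}`` — trial-resolved recordings;
* ``/ground_truth`` — the simulator's true weights, biases, temporal
  profiles and noise scale;
* ``/labels/{train,test}`` — class labels for class-based splits.

The channel map (channel, array, region) travels as a plain CSV next to
the container.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .features import FeatureMatrix, LatentMatrix
from .responses import RegionMap, ResponseRecording, build_region_map
from .synthetic import GroundTruth, SyntheticConfig

__all__ = ["SimulatedDataset", "save_dataset", "load_dataset", "save_channel_map"]


@dataclass
class SimulatedDataset:
    """All artifacts of one simulated experiment, split into train/test."""

    cfg: SyntheticConfig
    region_map: RegionMap
    latents: dict[str, tuple[LatentMatrix, LatentMatrix]]  # kind -> (train, test)
    features: dict[str, tuple[FeatureMatrix, FeatureMatrix]]
    rec_train: ResponseRecording
    rec_test: ResponseRecording
    ground_truth: GroundTruth
    labels_train: np.ndarray | None = None
    labels_test: np.ndarray | None = None
    seed: int = 0

    def feature_values(self, kind: str) -> tuple[np.ndarray, np.ndarray]:
        """(train, test) value matrices for a latent or feature kind."""
        if kind in self.latents:
            tr, te = self.latents[kind]
        elif kind in self.features:
            tr, te = self.features[kind]
        else:
            raise KeyError(f"unknown feature kind {kind!r}")
        return tr.values, te.values


def _cfg_to_json(cfg: SyntheticConfig) -> str:
    d = {
        "n_train": cfg.n_train,
        "n_test": cfg.n_test,
        "latent_dim": cfg.latent_dim,
        "truncation_psi": cfg.truncation_psi,
        "regions": [list(r) for r in cfg.regions],
        "trial_ms": cfg.trial_ms,
        "onset_ms": cfg.onset_ms,
        "peak_ms": cfg.peak_ms,
        "windows": {k: list(v) for k, v in cfg.windows.items()},
        "noise_sigma": cfg.noise_sigma,
        "n_reps_train": cfg.n_reps_train,
        "n_reps_test": cfg.n_reps_test,
        "image_size": cfg.image_size,
        "seed": cfg.seed,
    }
    return json.dumps(d)


def _cfg_from_json(blob: str) -> SyntheticConfig:
    d = json.loads(blob)
    d["regions"] = tuple(tuple(r) for r in d["regions"])
    d["windows"] = {k: tuple(v) for k, v in d["windows"].items()}
    return SyntheticConfig(**d)


def save_dataset(path: str | Path, ds: SimulatedDataset) -> None:
    """Write a simulated dataset to one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["config"] = _cfg_to_json(ds.cfg)
        f.attrs["seed"] = ds.seed
        lat = f.create_group("latents")
        for kind, (tr, te) in ds.latents.items():
            g = lat.create_group(kind)
            g.create_dataset("train", data=tr.values)
            g.create_dataset("test", data=te.values)
        feat = f.create_group("features")
        for kind, (tr, te) in ds.features.items():
            g = feat.create_group(kind)
            g.create_dataset("train", data=tr.values)
            g.create_dataset("test", data=te.values)
        resp = f.create_group("responses")
        for split, rec in (("train", ds.rec_train), ("test", ds.rec_test)):
            d = resp.create_dataset(split, data=rec.values)
            d.attrs["onset_ms"] = rec.onset_ms
            d.attrs["bin_ms"] = rec.bin_ms
        gt = f.create_group("ground_truth")
        gt.attrs["noise_sigma"] = ds.ground_truth.noise_sigma
        gt.attrs["seed"] = ds.ground_truth.seed
        gt.create_dataset("bias", data=ds.ground_truth.bias)
        wg = gt.create_group("weights")
        for region, w in ds.ground_truth.weights.items():
            wg.create_dataset(region, data=w)
        pg = gt.create_group("profiles")
        for region, p in ds.ground_truth.profiles.items():
            pg.create_dataset(region, data=p)
        if ds.labels_train is not None:
            lab = f.create_group("labels")
            lab.create_dataset("train", data=ds.labels_train)
            lab.create_dataset("test", data=ds.labels_test)


def load_dataset(path: str | Path) -> SimulatedDataset:
    """Read a simulated dataset back from its HDF5 container."""
    with h5py.File(path, "r") as f:
        cfg = _cfg_from_json(f.attrs["config"])
        seed = int(f.attrs["seed"])
        latents = {}
        for kind, g in f["latents"].items():
            latents[kind] = (
                LatentMatrix(g["train"][()], kind=kind),
                LatentMatrix(g["test"][()], kind=kind),
            )
        features = {}
        for kind, g in f["features"].items():
            features[kind] = (
                FeatureMatrix(g["train"][()], kind=kind),
                FeatureMatrix(g["test"][()], kind=kind),
            )
        recs = {}
        for split in ("train", "test"):
            d = f["responses"][split]
            recs[split] = ResponseRecording(
                values=d[()],
                onset_ms=int(d.attrs["onset_ms"]),
                bin_ms=int(d.attrs["bin_ms"]),
            )
        gt_group = f["ground_truth"]
        ground_truth = GroundTruth(
            weights={k: v[()] for k, v in gt_group["weights"].items()},
            bias=gt_group["bias"][()],
            profiles={k: v[()] for k, v in gt_group["profiles"].items()},
            noise_sigma=float(gt_group.attrs["noise_sigma"]),
            seed=int(gt_group.attrs["seed"]),
        )
        labels_train = labels_test = None
        if "labels" in f:
            labels_train = f["labels"]["train"][()]
            labels_test = f["labels"]["test"][()]
    return SimulatedDataset(
        cfg=cfg,
        region_map=cfg.region_map(),
        latents=latents,
        features=features,
        rec_train=recs["train"],
        rec_test=recs["test"],
        ground_truth=ground_truth,
        labels_train=labels_train,
        labels_test=labels_test,
        seed=seed,
    )


def save_channel_map(path: str | Path, region_map: RegionMap) -> None:
    """Write the channel map as CSV (channel, array, region)."""
    region_map.to_frame().to_csv(path, index=False)
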