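"""Per-unit kernel ridge encoding and the complexity gradient.

Fits one ridge encoder per electrode for several candidate feature
spaces (z- and w-latents plus three pyramid levels), selects the
regularizer per visual area on the degrees-of-freedom grid by 5-fold
cross-validation, scores every unit by held-out Pearson r, compares the
w- and z-based encoders with a pooled t-test, and assigns each unit the
best-encoding candidate.
"""

import numpy as np

from latentcoding import encoding
from latentcoding.pipeline import RunConfig, encode_stage, simulate_stage
from latentcoding.synthetic import SyntheticConfig

cfg = RunConfig(
    synthetic=SyntheticConfig(
        n_train=300,
        n_test=60,
        latent_dim=16,
        regions=(("V1", 1, 16), ("V4", 1, 16), ("IT", 1, 16)),
        noise_sigma=0.5,
        seed=1,
    ),
    seed=1,
)
ds = simulate_stage(cfg)
kinds = ("z", "w", "layer-1", "layer-3", "layer-5")
report, scores = encode_stage(ds, feature_kinds=kinds, grid_size=10, folds=5, seed=1)

print("mean held-out r per region and feature kind:")
print(
    report.pivot_table(index="region", columns="feature_kind", values="r")
    .loc[["V1", "V4", "IT"], list(kinds)]
    .round(3)
)

t, p, df = encoding.compare_encoders(scores["w"], scores["z"])
print(f"\nw vs z encoders, all units: t({df}) = {t:.2f}, p = {p:.2g}")
it = ds.region_map.channels("IT")
t_it, p_it, df_it = encoding.compare_encoders(scores["w"][it], scores["z"][it])
print(f"w vs z encoders, IT only:  t({df_it}) = {t_it:.2f}, p = {p_it:.2g}")
# IT is simulated from w-latents, which are nonlinear in z, so w-based
# encoders beat z there; V1/V4 respond to pyramid features and see no
# difference, which dilutes the pooled all-unit comparison.

candidates = np.vstack([scores[k] for k in ("layer-1", "layer-3", "w")])
result = encoding.assign_complexity(
    candidates, region_labels=ds.region_map.channel_region
)
print("\nunits assigned per candidate (0=layer-1, 1=layer-3, 2=w):")
print(result.histogram)
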