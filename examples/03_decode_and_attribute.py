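"""Latent decoding, occlusion-based region attribution, permutation test.

Fits one linear decoder from all channels to the w-latents, evaluates
reconstruction quality with six metrics (per-level perceptual cosine
similarity of toy renderings plus latent cosine similarity), attributes
performance to each visual area by occluding the other two with their
mean response, and ranks the observed similarity against a
random-latent permutation null.
"""

import pandas as pd

from latentcoding.pipeline import RunConfig, decode_stage, simulate_stage
from latentcoding.synthetic import SyntheticConfig

cfg = RunConfig(
    synthetic=SyntheticConfig(
        n_train=300,
        n_test=60,
        latent_dim=16,
        regions=(("V1", 1, 16), ("V4", 1, 16), ("IT", 1, 16)),
        noise_sigma=0.5,
        seed=2,
    ),
    seed=2,
)
ds = simulate_stage(cfg)
decoder, predicted, table, permutation = decode_stage(
    ds, decode_kind="w", n_permutations=199, seed=2
)

pd.set_option("display.width", 120)
print("similarity (mean) per region condition and metric:")
print(table[[c for c in table.columns if c.endswith("_mean")]].round(3))
print("\npermutation p-values (199 random-latent iterations):")
print({k: round(v, 4) for k, v in permutation.p_values.items()})
# 'all' should dominate each single region; IT (driven by w) carries
# most latent information, and every p-value sits at the add-one floor
# 1/200 because random latents never beat the decoded ones.
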