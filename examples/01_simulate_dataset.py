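"""Build a small synthetic experiment and inspect its structure.

Generates Gaussian w-latents, renders toy blob stimuli, extracts the
pyramid features that drive each simulated visual area, and simulates
trial-resolved multi-electrode recordings (1 training repetition, 20
test repetitions).
"""

from latentcoding.pipeline import RunConfig, simulate_stage
from latentcoding.synthetic import SyntheticConfig

cfg = RunConfig(
    synthetic=SyntheticConfig(
        n_train=200,
        n_test=50,
        latent_dim=16,
        regions=(("V1", 1, 16), ("V4", 1, 16), ("IT", 1, 16)),
        seed=0,
    ),
    seed=0,
)
ds = simulate_stage(cfg)

print("channels:", ds.region_map.n_channels)
print("region windows (ms after onset):", ds.region_map.windows)
print("train recording (stim, reps, chan, bins):", ds.rec_train.values.shape)
print("test recording  (stim, reps, chan, bins):", ds.rec_test.values.shape)
for kind in ("z", "w"):
    print(f"{kind}-latents:", ds.feature_values(kind)[0].shape)
for level in range(1, 6):
    print(f"layer-{level} features:", ds.feature_values(f'layer-{level}')[0].shape)
# The response tensors are stimuli x repetitions x channels x 1 ms bins;
# each region's channels peak at its own latency after the 100 ms onset.
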