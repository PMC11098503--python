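"""Linear operations in latent space and 'linearity stacking'.

Because both the decoder and latent-space interpolation/arithmetic are
linear, applying an operation to responses and then decoding gives the
same latents as decoding first and operating afterwards.  The decoded
latents can be rendered by the toy generator to visualize smooth
semantic paths.
"""

import numpy as np

from latentcoding.decoding import decode, fit_decoder
from latentcoding.evaluation import rowwise_cosine
from latentcoding.features import interpolate_latents, latent_arithmetic
from latentcoding.pipeline import prepare_response_matrices, RunConfig, simulate_stage
from latentcoding.synthetic import SyntheticConfig, render_toy_images

cfg = RunConfig(
    synthetic=SyntheticConfig(
        n_train=250,
        n_test=50,
        latent_dim=16,
        regions=(("V1", 1, 16), ("V4", 1, 16), ("IT", 1, 16)),
        noise_sigma=0.3,
        seed=5,
    ),
    seed=5,
)
ds = simulate_stage(cfg)
resp_train, resp_test = prepare_response_matrices(ds)
lat_train, lat_test = ds.feature_values("w")
model = fit_decoder(resp_train, lat_train)

# interpolate two test responses, decode the path
x1, x2 = resp_test[0], resp_test[1]
response_path = interpolate_latents(x1, x2, steps=5)
decoded_path = decode(model, response_path)

# decode first, interpolate afterwards: identical by linearity
latent_path = interpolate_latents(
    decode(model, x1[None])[0], decode(model, x2[None])[0], steps=5
)
print("max |decode(interp(x)) - interp(decode(x))|:",
      f"{np.abs(decoded_path - latent_path).max():.2e}")

sims = rowwise_cosine(decoded_path[[0, -1]], lat_test[[0, 1]])
print("endpoint similarity to true latents:", np.round(sims, 3))

# vector arithmetic on responses carries over to latents the same way
analogy = decode(model, latent_arithmetic(x1, x2, resp_test[2])[None])[0]
direct = decoded_path[0] - decoded_path[-1] + decode(model, resp_test[2][None])[0]
print("arithmetic commutes with decoding:",
      bool(np.allclose(analogy, direct, atol=1e-10)))

# the decoded path renders to a smooth image morph
frames = render_toy_images(decoded_path, size=64)
print("rendered morph frames:", frames.shape,
      "adjacent-frame RMS steps:",
      np.round([np.sqrt(((frames[i+1]-frames[i])**2).mean()) for i in range(4)], 4))
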