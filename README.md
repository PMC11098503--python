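# latentcoding

Neural encoding and decoding of generative-model latents from simulated
multi-electrode recordings of macaque visual cortex.

## The problem

How well do the latent spaces of deep generative models describe what
visual cortex computes?  One productive experimental design presents
GAN-synthesized stimuli (whose ground-truth latents are known exactly) to
a fixating animal while recording multi-unit activity (MUA) from
microelectrode arrays in V1, V4 and IT, then asks two complementary
questions:

* **Encoding** — how much of each electrode's response is a linear
  function of a candidate feature space (the entangled *z*-latents, the
  feature-disentangled *w*-latents, or layer activations of a
  discriminative hierarchy)?
* **Decoding** — how much of the stimulus latent can a linear readout
  recover from the population response, and which visual area carries
  that information?

This package reimplements that analysis pipeline as a tested library,
driven by a synthetic-data generator that emulates the statistical
structure of such a study (Gaussian latents with ψ-truncation, a
deterministic latent→image→feature chain with a coarse-to-fine level
hierarchy, region-specific linear response weights and onset-locked
temporal profiles, 1-repetition training vs 20-repetition test trials,
i.i.d. channel noise).  Because the simulator's ground truth is known,
every stage — windowing, normalization, regularization, decoding,
attribution, significance — is verifiable end to end.  It is intended
for computational neuroscientists who want the analysis machinery, and
its failure modes, on the desk rather than on a cluster.

## The model

**Encoding** is per-electrode ridge regression from stimulus features
φ(x) ∈ R^q to the windowed, z-scored response y:

    L = ½ Σᵢ (yᵢ − wᵀφ(xᵢ))² + ½ λ‖w‖²

solved in the N × N dual (the kernel trick, essential when q ≫ N):
α = (ΦΦᵀ + λI_N)⁻¹ y, predictions Φ*Φᵀα.  The λ grid is parameterized
by the fit's effective degrees of freedom,

    dof(λ) = Σᵢ sᵢ² / (sᵢ² + λ),

with s the singular values of Φ: M dof targets are spaced evenly in
[1, rank Φ] and each is inverted to a λ by a safeguarded Newton
iteration.  λ is selected per visual area by 5-fold cross-validated MSE
pooled over that area's electrodes.  Units are scored by held-out
Pearson r, with significance at the Bonferroni-corrected critical value
r_c = t_c/√(t_c² + df) (at α = 0.05/960: r_c = 0.3895 for df = 100,
0.2807 for df = 200), encoder banks compared by pooled two-sample
t-tests, and each unit assigned the candidate feature space that
encodes it best (the complexity gradient).

**Decoding** is multivariate OLS from all channels to the latent
vector, L = ½ Σᵢ ‖yᵢ − Wᵀxᵢ‖².  Region contributions are measured by
occlusion: the full-population decoder is evaluated with the other two
areas' test responses replaced by their per-channel mean.  Decoding
quality is scored per stimulus by latent cosine similarity and by
per-level perceptual cosine similarity between hierarchical features of
the rendered stimulus and reconstruction; significance comes from a
permutation null over random latents with an add-one p estimator.
Time-resolved decoding slides a 100 ms window in 25 ms steps over the
300 ms trial (nine windows) with a fresh decoder per window.

## Worked example

`examples/` holds one short script per capability.  Decoding with
occlusion attribution (`examples/03_decode_and_attribute.py`) on a
48-channel world where V1 is driven by fine pyramid features, V4 by
mid-level features and IT by the w-latents:

```
similarity (mean) per region condition and metric:
     level-1_mean  level-2_mean  ...  level-5_mean  latent_mean
all         0.874         0.841  ...         0.907        0.974
V1          0.240         0.246  ...         0.460        0.124
V4          0.173         0.140  ...         0.295        0.135
IT          0.821         0.778  ...         0.798        0.954

permutation p-values (199 random-latent iterations):
{'level-1': 0.005, ..., 'latent': 0.005}
```

Reading it: the full population ('all') reconstructs best on every
metric; IT — the area actually driven by the latents — dominates the
single-area rows; and every observed similarity beats all 199 random
latents, so each p sits at the add-one floor 1/200.  Time-resolved
decoding (`examples/04_time_resolved_decoding.py`) shows latent
similarity at chance for windows ending before the 100 ms stimulus
onset and climbing to ~0.95 once the window covers the response peaks.

A complete run (`latentcoding run --config cfg.toml --out rundir` or
`pipeline.run_experiment`) writes the simulated HDF5 container, channel
map CSV, per-unit encoding report, region similarity table, permutation
p-values, time-resolved curves, a log and the resolved configuration.

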