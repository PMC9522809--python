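# scentmap

**Inverse olfactory mapping: from a desired scent impression back to the mass
spectra of candidate odorant molecules.**

Perfumers and flavor scientists usually work *forward*: given a molecule's
sensing data (here, its electron-ionization mass spectrum), predict how it
smells. `scentmap` solves the *inverse* problem for binary odor descriptors:
given a desired impression such as *peach* or *spicy + warm*, extract the mass
spectra of all molecules whose sensing data cluster at the matching place in a
learned spectrum space. Because one impression maps to many molecules (and one
molecule carries several impressions), the answer is a neighborhood, not a
single spectrum — exactly what a scent designer blending components needs.

## Method

1. **Preprocess.** Unit-mass EI spectra are windowed to the odor-relevant m/z
   region 51–262 (212 channels; lower masses are dominated by odorless
   fragments) and base-peak normalized per spectrum to [0, 1].
2. **Compress.** A 5-layer sparse autoencoder (212–90–50–90–212, logistic
   sigmoid activations) reduces each spectrum x ∈ [0,1]²¹² to a 50-d latent
   code, trained by mini-batch gradient descent on

   E = (1/N) Σₙ Σₖ (y<sub>kn</sub> − x<sub>kn</sub>)² + (λ/2) Σ‖W‖²
   + β Σⱼ KL(ρ ‖ ρ̂ⱼ),

   with L2 coefficient λ = 10⁻⁴, sparsity coefficient β = 1 and target mean
   bottleneck activation ρ = 0.05 (defaults; learning rate η = 0.01).
3. **Organize.** The latent codes train a 30×20 *hexagonal* self-organizing
   map (Gaussian neighborhood, radius 1, learning rate 0.5): competitive
   learning places similar spectra on the same or neighboring neurons.
   Map size is chosen by scanning quantization error (mean distance from each
   sample to its best matching unit, BMU) against empty-lattice counts.
4. **Label and invert.** Each neuron is labeled with the union of its member
   molecules' odor descriptors. A query descriptor (or pair) selects neurons;
   *inverse mapping* a neuron returns the co-clustered molecules and their
   latent spectra, scored by cosine similarity cos θ against a reference and
   projected by PCA to check closeness.
5. **Validate.** Duo-trio sensory panels comparing same-neuron vs
   nearest-neuron molecules are evaluated with the exact right-tailed
   one-proportion binomial test (small panels; z statistic reported
   alongside).

Licensed spectral/descriptor databases cannot be redistributed, so the package
ships a first-class synthetic generator: archetype spectra built as CH₂-style
fragment ladders (step 14 m/z) with lognormal intensity jitter, spurious minor
peaks, and overlapping descriptor sets — the statistical structure the method
relies on, with ground truth retained for evaluation.

## Worked example

```sh
python examples/03_train_map_and_extract.py
```

trains the full pipeline on a 120-molecule synthetic dataset (8 archetypes)
and queries one impression:

```
map 8x6: quantization error 0.0018, 20 empty neurons

query: desired scent impression 'coconut'
  neuron (H=3, V=0): 6 co-clustered molecules
    mol001  descriptors=['coconut', 'floral']
    mol017  descriptors=['coconut', 'floral']
    mol065  descriptors=['coconut']
    ...
```

Molecules listed under one neuron have similar fragment patterns; any of them
is a candidate carrier of the queried impression. The other examples cover
dataset generation, autoencoder cross-validation, cosine/head-to-tail/PCA
similarity, and the duo-trio statistics, e.g.

```
16/21 correct, z = 2.40, exact right-tailed p = 0.01330185 < alpha = 0.05:
reject the null of no perceivable difference
```

A thin CLI wraps the same functions: `scentmap simulate`, `scentmap pipeline`,
`scentmap query -d peach`, `scentmap duotrio 16 21`, `scentmap map-scan`.

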