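# Methods

This note documents the model, the numerical choices, and the limits of what
the synthetic experiments demonstrate.

## Preprocessing

Spectra are unit-mass binned (fractional m/z rounded to nearest integer,
duplicate bins merged by summing) and windowed to m/z 51–262 inclusive — 212
channels. Low m/z is dominated by fragments common to odorless small molecules
and masses above ~262 contribute little to perception because of low
volatility, so the window both denoises and fixes the input dimension.

Each windowed spectrum is divided by its own in-window maximum (base-peak
normalization), mapping every channel to [0, 1]. This convention was a
genuinely open choice; base-peak scaling was adopted because (a) EI libraries
conventionally report relative intensities against the base peak and (b) the
autoencoder's sigmoid output layer constrains reconstructions to (0, 1), so
inputs must live in that range. Total-ion-current scaling would also satisfy
(b) but makes single-peak spectra indistinguishable from noise-rich ones.
Molecules with *no* in-window intensity cannot be normalized and are excluded
with a logged warning — never silently.

## Sparse autoencoder

Architecture 212–90–50–90–212, logistic sigmoid at every layer. The objective
is the per-sample-averaged, channel-summed squared reconstruction error, plus
an L2 penalty (λ/2)Σ(W)² over weights *and biases*, plus β·Ω where
Ω = Σⱼ KL(ρ‖ρ̂ⱼ) over bottleneck units and ρ̂ⱼ is unit j's mean activation
over the batch. Including biases in the L2 sum is unusual but deliberate and
kept consistent between loss and gradient. Defaults: η = 0.01, λ = 10⁻⁴,
β = 1, ρ = 0.05, 1000 epochs, batch 32.

Decisions taken where the design was open:

* **Output activation** — sigmoid, to keep reconstructions in the input range.
* **Sparsity form** — KL divergence to target ρ; the standard convention for
  this penalty. ρ is exposed in config (0.05 default).
* **Penalty coverage** — bottleneck layer only by default; a
  `sparsity_layers="all_hidden"` switch covers the 90-unit layers too, since
  either reading of "output sparsity from the hidden layer" is defensible.
* **Optimizer** — plain seeded mini-batch SGD with fixed η. The method is
  specified by its cost, learning rate and epoch count, not by an adaptive
  optimizer; determinism given the seed matters more here than speed.
* **Initialization** — seeded Glorot-uniform weights, zero biases.
* **K normalization** — the error term divides by N (samples) only, summed
  over channels; evaluation (`cross_validate`) reports the same summed
  per-sample error with regularizers excluded.
* If ρ̂ⱼ reaches exactly 0 or 1 it is clamped to [1e-12, 1−1e-12] and logged;
  a non-finite training loss aborts with the epoch named.

Gradients are analytic backpropagation including the KL term through the
batch mean; correctness is enforced by central-difference checks at 1e-5
relative tolerance on small nets (a standing test, not a one-off).

Model selection follows k-fold cross-validation (seeded shuffle, disjoint
exhaustive folds, k = 5 default) over a config grid; ties prefer the smaller
bottleneck, then listing order. The deployed model is retrained on all data
with the winning config — CV exists to score configs, not to produce the
final weights.

## Self-organizing map

30×20 hexagonal lattice (defaults), Gaussian neighborhood, radius σ = 1,
learning rate α₀ = 0.5, 500 iterations. Hexagon centers are planar points
(x = col + 0.5·(row mod 2), y = row·√3/2) so each interior neuron has six
neighbors at center distance exactly 1 — "radius 1" therefore means one ring.
All neighborhood and nearest-neuron computations use this planar geometry.

* **Training regime** — single-sample draws: at step t a seeded-random sample
  updates every codebook vector by α(t)·h(u)·(x − w). An iteration count far
  below the dataset size only makes sense sample-wise; an `epochs`-style
  reading is available by raising `iterations`.
* **Decay** — α(t) = α₀/(1 + t/(T/2)) and likewise σ(t) (the asymptotic decay
  customary in NumPy SOM implementations); `decay="none"` reproduces the
  fixed-rate reading, since the original condition table lists constants
  without a schedule.
* **BMU ties** — smallest row-major linear index; deterministic and only
  relevant at exact float equality.
* **Codebook init** — seeded uniform within each dimension's data range.
* **Quantization error** — mean sample-to-BMU Euclidean distance, computed
  with exact pairwise differences so coincident data give exactly 0.
* **U-matrix** — per-neuron mean codebook distance to its lattice neighbors
  (6 interior, fewer at edges), exported as an array for any plotting layer.
* **Map-size choice** — `map_size_scan` reports QE and empty-neuron count per
  candidate size; QE falls with capacity while blank lattices proliferate, so
  the caller picks the knee. Nothing is automated beyond the table.

## Extraction

Lattice labels are the union of member-molecule descriptor sets: the only
rule under which a neuron can carry two impressions contributed by different
members, which is what the two-descriptor query exploits. Molecules without
annotations still occupy neurons (they can be extracted; they just add no
labels). A descriptor-pair query supports two modes: `both_on_neuron` (label
union contains both) and the stricter `both_on_molecule` (some member carries
both itself) — the second is always a subset of the first. Coordinates are
(H, V) = (column, row), 0-based, stated in every output header. An optional
exclusion list keeps overly familiar impressions (e.g. "sweet", "fruity")
off the lattice without hard-coding any vocabulary.

Reference-based scoring inside an extraction uses latent vectors by default
(that is the space in which molecules were co-clustered) with a switch to raw
windowed spectra; both go through the same cosine implementation.

## Similarity and PCA

The similarity score is plain cos θ between intensity vectors — no m/z
weighting, no peak matching tolerance — applied identically to 212-channel
spectra and 50-d codes. With sigmoid latents all vectors are nonnegative, so
scores live in [0, 1]; proportional vectors score exactly 1. PCA is
mean-centered covariance eigendecomposition without variance scaling; the
sign of each axis is fixed by making its largest-magnitude loading positive.

## Duo-trio statistics

Correct-response counts under the null are Binomial(n, ½). The p-value is the
exact right tail P(X ≥ k), computed with integer binomial coefficients for
n ≤ 64 and a log-sum-exp fallback above. The z statistic (k − np₀)/√(np₀q₀)
carries no continuity correction. For the 21-panelist case: 16 correct gives
p = 0.0133018 (reject at α = 0.05), 20 gives 1.04904×10⁻⁵, 4 gives 0.999.

## Synthetic data: what it emulates, and what it does not

Each archetype is a fragment ladder — peaks at base + k·14 m/z with
geometrically decaying intensities — mimicking the homologous CH₂ series that
make same-family EI spectra genuinely similar, rather than arbitrary Gaussian
blobs. Molecules inherit their archetype's template with lognormal intensity
jitter (σ = 0.3), Poisson(2) spurious minor peaks (≤ 10% of base), and the
archetype's 2–4 descriptors with 10% per-label dropout emulating annotation
sparsity. Adjacent archetypes share a configurable fraction (default 0.25) of
descriptors; each archetype's *first* descriptor is kept archetype-owned
while the pool allows, so "query the signature impression" is a well-posed
recovery task. Defaults: 300 molecules, 12 archetypes, pool of 20 labels.

Not emulated: real fragmentation chemistry, isotope patterns, rearrangement
ions, the long-tailed descriptor frequency distribution of commercial flavor
databases, or inter-family spectral overlap (real lactones vs esters are far
less separable than two random ladders). Passing the recovery test therefore
shows the pipeline is *correct and coherent end-to-end*, not that it attains
any particular accuracy on licensed real data.

## Problem sizes and determinism

The shipped tests and the acceptance script run the pipeline at desk scale —
300 molecules, reduced autoencoder epochs (200), a 10×8 map with 2000 sample
draws — sizes at which the synthetic structure is learnable in seconds while
exercising every stage; the full-scale defaults (1000-epoch autoencoder,
30×20 map) remain the config defaults. Every stochastic stage takes a seed,
and a pipeline-level seed fans out to generator, autoencoder and SOM;
identical seeds give bitwise-identical artifacts.

## Known limitations

* Inverse mapping returns *candidates*, not guarantees: descriptor-to-spectrum
  relationships are many-to-many, and a neuron's members can include molecules
  whose annotations lack the queried impression.
* Checkpoints are JSON for inspectability; for codebooks far larger than
  600×50 a binary container would be preferable.
* The SOM uses sample-wise stochastic training only; batch-SOM, toroidal
  topology and growing maps are out of scope.
* The exact binomial test assumes independent panelists and a fixed panel
  size; no power analysis or sequential designs are provided.
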