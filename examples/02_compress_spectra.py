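"""Compress windowed mass spectra with the 5-layer sparse autoencoder.

Spectra are windowed to m/z 51-262 (212 channels) and base-peak
normalized, then compressed through a 212-90-50-90-212 sigmoid network
whose cost adds an L2 weight penalty and a KL sparsity penalty on the
bottleneck activations.  Five-fold cross-validation scores the
reconstruction error on held-out spectra.
"""

from scentmap import (
    AEConfig, GeneratorConfig, cross_validate, encode, sample_dataset,
    train, window_and_normalize,
)

dataset = sample_dataset(GeneratorConfig(n_molecules=100, n_archetypes=8, seed=1))
matrix = window_and_normalize(dataset.spectra)
print(f"input: {len(matrix.molecule_ids)} spectra x {matrix.n_channels} channels")

# reduced epochs keep this demo quick; the full setting is epochs=1000
config = AEConfig(epochs=150, seed=1)
cv = cross_validate(config, matrix, folds=5)
print(f"5-fold CV reconstruction error per fold: "
      f"{[round(e, 3) for e in cv.fold_errors]}")
print(f"mean CV error: {cv.mean_error:.3f} "
      "(summed squared error per held-out spectrum)")

model = train(config, matrix)
latents = encode(model, matrix)
print(f"latent codes: {latents.values.shape[0]} molecules x "
      f"{latents.values.shape[1]} dimensions, "
      f"mean activation {latents.values.mean():.3f}")
# A low mean activation reflects the sparsity penalty pulling bottleneck
# units toward the 0.05 target except where a spectrum needs them.
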