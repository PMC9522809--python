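"""Score extracted molecules against a reference spectrum.

The similarity score is cos(theta) between intensity vectors; 1 means
proportional spectra.  A head-to-tail report pairs reference (up) and
query (down) intensities for mirror plotting, and a 2-d PCA projection
shows how tightly the extracted molecules cluster.
"""

import numpy as np

from scentmap import (
    GeneratorConfig, cosine_similarity, head_to_tail, pca_project,
    sample_dataset, window_and_normalize,
)

dataset = sample_dataset(GeneratorConfig(n_molecules=30, n_archetypes=3, seed=9))
matrix = window_and_normalize(dataset.spectra)

ref = dataset.spectra[0]  # archetype 0
same = dataset.spectra[3]  # also archetype 0 (round-robin assignment)
other = dataset.spectra[1]  # archetype 1

print(f"reference: {ref.molecule_id}")
for q in (same, other):
    score = cosine_similarity(matrix.row(ref.molecule_id), matrix.row(q.molecule_id))
    kin = "same archetype" if dataset.truth[q.molecule_id] == 0 else "different"
    print(f"  vs {q.molecule_id} ({kin}): cos = {score:.4f}")

rep = head_to_tail(ref, same)
top = max(rep.head_to_tail, key=lambda t: t[1])
print(f"head-to-tail {rep.reference_id} vs {rep.query_id}: score {rep.score:.4f}, "
      f"base peak channel {top[0]} (ref {top[1]:.0f} up, query {-top[2]:.0f} down)")

scores, frac = pca_project(matrix.values, components=2)
print(f"PCA of all 30 spectra: PC1+PC2 explain {100 * frac.sum():.1f}% of variance")
rms_spread = np.sqrt(np.mean(scores**2))
print(f"rms score spread: {rms_spread:.3f} "
      "(same-archetype molecules land near each other in this plane)")
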