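"""Evaluation helpers for synthetic ground-truth recovery.

On generated data every molecule descends from a known archetype; a
trained map recovers the structure if querying an archetype's signature
descriptor leads back to a neuron whose members mostly come from that
archetype.
"""

from __future__ import annotations

from collections import Counter

from .extraction import LatticeLabels, label_lattice, neurons_for_descriptor
from .spectra import DescriptorTable
from .synthetic import Archetype


def descriptor_recovery_rate(
    archetypes: list[Archetype],
    labels: LatticeLabels,
    table: DescriptorTable,
    truth: dict[str, int],
) -> float:
    """Fraction of archetypes recovered by querying their first descriptor.

    For each archetype, its first (signature) descriptor is queried; of
    the neurons carrying it, the one with the most members annotated with
    that descriptor is inverse-mapped, and the archetype majority among
    its members is compared with the owning archetype.
    """
    hits = 0
    for arch in archetypes:
        d = arch.descriptors[0]
        coords = neurons_for_descriptor(labels, d)
        if not coords:
            continue
        best = max(
            coords,
            key=lambda c: sum(
                1 for m in labels.members_at(c) if d in table.descriptors_for(m)
            ),
        )
        members = labels.members_at(best)
        majority = Counter(truth[m] for m in members).most_common(1)[0][0]
        hits += majority == arch.archetype_id
    return hits / len(archetypes)


def end_to_end_recovery(
    seed: int,
    n_molecules: int = 300,
    n_archetypes: int = 12,
    ae_epochs: int = 200,
    som_shape: tuple[int, int] = (10, 8),
    som_iterations: int = 2000,
) -> float:
    """Full-pipeline recovery rate on a default synthetic fixture.

    Generates a dataset, preprocesses, trains the autoencoder at reduced
    epochs, trains a desk-scale SOM, labels the lattice, and measures
    :func:`descriptor_recovery_rate`.  Deterministic given the seed.
    """
    from . import autoencoder as ae
    from .som import SOMConfig, assign_bmus, train_som
    from .spectra import window_and_normalize
    from .synthetic import GeneratorConfig, sample_dataset

    dataset = sample_dataset(
        GeneratorConfig(
            n_molecules=n_molecules, n_archetypes=n_archetypes, seed=seed
        )
    )
    matrix = window_and_normalize(dataset.spectra)
    cfg = ae.AEConfig(epochs=ae_epochs, seed=seed + 1)
    latents = ae.encode(ae.train(cfg, matrix), matrix)
    grid = train_som(
        SOMConfig(
            width=som_shape[0],
            height=som_shape[1],
            iterations=som_iterations,
            seed=seed + 2,
        ),
        latents,
    )
    labels = label_lattice(grid, assign_bmus(grid, latents), dataset.table)
    return descriptor_recovery_rate(
        dataset.archetypes, labels, dataset.table, dataset.truth
    )
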