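"""Inverse mapping: from a desired scent impression back to spectra.

After the SOM is trained, each lattice neuron is labeled with the union
of the odor descriptors of the molecules whose BMU it is.  Querying a
descriptor (or a pair) returns the matching neurons; inverse-mapping a
neuron returns the co-clustered molecules with their latent spectra —
the method's answer to "which sensing data smell like peach?".
"""

from __future__ import annotations

import difflib
import logging
from dataclasses import dataclass, field

import numpy as np

from .autoencoder import LatentMatrix
from .som import BMUAssignment, SOMGrid
from .spectra import DescriptorTable
from .similarity import cosine_similarity

logger = logging.getLogger(__name__)

Coord = tuple[int, int]


@dataclass
class LatticeLabels:
    """Per-neuron descriptor label sets and member molecule lists."""

    width: int
    height: int
    members: dict[Coord, list[str]] = field(default_factory=dict)
    labels: dict[Coord, set[str]] = field(default_factory=dict)
    bmu_of: dict[str, Coord] = field(default_factory=dict)

    def members_at(self, coord: Coord) -> list[str]:
        return self.members.get(coord, [])

    def labels_at(self, coord: Coord) -> set[str]:
        return self.labels.get(coord, set())

    def coords_row_major(self):
        for v in range(self.height):
            for h in range(self.width):
                yield (h, v)


@dataclass
class ExtractionResult:
    """Molecules co-clustered at one neuron, with their latent spectra."""

    query: str
    neuron: Coord
    member_ids: list[str]
    member_latents: np.ndarray
    member_descriptors: dict[str, set[str]] = field(default_factory=dict)
    similarity_to_reference: dict[str, float] | None = None
    reference_id: str | None = None

    def __post_init__(self) -> None:
        self.member_latents = np.asarray(self.member_latents, dtype=float)
        if self.member_latents.shape[0] != len(self.member_ids):
            raise ValueError("latent row count must equal member count")


def label_lattice(
    grid_shape: tuple[int, int] | SOMGrid,
    assignments: BMUAssignment,
    table: DescriptorTable,
    exclude: set[str] | None = None,
) -> LatticeLabels:
    """Write descriptors on the lattice: union of member descriptor sets.

    Molecules absent from the descriptor table (or with all-zero rows)
    still count as members; they just contribute no labels.  Descriptors
    in ``exclude`` (e.g. overly familiar impressions like "sweet") are
    left off the lattice.
    """
    if isinstance(grid_shape, SOMGrid):
        width, height = grid_shape.config.width, grid_shape.config.height
    else:
        width, height = grid_shape
    exclude = {e.lower() for e in (exclude or set())}
    out = LatticeLabels(width=width, height=height)
    for mol, coord in zip(assignments.molecule_ids, assignments.bmu_coords):
        h, v = coord
        if not (0 <= h < width and 0 <= v < height):
            raise ValueError(f"molecule {mol}: BMU {coord} out of lattice bounds")
        coord = (h, v)
        out.members.setdefault(coord, []).append(mol)
        out.bmu_of[mol] = coord
        labels = table.descriptors_for(mol) - exclude
        if labels:
            out.labels.setdefault(coord, set()).update(labels)
    return out


def neurons_for_descriptor(labels: LatticeLabels, descriptor: str) -> list[Coord]:
    """All neurons whose label set contains ``descriptor``, row-major."""
    d = descriptor.strip().lower()
    hits = [c for c in labels.coords_row_major() if d in labels.labels_at(c)]
    if not hits:
        logger.warning("descriptor %r labels no neuron on this lattice", descriptor)
    return hits


def neurons_for_descriptor_pair(
    labels: LatticeLabels,
    d1: str,
    d2: str,
    table: DescriptorTable | None = None,
    mode: str = "both_on_neuron",
) -> list[Coord]:
    """Neurons matching two impressions at once.

    ``both_on_neuron``: the neuron's label set contains both descriptors
    (possibly contributed by different molecules).  ``both_on_molecule``:
    at least one member molecule carries both itself (stricter; needs the
    descriptor table).
    """
    d1, d2 = d1.strip().lower(), d2.strip().lower()
    if mode == "both_on_neuron":
        return [
            c
            for c in labels.coords_row_major()
            if {d1, d2} <= labels.labels_at(c)
        ]
    if mode == "both_on_molecule":
        if table is None:
            raise ValueError("both_on_molecule mode needs the descriptor table")
        return [
            c
            for c in labels.coords_row_major()
            if any(
                {d1, d2} <= table.descriptors_for(m) for m in labels.members_at(c)
            )
        ]
    raise ValueError(f"unknown mode {mode!r}")


def locate_molecule(labels: LatticeLabels, molecule_id: str) -> Coord:
    """The molecule's BMU coordinate; unknown ids raise with suggestions."""
    try:
        return labels.bmu_of[molecule_id]
    except KeyError:
        lowered = {k.lower(): k for k in labels.bmu_of}
        close = [
            lowered[c]
            for c in difflib.get_close_matches(
                molecule_id.lower(), lowered.keys(), n=3
            )
        ]
        hint = f"; did you mean {close}?" if close else ""
        raise KeyError(f"unknown molecule {molecule_id!r}{hint}") from None


def inverse_map(
    labels: LatticeLabels,
    latents,
    neuron: Coord,
    table: DescriptorTable | None = None,
    reference_id: str | None = None,
) -> ExtractionResult:
    """All molecules whose BMU is ``neuron``, with their vectors.

    ``latents`` is normally the :class:`LatentMatrix` the map was trained
    on, but any molecule-by-feature matrix with the same interface works —
    pass the raw windowed :class:`~scentmap.spectra.SpectrumMatrix` to
    score in the 212-channel space instead.  With a ``reference_id``,
    each member's cosine similarity to the reference's vector is
    attached — the closeness check applied to molecules extracted for one
    scent impression.
    """
    h, v = neuron
    if not (0 <= h < labels.width and 0 <= v < labels.height):
        raise ValueError(f"neuron {neuron} out of lattice bounds")
    member_ids = list(labels.members_at((h, v)))
    if not member_ids:
        logger.warning("neuron %s has no member molecules", (h, v))
    rows = (
        np.vstack([latents.row(m) for m in member_ids])
        if member_ids
        else np.empty((0, latents.values.shape[1]))
    )
    descriptors = {
        m: (table.descriptors_for(m) if table is not None else set())
        for m in member_ids
    }
    sims = None
    if reference_id is not None:
        ref = latents.row(reference_id)
        sims = {m: cosine_similarity(ref, latents.row(m)) for m in member_ids}
    return ExtractionResult(
        query=f"neuron {neuron}",
        neuron=(h, v),
        member_ids=member_ids,
        member_latents=rows,
        member_descriptors=descriptors,
        similarity_to_reference=sims,
        reference_id=reference_id,
    )


def nearest_neuron(
    grid: SOMGrid,
    origin: Coord,
    predicate,
) -> Coord:
    """Closest neuron (planar hexagon-center distance) satisfying a
    predicate on (coord), excluding the origin itself; ties row-major."""
    best: Coord | None = None
    best_d = np.inf
    p0 = grid.planar(origin)
    for c in grid.coords_row_major():
        if c == tuple(origin):
            continue
        if not predicate(c):
            continue
        d = float(np.linalg.norm(grid.planar(c) - p0))
        if d < best_d - 1e-12:
            best, best_d = c, d
    if best is None:
        raise ValueError(f"no neuron other than {origin} satisfies the predicate")
    return best


def lattice_report(labels: LatticeLabels):
    """One row per neuron: H, V, member count, sorted labels (DataFrame)."""
    import pandas as pd

    rows = [
        {
            "H": h,
            "V": v,
            "members": len(labels.members_at((h, v))),
            "labels": ";".join(sorted(labels.labels_at((h, v)))),
        }
        for (h, v) in labels.coords_row_major()
    ]
    return pd.DataFrame(rows)
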