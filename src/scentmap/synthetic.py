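"""Synthetic odorant datasets with the structure the method assumes.

Real EI spectra of odorants within one functional-group family share
fragment ladders (homologous series spaced by CH2, 14 u) and overlapping
odor descriptors; commercial flavor databases annotate molecules with a
few binary descriptors each.  The generator emulates exactly that:
"archetype" template spectra built as decaying m/z ladders, per-molecule
lognormal intensity jitter plus a Poisson number of spurious minor peaks,
and 2-4 descriptors per archetype drawn from a shared pool with a
configurable overlap between adjacent archetypes.  Ground-truth archetype
assignments are kept for evaluation only and never consumed by the
pipeline.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import (
    DescriptorTable,
    MassSpectrum,
    write_descriptor_csv,
    write_msp,
)

DEFAULT_POOL = [
    "peach", "minty", "vanilla", "spicy", "warm", "coconut", "pineapple",
    "strawberry", "pear", "butter", "floral", "green", "herbal",
    "camphoraceous", "cooling", "balsamic", "smoky", "honey", "banana",
    "citrus",
]


@dataclass
class GeneratorConfig:
    n_molecules: int = 300
    n_archetypes: int = 12
    mz_lo: int = 51
    mz_hi: int = 262
    peaks_per_archetype: int = 8
    ladder_step: int = 14  # CH2 homologous-series spacing
    intensity_jitter: float = 0.3  # lognormal sigma
    spurious_peak_rate: float = 2.0  # expected extra minor peaks
    descriptor_pool: list[str] = field(default_factory=lambda: list(DEFAULT_POOL))
    descriptors_per_archetype: tuple[int, int] = (2, 4)
    descriptor_overlap: float = 0.25  # fraction shared with the previous archetype
    descriptor_dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_archetypes > self.n_molecules:
            raise ValueError("n_archetypes must be <= n_molecules")
        if self.mz_lo >= self.mz_hi:
            raise ValueError("mz_lo must be < mz_hi")
        if self.peaks_per_archetype < 1 or self.ladder_step < 1:
            raise ValueError("peaks_per_archetype and ladder_step must be >= 1")
        lo, hi = self.descriptors_per_archetype
        if not 1 <= lo <= hi:
            raise ValueError("bad descriptors_per_archetype range")
        if not 0 <= self.descriptor_overlap <= 1:
            raise ValueError("descriptor_overlap must be in [0, 1]")
        if not 0 <= self.descriptor_dropout < 1:
            raise ValueError("descriptor_dropout must be in [0, 1)")


@dataclass
class Archetype:
    archetype_id: int
    template: list[tuple[int, float]]  # (m/z, intensity), ascending m/z
    descriptors: list[str]  # first entries are archetype-owned, shared at end


@dataclass
class SyntheticDataset:
    spectra: list[MassSpectrum]
    table: DescriptorTable
    truth: dict[str, int]  # molecule_id -> archetype_id
    archetypes: list[Archetype]


def make_archetypes(config: GeneratorConfig) -> list[Archetype]:
    """Template spectra (m/z ladders) plus overlapping descriptor sets.

    Each archetype gets a random base m/z and a ladder of peaks at
    base + k*ladder_step with geometrically decaying intensities, clipped
    to the window.  Descriptor sets are drawn from the pool; a fraction
    ``descriptor_overlap`` of each set is shared with the previous
    archetype (those shared labels sit at the end of the list, so the
    first descriptor stays archetype-owned while the pool lasts).
    """
    if config.mz_hi - config.mz_lo < config.ladder_step:
        raise ValueError(
            f"window [{config.mz_lo}, {config.mz_hi}] too small for "
            f"ladder step {config.ladder_step}"
        )
    rng = np.random.default_rng(config.seed)
    # distinct bases spread through the window keep archetypes separable
    base_hi = config.mz_hi - config.ladder_step
    candidates = np.arange(config.mz_lo, base_hi + 1)
    bases = rng.choice(
        candidates,
        size=min(config.n_archetypes, len(candidates)),
        replace=len(candidates) < config.n_archetypes,
    )
    pool = list(config.descriptor_pool)
    rng.shuffle(pool)
    # each archetype owns a signature first descriptor (unique while the
    # pool allows); the rest of its set may overlap with neighbors
    primaries = [pool[a % len(pool)] for a in range(config.n_archetypes)]
    extras = [d for d in pool if d not in primaries[: len(pool)]]
    remaining = list(extras)
    lo_d, hi_d = config.descriptors_per_archetype
    out: list[Archetype] = []
    prev: list[str] = []
    for a in range(config.n_archetypes):
        base = int(bases[a % len(bases)])
        template = []
        for k in range(config.peaks_per_archetype):
            mz = base + k * config.ladder_step
            if mz > config.mz_hi:
                break
            template.append((mz, 999.0 * 0.7**k))
        size = int(rng.integers(lo_d, hi_d + 1))
        n_shared = min(int(round(config.descriptor_overlap * size)), len(prev))
        shared = prev[-n_shared:] if n_shared else []
        own: list[str] = [] if n_shared >= size else [primaries[a]]
        while len(own) + n_shared < size:
            if not remaining:
                fresh = [
                    d for d in pool
                    if d not in prev and d not in shared and d not in own
                ]
                remaining = [d for d in fresh if d not in primaries] or fresh
                if not remaining:
                    raise ValueError(
                        "descriptor pool too small for the requested set sizes"
                    )
                rng.shuffle(remaining)
            cand = remaining.pop(0)
            if cand not in shared and cand not in own:
                own.append(cand)
        descriptors = own + shared
        out.append(Archetype(a, template, descriptors))
        prev = descriptors
    return out


def sample_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Molecules round-robin over archetypes, with jitter and noise peaks.

    Each molecule's spectrum is its archetype template with per-peak
    lognormal intensity jitter plus Poisson(spurious_peak_rate) random
    minor peaks (intensity at most 10% of the base peak); its descriptors
    are the archetype's, each independently dropped with probability
    ``descriptor_dropout``.  Fully deterministic given the seed.
    """
    archetypes = make_archetypes(config)
    rng = np.random.default_rng(config.seed + 1)
    width = len(str(config.n_molecules))
    spectra: list[MassSpectrum] = []
    truth: dict[str, int] = {}
    per_mol_desc: list[set[str]] = []
    for i in range(config.n_molecules):
        arch = archetypes[i % config.n_archetypes]
        mol = f"mol{i + 1:0{width}d}"
        peaks = [
            (mz, inten * rng.lognormal(0.0, config.intensity_jitter))
            if config.intensity_jitter > 0
            else (mz, inten)
            for mz, inten in arch.template
        ]
        base = max(i for _, i in peaks)
        for _ in range(rng.poisson(config.spurious_peak_rate)):
            mz = int(rng.integers(config.mz_lo, config.mz_hi + 1))
            peaks.append((mz, float(rng.uniform(0.0, 0.1 * base))))
        kept = {
            d for d in arch.descriptors if rng.random() >= config.descriptor_dropout
        }
        spectra.append(MassSpectrum.from_peaks(mol, peaks, kept))
        truth[mol] = arch.archetype_id
        per_mol_desc.append(kept)
    names = sorted({d for a in archetypes for d in a.descriptors})
    matrix = np.array(
        [[1 if n in s else 0 for n in names] for s in per_mol_desc], dtype=np.uint8
    ).reshape(config.n_molecules, len(names))
    table = DescriptorTable([s.molecule_id for s in spectra], names, matrix)
    return SyntheticDataset(spectra, table, truth, archetypes)


def write_fixture(dataset: SyntheticDataset, directory) -> dict[str, str]:
    """Emit spectra.msp, descriptors.csv (wide), descriptors_list.csv and
    truth.csv; read-back through the spectra module reproduces the data."""
    os.makedirs(directory, exist_ok=True)
    paths = {
        "spectra": os.path.join(directory, "spectra.msp"),
        "descriptors": os.path.join(directory, "descriptors.csv"),
        "descriptors_list": os.path.join(directory, "descriptors_list.csv"),
        "truth": os.path.join(directory, "truth.csv"),
    }
    write_msp(dataset.spectra, paths["spectra"])
    write_descriptor_csv(dataset.table, paths["descriptors"], dialect="wide")
    write_descriptor_csv(dataset.table, paths["descriptors_list"], dialect="list")
    pd.DataFrame(
        {
            "molecule_id": list(dataset.truth.keys()),
            "archetype_id": list(dataset.truth.values()),
        }
    ).to_csv(paths["truth"], index=False)
    return paths
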