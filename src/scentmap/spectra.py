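"""Data model, file I/O and preprocessing for odorant mass spectra.

Electron-ionization mass spectra are carried as unit-mass peak lists
(integer m/z, nonnegative relative intensity).  For the inverse-mapping
pipeline each spectrum is windowed to the odor-relevant m/z region
(51..262 by default; lower masses are dominated by odorless fragments,
higher ones contribute little to perception) and base-peak normalized so
every channel lies in [0, 1].

Odor-descriptor annotations (binary labels such as "peach" or "minty")
live in a :class:`DescriptorTable` that pairs with the spectra by
molecule identifier.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MZ_LO = 51
DEFAULT_MZ_HI = 262


class MSPParseError(ValueError):
    """Raised when an MSP record is malformed; the message names the record."""


@dataclass
class MassSpectrum:
    """One molecule's peak list plus identifier and odor descriptors.

    Peaks are stored sorted by strictly increasing integer m/z; duplicate
    m/z values must be merged (summed) before construction — the
    :meth:`from_peaks` factory does this, rounding fractional m/z to the
    nearest integer first.
    """

    molecule_id: str
    peaks: list[tuple[int, float]]
    descriptors: set[str] = field(default_factory=set)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError(
                f"{self.molecule_id}: m/z values must be strictly increasing"
            )
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"{self.molecule_id}: negative intensity")
        if not any(i > 0 for _, i in self.peaks):
            raise ValueError(f"{self.molecule_id}: all intensities are zero")

    @classmethod
    def from_peaks(
        cls,
        molecule_id: str,
        peaks,
        descriptors=None,
        metadata=None,
    ) -> "MassSpectrum":
        """Build a spectrum from raw (m/z, intensity) pairs.

        Fractional m/z is rounded to the nearest integer (unit-mass
        binning); duplicates are merged by summing intensities.
        """
        merged: dict[int, float] = {}
        for mz, inten in peaks:
            key = int(round(float(mz)))
            merged[key] = merged.get(key, 0.0) + float(inten)
        ordered = sorted(merged.items())
        return cls(
            molecule_id=molecule_id,
            peaks=ordered,
            descriptors=set(descriptors or ()),
            metadata=dict(metadata or {}),
        )

    @property
    def base_peak_intensity(self) -> float:
        return max(i for _, i in self.peaks)

    def intensity_at(self, mz: int) -> float:
        for m, i in self.peaks:
            if m == mz:
                return i
        return 0.0


@dataclass
class SpectrumMatrix:
    """N molecules x C windowed, base-peak-normalized intensity channels."""

    molecule_ids: list[str]
    channels: np.ndarray  # integer m/z values, ascending
    values: np.ndarray  # (N, C) floats in [0, 1]
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.molecule_ids),
            len(self.channels),
        ):
            raise ValueError("values shape inconsistent with ids/channels")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def row(self, molecule_id: str) -> np.ndarray:
        return self.values[self.molecule_ids.index(molecule_id)]


@dataclass
class DescriptorTable:
    """Binary molecule x odor-descriptor indicator matrix."""

    molecule_ids: list[str]
    descriptor_names: list[str]
    matrix: np.ndarray  # (N, D) of {0, 1}

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("descriptor matrix entries must be 0/1")
        if len(set(self.descriptor_names)) != len(self.descriptor_names):
            raise ValueError("descriptor names must be unique")
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            raise ValueError("duplicate molecule_id in descriptor table")
        if self.matrix.shape != (len(self.molecule_ids), len(self.descriptor_names)):
            raise ValueError("matrix shape inconsistent with ids/names")

    def descriptors_for(self, molecule_id: str) -> set[str]:
        """Descriptor set of a molecule; empty set if the id is unknown."""
        try:
            r = self.molecule_ids.index(molecule_id)
        except ValueError:
            return set()
        return {d for d, v in zip(self.descriptor_names, self.matrix[r]) if v}


# ---------------------------------------------------------------------------
# MSP text format (NIST-style): Name:, optional annotation fields,
# Num Peaks:, then "mz intensity" pairs (whitespace separated, optionally
# several pairs per line separated by ';'), records separated by blank lines.
# ---------------------------------------------------------------------------

def _parse_peak_line(line: str) -> list[tuple[float, float]]:
    """Peak pairs from a line: 'mz intensity' or several ';'-separated."""
    pairs = []
    for chunk in re.split(r"[;,]", line):
        toks = chunk.split()
        for i in range(0, len(toks) - 1, 2):
            pairs.append((float(toks[i]), float(toks[i + 1])))
    return pairs


def read_msp(path) -> list[MassSpectrum]:
    """Parse an MSP file into a list of :class:`MassSpectrum`.

    Duplicate m/z within a record are merged by summing intensities.
    A record missing ``Num Peaks`` or whose peak count disagrees with the
    header raises :class:`MSPParseError` naming the record.
    """
    with open(path) as fh:
        text = fh.read()
    spectra: list[MassSpectrum] = []
    for block in re.split(r"\n\s*\n", text.strip()):
        if not block.strip():
            continue
        spectra.append(_parse_msp_block(block))
    return spectra


def _parse_msp_block(block: str) -> MassSpectrum:
    name = None
    num_peaks = None
    metadata: dict[str, str] = {}
    descriptors: set[str] = set()
    raw_peaks: list[tuple[float, float]] = []
    in_peaks = False
    for line in block.splitlines():
        line = line.strip()
        if not line:
            continue
        if not in_peaks and ":" in line:
            key, _, val = line.partition(":")
            key_l = key.strip().lower()
            val = val.strip()
            if key_l == "name":
                name = val
                continue
            if key_l in ("num peaks", "numpeaks"):
                try:
                    num_peaks = int(val)
                except ValueError as exc:
                    raise MSPParseError(
                        f"record {name!r}: bad Num Peaks value {val!r}"
                    ) from exc
                in_peaks = True
                continue
            if key_l == "descriptors":
                descriptors = {
                    d.strip().lower() for d in val.split(";") if d.strip()
                }
                continue
            metadata[key_l] = val
            continue
        if in_peaks:
            raw_peaks.extend(_parse_peak_line(line))
    if name is None:
        raise MSPParseError(f"record with peaks {raw_peaks[:2]}...: missing Name")
    if num_peaks is None:
        raise MSPParseError(f"record {name!r}: missing Num Peaks")
    if len(raw_peaks) != num_peaks:
        raise MSPParseError(
            f"record {name!r}: Num Peaks={num_peaks} but {len(raw_peaks)} peaks listed"
        )
    return MassSpectrum.from_peaks(name, raw_peaks, descriptors, metadata)


def write_msp(spectra: list[MassSpectrum], path) -> None:
    """Write spectra in the MSP dialect :func:`read_msp` understands."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write(f"Name: {s.molecule_id}\n")
            for key, val in s.metadata.items():
                fh.write(f"{key.upper()}: {val}\n")
            if s.descriptors:
                fh.write("Descriptors: " + ";".join(sorted(s.descriptors)) + "\n")
            fh.write(f"Num Peaks: {len(s.peaks)}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz} {inten:.6f}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Descriptor CSV: molecule_id + either a 'descriptors' list column
# (';'-separated) or one binary column per descriptor (wide dialect).
# ---------------------------------------------------------------------------


def read_descriptor_csv(path) -> DescriptorTable:
    df = pd.read_csv(path, dtype={"molecule_id": str})
    if "molecule_id" not in df.columns:
        raise ValueError(f"{path}: missing molecule_id column")
    ids = df["molecule_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = df["molecule_id"][df["molecule_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate molecule_id {dupes}")
    other = [c for c in df.columns if c != "molecule_id"]
    if other == ["descriptors"]:
        per_mol = [
            {d.strip().lower() for d in str(cell).split(";") if d.strip()}
            if not pd.isna(cell)
            else set()
            for cell in df["descriptors"]
        ]
        names = sorted(set().union(*per_mol)) if per_mol else []
        matrix = np.array(
            [[1 if n in s else 0 for n in names] for s in per_mol], dtype=np.uint8
        ).reshape(len(ids), len(names))
        return DescriptorTable(ids, names, matrix)
    # wide-binary dialect
    names = [c.strip().lower() for c in other]
    try:
        matrix = df[other].astype(int).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: unknown descriptor CSV dialect") from exc
    if not np.isin(matrix, (0, 1)).all():
        raise ValueError(f"{path}: wide dialect requires binary 0/1 entries")
    return DescriptorTable(ids, names, matrix.astype(np.uint8))


def write_descriptor_csv(table: DescriptorTable, path, dialect: str = "wide") -> None:
    if dialect == "wide":
        df = pd.DataFrame(table.matrix, columns=table.descriptor_names)
        df.insert(0, "molecule_id", table.molecule_ids)
        df.to_csv(path, index=False)
    elif dialect == "list":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["molecule_id", "descriptors"])
            for i, mol in enumerate(table.molecule_ids):
                labels = [
                    d for d, v in zip(table.descriptor_names, table.matrix[i]) if v
                ]
                w.writerow([mol, ";".join(labels)])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Matrix CSV: first column molecule_id, remaining columns integer m/z.
# ---------------------------------------------------------------------------


def write_matrix_csv(matrix: SpectrumMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, columns=[str(c) for c in matrix.channels])
    df.insert(0, "molecule_id", matrix.molecule_ids)
    df.to_csv(path, index=False)


def read_matrix_csv(path) -> SpectrumMatrix:
    df = pd.read_csv(path, dtype={"molecule_id": str})
    channels = [int(c) for c in df.columns if c != "molecule_id"]
    return SpectrumMatrix(
        molecule_ids=df["molecule_id"].tolist(),
        channels=np.array(channels),
        values=df[[str(c) for c in channels]].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def window_and_normalize(
    spectra: list[MassSpectrum],
    lo: int = DEFAULT_MZ_LO,
    hi: int = DEFAULT_MZ_HI,
) -> SpectrumMatrix:
    """Window spectra to [lo, hi] m/z and base-peak normalize each row.

    Channel c holds the intensity at m/z = c (0 if absent); each row is
    divided by its own maximum so the in-window base peak equals 1.
    Molecules with no in-window intensity are excluded (reported in
    ``excluded_ids`` and via a logged warning, never silently dropped).
    """
    if lo >= hi:
        raise ValueError(f"window lo={lo} must be < hi={hi}")
    channels = np.arange(lo, hi + 1)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    excluded: list[str] = []
    for s in spectra:
        row = np.zeros(len(channels))
        for mz, inten in s.peaks:
            if lo <= mz <= hi:
                row[mz - lo] = inten
        peak = row.max()
        if peak <= 0:
            excluded.append(s.molecule_id)
            continue
        rows.append(row / peak)
        ids.append(s.molecule_id)
    if excluded:
        logger.warning(
            "window_and_normalize: excluded %d molecule(s) with no peak in "
            "m/z [%d, %d]: %s",
            len(excluded), lo, hi, excluded,
        )
    values = np.vstack(rows) if rows else np.empty((0, len(channels)))
    return SpectrumMatrix(ids, channels, values, excluded_ids=excluded)
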