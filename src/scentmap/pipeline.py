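"""Staged pipeline wiring: preprocess -> autoencode -> SOM -> labels.

Every stage persists a text checkpoint (JSON / CSV) in the output
directory so runs are resumable and every intermediate is inspectable.
A single top-level seed fans out deterministically to the autoencoder,
the SOM and the generator.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import autoencoder as ae
from . import som as som_mod
from .autoencoder import AEConfig, AEModel, LatentMatrix
from .extraction import (
    ExtractionResult,
    LatticeLabels,
    inverse_map,
    label_lattice,
    locate_molecule,
    neurons_for_descriptor,
    neurons_for_descriptor_pair,
)
from .sensory import DuoTrioResult, duo_trio_report
from .som import BMUAssignment, SOMConfig, SOMGrid
from .spectra import (
    DescriptorTable,
    SpectrumMatrix,
    read_descriptor_csv,
    read_matrix_csv,
    read_msp,
    window_and_normalize,
    write_matrix_csv,
)
from .synthetic import GeneratorConfig, sample_dataset, write_fixture

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    spectra_path: str
    descriptors_path: str
    output_dir: str
    mz_lo: int = 51
    mz_hi: int = 262
    ae: AEConfig = field(default_factory=AEConfig)
    som: SOMConfig = field(default_factory=SOMConfig)
    exclude_descriptors: list[str] = field(default_factory=list)
    cv_folds: int = 0  # >0: score the AE config by k-fold CV before training
    seed: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.ae, dict):
            self.ae = AEConfig(**self.ae)
        if isinstance(self.som, dict):
            self.som = SOMConfig(**self.som)
        if self.seed is not None:
            # one top-level seed fans out to every stochastic stage
            self.ae.seed = int(self.seed)
            self.som.seed = int(self.seed) + 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


@dataclass
class PipelineResult:
    matrix: SpectrumMatrix
    table: DescriptorTable
    model: AEModel
    latents: LatentMatrix
    grid: SOMGrid
    assignments: BMUAssignment
    labels: LatticeLabels
    quantization_error: float
    empty_neurons: int


def _latents_path(d):
    return os.path.join(d, "latents.csv")


def write_latents_csv(latents: LatentMatrix, path) -> None:
    df = pd.DataFrame(
        latents.values, columns=[f"z{i+1}" for i in range(latents.values.shape[1])]
    )
    df.insert(0, "molecule_id", latents.molecule_ids)
    df.to_csv(path, index=False)


def read_latents_csv(path) -> LatentMatrix:
    df = pd.read_csv(path, dtype={"molecule_id": str})
    cols = [c for c in df.columns if c != "molecule_id"]
    return LatentMatrix(df["molecule_id"].tolist(), df[cols].to_numpy(float))


def write_assignments_csv(assignments: BMUAssignment, path) -> None:
    pd.DataFrame(
        {
            "molecule_id": assignments.molecule_ids,
            "H": [c[0] for c in assignments.bmu_coords],
            "V": [c[1] for c in assignments.bmu_coords],
            "distance": assignments.distances,
        }
    ).to_csv(path, index=False)


def read_assignments_csv(path) -> BMUAssignment:
    df = pd.read_csv(path, dtype={"molecule_id": str})
    return BMUAssignment(
        df["molecule_id"].tolist(),
        [(int(h), int(v)) for h, v in zip(df["H"], df["V"])],
        df["distance"].tolist(),
    )


def run_simulate(config: GeneratorConfig, directory) -> dict[str, str]:
    """Generate a synthetic odorant fixture on disk."""
    dataset = sample_dataset(config)
    paths = write_fixture(dataset, directory)
    logger.info(
        "simulate: wrote %d molecules, %d archetypes, %d descriptors to %s",
        config.n_molecules, config.n_archetypes,
        len(dataset.table.descriptor_names), directory,
    )
    return paths


def run_pipeline(config: PipelineConfig, resume: bool = True) -> PipelineResult:
    """Execute the full extraction pipeline, checkpointing every stage.

    Stages: window/normalize the spectra, train the sparse autoencoder
    (on all data), encode to latent codes, train the SOM, assign BMUs,
    label the lattice with descriptors.  With ``resume=True``, stages
    whose checkpoint files already exist are loaded instead of recomputed.
    """
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    config.to_yaml(os.path.join(out, "pipeline_config.yaml"))

    matrix_path = os.path.join(out, "matrix.csv")
    if resume and os.path.exists(matrix_path):
        matrix = read_matrix_csv(matrix_path)
        logger.info("preprocess: resumed from %s", matrix_path)
    else:
        spectra = read_msp(config.spectra_path)
        matrix = window_and_normalize(spectra, config.mz_lo, config.mz_hi)
        write_matrix_csv(matrix, matrix_path)
        logger.info(
            "preprocess: %d molecules x %d channels (%d excluded)",
            len(matrix.molecule_ids), matrix.n_channels, len(matrix.excluded_ids),
        )
    table = read_descriptor_csv(config.descriptors_path)

    model_path = os.path.join(out, "ae_model.json")
    if resume and os.path.exists(model_path):
        model = ae.load_model(model_path)
        logger.info("train-ae: resumed from %s", model_path)
    else:
        cfg = config.ae
        if cfg.layer_sizes[0] != matrix.n_channels:
            sizes = (matrix.n_channels,) + tuple(cfg.layer_sizes[1:-1]) + (
                matrix.n_channels,
            )
            cfg = AEConfig(**{**asdict(cfg), "layer_sizes": sizes})
        if config.cv_folds > 1:
            cv = ae.cross_validate(cfg, matrix, config.cv_folds)
            logger.info(
                "train-ae: %d-fold CV reconstruction error %.5f",
                config.cv_folds, cv.mean_error,
            )
        model = ae.train(cfg, matrix)
        ae.save_model(model, model_path)
        logger.info(
            "train-ae: %d epochs, final loss %.5f",
            cfg.epochs, model.training_history[-1],
        )

    if resume and os.path.exists(_latents_path(out)):
        latents = read_latents_csv(_latents_path(out))
    else:
        latents = ae.encode(model, matrix)
        write_latents_csv(latents, _latents_path(out))

    grid_path = os.path.join(out, "som_grid.json")
    if resume and os.path.exists(grid_path):
        grid = som_mod.load_grid(grid_path)
        logger.info("train-som: resumed from %s", grid_path)
    else:
        grid = som_mod.train_som(config.som, latents)
        som_mod.save_grid(grid, grid_path)

    assign_path = os.path.join(out, "assignments.csv")
    if resume and os.path.exists(assign_path):
        assignments = read_assignments_csv(assign_path)
    else:
        assignments = som_mod.assign_bmus(grid, latents)
        write_assignments_csv(assignments, assign_path)

    labels = label_lattice(
        grid, assignments, table, exclude=set(config.exclude_descriptors)
    )
    qe = som_mod.quantization_error(grid, latents)
    empty = som_mod.empty_neuron_count(grid, latents)
    logger.info(
        "train-som: %dx%d map, QE %.4f, %d empty neurons",
        config.som.width, config.som.height, qe, empty,
    )
    from .extraction import lattice_report

    lattice_report(labels).to_csv(os.path.join(out, "lattice_labels.csv"), index=False)
    return PipelineResult(
        matrix, table, model, latents, grid, assignments, labels, qe, empty
    )


def run_query(
    result: PipelineResult,
    descriptor: str | None = None,
    descriptor2: str | None = None,
    molecule_id: str | None = None,
    pair_mode: str = "both_on_neuron",
    reference_id: str | None = None,
) -> list[ExtractionResult]:
    """Resolve a scent-impression (or molecule) query to extractions.

    Single descriptor: every neuron carrying it is inverse-mapped.
    Descriptor pair: neurons carrying both (per ``pair_mode``).
    Molecule id: that molecule's BMU neuron.
    """
    labels, latents, table = result.labels, result.latents, result.table
    if molecule_id is not None:
        coords = [locate_molecule(labels, molecule_id)]
        if reference_id is None:
            reference_id = molecule_id
    elif descriptor is not None and descriptor2 is not None:
        coords = neurons_for_descriptor_pair(
            labels, descriptor, descriptor2, table=table, mode=pair_mode
        )
    elif descriptor is not None:
        coords = neurons_for_descriptor(labels, descriptor)
    else:
        raise ValueError("query needs a descriptor, a pair, or a molecule_id")
    out = []
    for c in coords:
        r = inverse_map(labels, latents, c, table=table, reference_id=reference_id)
        r.query = molecule_id or (
            f"{descriptor}+{descriptor2}" if descriptor2 else descriptor
        )
        out.append(r)
    return out


def run_duotrio(k: int, n: int, p0: float = 0.5, alpha: float = 0.05) -> DuoTrioResult:
    return duo_trio_report(k, n, p0, alpha)
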