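"""Self-organizing map over latent spectrum codes.

A (width x height) lattice of codebook vectors — hexagonal by default, so
each interior neuron has six equidistant neighbors — is trained by
competitive learning: a random sample is drawn, its best matching unit
(BMU, the codebook vector at smallest Euclidean distance) is found, and
every codebook vector moves toward the sample weighted by a Gaussian
neighborhood around the BMU.  Defaults follow the odorant-spectrum study
conditions: 30x20 hexagonal map, Gaussian neighborhood with radius 1,
500 sample-draw iterations, learning rate 0.5.

Coordinates are (H, V) = (column, row), 0-based.  Hexagon centers live in
planar space with odd rows offset by 0.5 and row spacing sqrt(3)/2, which
makes nearest-neighbor center distance exactly 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autoencoder import LatentMatrix

SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass
class SOMConfig:
    width: int = 30
    height: int = 20
    topology: str = "hexagonal"  # or "rectangular"
    neighborhood: str = "gaussian"
    sigma: float = 1.0
    iterations: int = 500
    learning_rate: float = 0.5
    decay: str = "asymptotic"  # or "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1 or self.width * self.height < 2:
            raise ValueError("grid must have at least 2 units")
        if self.topology not in ("hexagonal", "rectangular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.neighborhood != "gaussian":
            raise ValueError("only the gaussian neighborhood is supported")
        if self.sigma <= 0 or self.learning_rate <= 0 or self.iterations < 1:
            raise ValueError("sigma, learning_rate, iterations must be positive")
        if self.decay not in ("asymptotic", "none"):
            raise ValueError("decay must be 'asymptotic' or 'none'")


def lattice_positions(config: SOMConfig) -> np.ndarray:
    """Planar hexagon-center coordinates, shape (height, width, 2)."""
    cols, rows = np.meshgrid(
        np.arange(config.width), np.arange(config.height)
    )
    if config.topology == "hexagonal":
        x = cols + 0.5 * (rows % 2)
        y = rows * SQRT3_2
    else:
        x = cols.astype(float)
        y = rows.astype(float)
    return np.stack([x, y], axis=-1).astype(float)


@dataclass
class SOMGrid:
    """Trained lattice: config, codebook (height, width, d) and positions."""

    config: SOMConfig
    codebook: np.ndarray
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=float)
        if self.codebook.shape[:2] != (self.config.height, self.config.width):
            raise ValueError("codebook shape inconsistent with config")
        if self.positions is None:
            self.positions = lattice_positions(self.config)

    @property
    def dim(self) -> int:
        return self.codebook.shape[2]

    def coords_row_major(self):
        """All (h, v) coordinates in row-major (v, then h) order."""
        for v in range(self.config.height):
            for h in range(self.config.width):
                yield (h, v)

    def planar(self, coord: tuple[int, int]) -> np.ndarray:
        h, v = coord
        return self.positions[v, h]


@dataclass
class BMUAssignment:
    molecule_ids: list[str]
    bmu_coords: list[tuple[int, int]]  # (H, V) per molecule
    distances: list[float]

    def coord_of(self, molecule_id: str) -> tuple[int, int]:
        return self.bmu_coords[self.molecule_ids.index(molecule_id)]


def find_bmu(grid: SOMGrid, vector: np.ndarray) -> tuple[int, int]:
    """(H, V) of the codebook vector nearest (Euclidean) to ``vector``.

    Ties broken by smallest row-major linear index (np.argmin's rule).
    """
    vector = np.asarray(vector, dtype=float)
    if not np.all(np.isfinite(vector)):
        raise ValueError("query vector contains non-finite values")
    if vector.shape != (grid.dim,):
        raise ValueError(f"query has shape {vector.shape}, codebook dim {grid.dim}")
    d2 = np.sum((grid.codebook - vector) ** 2, axis=2)
    flat = int(np.argmin(d2))
    v, h = divmod(flat, grid.config.width)
    return (h, v)


def neighborhood(grid: SOMGrid, bmu: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian weights exp(-d^2 / 2 sigma^2) over planar center distance."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, v = bmu
    if not (0 <= h < grid.config.width and 0 <= v < grid.config.height):
        raise ValueError(f"BMU {bmu} out of bounds")
    d2 = np.sum((grid.positions - grid.positions[v, h]) ** 2, axis=2)
    return np.exp(-d2 / (2.0 * sigma**2))


def train_som(config: SOMConfig, data: LatentMatrix | np.ndarray) -> SOMGrid:
    """Sample-wise competitive learning, deterministic given the seed.

    Codebook initialized uniformly within the data's per-dimension range;
    at step t the learning rate and radius decay as v0 / (1 + t/(T/2))
    (or stay fixed with decay='none').
    """
    x = data.values if isinstance(data, LatentMatrix) else np.asarray(data, float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("training data must be a non-empty 2-d array")
    rng = np.random.default_rng(config.seed)
    lo, hi = x.min(axis=0), x.max(axis=0)
    codebook = rng.uniform(
        lo, np.where(hi > lo, hi, lo + 1e-9),
        size=(config.height, config.width, x.shape[1]),
    )
    grid = SOMGrid(config, codebook)
    t_half = config.iterations / 2.0
    for t in range(config.iterations):
        sample = x[rng.integers(x.shape[0])]
        decay = 1.0 + t / t_half if config.decay == "asymptotic" else 1.0
        alpha = config.learning_rate / decay
        sigma = config.sigma / decay
        h = neighborhood(grid, find_bmu(grid, sample), sigma)
        grid.codebook += alpha * h[:, :, None] * (sample - grid.codebook)
    return grid


def assign_bmus(grid: SOMGrid, data: LatentMatrix) -> BMUAssignment:
    coords, dists = [], []
    for row in data.values:
        c = find_bmu(grid, row)
        coords.append(c)
        dists.append(float(np.linalg.norm(grid.codebook[c[1], c[0]] - row)))
    return BMUAssignment(list(data.molecule_ids), coords, dists)


def quantization_error(grid: SOMGrid, data: LatentMatrix | np.ndarray) -> float:
    """Mean Euclidean distance from each sample to its BMU codebook vector."""
    x = data.values if isinstance(data, LatentMatrix) else np.asarray(data, float)
    if x.shape[0] == 0:
        raise ValueError("quantization error undefined on empty data")
    from scipy.spatial.distance import cdist

    flat = grid.codebook.reshape(-1, grid.dim)
    d = cdist(x, flat)  # exact differences: QE is 0 on exact matches
    return float(d.min(axis=1).mean())


def lattice_neighbors(grid: SOMGrid, coord: tuple[int, int]) -> list[tuple[int, int]]:
    """Units at planar center distance 1 (6 for interior hexagons)."""
    p = grid.planar(coord)
    d = np.sqrt(np.sum((grid.positions - p) ** 2, axis=2))
    mask = np.abs(d - 1.0) < 1e-6
    return [(h, v) for (h, v) in grid.coords_row_major() if mask[v, h]]


def u_matrix(grid: SOMGrid) -> np.ndarray:
    """Per-neuron mean codebook distance to lattice neighbors (height, width)."""
    out = np.zeros((grid.config.height, grid.config.width))
    for h, v in grid.coords_row_major():
        nbrs = lattice_neighbors(grid, (h, v))
        out[v, h] = float(
            np.mean(
                [np.linalg.norm(grid.codebook[v, h] - grid.codebook[nv, nh])
                 for nh, nv in nbrs]
            )
        )
    return out


def empty_neuron_count(grid: SOMGrid, data: LatentMatrix | np.ndarray) -> int:
    """Units that are nobody's BMU over the dataset."""
    x = data.values if isinstance(data, LatentMatrix) else np.asarray(data, float)
    hit = np.zeros((grid.config.height, grid.config.width), dtype=bool)
    for row in x:
        h, v = find_bmu(grid, row)
        hit[v, h] = True
    return int((~hit).sum())


def map_size_scan(
    data: LatentMatrix | np.ndarray,
    sizes: list[tuple[int, int]],
    template: SOMConfig | None = None,
):
    """Train one seeded SOM per (width, height); report QE and empty units.

    Used to pick a map size: QE falls with capacity while blank lattices
    rise, and the chosen size balances the two.
    """
    import pandas as pd

    if not sizes:
        raise ValueError("need at least one size")
    template = template or SOMConfig()
    rows = []
    for w, h in sizes:
        cfg = SOMConfig(
            width=w, height=h, topology=template.topology,
            neighborhood=template.neighborhood, sigma=template.sigma,
            iterations=template.iterations,
            learning_rate=template.learning_rate, decay=template.decay,
            seed=template.seed,
        )
        grid = train_som(cfg, data)
        rows.append(
            {
                "width": w,
                "height": h,
                "units": w * h,
                "quantization_error": quantization_error(grid, data),
                "empty_neurons": empty_neuron_count(grid, data),
            }
        )
    return pd.DataFrame(rows)


def save_grid(grid: SOMGrid, path) -> None:
    payload = {"config": asdict(grid.config), "codebook": grid.codebook.tolist()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_grid(path) -> SOMGrid:
    with open(path) as fh:
        payload = json.load(fh)
    return SOMGrid(SOMConfig(**payload["config"]), np.array(payload["codebook"]))
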