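"""Five-layer sparse autoencoder compressing 212-d spectra to a 50-d code.

The network is 212-90-50-90-212 with logistic sigmoid activations at every
layer (inputs are base-peak normalized to [0, 1], so a sigmoid output keeps
reconstructions in range).  The training objective is

    E = (1/N) sum_n sum_k (y_kn - x_kn)^2
        + (lambda/2) * sum of squared weights (biases included)
        + beta * Omega_sparsity

where Omega_sparsity is the KL-divergence sparsity penalty
sum_j KL(rho || rho_hat_j) over bottleneck units, rho_hat_j being the mean
activation of unit j over the batch.  The squared error is summed over
channels and averaged over samples only.

Optimization is plain seeded mini-batch gradient descent with a fixed
learning rate; everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .spectra import SpectrumMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class AEConfig:
    """Hyperparameters of the 5-layer sparse autoencoder.

    Defaults follow the optimal values found by grid search for the
    odorant-spectrum task: hidden layers 90 and 50, learning rate
    eta = 0.01, L2 coefficient lambda = 1e-4, sparsity coefficient
    beta = 1, 1000 epochs.  The sparsity target rho is not part of that
    table; 0.05 is the customary default for KL sparsity penalties.
    """

    layer_sizes: tuple[int, ...] = (212, 90, 50, 90, 212)
    learning_rate: float = 0.01
    l2_coeff: float = 1e-4
    sparsity_coeff: float = 1.0
    sparsity_target: float = 0.05
    epochs: int = 1000
    batch_size: int = 32
    sparsity_layers: str = "bottleneck"  # or "all_hidden"
    seed: int = 0

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if len(self.layer_sizes) != 5:
            raise ValueError("layer_sizes must have 5 entries")
        if self.layer_sizes[0] != self.layer_sizes[-1]:
            raise ValueError("first and last layer sizes must match")
        if self.layer_sizes[2] >= self.layer_sizes[0]:
            raise ValueError("bottleneck must be smaller than the input layer")
        if self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("learning_rate and epochs must be positive")
        if not 0 < self.sparsity_target < 1:
            raise ValueError("sparsity_target must be in (0, 1)")
        if self.l2_coeff < 0 or self.sparsity_coeff < 0:
            raise ValueError("regularization coefficients must be >= 0")
        if self.sparsity_layers not in ("bottleneck", "all_hidden"):
            raise ValueError("sparsity_layers must be 'bottleneck' or 'all_hidden'")

    @property
    def bottleneck_size(self) -> int:
        return self.layer_sizes[2]


@dataclass
class AEModel:
    """Weights/biases of the autoencoder plus config and training history."""

    weights: list[np.ndarray]  # W[l] of shape (fan_in, fan_out)
    biases: list[np.ndarray]  # b[l] of shape (fan_out,)
    config: AEConfig
    training_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = self.config.layer_sizes
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l], sizes[l + 1]) or b.shape != (sizes[l + 1],):
                raise ValueError(f"layer {l}: weight shape {w.shape} inconsistent")


@dataclass
class LatentMatrix:
    """Bottleneck activations, one row per molecule."""

    molecule_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.molecule_ids):
            raise ValueError("row count must match molecule_ids")

    def row(self, molecule_id: str) -> np.ndarray:
        return self.values[self.molecule_ids.index(molecule_id)]


@dataclass
class LossParts:
    total: float
    reconstruction: float
    l2: float
    sparsity: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_model(config: AEConfig) -> AEModel:
    """Seeded Glorot-uniform weights, zero biases."""
    rng = np.random.default_rng(config.seed)
    weights, biases = [], []
    sizes = config.layer_sizes
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return AEModel(weights, biases, config)


def _forward_activations(model: AEModel, x: np.ndarray) -> list[np.ndarray]:
    """All layer activations a[0]=input ... a[4]=reconstruction."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.config.layer_sizes[0]:
        raise ValueError(
            f"input has {x.shape[1]} channels, model expects "
            f"{model.config.layer_sizes[0]}"
        )
    acts = [x]
    for w, b in zip(model.weights, model.biases):
        acts.append(_sigmoid(acts[-1] @ w + b))
    return acts


def forward(model: AEModel, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (latent codes, reconstructions) for a batch of rows."""
    acts = _forward_activations(model, batch)
    return acts[2], acts[4]


def _hidden_penalty_layers(config: AEConfig) -> list[int]:
    # activation indices (into the acts list) that the sparsity term covers
    return [2] if config.sparsity_layers == "bottleneck" else [1, 2, 3]


def _kl_sparsity(rho: float, rho_hat: np.ndarray) -> float:
    rho_hat = np.clip(rho_hat, _EPS, 1.0 - _EPS)
    return float(
        np.sum(
            rho * np.log(rho / rho_hat)
            + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_hat))
        )
    )


def loss(model: AEModel, batch: np.ndarray, reconstructions: np.ndarray | None = None) -> LossParts:
    """Evaluate the training objective on a batch; returns its parts.

    total = reconstruction + l2 + sparsity exactly (the parts already
    carry their coefficients lambda and beta).
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    acts = _forward_activations(model, batch)
    recon = acts[-1] if reconstructions is None else reconstructions
    n = batch.shape[0]
    rec = float(np.sum((recon - batch) ** 2) / n)
    cfg = model.config
    l2 = 0.0
    if cfg.l2_coeff > 0:
        sq = sum(float(np.sum(w**2)) for w in model.weights)
        sq += sum(float(np.sum(b**2)) for b in model.biases)  # biases included
        l2 = cfg.l2_coeff * 0.5 * sq
    sparsity = 0.0
    if cfg.sparsity_coeff > 0:
        for li in _hidden_penalty_layers(cfg):
            rho_hat = acts[li].mean(axis=0)
            if np.any((rho_hat <= 0) | (rho_hat >= 1)):
                logger.warning("mean activation hit {0,1}; clamped to [%g, %g]",
                               _EPS, 1 - _EPS)
            sparsity += _kl_sparsity(cfg.sparsity_target, rho_hat)
        sparsity *= cfg.sparsity_coeff
    return LossParts(rec + l2 + sparsity, rec, l2, sparsity)


def gradients(
    model: AEModel, batch: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray], LossParts]:
    """Analytic gradient of the objective w.r.t. every weight and bias."""
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    n = batch.shape[0]
    cfg = model.config
    acts = _forward_activations(model, batch)
    parts = loss(model, batch, reconstructions=acts[-1])

    penalty_layers = set(_hidden_penalty_layers(cfg)) if cfg.sparsity_coeff > 0 else set()
    rho = cfg.sparsity_target

    # d(loss)/d(activation) at the output layer
    grad_a = 2.0 * (acts[-1] - batch) / n
    grad_w = [np.zeros_like(w) for w in model.weights]
    grad_b = [np.zeros_like(b) for b in model.biases]
    for l in range(len(model.weights) - 1, -1, -1):
        a_out = acts[l + 1]
        if (l + 1) in penalty_layers:
            rho_hat = np.clip(a_out.mean(axis=0), _EPS, 1.0 - _EPS)
            # d Omega / d a_out[n, j] via the batch-mean rho_hat
            grad_a = grad_a + cfg.sparsity_coeff * (
                -rho / rho_hat + (1.0 - rho) / (1.0 - rho_hat)
            ) / n
        delta = grad_a * a_out * (1.0 - a_out)  # sigmoid'
        grad_w[l] = acts[l].T @ delta + cfg.l2_coeff * model.weights[l]
        grad_b[l] = delta.sum(axis=0) + cfg.l2_coeff * model.biases[l]
        grad_a = delta @ model.weights[l].T
    return grad_w, grad_b, parts


def train(config: AEConfig, data: SpectrumMatrix | np.ndarray) -> AEModel:
    """Mini-batch gradient descent for ``config.epochs`` epochs.

    training_history records the full-data total loss after each epoch.
    Deterministic given ``config.seed``; aborts with a diagnostic naming
    the epoch if the loss turns non-finite.
    """
    x = data.values if isinstance(data, SpectrumMatrix) else np.asarray(data, float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples to train")
    if x.shape[1] != config.layer_sizes[0]:
        raise ValueError(
            f"data has {x.shape[1]} channels, config expects {config.layer_sizes[0]}"
        )
    model = init_model(config)
    rng = np.random.default_rng(config.seed + 1)
    n = x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = x[order[start : start + config.batch_size]]
            gw, gb, _ = gradients(model, batch)
            for l in range(len(model.weights)):
                model.weights[l] -= config.learning_rate * gw[l]
                model.biases[l] -= config.learning_rate * gb[l]
        epoch_loss = loss(model, x).total
        if not np.isfinite(epoch_loss):
            raise TrainingDivergedError(
                f"non-finite loss at epoch {epoch}: {epoch_loss}"
            )
        model.training_history.append(epoch_loss)
    return model


def encode(model: AEModel, data: SpectrumMatrix) -> LatentMatrix:
    """Bottleneck activations for every molecule, order preserved."""
    latent, _ = forward(model, data.values)
    return LatentMatrix(list(data.molecule_ids), latent)


def reconstruction_error(model: AEModel, x: np.ndarray) -> float:
    """Mean per-sample summed-squared reconstruction error (no penalties)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    _, recon = forward(model, x)
    return float(np.sum((recon - x) ** 2) / x.shape[0])


@dataclass
class CVResult:
    fold_errors: list[float]
    mean_error: float
    fold_sizes: list[int]


def cross_validate(
    config: AEConfig, data: SpectrumMatrix | np.ndarray, folds: int = 5
) -> CVResult:
    """k-fold CV of the reconstruction error (regularizers excluded).

    The split is a seeded shuffle into ``folds`` disjoint, exhaustive
    parts; each fold is held out once while a fresh model trains on the
    rest.
    """
    x = data.values if isinstance(data, SpectrumMatrix) else np.asarray(data, float)
    n = x.shape[0]
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"cannot split {n} samples into {folds} folds")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    parts = np.array_split(order, folds)
    errors, sizes = [], []
    for i, test_idx in enumerate(parts):
        train_idx = np.concatenate([p for j, p in enumerate(parts) if j != i])
        model = train(config, x[train_idx])
        errors.append(reconstruction_error(model, x[test_idx]))
        sizes.append(len(test_idx))
    return CVResult(errors, float(np.mean(errors)), sizes)


def grid_search(
    configs: list[AEConfig], data: SpectrumMatrix | np.ndarray, folds: int = 5
) -> list[tuple[AEConfig, float]]:
    """Score each config by CV error; rank ascending.

    Ties broken by smaller bottleneck, then listing order.
    """
    if not configs:
        raise ValueError("grid_search needs at least one config")
    scored = [
        (cfg, cross_validate(cfg, data, folds).mean_error) for cfg in configs
    ]
    order = sorted(
        range(len(scored)),
        key=lambda i: (scored[i][1], scored[i][0].bottleneck_size, i),
    )
    return [scored[i] for i in order]


# ---------------------------------------------------------------------------
# Checkpointing (self-describing JSON, exact round-trip)
# ---------------------------------------------------------------------------


def save_model(model: AEModel, path) -> None:
    payload = {
        "config": asdict(model.config),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "training_history": model.training_history,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> AEModel:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = AEConfig(**payload["config"])
    return AEModel(
        [np.array(w) for w in payload["weights"]],
        [np.array(b) for b in payload["biases"]],
        cfg,
        payload.get("training_history", []),
    )
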