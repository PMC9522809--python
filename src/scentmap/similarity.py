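"""Spectral similarity scoring and principal-component closeness checks.

The similarity score between two spectra is cos(theta), the cosine of the
angle between their intensity vectors — scale invariant, 1 for
proportional spectra, 0 for spectra with no shared channels.  It applies
unchanged to raw 212-channel windowed spectra and to 50-d latent codes
(one implementation, representation-agnostic).  Head-to-tail reports pair
the reference spectrum (positive) with the negated query for mirror
plotting.  PCA here is plain mean-centered covariance eigendecomposition,
used to eyeball how tightly molecules extracted for one impression
cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import MassSpectrum


@dataclass
class SimilarityReport:
    reference_id: str
    query_id: str
    score: float
    head_to_tail: list[tuple[int, float, float]]  # (channel, ref, -query)


def cosine_similarity(a, b) -> float:
    """dot(a, b) / (|a| |b|); raises on zero-norm input."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(a, b) / (na * nb))


def _as_channel_vector(x, channels=None):
    """(ids, vector) pair for either a MassSpectrum or a plain vector."""
    if isinstance(x, MassSpectrum):
        return x.molecule_id, x
    return None, np.asarray(x, dtype=float).ravel()


def head_to_tail(reference, query, reference_id="reference", query_id="query") -> SimilarityReport:
    """Aligned-channel comparison: reference up, query mirrored down.

    Both arguments must be the same representation: two MassSpectrum
    objects (aligned on the union of their m/z values) or two equal-length
    vectors (aligned on index).
    """
    both_spectra = isinstance(reference, MassSpectrum) and isinstance(query, MassSpectrum)
    both_vectors = not isinstance(reference, MassSpectrum) and not isinstance(query, MassSpectrum)
    if not (both_spectra or both_vectors):
        raise TypeError("reference and query must share one representation")
    if both_spectra:
        reference_id, query_id = reference.molecule_id, query.molecule_id
        mzs = sorted(
            {mz for mz, _ in reference.peaks} | {mz for mz, _ in query.peaks}
        )
        ref_vec = np.array([reference.intensity_at(m) for m in mzs])
        qry_vec = np.array([query.intensity_at(m) for m in mzs])
        channels = mzs
    else:
        ref_vec = np.asarray(reference, dtype=float).ravel()
        qry_vec = np.asarray(query, dtype=float).ravel()
        if ref_vec.shape != qry_vec.shape:
            raise ValueError("vector representations must have equal length")
        channels = list(range(len(ref_vec)))
    score = cosine_similarity(ref_vec, qry_vec)
    pairs = [
        (int(c), float(r), float(-q)) for c, r, q in zip(channels, ref_vec, qry_vec)
    ]
    return SimilarityReport(reference_id, query_id, score, pairs)


def similarity_matrix(vectors: np.ndarray, ids: list[str]):
    """Pairwise cosine similarity DataFrame (exported as CSV by callers)."""
    import pandas as pd

    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero-norm row in similarity matrix input")
    m = (vectors / norms[:, None]) @ (vectors / norms[:, None]).T
    return pd.DataFrame(m, index=ids, columns=ids)


def pca_project(vectors: np.ndarray, components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered projection onto the top principal axes.

    Returns (scores of shape (N, components), explained-variance
    fractions).  No variance scaling.  Sign convention: each axis's
    largest-magnitude loading is made positive.  Constant (zero-variance)
    data raises.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need an (N>=2, d) array")
    if not 1 <= components <= min(x.shape[0] - 1, x.shape[1]):
        raise ValueError(f"components must be in [1, {min(x.shape[0]-1, x.shape[1])}]")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / (x.shape[0] - 1)
    total_var = float(np.trace(cov))
    if total_var <= 0:
        raise ValueError("constant data has no principal components")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:components]
    axes = evecs[:, order]
    for j in range(axes.shape[1]):
        k = int(np.argmax(np.abs(axes[:, j])))
        if axes[k, j] < 0:
            axes[:, j] = -axes[:, j]
    scores = xc @ axes
    frac = np.maximum(evals[order], 0.0) / total_var
    return scores, frac
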