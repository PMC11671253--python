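"""Gaussian interaction-profile (GIP) kernel similarity networks.

Each microbe's interaction profile is its row of the association matrix, each
disease's its column.  The kernel between two entities is
``exp(-gamma * ||IP_i - IP_j||^2)`` with the bandwidth normalized by the mean
squared profile norm, ``gamma = gamma' / ((1/n) sum_i ||IP_i||^2)`` (raw
bandwidth ``gamma'`` defaults to 1).  Thresholding the kernel at ``t`` gives
the binary similarity adjacency used as a message-passing graph; the
diagonal is forced to zero because the encoder adds self-loops explicitly,
and keeping K_ii = 1 edges would double-count them.

Always compute kernels from the *training* matrix of a split — held-out
cells must not leak into the similarity networks.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import io as spio
from scipy import sparse
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "SimilarityNetwork",
    "gip_bandwidth",
    "gip_kernel",
    "threshold_network",
    "build_similarity_networks",
]

logger = logging.getLogger(__name__)


class ThresholdError(ValueError):
    pass


@dataclass
class SimilarityNetwork:
    """A GIP kernel matrix plus its thresholded binary adjacency."""

    kernel: np.ndarray
    adjacency: np.ndarray
    threshold: float
    gamma: float = np.nan
    gamma_prime: float = 1.0

    def save(self, directory: str | os.PathLike, stem: str,
             source_hash: str | None = None) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(d / f"{stem}_kernel.mtx"), sparse.coo_matrix(self.kernel))
        spio.mmwrite(str(d / f"{stem}_adjacency.mtx"),
                     sparse.coo_matrix(self.adjacency))
        meta = {
            "threshold": self.threshold,
            "gamma": self.gamma,
            "gamma_prime": self.gamma_prime,
            "source_hash": source_hash,
        }
        (d / f"{stem}_provenance.json").write_text(json.dumps(meta, indent=2))


def gip_bandwidth(profiles: np.ndarray, gamma_prime: float = 1.0) -> float:
    """Normalized kernel bandwidth gamma = gamma' / mean(||IP_i||^2).

    Returns 0 for an all-zero profile matrix (degenerate: every pairwise
    distance is then 0 and the kernel is all-ones regardless).
    """
    profiles = np.asarray(profiles, dtype=np.float64)
    mean_sq_norm = float(np.mean((profiles ** 2).sum(axis=1)))
    if mean_sq_norm == 0.0:
        logger.warning("all-zero profiles: bandwidth degenerates to 0")
        return 0.0
    return gamma_prime / mean_sq_norm


def gip_kernel(profiles: np.ndarray, gamma: float) -> np.ndarray:
    """K_ij = exp(-gamma * ||IP_i - IP_j||^2); symmetric, unit diagonal."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    profiles = np.asarray(profiles, dtype=np.float64)
    if not np.isin(profiles, (0.0, 1.0)).all():
        logger.info("non-binary profiles passed to gip_kernel; formula still valid")
    if profiles.shape[0] == 1:
        return np.ones((1, 1))
    sq = squareform(pdist(profiles, metric="sqeuclidean"))
    K = np.exp(-gamma * sq)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return K


def threshold_network(kernel: np.ndarray, t: float,
                      gamma: float = np.nan,
                      gamma_prime: float = 1.0) -> SimilarityNetwork:
    """Binarize: an edge where K_ij >= t (i != j); diagonal stays 0."""
    if not (0.0 < t < 1.0):
        raise ThresholdError(f"threshold t={t} must lie in (0, 1)")
    kernel = np.asarray(kernel, dtype=np.float64)
    adjacency = (kernel >= t).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return SimilarityNetwork(kernel=kernel, adjacency=adjacency, threshold=t,
                             gamma=gamma, gamma_prime=gamma_prime)


def build_similarity_networks(
    A_train: np.ndarray, t: float, gamma_prime: float = 1.0
) -> tuple[SimilarityNetwork, SimilarityNetwork]:
    """Microbe (rows of A) and disease (columns of A) similarity networks."""
    A_train = np.asarray(A_train, dtype=np.float64)
    gm = gip_bandwidth(A_train, gamma_prime)
    gd = gip_bandwidth(A_train.T, gamma_prime)
    km = gip_kernel(A_train, gm)
    kd = gip_kernel(A_train.T, gd)
    return (
        threshold_network(km, t, gamma=gm, gamma_prime=gamma_prime),
        threshold_network(kd, t, gamma=gd, gamma_prime=gamma_prime),
    )


def matrix_hash(A: np.ndarray) -> str:
    """Stable content hash used in provenance sidecars."""
    return hashlib.sha256(np.ascontiguousarray(A, dtype=np.int8).tobytes()).hexdigest()
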