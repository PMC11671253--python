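"""Planted-block synthetic association matrices.

The Gaussian interaction-profile hypothesis — functionally similar microbes
(or diseases) share interaction patterns — is exactly a block structure in
the bipartite matrix.  The generator plants ``n_blocks`` communities: a cell
whose microbe and disease sit in the same block is positive with probability
``p_in``, otherwise ``p_out``.  Block assignment is deterministic round-robin
(microbe ``i`` to block ``i % n_blocks``), which makes expected positive
counts exactly computable for tests; ground-truth labels are returned for
diagnostics, never for training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import AssociationDataset

__all__ = ["SyntheticConfig", "generate"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-block bipartite generator."""

    n_m: int = 200
    n_d: int = 40
    n_blocks: int = 4
    p_in: float = 0.3
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ConfigError("require 0 <= p_out <= p_in <= 1")
        if self.n_blocks > min(self.n_m, self.n_d):
            raise ConfigError("n_blocks exceeds the smaller axis")
        if self.n_blocks < 1 or self.n_m < 2 or self.n_d < 2:
            raise ConfigError("need n_blocks >= 1 and at least 2 nodes per axis")


def block_labels(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    """Round-robin block assignment for microbes and diseases."""
    return (
        np.arange(cfg.n_m) % cfg.n_blocks,
        np.arange(cfg.n_d) % cfg.n_blocks,
    )


def generate(
    cfg: SyntheticConfig, return_blocks: bool = False
) -> AssociationDataset | tuple[AssociationDataset, np.ndarray, np.ndarray]:
    """Draw one planted-block dataset; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    mb, db = block_labels(cfg)
    same = mb[:, None] == db[None, :]
    probs = np.where(same, cfg.p_in, cfg.p_out)
    A = (rng.random((cfg.n_m, cfg.n_d)) < probs).astype(np.int8)
    ds = AssociationDataset(
        [f"m{i}" for i in range(cfg.n_m)],
        [f"d{j}" for j in range(cfg.n_d)],
        A,
    )
    if return_blocks:
        return ds, mb, db
    return ds
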