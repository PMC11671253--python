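"""Canned benchmark experiments on the planted-block generator.

These are the package's standing health checks: a held-out recovery
experiment on the default planted-block conditions (200 x 40, 4 blocks,
p_in=0.3, p_out=0.02) and a small-capacity overfit check.  Both are pure
functions of their seeds, so results are reproducible anywhere.
"""

from __future__ import annotations

import numpy as np

from .data_io import make_cv_splits
from .evaluation import MetricsReport, compute_metrics, evaluate_split
from .synthetic import SyntheticConfig, generate
from .training import ModelConfig, score_matrix, train

__all__ = ["planted_recovery", "capacity_check"]

RECOVERY_GENERATOR = dict(n_m=200, n_d=40, n_blocks=4, p_in=0.3, p_out=0.02)
# training conditions for the synthetic benchmark: the similarity threshold
# and architecture stay at their defaults; the higher learning rate and
# longer schedule suit the denser synthetic matrix
RECOVERY_TRAINING = dict(lr=1e-3, epochs=200)


def planted_recovery(variant: str = "full", n_seeds: int = 5,
                     base_seed: int = 0) -> list[MetricsReport]:
    """Held-out metrics on the planted-block benchmark, one 5-fold split
    per seed; dataset, split, and weight-initialization seeds all vary."""
    reports = []
    for s in range(n_seeds):
        seed = base_seed + s
        ds = generate(SyntheticConfig(seed=seed, **RECOVERY_GENERATOR))
        split = make_cv_splits(ds, k=5, repetitions=1, base_seed=seed)[0]
        cfg = ModelConfig(variant=variant, seed=seed, **RECOVERY_TRAINING)
        report, _ = evaluate_split(ds, split, cfg)
        reports.append(report)
    return reports


def capacity_check(seed: int = 0) -> float:
    """Train AUC after overfitting a 40 x 10 dataset (capacity sanity)."""
    ds = generate(SyntheticConfig(n_m=40, n_d=10, n_blocks=2,
                                  p_in=0.5, p_out=0.05, seed=seed))
    split = make_cv_splits(ds, k=5, repetitions=1, base_seed=seed)[0]
    cfg = ModelConfig(lr=1e-3, epochs=500, seed=seed)
    result = train(ds, split, cfg)
    scores = score_matrix(result)
    pairs = split.train_pos + split.train_neg
    labels = [1] * len(split.train_pos) + [0] * len(split.train_neg)
    s = np.array([scores[i, j] for i, j in pairs])
    return compute_metrics(s, labels).auc
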