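"""Association tables, the binary bipartite matrix, and cross-validation splits.

Input data are curated microbe-disease association edge lists (one row per
literature evidence, so the same pair may appear many times).  Reading a table
collapses duplicates: the association matrix ``A`` is a 0/1 indicator with
``A[i, j] = 1`` iff the pair (microbe i, disease j) occurred at least once.
A zero cell means *unlabeled*, not "no association" — zero cells are the pool
from which balanced negative samples are drawn.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "AssociationDataset",
    "EdgeSplit",
    "SchemaError",
    "EmptyDatasetError",
    "SplitError",
    "read_association_table",
    "make_cv_splits",
    "full_training_split",
    "training_matrix",
    "save_splits",
    "load_splits",
]

Pair = tuple[int, int]


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class EmptyDatasetError(ValueError):
    """The table parsed to zero usable association rows."""


class SplitError(ValueError):
    """Cross-validation split request cannot be satisfied."""


@dataclass
class AssociationDataset:
    """Named binary bipartite association matrix (microbes x diseases)."""

    microbe_names: list[str]
    disease_names: list[str]
    A: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        n_m, n_d = self.A.shape
        if len(self.microbe_names) != n_m or len(self.disease_names) != n_d:
            raise ValueError("name lists do not match matrix shape")
        if len(set(self.microbe_names)) != n_m:
            raise ValueError("duplicate microbe names")
        if len(set(self.disease_names)) != n_d:
            raise ValueError("duplicate disease names")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("association matrix must be binary")
        self.A = self.A.astype(np.int8)

    @property
    def n_microbes(self) -> int:
        return self.A.shape[0]

    @property
    def n_diseases(self) -> int:
        return self.A.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.A.sum())

    def positive_pairs(self) -> list[Pair]:
        return [tuple(p) for p in np.argwhere(self.A == 1)]

    # -- persistence (MatrixMarket + plain-text name indexes) ---------------

    def save(self, directory: str | os.PathLike) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(d / "associations.mtx"), sparse.coo_matrix(self.A))
        (d / "microbes.txt").write_text("\n".join(self.microbe_names) + "\n")
        (d / "diseases.txt").write_text("\n".join(self.disease_names) + "\n")

    @classmethod
    def load(cls, directory: str | os.PathLike) -> "AssociationDataset":
        d = Path(directory)
        A = np.asarray(spio.mmread(str(d / "associations.mtx")).todense())
        microbes = (d / "microbes.txt").read_text().splitlines()
        diseases = (d / "diseases.txt").read_text().splitlines()
        return cls(microbes, diseases, A)


@dataclass
class EdgeSplit:
    """One train/test partition of positive pairs with sampled negatives.

    Negatives are drawn once, uniformly without replacement from the zero
    cells, balanced (``|train_neg| == |train_pos|``, ``|test_neg| ==
    |test_pos|``) and disjoint between train and test.
    """

    train_pos: list[Pair]
    train_neg: list[Pair]
    test_pos: list[Pair]
    test_neg: list[Pair]
    seed: int
    rep: int = 0
    fold: int = 0

    def validate(self, ds: AssociationDataset) -> None:
        pos = set(map(tuple, self.train_pos)) | set(map(tuple, self.test_pos))
        if pos != {tuple(p) for p in ds.positive_pairs()}:
            raise SplitError("train_pos and test_pos do not cover the positives")
        if set(map(tuple, self.train_pos)) & set(map(tuple, self.test_pos)):
            raise SplitError("train/test positives overlap")
        negs = set(map(tuple, self.train_neg)) | set(map(tuple, self.test_neg))
        if len(negs) != len(self.train_neg) + len(self.test_neg):
            raise SplitError("train/test negatives overlap")
        if negs & pos:
            raise SplitError("a sampled negative coincides with a positive")
        for i, j in negs:
            if ds.A[i, j] != 0:
                raise SplitError("negative pair has A_ij != 0")
        if len(self.train_neg) != len(self.train_pos):
            raise SplitError("train negatives not balanced")
        if len(self.test_neg) != len(self.test_pos):
            raise SplitError("test negatives not balanced")


def read_association_table(
    path: str | os.PathLike,
    microbe_col: str = "microbe",
    disease_col: str = "disease",
    sep: str = "\t",
) -> AssociationDataset:
    """Read an edge list, de-duplicate multi-evidence rows, and index it.

    Every (microbe, disease) pair occurring at least once — regardless of how
    many evidence rows repeat it — becomes a single ``A_ij = 1`` entry.  Names
    are stripped of surrounding whitespace (case preserved; taxonomy carries
    case) and sorted lexicographically so indices are stable across reads.

    A headerless two-column file is accepted as a minimal edge-list dialect
    when the named columns are absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    if microbe_col not in df.columns or disease_col not in df.columns:
        if df.shape[1] == 2:
            df = pd.read_csv(path, sep=sep, header=None, dtype=str)
            df.columns = [microbe_col, disease_col]
        else:
            raise SchemaError(
                f"columns {microbe_col!r}/{disease_col!r} not found in {list(df.columns)}"
            )
    df = df[[microbe_col, disease_col]].dropna()
    pairs = {
        (str(m).strip(), str(d).strip())
        for m, d in zip(df[microbe_col], df[disease_col])
        if str(m).strip() and str(d).strip()
    }
    if not pairs:
        raise EmptyDatasetError(f"no association rows parsed from {path}")
    microbes = sorted({m for m, _ in pairs})
    diseases = sorted({d for _, d in pairs})
    m_idx = {m: i for i, m in enumerate(microbes)}
    d_idx = {d: j for j, d in enumerate(diseases)}
    A = np.zeros((len(microbes), len(diseases)), dtype=np.int8)
    for m, d in pairs:
        A[m_idx[m], d_idx[d]] = 1
    return AssociationDataset(microbes, diseases, A)


def _sample_negatives(
    rng: np.random.Generator, zero_cells: np.ndarray, n: int
) -> list[Pair]:
    if n > len(zero_cells):
        raise SplitError(
            f"need {n} negative cells but only {len(zero_cells)} zero cells exist"
        )
    chosen = rng.choice(len(zero_cells), size=n, replace=False)
    return [tuple(zero_cells[c]) for c in chosen]


def make_cv_splits(
    ds: AssociationDataset, k: int, repetitions: int, base_seed: int
) -> list[EdgeSplit]:
    """Repeated k-fold splits of the positive pairs with balanced negatives.

    For repetition ``r`` the positives are shuffled with seed ``base_seed + r``
    and partitioned into ``k`` folds; each fold in turn is the test set.  Per
    split, ``|positives|`` distinct zero cells are sampled and divided into
    test and train negatives, so the two never overlap.
    """
    if k < 2:
        raise SplitError("k must be >= 2")
    positives = np.array(ds.positive_pairs(), dtype=np.int64)
    if len(positives) < k:
        raise SplitError(f"{len(positives)} positives cannot fill {k} folds")
    zero_cells = np.argwhere(ds.A == 0)
    splits: list[EdgeSplit] = []
    for rep in range(repetitions):
        rng = np.random.default_rng(base_seed + rep)
        order = rng.permutation(len(positives))
        folds = np.array_split(order, k)
        for fold_id, fold in enumerate(folds):
            test_pos = [tuple(p) for p in positives[fold]]
            train_idx = np.setdiff1d(order, fold, assume_unique=True)
            train_pos = [tuple(p) for p in positives[train_idx]]
            negs = _sample_negatives(rng, zero_cells, len(positives))
            test_neg = negs[: len(test_pos)]
            train_neg = negs[len(test_pos):]
            splits.append(
                EdgeSplit(
                    train_pos=train_pos,
                    train_neg=train_neg,
                    test_pos=test_pos,
                    test_neg=test_neg,
                    seed=base_seed + rep,
                    rep=rep,
                    fold=fold_id,
                )
            )
    return splits


def full_training_split(ds: AssociationDataset, seed: int) -> EdgeSplit:
    """All positives in training with balanced negatives; empty test sets.

    Used for candidate ranking, where the model is fit on every known
    association before scoring the unknown cells.
    """
    rng = np.random.default_rng(seed)
    positives = ds.positive_pairs()
    zero_cells = np.argwhere(ds.A == 0)
    negs = _sample_negatives(rng, zero_cells, len(positives))
    return EdgeSplit(positives, negs, [], [], seed=seed)


def training_matrix(ds: AssociationDataset, split: EdgeSplit) -> np.ndarray:
    """Association matrix with held-out positive cells zeroed.

    This matrix is the *only* input to similarity construction and to the
    message-passing graph: held-out links never inform the model.
    """
    A = ds.A.astype(np.int8).copy()
    for i, j in split.test_pos:
        if not (0 <= i < A.shape[0] and 0 <= j < A.shape[1]):
            raise SplitError(f"test pair {(i, j)} outside matrix of shape {A.shape}")
        A[i, j] = 0
    return A


# -- split persistence (TSV of rep, fold, role, microbe, disease) -----------

_ROLES = ("train_pos", "train_neg", "test_pos", "test_neg")


def save_splits(
    splits: list[EdgeSplit], ds: AssociationDataset, path: str | os.PathLike
) -> None:
    rows = []
    for s in splits:
        for role in _ROLES:
            for i, j in getattr(s, role):
                rows.append(
                    (s.rep, s.fold, role, ds.microbe_names[i], ds.disease_names[j])
                )
    pd.DataFrame(
        rows, columns=["rep", "fold", "role", "microbe", "disease"]
    ).to_csv(path, sep="\t", index=False)


def load_splits(
    path: str | os.PathLike, ds: AssociationDataset, seed: int = 0
) -> list[EdgeSplit]:
    df = pd.read_csv(path, sep="\t", dtype={"rep": int, "fold": int})
    m_idx = {m: i for i, m in enumerate(ds.microbe_names)}
    d_idx = {d: j for j, d in enumerate(ds.disease_names)}
    splits = []
    for (rep, fold), grp in df.groupby(["rep", "fold"], sort=True):
        kwargs = {role: [] for role in _ROLES}
        for _, row in grp.iterrows():
            kwargs[row["role"]].append((m_idx[row["microbe"]], d_idx[row["disease"]]))
        splits.append(EdgeSplit(seed=seed, rep=rep, fold=fold, **kwargs))
    return splits
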