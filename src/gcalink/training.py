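"""Model assembly and the full-batch Adam training loop.

The full model runs three independent GCAT encoders — on the bipartite
association graph, the microbe similarity graph, and the disease similarity
graph — splits the association-graph output into microbe rows (the first
``n_m``) and disease rows, and decodes association scores as
``sigmoid(Z_m @ Z_d^T)`` where ``Z_m = [ZA_m || ZS_m]`` and
``Z_d = [ZA_d || ZS_d]``.  Training minimizes BCE on the balanced train
pairs plus ``lambda`` times the cross-view contrastive loss, full-batch
(the graphs have a few hundred nodes), for a fixed number of epochs.

Ablation variants are configuration, not separate code paths: single-view
models duplicate the remaining view, ``no_gcn``/``no_gat`` drop one encoder
mechanism, the fusion rule is selectable, and ``no_cl`` zeroes ``lambda``.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from .data_io import AssociationDataset, EdgeSplit, training_matrix
from .encoder import (
    EncoderParams,
    GraphInput,
    association_graph,
    encode,
    init_encoder_params,
)
from .objectives import EmbeddingViews, LossConfig, bce_loss, contrastive_total
from .similarity import build_similarity_networks

__all__ = [
    "ModelConfig",
    "ModelParams",
    "TrainResult",
    "decode",
    "prepare_graphs",
    "forward",
    "train",
    "Adam",
]

logger = logging.getLogger(__name__)

VARIANTS = ("full", "sim_only", "asso_only", "no_gcn", "no_gat", "no_cl")
FUSIONS = ("dual", "C", "S", "H", "CS", "CH", "SH", "CSH", "SUM")


@dataclass
class ModelConfig:
    """Hyperparameters; defaults are the tuned values for the curated dataset."""

    t: float = 0.4
    F: int = 128
    L: int = 3
    heads: int = 2
    tau: float = 1.0
    lam: float = 0.2
    lr: float = 1e-5
    wd: float = 1e-3
    epochs: int = 100
    seed: int = 0
    variant: str = "full"
    fusion: str = "dual"
    sigma_gcn: str = "relu"
    sigma_att: str = "elu"
    leaky_slope: float = 0.2
    eps: float = 1e-7

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.fusion not in FUSIONS:
            raise ValueError(f"fusion must be one of {FUSIONS}")

    @property
    def effective_lam(self) -> float:
        return 0.0 if self.variant == "no_cl" else self.lam

    def loss_config(self) -> LossConfig:
        return LossConfig(tau=self.tau, lam=self.effective_lam, eps=self.eps)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ModelConfig":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class ModelParams:
    """Independent encoder parameter sets for the three graphs."""

    enc_asso: EncoderParams
    enc_msim: EncoderParams
    enc_dsim: EncoderParams

    def trainables(self) -> list[Tensor]:
        return (
            self.enc_asso.trainables()
            + self.enc_msim.trainables()
            + self.enc_dsim.trainables()
        )


@dataclass
class PreparedGraphs:
    """Graphs and kernels derived from the training matrix of one split."""

    A_train: np.ndarray
    asso: GraphInput
    msim: GraphInput
    dsim: GraphInput
    KM: np.ndarray
    KD: np.ndarray


@dataclass
class TrainResult:
    params: ModelParams
    log: list[dict]
    graphs: PreparedGraphs
    config: ModelConfig

    def log_to_tsv(self, path: str | os.PathLike) -> None:
        lines = ["epoch\tclassify\tcontrast\ttotal"]
        for row in self.log:
            lines.append(
                f"{row['epoch']}\t{row['classify']:.10g}"
                f"\t{row['contrast']:.10g}\t{row['total']:.10g}"
            )
        Path(path).write_text("\n".join(lines) + "\n")


def decode(Z_m: Tensor, Z_d: Tensor) -> Tensor:
    """Inner-product decoder: A' = sigmoid(Z_m @ Z_d^T), entries in (0, 1)."""
    Z_m, Z_d = as_tensor(Z_m), as_tensor(Z_d)
    if Z_m.shape[1] != Z_d.shape[1]:
        raise ValueError("embedding dimensions do not match")
    return (Z_m @ Z_d.T).sigmoid()


def prepare_graphs(ds: AssociationDataset, split: EdgeSplit,
                   cfg: ModelConfig) -> PreparedGraphs:
    """Build the three encoder inputs from the training matrix only."""
    A_train = training_matrix(ds, split).astype(np.float64)
    msim, dsim = build_similarity_networks(A_train, cfg.t)
    return PreparedGraphs(
        A_train=A_train,
        asso=association_graph(A_train, msim.kernel, dsim.kernel),
        msim=GraphInput(adjacency=msim.adjacency, features=msim.kernel),
        dsim=GraphInput(adjacency=dsim.adjacency, features=dsim.kernel),
        KM=msim.kernel,
        KD=dsim.kernel,
    )


def init_model_params(cfg: ModelConfig, n_m: int, n_d: int,
                      seed: int | None = None) -> ModelParams:
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    kwargs = dict(
        F=cfg.F, L=cfg.L, K=cfg.heads,
        sigma_gcn=cfg.sigma_gcn, sigma_att=cfg.sigma_att,
        leaky_slope=cfg.leaky_slope,
    )
    return ModelParams(
        enc_asso=init_encoder_params(d_in=n_m + n_d, rng=rng, **kwargs),
        enc_msim=init_encoder_params(d_in=n_m, rng=rng, **kwargs),
        enc_dsim=init_encoder_params(d_in=n_d, rng=rng, **kwargs),
    )


def forward(graphs: PreparedGraphs, params: ModelParams,
            cfg: ModelConfig) -> tuple[Tensor, EmbeddingViews]:
    """One forward pass; returns the score matrix and the embedding views."""
    n_m = graphs.A_train.shape[0]
    use_gcn = cfg.variant != "no_gcn"
    use_gat = cfg.variant != "no_gat"
    enc_kwargs = dict(use_gcn=use_gcn, use_gat=use_gat, fusion=cfg.fusion)

    if cfg.variant != "sim_only":
        Z_asso = encode(graphs.asso, params.enc_asso, **enc_kwargs).Z_fused
        ZA_m = Z_asso[np.arange(n_m)]
        ZA_d = Z_asso[np.arange(n_m, graphs.asso.n)]
    if cfg.variant != "asso_only":
        ZS_m = encode(graphs.msim, params.enc_msim, **enc_kwargs).Z_fused
        ZS_d = encode(graphs.dsim, params.enc_dsim, **enc_kwargs).Z_fused

    if cfg.variant == "sim_only":
        ZA_m, ZA_d = ZS_m, ZS_d
    elif cfg.variant == "asso_only":
        ZS_m, ZS_d = ZA_m, ZA_d

    views = EmbeddingViews(ZA_m=ZA_m, ZS_m=ZS_m, ZA_d=ZA_d, ZS_d=ZS_d)
    Z_m = concat([views.ZA_m, views.ZS_m], axis=1)
    Z_d = concat([views.ZA_d, views.ZS_d], axis=1)
    return decode(Z_m, Z_d), views


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 wd: float = 0.0, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, wd
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.step_count = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.step_count += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.wd:
                g = g + self.wd * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1 ** self.step_count)
            v_hat = self.v[i] / (1 - b2 ** self.step_count)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(ds: AssociationDataset, split: EdgeSplit,
          cfg: ModelConfig) -> TrainResult:
    """Fixed-epoch full-batch training on one split.

    The loss sees only train_pos/train_neg cells; the contrastive term runs
    over all nodes (it involves no labels).  Deterministic given cfg.seed.
    """
    if not split.train_pos:
        raise ValueError("split has no training positives")
    graphs = prepare_graphs(ds, split, cfg)
    params = init_model_params(cfg, ds.n_microbes, ds.n_diseases)
    opt = Adam(params.trainables(), lr=cfg.lr, wd=cfg.wd)
    loss_cfg = cfg.loss_config()

    pairs = split.train_pos + split.train_neg
    rows = np.array([p[0] for p in pairs])
    cols = np.array([p[1] for p in pairs])
    labels = np.array([1.0] * len(split.train_pos) + [0.0] * len(split.train_neg))

    log: list[dict] = []
    for epoch in range(cfg.epochs):
        opt.zero_grad()
        scores, views = forward(graphs, params, cfg)
        classify = bce_loss(scores[rows, cols], labels, eps=cfg.eps)
        contrast = contrastive_total(views, loss_cfg)
        total = classify + contrast * loss_cfg.lam
        if not np.isfinite(total.data):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        total.backward()
        opt.step()
        log.append(
            {
                "epoch": epoch,
                "classify": float(classify.data),
                "contrast": float(contrast.data),
                "total": float(total.data),
            }
        )
    return TrainResult(params=params, log=log, graphs=graphs, config=cfg)


def score_matrix(result: TrainResult) -> np.ndarray:
    """Decode the trained model's full score matrix as a plain array."""
    scores, _ = forward(result.graphs, result.params, result.config)
    return scores.data


# -- checkpointing ----------------------------------------------------------

def _flatten_params(params: ModelParams) -> dict[str, Tensor]:
    out: dict[str, Tensor] = {}
    for enc_name in ("enc_asso", "enc_msim", "enc_dsim"):
        enc: EncoderParams = getattr(params, enc_name)
        out[f"{enc_name}/W_proj"] = enc.W_proj
        for l, W in enumerate(enc.W_gcn):
            out[f"{enc_name}/W_gcn_{l}"] = W
        for l, layer in enumerate(enc.heads):
            for k, (W_att, a) in enumerate(layer):
                out[f"{enc_name}/W_att_{l}_{k}"] = W_att
                out[f"{enc_name}/a_{l}_{k}"] = a
        out[f"{enc_name}/W_cat"] = enc.W_cat
        out[f"{enc_name}/W_had"] = enc.W_had
        out[f"{enc_name}/W_sum"] = enc.W_sum
    return out


def save_checkpoint(result: TrainResult, path: str | os.PathLike) -> None:
    """Archive trained weights with a shape manifest, the config, and the
    hash of the association matrix the model was trained on."""
    from .similarity import matrix_hash

    flat = _flatten_params(result.params)
    arrays = {k.replace("/", "."): v.data for k, v in flat.items()}
    manifest = {
        "config": json.loads(result.config.to_json()),
        "dataset_hash": matrix_hash(result.graphs.A_train),
        "shapes": {k: list(v.shape) for k, v in arrays.items()},
    }
    np.savez(path, __manifest__=json.dumps(manifest), **arrays)


def load_checkpoint(path: str | os.PathLike,
                    n_m: int, n_d: int) -> tuple[ModelParams, ModelConfig, str]:
    """Restore (params, config, dataset_hash) from a checkpoint archive."""
    with np.load(path, allow_pickle=False) as archive:
        manifest = json.loads(str(archive["__manifest__"]))
        cfg = ModelConfig.from_mapping(manifest["config"])
        params = init_model_params(cfg, n_m, n_d)
        flat = _flatten_params(params)
        for key, tensor in flat.items():
            stored = archive[key.replace("/", ".")]
            if stored.shape != tensor.data.shape:
                raise ValueError(
                    f"shape mismatch for {key}: archive {stored.shape}, "
                    f"model {tensor.data.shape}"
                )
            tensor.data = stored.astype(np.float64)
    return params, cfg, manifest["dataset_hash"]
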