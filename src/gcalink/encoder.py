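"""The graph convolution + attention (GCAT) feature encoder.

One encoder layer is a GCN propagation (symmetric-normalized adjacency with
self-loops) followed by multi-head graph attention over first-order
neighborhoods; the attention output of layer ``l`` feeds the GCN of layer
``l+1``.  The per-layer attention outputs ``Z^(1)..Z^(L)`` are combined by a
dual-fusion module: a linear map of their concatenation plus a linear map of
their elementwise (Hadamard) product.  Ablation switches let callers drop the
GCN step, drop the attention step, or swap the fusion rule for any
combination of concatenation / sum / Hadamard terms.

Three graphs are encoded with independent parameter sets: the bipartite
association graph (block adjacency ``[0 A; A^T 0]``, features
``blockdiag(KM, KD)``), the microbe similarity graph (adjacency ``MA``,
features ``KM``) and the disease similarity graph (``DA``, ``KD``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concat

__all__ = [
    "GraphInput",
    "EncoderParams",
    "LayerOutputs",
    "normalized_adjacency",
    "gcn_propagate",
    "attention_coefficients",
    "gat_aggregate",
    "dual_fuse",
    "fuse",
    "encode",
    "init_encoder_params",
    "association_graph",
]

_NEG_INF = -1e30

ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "elu": lambda t: t.elu(),
    "identity": lambda t: t,
    "sigmoid": lambda t: t.sigmoid(),
}


@dataclass
class GraphInput:
    """A homogeneous graph for the encoder: binary adjacency + dense features."""

    adjacency: np.ndarray
    features: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=np.float64)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(A).any():
            raise ValueError("adjacency diagonal must be zero (self-loops are added explicitly)")
        self.adjacency = A
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape[0] != A.shape[0]:
            raise ValueError("feature rows must match node count")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class EncoderParams:
    """Trainable weights of one GCAT encoder.

    ``heads[l][k]`` holds ``(W_att, a)`` for head ``k`` of layer ``l`` with
    ``a`` of length 2F.  ``W_cat``/``W_had``/``W_sum`` are the fusion maps for
    the concatenation, Hadamard, and sum terms.
    """

    W_proj: Tensor
    W_gcn: list[Tensor]
    heads: list[list[tuple[Tensor, Tensor]]]
    W_cat: Tensor
    W_had: Tensor
    W_sum: Tensor
    sigma_gcn: str = "relu"
    sigma_att: str = "elu"
    leaky_slope: float = 0.2

    def trainables(self) -> list[Tensor]:
        out = [self.W_proj, *self.W_gcn, self.W_cat, self.W_had, self.W_sum]
        for layer in self.heads:
            for W_att, a in layer:
                out.extend([W_att, a])
        return out

    @property
    def n_layers(self) -> int:
        return len(self.W_gcn)


@dataclass
class LayerOutputs:
    """Per-layer attention outputs and their fused combination."""

    Z_list: list[Tensor]
    Z_fused: Tensor


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def init_encoder_params(
    d_in: int,
    F: int,
    L: int,
    K: int,
    rng: np.random.Generator,
    sigma_gcn: str = "relu",
    sigma_att: str = "elu",
    leaky_slope: float = 0.2,
) -> EncoderParams:
    """Glorot-uniform initialization of all encoder weights."""
    return EncoderParams(
        W_proj=_glorot(rng, (d_in, F)),
        W_gcn=[_glorot(rng, (F, F)) for _ in range(L)],
        heads=[
            [(_glorot(rng, (F, F)), _glorot(rng, (2 * F,))) for _ in range(K)]
            for _ in range(L)
        ],
        W_cat=_glorot(rng, (L * F, F)),
        W_had=_glorot(rng, (F, F)),
        W_sum=_glorot(rng, (F, F)),
        sigma_gcn=sigma_gcn,
        sigma_att=sigma_att,
        leaky_slope=leaky_slope,
    )


def normalized_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization D~^(-1/2) (G + I) D~^(-1/2).

    Self-loops guarantee every degree is >= 1, so isolated nodes reduce to a
    pure self-loop of weight 1.
    """
    G = np.asarray(adjacency, dtype=np.float64)
    if G.ndim != 2 or G.shape[0] != G.shape[1] or not np.array_equal(G, G.T):
        raise ValueError("adjacency must be square and symmetric")
    Gt = G + np.eye(G.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(Gt.sum(axis=1))
    return Gt * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_propagate(norm_adj: np.ndarray, H: Tensor, W: Tensor,
                  sigma_gcn: str = "relu") -> Tensor:
    """One graph-convolution step: sigma(norm_adj @ H @ W)."""
    out = as_tensor(norm_adj) @ H @ W
    if not np.isfinite(out.data).all():
        raise FloatingPointError("non-finite values after GCN propagation")
    return ACTIVATIONS[sigma_gcn](out)


def attention_coefficients(
    adjacency: np.ndarray,
    H: Tensor,
    W_att: Tensor,
    a: Tensor,
    slope: float = 0.2,
) -> Tensor:
    """Attention matrix alpha: softmax over N_i plus the node itself.

    The raw score for edge (i, j) is ``LeakyReLU(a . [W h_i || W h_j])``;
    splitting ``a`` into its source and target halves turns the score matrix
    into an outer sum, and non-edges are masked out before the row softmax.
    Self-inclusion makes every neighborhood non-empty.
    """
    n = adjacency.shape[0]
    F = W_att.shape[1]
    Wh = H @ W_att
    a_src = a[np.arange(F)]
    a_dst = a[np.arange(F, 2 * F)]
    # score_ij = leaky(f1_i + f2_j): the two halves of a give column vectors
    f1 = (Wh * a_src).sum(axis=1, keepdims=True)          # n x 1
    f2 = (Wh * a_dst).sum(axis=1, keepdims=True)          # n x 1
    E = (f1 + f2.T).leaky_relu(slope)                     # n x n raw scores
    support = np.asarray(adjacency, dtype=np.float64) + np.eye(n)
    support = (support > 0).astype(np.float64)
    # numerically stable masked softmax; the row max is a detached constant
    masked = E.data * support + _NEG_INF * (1.0 - support)
    row_max = masked.max(axis=1, keepdims=True)
    # clip keeps off-support entries (which can sit above the support max)
    # from overflowing exp; on the support the shift is already <= 0
    expE = (E - row_max).clip(-60.0, 0.0).exp() * support
    alpha = expE / expE.sum(axis=1, keepdims=True)
    return alpha


def gat_aggregate(
    adjacency: np.ndarray,
    H: Tensor,
    heads: list[tuple[Tensor, Tensor]],
    sigma_att: str = "elu",
    slope: float = 0.2,
) -> Tensor:
    """Multi-head attention aggregation, heads averaged then activated."""
    if not heads:
        raise ValueError("need at least one attention head")
    total = None
    for W_att, a in heads:
        alpha = attention_coefficients(adjacency, H, W_att, a, slope)
        out = alpha @ (H @ W_att)
        total = out if total is None else total + out
    avg = total * (1.0 / len(heads))
    return ACTIVATIONS[sigma_att](avg)


def dual_fuse(Z_list: list[Tensor], W_cat: Tensor, W_had: Tensor) -> Tensor:
    """Concatenation term plus Hadamard-product term (the default fusion)."""
    return fuse(Z_list, "CH", W_cat=W_cat, W_had=W_had)


def fuse(
    Z_list: list[Tensor],
    mode: str,
    W_cat: Tensor | None = None,
    W_had: Tensor | None = None,
    W_sum: Tensor | None = None,
) -> Tensor:
    """Combine per-layer outputs with any subset of {C, S, H} terms.

    ``C``: concat(Z_list) @ W_cat; ``S``: (sum Z) @ W_sum;
    ``H``: (hadamard-product Z) @ W_had.  ``mode`` "dual" is an alias for
    "CH".  ``SUM`` (plain summation, no weight) is the fusion-ablation
    baseline that replaces the module with simple addition.
    """
    mode = "CH" if mode == "dual" else mode
    if mode == "SUM":
        out = Z_list[0]
        for Z in Z_list[1:]:
            out = out + Z
        return out
    if not mode or any(c not in "CSH" for c in mode):
        raise ValueError(f"unknown fusion mode {mode!r}")
    terms = []
    if "C" in mode:
        terms.append(concat(Z_list, axis=1) @ W_cat)
    if "S" in mode:
        s = Z_list[0]
        for Z in Z_list[1:]:
            s = s + Z
        terms.append(s @ W_sum)
    if "H" in mode:
        h = Z_list[0]
        for Z in Z_list[1:]:
            h = h * Z
        terms.append(h @ W_had)
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out


def encode(
    graph: GraphInput,
    params: EncoderParams,
    use_gcn: bool = True,
    use_gat: bool = True,
    fusion: str = "dual",
) -> LayerOutputs:
    """Run the full encoder: projection, L stacked layers, dual fusion.

    With ``use_gat=False`` the per-layer output is the GCN output; with
    ``use_gcn=False`` attention runs directly on the previous layer's
    features.  At least one of the two mechanisms must stay on.
    """
    if not (use_gcn or use_gat):
        raise ValueError("cannot disable both GCN and GAT")
    norm_adj = normalized_adjacency(graph.adjacency)
    H = as_tensor(graph.features) @ params.W_proj
    Z_list: list[Tensor] = []
    for l in range(params.n_layers):
        try:
            if use_gcn:
                H = gcn_propagate(norm_adj, H, params.W_gcn[l], params.sigma_gcn)
            if use_gat:
                H = gat_aggregate(
                    graph.adjacency, H, params.heads[l],
                    params.sigma_att, params.leaky_slope,
                )
        except FloatingPointError as exc:
            raise FloatingPointError(f"layer {l + 1}: {exc}") from exc
        Z_list.append(H)
    Z_fused = fuse(Z_list, fusion, params.W_cat, params.W_had, params.W_sum)
    return LayerOutputs(Z_list=Z_list, Z_fused=Z_fused)


def association_graph(
    A_train: np.ndarray, KM: np.ndarray, KD: np.ndarray
) -> GraphInput:
    """Bipartite graph [0 A; A^T 0] with blockdiag(KM, KD) initial features."""
    A = np.asarray(A_train, dtype=np.float64)
    n_m, n_d = A.shape
    G = np.zeros((n_m + n_d, n_m + n_d))
    G[:n_m, n_m:] = A
    G[n_m:, :n_m] = A.T
    H0 = np.zeros((n_m + n_d, n_m + n_d))
    H0[:n_m, :n_m] = KM
    H0[n_m:, n_m:] = KD
    return GraphInput(adjacency=G, features=H0)
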