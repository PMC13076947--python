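"""Graph transformer over the typed interaction tensor: soft meta-path
learning, graph convolution, and channel attention pooling.

The three typed adjacencies of a cell line are mixed, per channel, into a
convex combination by a softmax over edge types (a 1x1 convolution along the
type axis).  Chaining L+1 such mixtures by degree-normalized matrix products
composes soft meta-paths of length up to L+1; a graph convolution over the
composed adjacency projects drug fingerprints into per-channel embeddings,
and attention pooling over channels yields the local drug representation
``Z_r``.  Concatenating ``Z_r`` with the Tucker mode-1 factor ``U_r`` gives
the per-drug global-local interaction feature.

Every function here accepts either plain ``ndarray`` parameters (for oracles
and inspection) or autodiff :class:`~synergraph.autodiff.Tensor` parameters
(during training); the arithmetic is shared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as F
from .autodiff import Tensor
from .graphs import InteractionTensor
from .nn import glorot


def _tensor_values(tensor) -> np.ndarray:
    if isinstance(tensor, InteractionTensor):
        return tensor.values
    return np.asarray(tensor, dtype=float)


def _is_param(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def edge_type_conv(tensor, W):
    """Mix the three typed adjacency slices into C channel matrices.

    ``softmax(W)`` is taken over the edge-type axis (per channel), so every
    channel matrix is a convex combination of the three slices.

    Returns an (n, n, C) array for ndarray ``W``; a list of C per-channel
    matrices when ``W`` is an autodiff Tensor.
    """
    A = _tensor_values(tensor)
    if A.ndim != 3 or A.shape[2] != 3:
        raise ValueError(f"expected (n, n, 3) tensor, got {A.shape}")
    W_shape = W.shape
    if W_shape[0] != 3:
        raise ValueError(f"edge-type weights must be (3, C), got {W_shape}")
    sm = F.softmax(W, axis=0)
    channels = []
    for c in range(W_shape[1]):
        q = sm[0, c] * A[:, :, 0]
        for t in (1, 2):
            q = q + sm[t, c] * A[:, :, t]
        channels.append(q)
    if _is_param(W):
        return channels
    return np.stack(channels, axis=2)


def normalize_rows(M):
    """Row-degree normalization ``D^{-1} M`` with absolute-value degrees
    (robust to score-weighted edges); zero rows keep degree 1 (no-op)."""
    if isinstance(M, Tensor):
        rowsum = M.abs().sum(axis=1, keepdims=True)
        zero = (rowsum.data == 0).astype(float)
        return M / (rowsum + zero)
    rowsum = np.abs(M).sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return M / rowsum


def _channels(Q, C):
    """Per-channel views of an edge_type_conv result (array or list)."""
    if isinstance(Q, list):
        return Q
    return [Q[:, :, c] for c in range(C)]


def compose_adjacency(tensor, weights):
    """Recursively composed meta-path adjacency (per channel).

    ``weights`` holds L+1 edge-type weight matrices (3 x C).  Layer 1 is the
    normalized product of the first two channel mixtures; each further layer
    multiplies by the next mixture and renormalizes.  The degree normalizer is
    the row-degree matrix of the unnormalized product being normalized.

    Returns (n, n, C) for ndarray weights, else a list of C channel matrices.
    """
    if len(weights) < 2:
        raise ValueError(f"need at least 2 (= L+1) weight matrices, got {len(weights)}")
    C = weights[0].shape[1]
    Q_layers = [_channels(edge_type_conv(tensor, W), C) for W in weights]
    out = []
    for c in range(C):
        a = normalize_rows(Q_layers[0][c] @ Q_layers[1][c])
        for layer in Q_layers[2:]:
            a = normalize_rows(a @ layer[c])
        out.append(a)
    if _is_param(*weights):
        return out
    return np.stack(out, axis=2)


def gtn_embed(composite, X, W_proj):
    """Graph convolution on each composed channel: with self-loops added,
    ``Z_c = relu(D~^{-1} (A_c + I) X W)``.

    Returns (n, d, C) for ndarray inputs, else a list of C (n, d) Tensors.
    """
    C = len(composite) if isinstance(composite, list) else composite.shape[2]
    chans = _channels(composite, C)
    n = chans[0].shape[0]
    eye = np.eye(n)
    XW = X @ W_proj
    out = []
    for A_c in chans:
        if isinstance(A_c, Tensor):
            if not np.isfinite(A_c.data).all():
                raise ValueError("non-finite composite adjacency")
        elif not np.isfinite(A_c).all():
            raise ValueError("non-finite composite adjacency")
        A_tilde = A_c + eye
        deg = A_tilde.abs() if isinstance(A_tilde, Tensor) else np.abs(A_tilde)
        deg = deg.sum(axis=1, keepdims=True)
        out.append(F.relu((A_tilde @ XW) / deg))
    if _is_param(*chans, X, W_proj):
        return out
    return np.stack(out, axis=2)


def channel_attention_pool(embeddings, q, P, b):
    """Attention pooling over channels.

    Per channel, the score is the graph-average of ``q^T tanh(z_i P + b)``
    over drug rows; softmax over channels gives the mixture weights beta and
    the pooled representation ``Z = sum_c beta_c Z_c``.

    Returns ``(a, beta, Z)``.
    """
    C = len(embeddings) if isinstance(embeddings, list) else embeddings.shape[2]
    chans = _channels(embeddings, C)
    scores = []
    for Z_c in chans:
        s = F.tanh(Z_c @ P + b) @ q  # (n,)
        scores.append(s.mean() if isinstance(s, Tensor) else float(np.mean(s)))
    if _is_param(*chans, q, P, b):
        a = F.concat([s.reshape(1) if isinstance(s, Tensor) else Tensor([s])
                      for s in scores], axis=0)
    else:
        a = np.asarray(scores)
    beta = F.softmax(a, axis=0)
    Z = beta[0] * chans[0]
    for c in range(1, C):
        Z = Z + beta[c] * chans[c]
    return a, beta, Z


def fuse_global_local(U, Z):
    """Concatenate global (Tucker) and local (graph) drug features row-wise:
    row i is ``[U[i, :]; Z[i, :]]``."""
    if U.shape[0] != Z.shape[0]:
        raise ValueError(f"row-count mismatch: U has {U.shape[0]}, Z has {Z.shape[0]}")
    return F.concat([U, Z], axis=1)


@dataclass
class GtnParams:
    """Learnable state of one cell line's graph transformer."""

    edge_conv_weights: list  # L+1 matrices, each (3, C)
    projection: object       # (m, d)
    attention_query: object  # (h,)
    attention_proj: object   # (d, h)
    attention_bias: object   # (h,)
    C: int
    L: int
    d: int
    h: int

    @classmethod
    def init(cls, rng: np.random.Generator, m: int, C: int = 2, L: int = 1,
             d: int = 32, h: int | None = None, trainable: bool = True):
        """Seeded initialization: near-zero edge-type weights (initial softmax
        ~ uniform over types), fan-average scaling elsewhere."""
        h = d if h is None else h
        t = lambda a: Tensor(a, requires_grad=trainable)
        return cls(
            edge_conv_weights=[t(rng.normal(0.0, 0.01, size=(3, C)))
                               for _ in range(L + 1)],
            projection=t(glorot(rng, (m, d))),
            attention_query=t(rng.normal(0.0, 1.0 / np.sqrt(h), size=h)),
            attention_proj=t(glorot(rng, (d, h))),
            attention_bias=t(np.zeros(h)),
            C=C, L=L, d=d, h=h,
        )

    def parameters(self) -> list[Tensor]:
        return [*self.edge_conv_weights, self.projection, self.attention_query,
                self.attention_proj, self.attention_bias]


@dataclass
class GtnOutput:
    composite: object        # per-channel composed adjacency
    per_channel: object      # per-channel embeddings
    channel_scores: object   # a (C,)
    channel_weights: object  # beta (C,)
    pooled: object           # Z (n, d)


def gtn_forward(tensor, X, params: GtnParams) -> GtnOutput:
    """Full local-feature pipeline for one cell line."""
    composite = compose_adjacency(tensor, params.edge_conv_weights)
    per_channel = gtn_embed(composite, X, params.projection)
    a, beta, Z = channel_attention_pool(
        per_channel, params.attention_query, params.attention_proj,
        params.attention_bias)
    return GtnOutput(composite, per_channel, a, beta, Z)
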