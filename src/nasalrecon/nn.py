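"""NumPy backend for the mesh autoencoder: layers, backprop, Adam.

All layer functions operate on batched per-vertex features of shape
(B, N, F).  Because every mesh in a batch shares one template topology,
a sparse graph operator is applied to the whole batch with a single
sparse-dense product.  Forward passes return explicit caches; backward
passes consume them and return parameter gradients, which keeps the
whole model differentiable without an autodiff framework.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp

__all__ = ["ModelConfig", "GraphOps", "init_params", "encoder_forward",
           "encoder_backward", "decoder_forward", "decoder_backward", "Adam"]


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    latent_dim     : D, dimensionality of the latent code z
    widths         : feature widths of the three conv stages
    fusion_dim     : width of each branch head before fusion
    negative_slope : leaky-ReLU slope for x < 0
    seed           : weight-initialization seed
    """

    latent_dim: int = 256
    widths: tuple = (16, 32, 64)
    fusion_dim: int = 64
    negative_slope: float = 0.01
    seed: int = 0

    @property
    def n_levels(self) -> int:
        return len(self.widths) + 1


class GraphOps:
    """Sparse operators derived from a FaceGraph.

    A[l] : normalized adjacency at level l
    P[l] : average-pool  level l -> l+1   (rows sum to 1)
    U[l] : copy-up       level l+1 -> l   (binary assignment)
    """

    def __init__(self, graph) -> None:
        self.A = [sp.csr_matrix(a) for a in graph.level_adjacency]
        self.U = []
        self.P = []
        sizes = graph.level_sizes
        for l, assign in enumerate(graph.pool_maps):
            nf, nc = sizes[l], sizes[l + 1]
            U = sp.coo_matrix(
                (np.ones(nf), (np.arange(nf), assign)), shape=(nf, nc)
            ).tocsr()
            counts = np.asarray(U.sum(axis=0)).ravel()
            P = sp.diags(1.0 / counts) @ U.T
            self.U.append(U)
            self.P.append(sp.csr_matrix(P))
        self.sizes = sizes


def spmm(A: sp.csr_matrix, X: np.ndarray) -> np.ndarray:
    """(n_out, n_in) sparse @ (B, n_in, F) -> (B, n_out, F)."""
    B, N, F = X.shape
    Y = A @ X.transpose(1, 0, 2).reshape(N, B * F)
    return Y.reshape(A.shape[0], B, F).transpose(1, 0, 2)


# -- elementary layers -------------------------------------------------------


def graph_conv(A, X, W, b):
    """Y = A (X W) + b; first-order neighborhood propagation."""
    return spmm(A, X @ W) + b


def graph_conv_bwd(A, X, W, dY):
    dXW = spmm(A.T.tocsr(), dY)  # A is symmetric, kept explicit for clarity
    F, Fo = W.shape
    dW = X.reshape(-1, F).T @ dXW.reshape(-1, Fo)
    db = dY.sum(axis=(0, 1))
    dX = dXW @ W.T
    return dX, dW, db


def leaky_relu(X, slope):
    return np.where(X > 0, X, slope * X)


def leaky_relu_bwd(X, slope, dY):
    return np.where(X > 0, dY, slope * dY)


# -- parameter initialization ------------------------------------------------


def _glorot(rng, fan_in, fan_out):
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / (fan_in + fan_out))


def init_params(config: ModelConfig, ops: GraphOps) -> dict:
    """Initialize all encoder/decoder weights (seeded Glorot)."""
    rng = np.random.default_rng(config.seed)
    w0, w1, w2 = config.widths
    fd, D = config.fusion_dim, config.latent_dim
    n_coarse = ops.sizes[-1]
    p = {}
    # encoder, global branch: conv/pool down the hierarchy
    p["enc_gW0"], p["enc_gb0"] = _glorot(rng, 3, w0), np.zeros(w0)
    p["enc_gW1"], p["enc_gb1"] = _glorot(rng, w0, w1), np.zeros(w1)
    p["enc_gW2"], p["enc_gb2"] = _glorot(rng, w1, w2), np.zeros(w2)
    p["enc_gLW"], p["enc_gLb"] = _glorot(rng, n_coarse * w2, fd), np.zeros(fd)
    # encoder, local branch: convs at full resolution
    p["enc_lW0"], p["enc_lb0"] = _glorot(rng, 3, w0), np.zeros(w0)
    p["enc_lW1"], p["enc_lb1"] = _glorot(rng, w0, w1), np.zeros(w1)
    p["enc_lW2"], p["enc_lb2"] = _glorot(rng, w1, w2), np.zeros(w2)
    p["enc_lLW"], p["enc_lLb"] = _glorot(rng, w2, fd), np.zeros(fd)
    # fusion
    p["fuse_W"], p["fuse_b"] = _glorot(rng, 2 * fd, D), np.zeros(D)
    # decoder: latent -> coarsest features, conv/unpool back up
    p["dec_LW"] = _glorot(rng, D, n_coarse * w2)
    p["dec_Lb"] = np.zeros(n_coarse * w2)
    p["dec_W2"], p["dec_b2"] = _glorot(rng, w2, w1), np.zeros(w1)
    p["dec_W1"], p["dec_b1"] = _glorot(rng, w1, w0), np.zeros(w0)
    p["dec_W0"], p["dec_b0"] = _glorot(rng, w0, 3) * 0.1, np.zeros(3)
    return p


# -- encoder -----------------------------------------------------------------


def encoder_forward(p: dict, ops: GraphOps, config: ModelConfig, X: np.ndarray):
    """X (B, N, 3) centered coordinates -> Z (B, D), cache."""
    s = config.negative_slope
    c = {"X": X}
    # global branch: [conv, act, pool] x3, mean, linear
    h = graph_conv(ops.A[0], X, p["enc_gW0"], p["enc_gb0"]); c["g_pre0"] = h
    h = leaky_relu(h, s); c["g_in1"] = h
    h = spmm(ops.P[0], h); c["g_pool1"] = h
    h = graph_conv(ops.A[1], h, p["enc_gW1"], p["enc_gb1"]); c["g_pre1"] = h
    h = leaky_relu(h, s); c["g_in2"] = h
    h = spmm(ops.P[1], h); c["g_pool2"] = h
    h = graph_conv(ops.A[2], h, p["enc_gW2"], p["enc_gb2"]); c["g_pre2"] = h
    h = leaky_relu(h, s); c["g_in3"] = h
    h = spmm(ops.P[2], h); c["g_pool3"] = h
    g = h.reshape(h.shape[0], -1); c["g_feat"] = g  # coarsest-level features, flattened
    g = g @ p["enc_gLW"] + p["enc_gLb"]
    # local branch: [conv, act] x3 at level 0, mean, linear
    h = graph_conv(ops.A[0], X, p["enc_lW0"], p["enc_lb0"]); c["l_pre0"] = h
    h = leaky_relu(h, s); c["l_in1"] = h
    h = graph_conv(ops.A[0], h, p["enc_lW1"], p["enc_lb1"]); c["l_pre1"] = h
    h = leaky_relu(h, s); c["l_in2"] = h
    h = graph_conv(ops.A[0], h, p["enc_lW2"], p["enc_lb2"]); c["l_pre2"] = h
    h = leaky_relu(h, s); c["l_act2"] = h
    l = h.mean(axis=1); c["l_feat"] = l
    l = l @ p["enc_lLW"] + p["enc_lLb"]
    # fusion: concatenate branch heads, one linear map to the latent
    fused = np.concatenate([g, l], axis=1); c["fused"] = fused
    Z = fused @ p["fuse_W"] + p["fuse_b"]
    return Z, c


def encoder_backward(p: dict, ops: GraphOps, config: ModelConfig, c: dict, dZ: np.ndarray):
    s = config.negative_slope
    g = {}
    fd = config.fusion_dim
    g["fuse_W"] = c["fused"].T @ dZ
    g["fuse_b"] = dZ.sum(axis=0)
    dfused = dZ @ p["fuse_W"].T
    dg, dl = dfused[:, :fd], dfused[:, fd:]

    # global head
    g["enc_gLW"] = c["g_feat"].T @ dg
    g["enc_gLb"] = dg.sum(axis=0)
    dgf = dg @ p["enc_gLW"].T
    dh = dgf.reshape(c["g_pool3"].shape)
    dh = spmm(ops.P[2].T.tocsr(), dh)
    dh = leaky_relu_bwd(c["g_pre2"], s, dh)
    dh, g["enc_gW2"], g["enc_gb2"] = graph_conv_bwd(ops.A[2], c["g_pool2"], p["enc_gW2"], dh)
    dh = spmm(ops.P[1].T.tocsr(), dh)
    dh = leaky_relu_bwd(c["g_pre1"], s, dh)
    dh, g["enc_gW1"], g["enc_gb1"] = graph_conv_bwd(ops.A[1], c["g_pool1"], p["enc_gW1"], dh)
    dh = spmm(ops.P[0].T.tocsr(), dh)
    dh = leaky_relu_bwd(c["g_pre0"], s, dh)
    _, g["enc_gW0"], g["enc_gb0"] = graph_conv_bwd(ops.A[0], c["X"], p["enc_gW0"], dh)

    # local head
    g["enc_lLW"] = c["l_feat"].T @ dl
    g["enc_lLb"] = dl.sum(axis=0)
    dlf = dl @ p["enc_lLW"].T
    n0 = ops.sizes[0]
    dh = np.repeat(dlf[:, None, :], n0, axis=1) / n0
    dh = leaky_relu_bwd(c["l_pre2"], s, dh)
    dh, g["enc_lW2"], g["enc_lb2"] = graph_conv_bwd(ops.A[0], c["l_in2"], p["enc_lW2"], dh)
    dh = leaky_relu_bwd(c["l_pre1"], s, dh)
    dh, g["enc_lW1"], g["enc_lb1"] = graph_conv_bwd(ops.A[0], c["l_in1"], p["enc_lW1"], dh)
    dh = leaky_relu_bwd(c["l_pre0"], s, dh)
    _, g["enc_lW0"], g["enc_lb0"] = graph_conv_bwd(ops.A[0], c["X"], p["enc_lW0"], dh)
    return g


# -- decoder -----------------------------------------------------------------


def decoder_forward(p: dict, ops: GraphOps, config: ModelConfig, Z: np.ndarray):
    """Z (B, D) -> centered vertex coordinates (B, N, 3), cache."""
    s = config.negative_slope
    B = Z.shape[0]
    w0, w1, w2 = config.widths
    n3 = ops.sizes[3]
    c = {"Z": Z}
    h = (Z @ p["dec_LW"] + p["dec_Lb"]).reshape(B, n3, w2)
    h = spmm(ops.U[2], h); c["in2"] = h
    h = graph_conv(ops.A[2], h, p["dec_W2"], p["dec_b2"]); c["pre2"] = h
    h = leaky_relu(h, s)
    h = spmm(ops.U[1], h); c["in1"] = h
    h = graph_conv(ops.A[1], h, p["dec_W1"], p["dec_b1"]); c["pre1"] = h
    h = leaky_relu(h, s)
    h = spmm(ops.U[0], h); c["in0"] = h
    out = graph_conv(ops.A[0], h, p["dec_W0"], p["dec_b0"])
    return out, c


def decoder_backward(p: dict, ops: GraphOps, config: ModelConfig, c: dict, dOut: np.ndarray):
    """Returns (param gradients, dZ)."""
    s = config.negative_slope
    g = {}
    dh, g["dec_W0"], g["dec_b0"] = graph_conv_bwd(ops.A[0], c["in0"], p["dec_W0"], dOut)
    dh = spmm(ops.U[0].T.tocsr(), dh)
    dh = leaky_relu_bwd(c["pre1"], s, dh)
    dh, g["dec_W1"], g["dec_b1"] = graph_conv_bwd(ops.A[1], c["in1"], p["dec_W1"], dh)
    dh = spmm(ops.U[1].T.tocsr(), dh)
    dh = leaky_relu_bwd(c["pre2"], s, dh)
    dh, g["dec_W2"], g["dec_b2"] = graph_conv_bwd(ops.A[2], c["in2"], p["dec_W2"], dh)
    dh = spmm(ops.U[2].T.tocsr(), dh)
    B = dh.shape[0]
    dflat = dh.reshape(B, -1)
    g["dec_LW"] = c["Z"].T @ dflat
    g["dec_Lb"] = dflat.sum(axis=0)
    dZ = dflat @ p["dec_LW"].T
    return g, dZ


# -- optimizer ---------------------------------------------------------------


class Adam:
    """Adaptive-moment gradient descent over a dict of arrays."""

    def __init__(self, params: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, gk in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gk
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gk**2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] = params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
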