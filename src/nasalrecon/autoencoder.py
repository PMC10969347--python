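"""The dual-branch graph-convolutional face autoencoder.

The encoder extracts global features (three conv/pool stages down the
graph hierarchy) and local features (three convs at full resolution),
fuses them, and maps to a D-dimensional latent code z (default D = 256).
The decoder maps z back to per-vertex coordinates on the template
topology.  Training is unsupervised — each face is its own target —
minimizing

    L = L_recon + lambda * L_reg,

where L_recon is the mean over vertices of the squared Euclidean
distance between corresponding vertices and L_reg = (||z|| - 1)^2 is a
spherical regularizer that draws latent codes toward the unit
hypersphere (default lambda = 0.01, Adam with initial learning rate
0.001).  Coordinates are centered on the training-mean face internally;
losses are unaffected since they act on differences.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import nn
from .mesh_core import FaceGraph, MeshTopologyError, StructuredMesh, build_face_graph

__all__ = [
    "ModelParams",
    "TrainConfig",
    "split_dataset",
    "encode",
    "decode",
    "recon_loss",
    "reg_loss",
    "total_loss",
    "init_model",
    "train",
    "test_mse",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass
class ModelParams:
    """Trained (or initialized) model state.

    weights      : all encoder/decoder arrays
    ref_vertices : (N, 3) reference face subtracted from inputs / added to
                   decoder outputs (the training-mean face)
    template_faces, topology_id : the shared mesh topology the model is
                   bound to; decoded meshes are emitted on it
    """

    config: nn.ModelConfig
    weights: dict
    ref_vertices: np.ndarray
    template_faces: np.ndarray
    topology_id: str

    @property
    def latent_dim(self) -> int:
        return self.config.latent_dim

    def copy_weights(self) -> dict:
        return {k: v.copy() for k, v in self.weights.items()}


@dataclasses.dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the model's selection:
    lambda = 0.01, Adam at initial learning rate 0.001)."""

    lambda_reg: float = 0.01
    learning_rate: float = 0.001
    epochs: int = 500
    batch_size: int = 8
    split_ratio: tuple = (17, 2, 1)
    seed: int = 0
    patience: int = 50  # early stop when validation loss stops improving
    lr_patience: int = 20  # halve the learning rate on validation plateau
    lr_factor: float = 0.5
    model_config: nn.ModelConfig | None = None  # architecture; None = defaults

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


# ---------------------------------------------------------------------------
# dataset split
# ---------------------------------------------------------------------------


def split_dataset(n: int, ratio: tuple = (17, 2, 1), seed: int = 0):
    """Disjoint, exhaustive train/validation/test index sets.

    Sizes are round(n * r / sum(r)) with any remainder assigned to the
    training set; the assignment itself is a seeded shuffle.
    """
    if n < 20:
        raise ValueError("need at least 20 cases to split")
    r = np.asarray(ratio, dtype=float)
    if len(r) != 3 or np.any(r <= 0):
        raise ValueError("ratio must be three positive numbers")
    sizes = np.round(n * r / r.sum()).astype(int)
    sizes[0] = n - sizes[1] - sizes[2]
    if np.any(sizes <= 0):
        raise ValueError(f"split {tuple(sizes)} has an empty part for n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    train_ids = np.sort(perm[: sizes[0]])
    val_ids = np.sort(perm[sizes[0] : sizes[0] + sizes[1]])
    test_ids = np.sort(perm[sizes[0] + sizes[1] :])
    return train_ids, val_ids, test_ids


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _vertices(x) -> np.ndarray:
    return x.vertices if isinstance(x, StructuredMesh) else np.asarray(x, dtype=float)


def recon_loss(x, x_hat) -> float:
    """Mean over vertices of the squared distance between corresponding
    vertices (the reconstruction MSE); 0 iff the meshes coincide."""
    xv, hv = _vertices(x), _vertices(x_hat)
    if xv.shape != hv.shape:
        raise MeshTopologyError(f"topology mismatch: {xv.shape} vs {hv.shape}")
    if isinstance(x, StructuredMesh) and isinstance(x_hat, StructuredMesh):
        if x.topology_id != x_hat.topology_id:
            raise MeshTopologyError(
                f"topology mismatch: {x.topology_id!r} vs {x_hat.topology_id!r}"
            )
    d = xv - hv
    return float(np.mean(np.einsum("ij,ij->i", d, d)))


def reg_loss(z: np.ndarray) -> float:
    """Spherical latent regularizer (||z||_2 - 1)^2."""
    return float((np.linalg.norm(np.asarray(z, dtype=float)) - 1.0) ** 2)


def total_loss(x, x_hat, z, lambda_reg: float) -> float:
    return recon_loss(x, x_hat) + lambda_reg * reg_loss(z)


def reg_loss_grad(z: np.ndarray) -> np.ndarray:
    """d/dz (||z|| - 1)^2 = 2 (||z|| - 1) z / ||z|| (0 at the origin)."""
    z = np.asarray(z, dtype=float)
    nrm = np.linalg.norm(z)
    if nrm < 1e-12:
        return np.zeros_like(z)
    return 2.0 * (nrm - 1.0) * z / nrm


# ---------------------------------------------------------------------------
# model surface
# ---------------------------------------------------------------------------


def _ops(graph: FaceGraph) -> nn.GraphOps:
    ops = getattr(graph, "_nn_ops", None)
    if ops is None:
        ops = nn.GraphOps(graph)
        graph._nn_ops = ops
    return ops


def init_model(template: StructuredMesh, graph: FaceGraph, config: nn.ModelConfig) -> ModelParams:
    if graph.level_sizes[0] != template.n_vertices:
        raise MeshTopologyError("graph level 0 does not match the template")
    weights = nn.init_params(config, _ops(graph))
    return ModelParams(
        config=config,
        weights=weights,
        ref_vertices=template.vertices.copy(),
        template_faces=template.faces.copy(),
        topology_id=template.topology_id,
    )


def _check_input(params: ModelParams, graph: FaceGraph, x) -> np.ndarray:
    xv = _vertices(x)
    if xv.shape != params.ref_vertices.shape:
        raise MeshTopologyError(
            f"input has {xv.shape[0]} vertices, model expects {params.ref_vertices.shape[0]}"
        )
    if isinstance(x, StructuredMesh) and x.topology_id != params.topology_id:
        raise MeshTopologyError(
            f"input topology {x.topology_id!r} does not match model {params.topology_id!r}"
        )
    return xv


def encode(params: ModelParams, graph: FaceGraph, x) -> np.ndarray:
    """Encode one face to its D-dimensional latent code."""
    xv = _check_input(params, graph, x)
    X = (xv - params.ref_vertices)[None]
    Z, _ = nn.encoder_forward(params.weights, _ops(graph), params.config, X)
    return Z[0]


def decode(params: ModelParams, graph: FaceGraph, z: np.ndarray) -> StructuredMesh:
    """Decode a latent code to a face mesh on the template topology."""
    z = np.asarray(z, dtype=float).reshape(-1)
    if z.shape[0] != params.latent_dim:
        raise ValueError(f"latent has length {z.shape[0]}, model expects {params.latent_dim}")
    out, _ = nn.decoder_forward(params.weights, _ops(graph), params.config, z[None])
    return StructuredMesh(
        out[0] + params.ref_vertices, params.template_faces, params.topology_id
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _forward_losses(weights, ops, config, X, lambda_reg):
    Z, ec = nn.encoder_forward(weights, ops, config, X)
    Y, dc = nn.decoder_forward(weights, ops, config, Z)
    diff = Y - X
    rec = float(np.mean(np.einsum("bij,bij->bi", diff, diff)))
    norms = np.linalg.norm(Z, axis=1)
    reg = float(np.mean((norms - 1.0) ** 2))
    return Z, Y, ec, dc, rec, reg, rec + lambda_reg * reg, norms


def train(dataset: list, graph: FaceGraph, config: TrainConfig):
    """Unsupervised training on a list of same-topology meshes.

    Splits the dataset (default 17:2:1), centers coordinates on the
    training-mean face, and minimizes L_recon + lambda L_reg with Adam.
    Early-stops when the validation loss has not improved for
    ``config.patience`` epochs and returns the best-validation weights.
    Deterministic for a fixed seed.

    Returns ``(params, history)``; history holds per-epoch train/val
    losses, the mean latent-norm deviation, and the split index sets.
    """
    template = dataset[0]
    for m in dataset[1:]:
        if not m.same_topology(template):
            raise MeshTopologyError("all training meshes must share one topology")
    train_ids, val_ids, test_ids = split_dataset(
        len(dataset), config.split_ratio, config.seed
    )
    all_X = np.stack([m.vertices for m in dataset])
    ref = all_X[train_ids].mean(axis=0)
    Xtr = all_X[train_ids] - ref
    Xva = all_X[val_ids] - ref

    mcfg = dataclasses.replace(
        config.model_config or nn.ModelConfig(), seed=config.seed
    )
    ops = _ops(graph)
    weights = nn.init_params(mcfg, ops)
    adam = nn.Adam(weights, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    history = {
        "train_total": [], "train_recon": [], "val_total": [], "val_recon": [],
        "z_norm_dev": [],
        "split": {"train": train_ids.tolist(), "val": val_ids.tolist(),
                  "test": test_ids.tolist()},
    }
    best = (np.inf, None, -1)
    since_decay = -1
    lam = config.lambda_reg
    for epoch in range(config.epochs):
        perm = rng.permutation(len(Xtr))
        ep_tot = ep_rec = ep_zdev = 0.0
        for b0 in range(0, len(perm), config.batch_size):
            Xb = Xtr[perm[b0 : b0 + config.batch_size]]
            B, N = Xb.shape[0], Xb.shape[1]
            Z, ec = nn.encoder_forward(weights, ops, mcfg, Xb)
            Y, dc = nn.decoder_forward(weights, ops, mcfg, Z)
            diff = Y - Xb
            rec = float(np.mean(np.einsum("bij,bij->bi", diff, diff)))
            norms = np.linalg.norm(Z, axis=1)
            reg = float(np.mean((norms - 1.0) ** 2))
            tot = rec + lam * reg
            if not np.isfinite(tot):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={tot} "
                    f"(recon={rec}, reg={reg})"
                )
            ep_tot += tot * B
            ep_rec += rec * B
            ep_zdev += float(np.abs(norms - 1.0).sum())
            dY = 2.0 * diff / (B * N)
            gdec, dZ = nn.decoder_backward(weights, ops, mcfg, dc, dY)
            safe = np.maximum(norms, 1e-12)
            dZ = dZ + lam * (2.0 * (norms - 1.0) / safe / B)[:, None] * Z
            genc = nn.encoder_backward(weights, ops, mcfg, ec, dZ)
            adam.step(weights, {**gdec, **genc})
        history["train_total"].append(ep_tot / len(Xtr))
        history["train_recon"].append(ep_rec / len(Xtr))

        Zv, _, _, _, vrec, vreg, vtot, _ = _forward_losses(weights, ops, mcfg, Xva, lam)
        history["val_total"].append(vtot)
        history["val_recon"].append(vrec)
        history["z_norm_dev"].append(ep_zdev / len(Xtr))

        if vtot < best[0] - 1e-12:
            best = (vtot, {k: v.copy() for k, v in weights.items()}, epoch)
            since_decay = epoch
        elif epoch - best[2] >= config.patience:
            break
        elif epoch - max(best[2], since_decay) >= config.lr_patience:
            adam.lr *= config.lr_factor
            since_decay = epoch

    final_weights = best[1] if best[1] is not None else weights
    params = ModelParams(
        config=mcfg,
        weights=final_weights,
        ref_vertices=ref,
        template_faces=template.faces.copy(),
        topology_id=template.topology_id,
    )
    return params, history


def test_mse(params: ModelParams, graph: FaceGraph, test_set: list) -> float:
    """Mean reconstruction loss of encode -> decode over held-out faces."""
    ops = _ops(graph)
    X = np.stack([_check_input(params, graph, m) for m in test_set]) - params.ref_vertices
    Z, _ = nn.encoder_forward(params.weights, ops, params.config, X)
    Y, _ = nn.decoder_forward(params.weights, ops, params.config, Z)
    diff = Y - X
    return float(np.mean(np.einsum("bij,bij->bi", diff, diff)))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_checkpoint(path, params: ModelParams) -> None:
    meta = {
        "config": dataclasses.asdict(params.config),
        "topology_id": params.topology_id,
    }
    np.savez_compressed(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        ref_vertices=params.ref_vertices,
        template_faces=params.template_faces,
        **{f"w_{k}": v for k, v in params.weights.items()},
    )


def load_checkpoint(path) -> ModelParams:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg = meta["config"]
        cfg["widths"] = tuple(cfg["widths"])
        return ModelParams(
            config=nn.ModelConfig(**cfg),
            weights={k[2:]: data[k] for k in data.files if k.startswith("w_")},
            ref_vertices=data["ref_vertices"],
            template_faces=data["template_faces"],
            topology_id=meta["topology_id"],
        )
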