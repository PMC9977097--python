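"""SE(3)-equivariant residue-level network (geometric vector perceptron GNN).

Each residue carries paired scalar/vector feature channels. A geometric
vector perceptron (GVP) transforms such pairs so that scalar outputs are
rotation-invariant (vector information enters only through channel
norms) and vector outputs are rotation-equivariant (linear maps over the
channel axis scaled by an invariant sigmoid gate). Message passing
concatenates each neighbor's embedding with the connecting edge's
features, pushes that through a GVP stack, averages the incident
messages into the receiving residue's self-representation, and applies a
feed-forward GVP update; after ``num_layers`` rounds a scalar GVP
readout and a sigmoid give one cryptic-pocket probability per residue.

Training uses binary cross-entropy (soft targets for continuous
druggability labels), the class-balancing and batch-size schemes offered
as config options, and an Adam optimizer; everything is seeded and
deterministic on one device.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat, gather, segment_mean, stack_loss
from .featurize import (
    EDGE_SCALAR_DIM,
    EDGE_VECTOR_DIM,
    NODE_SCALAR_DIM,
    NODE_VECTOR_DIM,
    GraphFeatures,
    build_graph,
)
from .residue_pockets import ResidueLabelSet
from .structure_io import ProteinStructure

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "Prediction",
    "GVP",
    "GVPModel",
    "predict",
    "train",
    "train_two_phase",
    "save_weights",
    "load_weights",
]


@dataclass
class ModelConfig:
    node_embed_dims: tuple[int, int] = (50, 8)  # (scalar, vector)
    edge_embed_dims: tuple[int, int] = (32, 1)
    hidden_dims: tuple[int, int] = (100, 16)
    num_layers: int = 4
    k_neighbors: int = 30
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for dims in (self.node_embed_dims, self.edge_embed_dims, self.hidden_dims):
            if min(dims) < 0 or max(dims) <= 0:
                raise ValueError("dimensions must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_mode: str = "residues_4"
    # per_protein | residues_32 | residues_4 | balanced_draw_160 | balanced_draw_640
    balancing: str = "none"
    # none | oversample_positive | undersample_negative | loss_weighting
    include_intermediate: bool = False
    learning_rate: float = 1e-4
    seed: int = 0
    soft_targets: bool = False  # continuous (druggability) labels

    _BATCH_MODES = (
        "per_protein",
        "residues_32",
        "residues_4",
        "balanced_draw_160",
        "balanced_draw_640",
    )
    _BALANCING = ("none", "oversample_positive", "undersample_negative", "loss_weighting")

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_mode not in self._BATCH_MODES:
            raise ValueError(f"unknown batch mode {self.batch_mode!r}")
        if self.balancing not in self._BALANCING:
            raise ValueError(f"unknown balancing {self.balancing!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class Prediction:
    probs: np.ndarray  # aligned to structure residues; NaN where unfeaturizable
    mask: np.ndarray  # True where a probability was produced
    residue_indices: np.ndarray
    fingerprint: str = ""
    identifier: str = ""


# ---------------------------------------------------------------------------
# layers


class GVP:
    """One geometric vector perceptron: (s, V) -> (s', V').

    Vector channels are mixed by a linear map; their norms join the
    scalar channel; vector outputs are scaled by a sigmoid gate computed
    from the scalar branch, which keeps them exactly equivariant.
    """

    def __init__(
        self,
        in_dims: tuple[int, int],
        out_dims: tuple[int, int],
        activation: bool = True,
        rng: np.random.Generator | None = None,
        prefix: str = "gvp",
    ):
        rng = rng or np.random.default_rng(0)
        self.si, self.vi = in_dims
        self.so, self.vo = out_dims
        self.h = max(self.vi, self.vo) if (self.vi or self.vo) else 0
        self.activation = activation
        self.prefix = prefix

        def init(shape, fan_in):
            return Tensor(rng.normal(0.0, 1.0 / np.sqrt(max(fan_in, 1)), shape),
                          requires_grad=True)

        self.params: dict[str, Tensor] = {}
        if self.vi:
            self.params["Wh"] = init((self.vi, self.h), self.vi)
        self.params["Ws"] = init((self.si + (self.h if self.vi else 0), self.so),
                                 self.si + self.h)
        self.params["bs"] = Tensor(np.zeros(self.so), requires_grad=True)
        if self.vo:
            self.params["Wv"] = init((self.h if self.vi else 1, self.vo), max(self.h, 1))
            self.params["Wg"] = init((self.so, self.vo), self.so)
            self.params["bg"] = Tensor(np.zeros(self.vo), requires_grad=True)

    def named_params(self) -> dict[str, Tensor]:
        return {f"{self.prefix}.{k}": v for k, v in self.params.items()}

    def __call__(self, s: Tensor, V: Tensor | None) -> tuple[Tensor, Tensor | None]:
        if self.vi:
            Vh = V.channel_matmul(self.params["Wh"])
            sh = Vh.norm()
            s_in = concat([s, sh], axis=-1)
        else:
            Vh = None
            s_in = s
        sm = s_in.matmul(self.params["Ws"]) + self.params["bs"]
        s_out = sm.relu() if self.activation else sm
        V_out = None
        if self.vo:
            if self.vi:
                Vu = Vh.channel_matmul(self.params["Wv"])
                gate = (s_out.matmul(self.params["Wg"]) + self.params["bg"]).sigmoid()
                V_out = Vu * gate.reshape(*gate.shape, 1)
            else:
                V_out = Tensor(np.zeros(s.shape[:-1] + (self.vo, 3)))
        return s_out, V_out


def _dropout_pair(
    s: Tensor,
    V: Tensor | None,
    rate: float,
    rng: np.random.Generator | None,
) -> tuple[Tensor, Tensor | None]:
    """Inverted dropout; vector channels are dropped whole (equivariance)."""
    if rate <= 0 or rng is None:
        return s, V
    keep = 1.0 - rate
    s = s * Tensor(rng.binomial(1, keep, s.shape) / keep)
    if V is not None:
        mask = rng.binomial(1, keep, V.shape[:-1] + (1,)) / keep
        V = V * Tensor(mask)
    return s, V


class GVPModel:
    """Embedding + message-passing stack + per-residue sigmoid readout."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        ns, nv = cfg.node_embed_dims
        es, ev = cfg.edge_embed_dims
        hs, hv = cfg.hidden_dims
        self.node_embed = GVP((NODE_SCALAR_DIM, NODE_VECTOR_DIM), (ns, nv),
                              rng=rng, prefix="embed")
        if (es, ev) != (EDGE_SCALAR_DIM, EDGE_VECTOR_DIM):
            raise ValueError("edge_embed_dims must match the featurizer's edge dims")
        self.layers: list[dict[str, GVP]] = []
        for i in range(cfg.num_layers):
            self.layers.append(
                {
                    "msg1": GVP((ns + es, nv + ev), (hs, hv), rng=rng,
                                prefix=f"layer{i}.msg1"),
                    "msg2": GVP((hs, hv), (ns, nv), activation=False, rng=rng,
                                prefix=f"layer{i}.msg2"),
                    "ff1": GVP((ns, nv), (hs, hv), rng=rng, prefix=f"layer{i}.ff1"),
                    "ff2": GVP((hs, hv), (ns, nv), activation=False, rng=rng,
                               prefix=f"layer{i}.ff2"),
                }
            )
        self.readout1 = GVP((ns, nv), (ns, 0), rng=rng, prefix="readout1")
        self.readout_w = Tensor(rng.normal(0, 1.0 / np.sqrt(ns), (ns, 1)),
                                requires_grad=True)
        self.readout_b = Tensor(np.zeros(1), requires_grad=True)

    # -- parameters --------------------------------------------------------

    def named_params(self) -> dict[str, Tensor]:
        out = dict(self.node_embed.named_params())
        for layer in self.layers:
            for gvp in layer.values():
                out.update(gvp.named_params())
        out["readout1.Ws"] = self.readout1.params["Ws"]
        out["readout1.bs"] = self.readout1.params["bs"]
        if "Wh" in self.readout1.params:
            out["readout1.Wh"] = self.readout1.params["Wh"]
        out["readout.w"] = self.readout_w
        out["readout.b"] = self.readout_b
        return out

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name in sorted(self.named_params()):
            h.update(name.encode())
            h.update(self.named_params()[name].data.tobytes())
        return h.hexdigest()[:16]

    # -- forward -----------------------------------------------------------

    def message_passing_step(
        self,
        layer: dict[str, GVP],
        s: Tensor,
        V: Tensor,
        graph: GraphFeatures,
        dropout_rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, Tensor]:
        src, dst = graph.edge_index
        n = graph.n_nodes
        es = Tensor(graph.edge_scalars)
        eV = Tensor(graph.edge_vectors)
        ms = concat([gather(s, src), es], axis=-1)
        mV = concat([gather(V, src), eV], axis=-2)
        hs, hV = layer["msg1"](ms, mV)
        hs, hV = layer["msg2"](hs, hV)
        agg_s = segment_mean(hs, dst, n)
        agg_V = segment_mean(hV, dst, n)
        agg_s, agg_V = _dropout_pair(agg_s, agg_V, self.config.dropout, dropout_rng)
        s = s + agg_s
        V = V + agg_V
        fs, fV = layer["ff1"](s, V)
        fs, fV = layer["ff2"](fs, fV)
        fs, fV = _dropout_pair(fs, fV, self.config.dropout, dropout_rng)
        return s + fs, V + fV

    def forward(
        self,
        graph: GraphFeatures,
        dropout_rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Per-node probabilities, shape (n,). Dropout only when an RNG is given."""
        s, V = self.node_embed(Tensor(graph.node_scalars), Tensor(graph.node_vectors))
        for layer in self.layers:
            s, V = self.message_passing_step(layer, s, V, graph, dropout_rng)
        hs, _ = self.readout1(s, V)
        logits = hs.matmul(self.readout_w) + self.readout_b
        return logits.sigmoid().reshape(-1)


# ---------------------------------------------------------------------------
# inference


def predict(
    structure: ProteinStructure,
    model: GVPModel,
) -> Prediction:
    """Deterministic per-residue cryptic-pocket probabilities.

    Residues without a full backbone (and synthetic pseudo-residues) are
    masked, with their probability reported as NaN.
    """
    graph = build_graph(structure, k=model.config.k_neighbors)
    probs_nodes = model.forward(graph).data
    n = len(structure.residues)
    probs = np.full(n, np.nan)
    mask = np.zeros(n, dtype=bool)
    index_of = {r.index: i for i, r in enumerate(structure.residues)}
    for ridx, p in zip(graph.residue_indices, probs_nodes):
        i = index_of[int(ridx)]
        probs[i] = p
        mask[i] = True
    return Prediction(
        probs=probs,
        mask=mask,
        residue_indices=structure.residue_indices(),
        fingerprint=model.fingerprint(),
        identifier=structure.identifier,
    )


# ---------------------------------------------------------------------------
# training


class _Adam:
    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _align_labels(graph: GraphFeatures, labels: ResidueLabelSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-node (target, include) aligned to graph nodes by residue index."""
    lut = {int(r): i for i, r in enumerate(labels.residue_indices)}
    y = np.zeros(graph.n_nodes)
    inc = np.zeros(graph.n_nodes, dtype=bool)
    for node, ridx in enumerate(graph.residue_indices):
        i = lut.get(int(ridx))
        if i is not None:
            y[node] = labels.labels[i]
            inc[node] = labels.mask[i]
    return y, inc


def _batch_plan(
    pool: list[tuple[int, int]],  # (graph id, node id) of included residues
    targets: list[np.ndarray],
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[list[list[tuple[int, int]]], np.ndarray | None]:
    """Batches for one epoch plus optional per-class loss weights."""
    pos = [p for p in pool if targets[p[0]][p[1]] >= 0.5]
    neg = [p for p in pool if targets[p[0]][p[1]] < 0.5]
    class_weight = None
    items = list(pool)
    if config.balancing == "oversample_positive" and pos and len(pos) < len(neg):
        extra_idx = rng.integers(0, len(pos), len(neg) - len(pos))
        items = items + [pos[i] for i in extra_idx]
    elif config.balancing == "undersample_negative" and neg and len(neg) > len(pos):
        keep = rng.permutation(len(neg))[: max(len(pos), 1)]
        items = pos + [neg[i] for i in keep]
    elif config.balancing == "loss_weighting":
        n_pos, n_neg = max(len(pos), 1), max(len(neg), 1)
        total = n_pos + n_neg
        class_weight = np.array([total / (2.0 * n_neg), total / (2.0 * n_pos)])

    if config.batch_mode.startswith("balanced_draw"):
        size = int(config.batch_mode.rsplit("_", 1)[1])
        n_batches = max(1, len(items) // size)
        batches = []
        for _ in range(n_batches):
            half = size // 2
            ip = rng.integers(0, max(len(pos), 1), half)
            ineg = rng.integers(0, max(len(neg), 1), size - half)
            batch = [pos[i] for i in ip if pos] + [neg[i] for i in ineg if neg]
            batches.append(batch)
        return batches, class_weight

    order = rng.permutation(len(items))
    shuffled = [items[i] for i in order]
    if config.batch_mode == "per_protein":
        by_graph: dict[int, list[tuple[int, int]]] = {}
        for g, node in shuffled:
            by_graph.setdefault(g, []).append((g, node))
        graph_order = rng.permutation(sorted(by_graph))
        return [by_graph[g] for g in graph_order], class_weight
    size = {"residues_32": 32, "residues_4": 4}[config.batch_mode]
    return [shuffled[i : i + size] for i in range(0, len(shuffled), size)], class_weight


def train(
    dataset: list[tuple[GraphFeatures, ResidueLabelSet]],
    config: TrainConfig | None = None,
    model_config: ModelConfig | None = None,
    model: GVPModel | None = None,
    validation: list[tuple[GraphFeatures, ResidueLabelSet]] | None = None,
) -> tuple[GVPModel, dict]:
    """Train (or continue training) the network.

    Returns the model and a log with per-epoch mean loss, the sampled
    class ratio, and validation ROC-AUC when a validation set is given.
    Fully deterministic given config.seed.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    config = config or TrainConfig()
    model = model or GVPModel(model_config)
    rng = np.random.default_rng(config.seed)
    dropout_rng = np.random.default_rng(config.seed + 1)

    graphs = [g for g, _ in dataset]
    aligned = [_align_labels(g, lab) for g, lab in dataset]
    targets = [y for y, _ in aligned]
    pool = [
        (gi, node)
        for gi, (_, inc) in enumerate(aligned)
        for node in np.flatnonzero(inc)
    ]
    if not pool:
        raise ValueError("all residues are masked out; nothing to train on")

    params = model.named_params()
    opt = _Adam(params, lr=config.learning_rate)
    log: dict = {"epoch_loss": [], "epoch_pos_fraction": [], "val_roc_auc": []}

    for _epoch in range(config.epochs):
        batches, class_weight = _batch_plan(pool, targets, config, rng)
        losses = []
        n_pos_seen = 0
        n_seen = 0
        for batch in batches:
            if not batch:
                continue
            opt.zero_grad()
            graph_ids = sorted({g for g, _ in batch})
            probs = {g: model.forward(graphs[g], dropout_rng) for g in graph_ids}
            parts = []
            t_parts = []
            w_parts = []
            for g in graph_ids:
                nodes = np.array([node for gg, node in batch if gg == g])
                parts.append(gather(probs[g], nodes))
                t = targets[g][nodes]
                t_parts.append(t)
                if class_weight is not None:
                    w_parts.append(class_weight[(t >= 0.5).astype(int)])
            pred = concat(parts, axis=0) if len(parts) > 1 else parts[0]
            y = np.concatenate(t_parts)
            w = np.concatenate(w_parts) if w_parts else None
            loss = stack_loss(pred, y, weight=w)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            n_pos_seen += int((y >= 0.5).sum())
            n_seen += y.size
        log["epoch_loss"].append(float(np.mean(losses)) if losses else float("nan"))
        log["epoch_pos_fraction"].append(n_pos_seen / max(n_seen, 1))
        if validation is not None:
            from .evaluate import roc_pr

            ys, ss = [], []
            for g, lab in validation:
                yv, incv = _align_labels(g, lab)
                pv = model.forward(g).data
                ys.append(yv[incv])
                ss.append(pv[incv])
            yv_all = np.concatenate(ys)
            sv_all = np.concatenate(ss)
            try:
                log["val_roc_auc"].append(roc_pr(yv_all >= 0.5, sv_all).roc_auc)
            except ValueError:
                log["val_roc_auc"].append(float("nan"))
    return model, log


def train_two_phase(
    phase1_dataset: list[tuple[GraphFeatures, ResidueLabelSet]],
    phase2_dataset: list[tuple[GraphFeatures, ResidueLabelSet]],
    model_config: ModelConfig | None = None,
    phase1_epochs: int = 20,
    phase2_epochs: int = 1,
    learning_rate: float = 1e-4,
    batch_mode: str = "residues_4",
    seed: int = 0,
) -> tuple[GVPModel, dict]:
    """The two-phase schedule: volume-derived binary labels first, then a
    short refinement on continuous druggability-derived labels (soft targets).

    The refinement phase starts a fresh optimizer state.
    """
    cfg1 = TrainConfig(epochs=phase1_epochs, batch_mode=batch_mode,
                       learning_rate=learning_rate, seed=seed)
    model, log1 = train(phase1_dataset, cfg1, model_config)
    cfg2 = TrainConfig(epochs=phase2_epochs, batch_mode=batch_mode,
                       learning_rate=learning_rate, seed=seed + 1,
                       soft_targets=True)
    model, log2 = train(phase2_dataset, cfg2, model=model)
    return model, {"phase1": log1, "phase2": log2}


# ---------------------------------------------------------------------------
# checkpoints


def save_weights(model: GVPModel, path: str | Path) -> None:
    """Archive of named weight arrays plus a JSON config fingerprint."""
    path = Path(path)
    arrays = {k.replace(".", "__"): v.data for k, v in model.named_params().items()}
    np.savez(path, **arrays)
    cfg = model.config
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" else path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "node_embed_dims": list(cfg.node_embed_dims),
                "edge_embed_dims": list(cfg.edge_embed_dims),
                "hidden_dims": list(cfg.hidden_dims),
                "num_layers": cfg.num_layers,
                "k_neighbors": cfg.k_neighbors,
                "dropout": cfg.dropout,
                "seed": cfg.seed,
                "fingerprint": model.fingerprint(),
            },
            indent=2,
        )
    )


def load_weights(path: str | Path) -> GVPModel:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    sidecar = npz_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    config = ModelConfig(
        node_embed_dims=tuple(meta["node_embed_dims"]),
        edge_embed_dims=tuple(meta["edge_embed_dims"]),
        hidden_dims=tuple(meta["hidden_dims"]),
        num_layers=meta["num_layers"],
        k_neighbors=meta["k_neighbors"],
        dropout=meta["dropout"],
        seed=meta["seed"],
    )
    model = GVPModel(config)
    data = np.load(npz_path)
    params = model.named_params()
    for key, tensor in params.items():
        tensor.data = data[key.replace(".", "__")].astype(float)
    return model
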