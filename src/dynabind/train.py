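"""Two-stage training: MSE pretraining on MD snapshots, MAE finetuning.

Snapshot graphs from one trajectory all carry that trajectory's affinity
label (the label is a property of the complex, not of a frame), and the
frame order is discarded. Training minimizes MSE in the pretraining stage
and MAE in the finetuning stage, with linear warmup/decay around a peak
learning rate, optional FLAG adversarial augmentation of the node feature
embeddings, and best-validation checkpoint selection over a group-wise
9:1 split.

The public surface follows the statsmodels idiom: build a
:class:`Dynaformer` model object from a :class:`LabeledGraphSet`, call
``fit()``, and read estimates and diagnostics off the returned
:class:`DynaformerResults`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .featurize import ComplexGraph, FeaturizerConfig, build_graph
from .fingerprints import FingerprintVector, build_ecif_schema, default_fingerprints
from .model import DynaformerNet, ModelConfig
from .nn.autodiff import Adam, Tensor
from .structures import Trajectory, snapshot

__all__ = [
    "TrainConfig",
    "GraphItem",
    "LabeledGraphSet",
    "build_dataset",
    "split",
    "flag_perturb",
    "fit",
    "exclude_groups",
    "Dynaformer",
    "DynaformerResults",
]

STAGE_DEFAULTS = {
    "pretrain": dict(loss="mse", peak_lr=2e-4, batch_size=16),
    "finetune": dict(loss="mae", peak_lr=1e-5, batch_size=16),
}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol for one stage.

    Stage defaults: pretraining uses MSE with peak learning rate 2e-4;
    finetuning uses MAE with peak learning rate 1e-5 and batch size 16.
    Explicit values override the defaults.
    """

    stage: str = "pretrain"
    loss: Optional[str] = None
    peak_lr: Optional[float] = None
    batch_size: Optional[int] = None
    epochs: int = 50
    split_ratio: float = 0.9
    split_unit: str = "complex"
    flag_steps: int = 0
    flag_step_size: float = 1e-3
    seed: int = 0
    warmup_fraction: float = 0.06
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in STAGE_DEFAULTS:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not (0 < self.split_ratio < 1):
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.split_unit not in ("complex", "snapshot"):
            raise ValueError("split_unit must be 'complex' or 'snapshot'")
        if self.flag_steps < 0:
            raise ValueError("flag_steps must be >= 0")

    def resolved(self) -> "TrainConfig":
        d = STAGE_DEFAULTS[self.stage]
        return replace(
            self,
            loss=self.loss or d["loss"],
            peak_lr=self.peak_lr if self.peak_lr is not None else d["peak_lr"],
            batch_size=self.batch_size if self.batch_size is not None else d["batch_size"],
        )


@dataclass
class GraphItem:
    graph: ComplexGraph
    fingerprints: list[FingerprintVector]
    label: float
    group_id: str


@dataclass
class LabeledGraphSet:
    items: list[GraphItem]
    provenance: str = "synthetic"  # trajectory_snapshots | static_structures | synthetic
    ecif_schema: Optional[list[tuple]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for it in self.items:
            if not np.isfinite(it.label):
                raise ValueError(f"non-finite label in group {it.group_id}")
            if not it.group_id:
                raise ValueError("every item needs a group_id")

    def __len__(self) -> int:
        return len(self.items)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for it in self.items:
            seen.setdefault(it.group_id, None)
        return list(seen)

    def fingerprint_dims(self) -> tuple[int, ...]:
        return tuple(len(f.values) for f in self.items[0].fingerprints)


def build_dataset(trajs: Sequence[Trajectory],
                  cfg: FeaturizerConfig = FeaturizerConfig(),
                  ids: Optional[Sequence[str]] = None,
                  ecif_schema: Optional[list[tuple]] = None) -> LabeledGraphSet:
    """One labeled graph per frame; frames of a trajectory share its label.

    A single ECIF type schema is built over all reference complexes (or
    passed in) so every fingerprint vector has the same length.
    """
    if len(trajs) == 0:
        raise ValueError("no trajectories given")
    for t_idx, t in enumerate(trajs):
        if t.label_pKi is None:
            raise ValueError(f"trajectory {t_idx} has no affinity label")
    if ids is None:
        ids = [f"complex_{k}" for k in range(len(trajs))]
    if ecif_schema is None:
        ecif_schema = build_ecif_schema([t.reference for t in trajs])

    items: list[GraphItem] = []
    for gid, traj in zip(ids, trajs):
        for t in range(traj.n_frames):
            snap = snapshot(traj, t)
            g = build_graph(snap, cfg)
            fps = default_fingerprints(snap, ecif_schema=ecif_schema)
            items.append(GraphItem(graph=g, fingerprints=fps,
                                   label=float(traj.label_pKi), group_id=gid))
    return LabeledGraphSet(items=items, provenance="trajectory_snapshots",
                           ecif_schema=ecif_schema)


def split(ds: LabeledGraphSet, ratio: float = 0.9, unit: str = "complex",
          seed: int = 0) -> tuple[LabeledGraphSet, LabeledGraphSet]:
    """Deterministic train/validation partition.

    ``unit="complex"`` partitions by group_id so no complex straddles the
    split; ``unit="snapshot"`` shuffles items individually.
    """
    if not (0 < ratio < 1):
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if unit == "complex":
        groups = ds.groups
        if len(groups) < 2:
            raise ValueError("need at least 2 groups for a group-wise split")
        order = list(rng.permutation(len(groups)))
        n_train = int(round(ratio * len(groups)))
        n_train = min(max(n_train, 1), len(groups) - 1)
        train_groups = {groups[k] for k in order[:n_train]}
        tr = [it for it in ds.items if it.group_id in train_groups]
        va = [it for it in ds.items if it.group_id not in train_groups]
    elif unit == "snapshot":
        order = rng.permutation(len(ds.items))
        n_train = int(round(ratio * len(ds.items)))
        n_train = min(max(n_train, 1), len(ds.items) - 1)
        tr = [ds.items[k] for k in order[:n_train]]
        va = [ds.items[k] for k in order[n_train:]]
    else:
        raise ValueError("unit must be 'complex' or 'snapshot'")
    mk = lambda items: LabeledGraphSet(items=items, provenance=ds.provenance,
                                       ecif_schema=ds.ecif_schema)
    return mk(tr), mk(va)


def exclude_groups(ds: LabeledGraphSet, held_out_ids: Sequence[str]) -> LabeledGraphSet:
    """Drop any complex whose id appears in an evaluation set (overlap hygiene)."""
    banned = set(held_out_ids)
    return LabeledGraphSet(
        items=[it for it in ds.items if it.group_id not in banned],
        provenance=ds.provenance, ecif_schema=ds.ecif_schema,
    )


# ---------------------------------------------------------------------------
# losses and FLAG augmentation


def _item_loss(net: DynaformerNet, item: GraphItem, loss: str,
               delta: Optional[Tensor] = None) -> Tensor:
    y, _ = net.forward(item.graph, item.fingerprints, node_delta=delta)
    resid = y - item.label
    return resid ** 2 if loss == "mse" else resid.abs()


def batch_loss(net: DynaformerNet, batch: Sequence[GraphItem], loss: str,
               deltas: Optional[Sequence[Optional[Tensor]]] = None) -> Tensor:
    if deltas is None:
        deltas = [None] * len(batch)
    total = None
    for item, d in zip(batch, deltas):
        l = _item_loss(net, item, loss, d)
        total = l if total is None else total + l
    return total * (1.0 / len(batch))


def flag_perturb(net: DynaformerNet, batch: Sequence[GraphItem], loss: str,
                 step_size: float, steps: int) -> Tensor:
    """Adversarial node-embedding perturbation (FLAG-style).

    Starting from a zero perturbation of each graph's node embeddings, the
    loss gradient is ascended ``steps`` times with per-graph normalized
    steps of length ``step_size`` (so the final perturbation norm is bounded
    by steps x step_size). Returns the differentiable loss at the final
    perturbation; ``steps=0`` reduces exactly to the unaugmented loss.
    """
    if steps == 0:
        return batch_loss(net, batch, loss)
    H = net.cfg.hidden_dim
    delta_arrays = [np.zeros((item.graph.n_nodes, H)) for item in batch]
    for _ in range(steps):
        deltas = [Tensor(d.copy(), requires_grad=True) for d in delta_arrays]
        l = batch_loss(net, batch, loss, deltas)
        if not np.isfinite(l.data):
            raise ArithmeticError("non-finite loss during adversarial ascent")
        l.backward()
        for arr, d in zip(delta_arrays, deltas):
            if d.grad is None:
                continue
            norm = np.linalg.norm(d.grad)
            if norm > 0:
                arr += step_size * d.grad / norm
        for p in net.params.values():  # ascent must not touch parameter grads
            p.zero_grad()
    final = [Tensor(d) for d in delta_arrays]
    out = batch_loss(net, batch, loss, final)
    if not np.isfinite(out.data):
        raise ArithmeticError("non-finite loss at final adversarial perturbation")
    return out


# ---------------------------------------------------------------------------
# model / results objects


class Dynaformer:
    """Affinity model over a labeled graph dataset (statsmodels-style).

    Parameters
    ----------
    dataset : LabeledGraphSet
        Training substrate; fingerprint dimensions are read from it.
    model_config : ModelConfig, optional
        Architecture; ``fingerprint_dims`` is filled in from the dataset.
    train_config : TrainConfig, optional
        Stage protocol (loss, schedule, split, FLAG).
    """

    def __init__(self, dataset: LabeledGraphSet,
                 model_config: Optional[ModelConfig] = None,
                 train_config: Optional[TrainConfig] = None):
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        self.dataset = dataset
        mcfg = model_config or ModelConfig()
        self.model_config = replace(mcfg, fingerprint_dims=dataset.fingerprint_dims())
        self.train_config = (train_config or TrainConfig()).resolved()

    @classmethod
    def from_trajectories(cls, trajs: Sequence[Trajectory],
                          featurizer: FeaturizerConfig = FeaturizerConfig(),
                          **kwargs) -> "Dynaformer":
        return cls(build_dataset(trajs, featurizer), **kwargs)

    def fit(self, init_state: Optional[dict[str, np.ndarray]] = None,
            verbose: bool = False) -> "DynaformerResults":
        tcfg = self.train_config
        net = DynaformerNet(self.model_config)
        if init_state is not None:
            # allow warm starts from a checkpoint with a different head width
            own = net.state_dict()
            compat = {k: v for k, v in init_state.items()
                      if k in own and own[k].shape == np.asarray(v).shape}
            net.load_state_dict(compat)

        train_set, val_set = split(self.dataset, tcfg.split_ratio,
                                   tcfg.split_unit, tcfg.seed)
        # standardize the fingerprint block on training-split statistics
        fp_mat = np.array([np.concatenate([f.values for f in it.fingerprints])
                           for it in train_set.items])
        net.fp_mean = fp_mat.mean(axis=0)
        sd = fp_mat.std(axis=0)
        # floor the divisor so rare near-constant features cannot explode on
        # out-of-split structures
        floor = max(0.05 * float(sd.mean()), 1e-3)
        net.fp_std = np.where(sd > floor, sd, np.maximum(sd, floor))
        rng = np.random.default_rng(tcfg.seed + 1)
        opt = Adam(net.params, lr=tcfg.peak_lr, weight_decay=tcfg.weight_decay)

        n_items = len(train_set.items)
        steps_per_epoch = max(1, int(np.ceil(n_items / tcfg.batch_size)))
        total_steps = steps_per_epoch * tcfg.epochs
        warmup = max(1, int(tcfg.warmup_fraction * total_steps))

        def lr_at(step: int) -> float:
            if step < warmup:
                return tcfg.peak_lr * (step + 1) / warmup
            frac = (step - warmup) / max(1, total_steps - warmup)
            return tcfg.peak_lr * max(0.0, 1.0 - frac)

        history: list[dict[str, float]] = []
        best_val = np.inf
        best_state = net.state_dict()
        step = 0
        for epoch in range(tcfg.epochs):
            order = rng.permutation(n_items)
            ep_loss = 0.0
            for b0 in range(0, n_items, tcfg.batch_size):
                batch = [train_set.items[k] for k in order[b0:b0 + tcfg.batch_size]]
                opt.zero_grad()
                loss = flag_perturb(net, batch, tcfg.loss,
                                    tcfg.flag_step_size, tcfg.flag_steps)
                if not np.isfinite(loss.data):
                    raise ArithmeticError(f"training diverged at epoch {epoch}")
                loss.backward()
                opt.step(lr=lr_at(step))
                ep_loss += float(loss.data) * len(batch)
                step += 1
            train_loss = ep_loss / n_items
            val_loss = evaluate_loss(net, val_set.items, tcfg.loss)
            history.append({"epoch": epoch, "train_loss": train_loss,
                            "val_loss": val_loss, "lr": lr_at(step - 1)})
            if val_loss < best_val:
                best_val = val_loss
                best_state = net.state_dict()
            if verbose:
                print(f"epoch {epoch:4d}  train {train_loss:.4f}  val {val_loss:.4f}")

        net.load_state_dict(best_state)
        return DynaformerResults(model=self, net=net, history=history,
                                 best_val_loss=best_val,
                                 n_train=len(train_set.items),
                                 n_val=len(val_set.items))


def evaluate_loss(net: DynaformerNet, items: Sequence[GraphItem], loss: str) -> float:
    if not items:
        return np.nan
    total = 0.0
    for it in items:
        pred = net.predict(it.graph, it.fingerprints).pKi_hat
        r = pred - it.label
        total += r * r if loss == "mse" else abs(r)
    return total / len(items)


@dataclass
class DynaformerResults:
    """Fitted model: best-validation parameters, history, predictions."""

    model: Dynaformer
    net: DynaformerNet
    history: list[dict[str, float]]
    best_val_loss: float
    n_train: int
    n_val: int

    def predict(self, graph: ComplexGraph,
                fingerprints: Sequence[FingerprintVector]) -> float:
        return self.net.predict(graph, fingerprints).pKi_hat

    def predict_items(self, items: Sequence[GraphItem]) -> np.ndarray:
        return np.array([self.predict(it.graph, it.fingerprints) for it in items])

    @property
    def final_train_loss(self) -> float:
        return self.history[-1]["train_loss"] if self.history else np.nan

    def summary(self) -> str:
        tcfg = self.model.train_config
        mcfg = self.model.model_config
        n_params = sum(p.data.size for p in self.net.params.values())
        lines = [
            "Dynaformer fit results",
            "=" * 46,
            f"stage:            {tcfg.stage} ({tcfg.loss} loss)",
            f"layers x hidden:  {mcfg.n_layers} x {mcfg.hidden_dim} "
            f"({mcfg.n_heads} heads)",
            f"parameters:       {n_params}",
            f"train/val items:  {self.n_train}/{self.n_val}",
            f"epochs:           {len(self.history)}",
            f"peak lr:          {tcfg.peak_lr:g}",
            f"FLAG steps:       {tcfg.flag_steps}",
            f"final train loss: {self.final_train_loss:.4f}",
            f"best val loss:    {self.best_val_loss:.4f}",
        ]
        return "\n".join(lines)


def fit(ds: LabeledGraphSet, mcfg: Optional[ModelConfig] = None,
        tcfg: Optional[TrainConfig] = None,
        init_state: Optional[dict[str, np.ndarray]] = None) -> DynaformerResults:
    """Functional entry point; equivalent to ``Dynaformer(ds, ...).fit()``."""
    return Dynaformer(ds, mcfg, tcfg).fit(init_state=init_state)
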