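"""Graph transformer for binding affinity with Gaussian-basis attention biases.

The network reads a :class:`~dynabind.featurize.ComplexGraph` — categorical
node features, typed edges, pairwise distances, shortest paths and bond-angle
sums — and predicts pKi. Structural information enters only through additive
attention biases:

* a distance bias ``d(i, j)``: the edge distance r_ij, affine-modulated by the
  endpoint element categories, expanded in K learnable Gaussian basis
  functions exp(-(x - mu_k)^2 / (2 sigma_k^2)) and projected per head;
* an angle bias ``a(i, j)``: the summed bond angle at j, treated the same way;
* a path bias: per-head edge scores averaged along one shortest path between
  i and j (zero when no path within P_max exists).

Because every input to the biases is a rigid-motion-invariant scalar, the
prediction is invariant to rotations and translations of the complex, and
attention pooling over the coordinate-free virtual node makes it invariant to
atom reordering. The virtual node's final representation, concatenated with
the three interaction fingerprints, feeds a linear affinity head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .featurize import (
    BOND_ORDER_VOCAB, CHIRALITY_VOCAB, ELEMENT_VOCAB, HYBRIDIZATION_VOCAB,
    ComplexGraph, MAX_CHARGE, MAX_DEGREE, MAX_HCOUNT,
)
from .fingerprints import FingerprintVector
from .nn.autodiff import Parameter, Tensor, concat

__all__ = ["ModelConfig", "GBFParams", "DynaformerNet", "Prediction"]

# vocabulary sizes for the nine categorical node fields (order matches
# NodeFeatures.as_codes); index 0 everywhere is the virtual node's code
NODE_VOCAB_SIZES = (
    len(ELEMENT_VOCAB),      # element
    MAX_DEGREE + 2,          # degree (shifted)
    2 * MAX_CHARGE + 2,      # formal charge (shifted)
    MAX_HCOUNT + 2,          # hydrogen count (shifted)
    len(HYBRIDIZATION_VOCAB),
    3,                       # aromatic {reserved, no, yes}
    3,                       # ring
    len(CHIRALITY_VOCAB),
    3,                       # origin {virtual, ligand, protein}
)

# edge fields (EdgeRecord.as_codes): bond order, conjugated, ring, kind
EDGE_VOCAB_SIZES = (len(BOND_ORDER_VOCAB), 3, 3, 2)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The published configuration is four encoder layers with 512 hidden
    dimensions; head count and FFN width follow common transformer practice
    (8 heads, 2x hidden). ``denominator`` selects the attention scaling:
    ``"sqrt"`` divides logits by sqrt(d_K) (standard), ``"linear"`` by d_K.
    ``path_average`` selects the path-bias normalizer: ``"actual"`` divides
    by the real path length, ``"fixed"`` always by P_max.
    """

    n_layers: int = 4
    hidden_dim: int = 512
    n_heads: int = 8
    P_max: int = 5
    K_gbf: int = 32
    ffn_dim: Optional[int] = None
    fingerprint_dims: tuple[int, ...] = ()
    denominator: str = "sqrt"
    path_average: str = "actual"
    angle_max: float = 540.0  # upper end of GBF center range for angle sums
    distance_max: float = 5.0  # upper end of GBF center range for distances
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim % self.n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        if self.denominator not in ("sqrt", "linear"):
            raise ValueError("denominator must be 'sqrt' or 'linear'")
        if self.path_average not in ("actual", "fixed"):
            raise ValueError("path_average must be 'actual' or 'fixed'")

    @property
    def d_head(self) -> int:
        return self.hidden_dim // self.n_heads

    @property
    def ffn_width(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 2 * self.hidden_dim


@dataclass
class GBFParams:
    """Learnable Gaussian basis: centers mu_k and widths sigma_k (> 0 via
    softplus reparameterization), plus per-element-category affine (scale,
    shift) applied to the raw scalar before the basis."""

    mu: Parameter
    sigma_raw: Parameter  # sigma = softplus(sigma_raw) + 1e-3
    scale_emb: Parameter  # (n_elements,) per-endpoint scale contribution
    shift_emb: Parameter  # (n_elements,)

    def sigma(self) -> Tensor:
        return self.sigma_raw.softplus() + 1e-3


@dataclass
class Prediction:
    pKi_hat: float
    per_node_attention: Optional[list[np.ndarray]] = None


def _softplus_inverse(y: float) -> float:
    return float(np.log(np.expm1(y)))


class DynaformerNet:
    """The affinity network: parameters, forward pass, and checkpointing.

    Construction is deterministic for a fixed ``cfg.seed``; the forward pass
    contains no stochastic elements, so fixed parameters + fixed input give a
    bit-identical prediction.
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        H, heads, K = cfg.hidden_dim, cfg.n_heads, cfg.K_gbf
        p: dict[str, Parameter] = {}

        def init(name: str, *shape: int, scale: Optional[float] = None) -> Parameter:
            s = scale if scale is not None else 1.0 / np.sqrt(shape[-1])
            p[name] = Parameter(rng.normal(0.0, s, size=shape))
            return p[name]

        # node/edge categorical embeddings
        for f, vocab in enumerate(NODE_VOCAB_SIZES):
            init(f"node_emb_{f}", vocab, H, scale=0.02)
        for f, vocab in enumerate(EDGE_VOCAB_SIZES):
            init(f"edge_path_emb_{f}", vocab, heads, scale=0.02)

        # Gaussian bases for distances and angle sums
        self.gbf_dist = self._make_gbf(p, "dist", K, 0.0, cfg.distance_max)
        self.gbf_angle = self._make_gbf(p, "angle", K, 0.0, cfg.angle_max)
        init("W_d", K, heads, scale=0.02)
        init("W_a", K, heads, scale=0.02)
        init("virtual_bias", heads, scale=0.02)

        for layer in range(cfg.n_layers):
            init(f"W_Q_{layer}", H, H)
            init(f"W_K_{layer}", H, H)
            init(f"W_V_{layer}", H, H)
            init(f"W_O_{layer}", H, H)
            init(f"ffn_w1_{layer}", H, cfg.ffn_width)
            p[f"ffn_b1_{layer}"] = Parameter(np.zeros(cfg.ffn_width))
            init(f"ffn_w2_{layer}", cfg.ffn_width, H)
            p[f"ffn_b2_{layer}"] = Parameter(np.zeros(H))
            p[f"ln1_g_{layer}"] = Parameter(np.ones(H))
            p[f"ln1_b_{layer}"] = Parameter(np.zeros(H))
            p[f"ln2_g_{layer}"] = Parameter(np.ones(H))
            p[f"ln2_b_{layer}"] = Parameter(np.zeros(H))

        fp_total = sum(cfg.fingerprint_dims)
        init("head_w", H + fp_total, 1, scale=0.02)
        p["head_b"] = Parameter(np.zeros(1))
        self.params = p
        # non-trainable standardization buffers for the fingerprint block,
        # set from training data by the fitting routine
        self.fp_mean = np.zeros(fp_total)
        self.fp_std = np.ones(fp_total)

    @staticmethod
    def _make_gbf(p: dict[str, Parameter], tag: str, K: int,
                  lo: float, hi: float) -> GBFParams:
        mu0 = np.linspace(lo, hi, K)
        spacing = (hi - lo) / max(K - 1, 1)
        p[f"gbf_{tag}_mu"] = Parameter(mu0)
        p[f"gbf_{tag}_sigma_raw"] = Parameter(
            np.full(K, _softplus_inverse(max(spacing, 1e-2)))
        )
        n_el = NODE_VOCAB_SIZES[0]
        p[f"gbf_{tag}_scale"] = Parameter(np.full(n_el, 0.5))
        p[f"gbf_{tag}_shift"] = Parameter(np.zeros(n_el))
        return GBFParams(
            mu=p[f"gbf_{tag}_mu"], sigma_raw=p[f"gbf_{tag}_sigma_raw"],
            scale_emb=p[f"gbf_{tag}_scale"], shift_emb=p[f"gbf_{tag}_shift"],
        )

    # ------------------------------------------------------------------
    def gbf_encode(self, x: Tensor, gbf: GBFParams,
                   el_i: Optional[np.ndarray] = None,
                   el_j: Optional[np.ndarray] = None) -> Tensor:
        """Expand scalars ``x`` (m,) in the K Gaussian bases -> (m, K).

        When endpoint element codes are given, x is first passed through the
        pair-conditioned affine x' = (s_i + s_j) x + (t_i + t_j).
        """
        if not np.all(np.isfinite(x.data)):
            raise ArithmeticError("non-finite input to Gaussian basis encoding")
        if el_i is not None:
            scale = gbf.scale_emb.take_rows(el_i) + gbf.scale_emb.take_rows(el_j)
            shift = gbf.shift_emb.take_rows(el_i) + gbf.shift_emb.take_rows(el_j)
            x = x * scale + shift
        diff = x.reshape(-1, 1) - gbf.mu.reshape(1, -1)
        sig = gbf.sigma().reshape(1, -1)
        return (-(diff ** 2) / (2.0 * sig ** 2)).exp()

    # ------------------------------------------------------------------
    def attention_bias(self, g: ComplexGraph) -> Tensor:
        """Per-head additive attention bias, shape (n_heads, n, n)."""
        if g.sp_paths is None or g.angle_sum is None:
            raise ValueError("graph is missing shortest paths or angle sums")
        n = g.n_nodes
        heads = self.cfg.n_heads
        p = self.params
        el = np.array([nf.element for nf in g.nodes], dtype=int)

        pieces: list[tuple[np.ndarray, np.ndarray, Tensor]] = []

        # distance bias over edges (the pairs with a stored r_ij)
        if g.edges:
            ei = np.array([e.i for e in g.edges], dtype=int)
            ej = np.array([e.j for e in g.edges], dtype=int)
            r = Tensor(np.array([e.distance for e in g.edges]))
            phi = self.gbf_encode(r, self.gbf_dist, el[ei], el[ej])
            d_bias = phi @ p["W_d"]  # (m, heads)
            pieces.append((ei, ej, d_bias))
            pieces.append((ej, ei, d_bias))

        # angle bias over covalently bonded ordered pairs
        if g.angle_sum:
            ai = np.array([i for (i, _) in g.angle_sum], dtype=int)
            aj = np.array([j for (_, j) in g.angle_sum], dtype=int)
            vals = Tensor(np.array(list(g.angle_sum.values())))
            phi = self.gbf_encode(vals, self.gbf_angle, el[ai], el[aj])
            a_bias = phi @ p["W_a"]
            pieces.append((ai, aj, a_bias))

        # path bias: average per-head edge scores along the stored path
        if g.sp_paths and g.edges:
            edge_codes = np.array([e.as_codes() for e in g.edges], dtype=int)
            per_edge = None
            for f in range(len(EDGE_VOCAB_SIZES)):
                emb = p[f"edge_path_emb_{f}"].take_rows(edge_codes[:, f])
                per_edge = emb if per_edge is None else per_edge + emb  # (m, heads)
            # aggregate per-edge scores along each path with one constant
            # (n_pairs x n_edges) averaging matrix
            pairs = [(i, j, path) for (i, j), path in g.sp_paths.items() if path]
            if pairs:
                agg = np.zeros((len(pairs), len(g.edges)))
                pi = np.empty(len(pairs), dtype=int)
                pj = np.empty(len(pairs), dtype=int)
                for row, (i, j, path) in enumerate(pairs):
                    denom = len(path) if self.cfg.path_average == "actual" else self.cfg.P_max
                    agg[row, path] = 1.0 / denom
                    pi[row], pj[row] = i, j
                pieces.append((pi, pj, Tensor(agg) @ per_edge))

        # virtual node: one learned scalar per head for virtual<->real pairs
        real = np.arange(1, n)
        vb = p["virtual_bias"].reshape(1, -1)
        ones = Tensor(np.ones((n - 1, 1)))
        v_rows = ones @ vb  # (n-1, heads), each row the virtual scalar
        pieces.append((np.zeros(n - 1, dtype=int), real, v_rows))
        pieces.append((real, np.zeros(n - 1, dtype=int), v_rows))

        return _scatter_pairs(pieces, heads, n)

    # ------------------------------------------------------------------
    def forward(self, g: ComplexGraph, fps: Sequence[FingerprintVector],
                node_delta: Optional[Tensor] = None,
                return_attention: bool = False) -> tuple[Tensor, Prediction]:
        """Run the network; returns the differentiable output and a Prediction.

        ``node_delta`` is an optional (n, hidden) perturbation added to the
        node embeddings (the hook used by adversarial FLAG augmentation).
        """
        cfg = self.cfg
        fp_lens = tuple(len(f.values) for f in fps)
        if fp_lens != tuple(cfg.fingerprint_dims):
            raise ValueError(
                f"fingerprint lengths {fp_lens} do not match configured "
                f"{tuple(cfg.fingerprint_dims)}"
            )
        p = self.params
        n = g.n_nodes
        codes = np.array([nf.as_codes() for nf in g.nodes], dtype=int)
        h = None
        for f in range(len(NODE_VOCAB_SIZES)):
            emb = p[f"node_emb_{f}"].take_rows(codes[:, f])
            h = emb if h is None else h + emb
        if node_delta is not None:
            h = h + node_delta

        bias = self.attention_bias(g)  # (heads, n, n)
        denom = np.sqrt(cfg.d_head) if cfg.denominator == "sqrt" else float(cfg.d_head)
        attn_maps: list[np.ndarray] = []

        for layer in range(cfg.n_layers):
            q = (h @ p[f"W_Q_{layer}"]).reshape(n, cfg.n_heads, cfg.d_head).transpose(1, 0, 2)
            k = (h @ p[f"W_K_{layer}"]).reshape(n, cfg.n_heads, cfg.d_head).transpose(1, 0, 2)
            v = (h @ p[f"W_V_{layer}"]).reshape(n, cfg.n_heads, cfg.d_head).transpose(1, 0, 2)
            logits = (q @ k.transpose(0, 2, 1)) * (1.0 / denom) + bias
            attn = logits.softmax(axis=-1)
            if return_attention:
                attn_maps.append(attn.data.copy())
            mixed = (attn @ v).transpose(1, 0, 2).reshape(n, cfg.hidden_dim)
            h = h + mixed @ p[f"W_O_{layer}"]
            h = h.layer_norm() * p[f"ln1_g_{layer}"] + p[f"ln1_b_{layer}"]
            ffn = (h @ p[f"ffn_w1_{layer}"] + p[f"ffn_b1_{layer}"]).relu()
            h = h + ffn @ p[f"ffn_w2_{layer}"] + p[f"ffn_b2_{layer}"]
            h = h.layer_norm() * p[f"ln2_g_{layer}"] + p[f"ln2_b_{layer}"]
            if not np.all(np.isfinite(h.data)):
                raise ArithmeticError(f"non-finite activations after encoder layer {layer}")

        virtual = h.take_rows(np.array([0]))  # (1, hidden)
        raw = np.concatenate([f.values for f in fps]) if fps else np.zeros(0)
        fp_scaled = Tensor(((raw - self.fp_mean) / self.fp_std).reshape(1, -1))
        fused = concat([virtual, fp_scaled], axis=1)
        out = fused @ p["head_w"] + p["head_b"]
        y = out.reshape(1).sum()
        pred = Prediction(pKi_hat=float(y.data),
                          per_node_attention=attn_maps if return_attention else None)
        return y, pred

    def predict(self, g: ComplexGraph, fps: Sequence[FingerprintVector]) -> Prediction:
        _, pred = self.forward(g, fps)
        return pred

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.params:
                raise KeyError(f"unknown parameter {k}")
            if self.params[k].data.shape != np.asarray(v).shape:
                raise ValueError(f"shape mismatch for {k}")
            self.params[k].data = np.array(v, dtype=np.float64)

    def save(self, path, fingerprint_schema_ids: Sequence[str] = ()) -> None:
        """Write a JSON checkpoint: config, parameters, schema ids."""
        obj = {
            "format_version": 1,
            "config": {**self.cfg.__dict__},
            "fingerprint_schema_ids": list(fingerprint_schema_ids),
            "fp_mean": self.fp_mean.tolist(),
            "fp_std": self.fp_std.tolist(),
            "params": {k: v.tolist() for k, v in self.state_dict().items()},
        }
        obj["config"]["fingerprint_dims"] = list(self.cfg.fingerprint_dims)
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def load(cls, path) -> "DynaformerNet":
        obj = json.loads(Path(path).read_text())
        cfg_d = obj["config"]
        cfg_d["fingerprint_dims"] = tuple(cfg_d["fingerprint_dims"])
        net = cls(ModelConfig(**cfg_d))
        net.load_state_dict({k: np.array(v) for k, v in obj["params"].items()})
        net.fp_mean = np.array(obj.get("fp_mean", net.fp_mean))
        net.fp_std = np.array(obj.get("fp_std", net.fp_std))
        return net


def _scatter_pairs(pieces: list[tuple[np.ndarray, np.ndarray, Tensor]],
                   heads: int, n: int) -> Tensor:
    """Assemble (heads, n, n) bias from per-pair (m, heads) contributions.

    Duplicate (i, j) entries across pieces add, matching the additive form of
    the bias. Custom autodiff op: backward gathers the dense gradient back to
    each contribution's positions.
    """
    data = np.zeros((heads, n, n))
    for ii, jj, vals in pieces:
        np.add.at(data, (slice(None), ii, jj), vals.data.T)
    out = Tensor(data)
    parents = tuple(v for _, _, v in pieces if v.requires_grad)
    if parents:
        def backward(gr: np.ndarray) -> None:
            for ii, jj, vals in pieces:
                if vals.requires_grad:
                    vals._accum(gr[:, ii, jj].T)

        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out
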