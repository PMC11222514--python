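"""SE(3)-equivariant, chirality-aware denoising network.

The network keeps two feature channels per node — invariant scalars and
equivariant 3D vectors — and passes messages over the fully-connected
molecular graph.  Scalars entering a message are rotation-invariant (vector
norms, and projections onto a per-edge local frame); vectors leaving a
message are linear combinations of input vectors with invariant
coefficients, so rotating the input rotates every vector output identically
while scalar outputs are unchanged.  Translations are absorbed by centring
the coordinates before lifting them into vector features.

Chirality enters through the local frames: for each directed edge (i, j) the
orthonormal triple

    a = (x_i - x_j)/|x_i - x_j|,  b = (x_i x x_j)/|x_i x x_j|,  c = a x b

contains two pseudo-vector axes (b and c), so projections onto them change
sign under reflection and mirror-image inputs become distinguishable.  With
frames disabled the network sees only norms and is exactly
reflection-equivariant; this switch reproduces the frames-ablation axis.

A per-edge logistic gate on the scalar message (scalar message attention,
SMA) acts as a lightweight fully-connected graph attention; disabling it
clamps the gate to one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, bmm, concat, gather_rows, segment_sum
from .diffusion import LatentState
from .molecules import fully_connected_edges

__all__ = [
    "LocalFrame",
    "DenoiserConfig",
    "NoisePrediction",
    "PropertyNormalizer",
    "build_local_frames",
    "lift_noisy_vectors",
    "scalar_message_attention",
    "GCPDenoiser",
]

_DEGENERACY_TOL = 1e-8


@dataclass(frozen=True)
class LocalFrame:
    """Orthonormal edge frame (a, b, c); zeroed when geometrically degenerate."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    defined_flag: bool

    def as_matrix(self) -> np.ndarray:
        return np.stack([self.a, self.b, self.c])


def build_local_frames(x_i: np.ndarray, x_j: np.ndarray) -> LocalFrame:
    """Local frame of one directed edge from already-centred coordinates.

    Degenerate geometry (coincident points, or points collinear with the
    origin, where the cross product vanishes) yields a zeroed frame with
    ``defined_flag`` False so downstream projections contribute nothing.
    """
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    d = x_i - x_j
    nd = np.linalg.norm(d)
    cr = np.cross(x_i, x_j)
    ncr = np.linalg.norm(cr)
    if nd < _DEGENERACY_TOL or ncr < _DEGENERACY_TOL:
        z = np.zeros(3)
        return LocalFrame(a=z, b=z.copy(), c=z.copy(), defined_flag=False)
    a = d / nd
    b = cr / ncr
    c = np.cross(a, b)
    return LocalFrame(a=a, b=b, c=c, defined_flag=True)


def _frames_batch(coords: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """(E, 3, 3) stack of per-edge frames, rows a/b/c, degenerate rows zeroed."""
    xi = coords[edges[:, 0]]
    xj = coords[edges[:, 1]]
    d = xi - xj
    cr = np.cross(xi, xj)
    nd = np.linalg.norm(d, axis=1)
    ncr = np.linalg.norm(cr, axis=1)
    ok = (nd > _DEGENERACY_TOL) & (ncr > _DEGENERACY_TOL)
    a = np.zeros_like(d)
    b = np.zeros_like(d)
    a[ok] = d[ok] / nd[ok, None]
    b[ok] = cr[ok] / ncr[ok, None]
    c = np.cross(a, b)
    return np.stack([a, b, c], axis=1)


def lift_noisy_vectors(zx: np.ndarray, edges: np.ndarray,
                       with_pseudo: bool = False):
    """Displacement-based vector channels derived from noisy coordinates.

    Returns ``(node_vec, edge_vec)``: per-node displacement towards the
    centre of gravity (the negated centred coordinate) with shape
    (N, 1, 3) — or (N, 2, 3) when ``with_pseudo`` adds the pseudo-vector
    channel x_i x n_i against the inverse-square-distance-weighted neighbour
    sum n_i — and per-edge displacement x_j - x_i with shape (E, 1, 3).

    All channels rotate with the input and ignore translations once the
    input is centred.  The displacement channels of one edge span the plane
    of x_i and x_j, so their projections onto the frame axis b vanish
    identically; the pseudo-vector channel points out of that plane, which
    is what lets the first message-passing layer already see chirality
    (its projections onto the true-vector axes a and c are pseudo-scalars).
    """
    zx = np.asarray(zx, dtype=np.float64)
    channels = [-zx[:, None, :]]
    if with_pseudo:
        d2 = ((zx[:, None, :] - zx[None, :, :]) ** 2).sum(-1)
        w = 1.0 / (1.0 + d2)
        np.fill_diagonal(w, 0.0)
        norm = w.sum(axis=1, keepdims=True)
        w = w / np.where(norm > 0, norm, 1.0)  # weighted neighbour mean
        neighbour = w @ zx
        channels.append(np.cross(zx, neighbour)[:, None, :])
    node_vec = np.concatenate(channels, axis=1)
    edge_vec = (zx[edges[:, 1]] - zx[edges[:, 0]])[:, None, :]
    return node_vec, edge_vec


def scalar_message_attention(message_scalars: np.ndarray, weight: np.ndarray,
                             bias: np.ndarray | float = 0.0,
                             enabled: bool = True) -> np.ndarray:
    """Per-edge logistic gate on scalar messages, in (0, 1).

    gate = logistic(message_scalars @ weight + bias); with ``enabled`` False
    the gate is identically 1, reducing the layer to ungated message passing.
    """
    message_scalars = np.asarray(message_scalars, dtype=np.float64)
    if not enabled:
        return np.ones(message_scalars.shape[:-1] + (1,))
    logits = message_scalars @ np.asarray(weight, dtype=np.float64).reshape(
        message_scalars.shape[-1], 1
    ) + bias
    return 1.0 / (1.0 + np.exp(-logits))


@dataclass
class DenoiserConfig:
    """Architecture hyperparameters of the denoising network.

    The reference configuration is 9 layers with 256/64 scalar/vector node
    features and 32/16 scalar/vector edge features; ``toy()`` gives a desk-
    scale profile that trains in seconds on a CPU.
    """

    n_layers: int = 9
    node_scalar_dim: int = 256
    node_vector_dim: int = 64
    edge_scalar_dim: int = 32
    edge_vector_dim: int = 16
    use_frames: bool = True
    use_sma: bool = True
    condition_dim: int = 0
    update_edges: bool = True

    @staticmethod
    def toy(condition_dim: int = 0, use_frames: bool = True,
            use_sma: bool = True) -> "DenoiserConfig":
        return DenoiserConfig(
            n_layers=2, node_scalar_dim=32, node_vector_dim=8,
            edge_scalar_dim=8, edge_vector_dim=4,
            use_frames=use_frames, use_sma=use_sma,
            condition_dim=condition_dim,
        )


@dataclass(frozen=True)
class NoisePrediction:
    """Joint noise estimate: equivariant eps_x (zero-CoG) and invariant eps_h."""

    eps_x: np.ndarray
    eps_h: np.ndarray


@dataclass
class PropertyNormalizer:
    """Affine normalisation (value - mean) / mad for the conditioning scalar."""

    name: str = ""
    mean: float = 0.0
    mad: float = 1.0

    def __call__(self, value: float) -> float:
        return (value - self.mean) / self.mad


def _vec_norm(v: Tensor) -> Tensor:
    # smooth norm over the trailing axis; the epsilon keeps d/dv finite at 0
    return ((v * v).sum(axis=-1) + 1e-12) ** 0.5


class GCPDenoiser:
    """Stack of geometry-complete message-passing layers predicting noise.

    The model consumes a noisy latent state, the normalised timestep t/T and
    an optional conditioning scalar appended to the node features, and emits
    the joint noise estimate.  All learnable state lives in ``self.params``
    (a flat name -> Tensor dict) so optimizers and serialisation stay
    trivial.
    """

    def __init__(self, config: DenoiserConfig, n_feat: int, T: int,
                 rng: np.random.Generator | None = None,
                 normalizer: PropertyNormalizer | None = None):
        self.config = config
        self.n_feat = int(n_feat)  # width of z^(h): alphabet size + charge slot
        self.T = int(T)
        self.normalizer = normalizer or PropertyNormalizer()
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(0) if rng is None else rng
        self._build(rng)

    # -- parameter construction ------------------------------------------------
    def _add_linear(self, name: str, d_in: int, d_out: int,
                    rng: np.random.Generator) -> None:
        w = rng.standard_normal((d_in, d_out)) / np.sqrt(d_in)
        self.params[f"{name}.W"] = Tensor(w, requires_grad=True)
        self.params[f"{name}.b"] = Tensor(np.zeros(d_out), requires_grad=True)

    def _add_weight(self, name: str, d_in: int, d_out: int,
                    rng: np.random.Generator) -> None:
        # bias-free map: used where a bias would break equivariance (vector lifts)
        w = rng.standard_normal((d_in, d_out)) / np.sqrt(d_in)
        self.params[f"{name}.W"] = Tensor(w, requires_grad=True)

    def _build(self, rng: np.random.Generator) -> None:
        c = self.config
        S, V = c.node_scalar_dim, c.node_vector_dim
        Es, Ve = c.edge_scalar_dim, c.edge_vector_dim
        d_in = self.n_feat + 1 + c.condition_dim
        self._add_linear("embed_h", d_in, S, rng)
        self._add_linear("embed_e", 2, Es, rng)
        n_src = 2 if c.use_frames else 1  # pseudo-vector channel only w/ frames
        self.params["lift_node.W"] = Tensor(
            rng.standard_normal((V, n_src)) / np.sqrt(n_src), requires_grad=True
        )
        self._add_weight("lift_edge", 1, Ve, rng)
        msg_in = 2 * S + Es + 2 * V + Ve
        if c.use_frames:
            msg_in += 3 * (2 * V + Ve)
        K = 2 * V + Ve  # vector basis size per edge
        for l in range(c.n_layers):
            self._add_linear(f"layer{l}.msg0", msg_in, S, rng)
            self._add_linear(f"layer{l}.msg1", S, S, rng)
            self._add_linear(f"layer{l}.sma", S, 1, rng)
            self._add_linear(f"layer{l}.upd0", 2 * S, S, rng)
            self._add_linear(f"layer{l}.upd1", S, S, rng)
            self._add_linear(f"layer{l}.vec_coeff", S, V * K, rng)
            self._add_linear(f"layer{l}.vec_gate", S, V, rng)
            if c.update_edges:
                self._add_linear(f"layer{l}.edge_upd", Es + S, Es, rng)
        self._add_linear("out_h0", S, S, rng)
        self._add_linear("out_h1", S, self.n_feat, rng)
        self._add_weight("out_x", V, 1, rng)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _linear(self, name: str, x: Tensor) -> Tensor:
        return x @ self.params[f"{name}.W"] + self.params[f"{name}.b"]

    def _mlp(self, name0: str, name1: str, x: Tensor) -> Tensor:
        return self._linear(name1, self._linear(name0, x).silu())

    # -- forward ----------------------------------------------------------------
    def forward(self, z: LatentState, t: int, cond: float | None = None
                ) -> tuple[Tensor, Tensor]:
        """Differentiable forward pass; returns (eps_x, eps_h) as Tensors."""
        c = self.config
        N = z.N
        edges = fully_connected_edges(N)
        send, recv = edges[:, 0], edges[:, 1]
        E = edges.shape[0]
        V, Ve, K = c.node_vector_dim, c.edge_vector_dim, (
            2 * c.node_vector_dim + c.edge_vector_dim
        )

        # scalar node inputs: features + t/T (+ normalised condition)
        ctx = [t / self.T]
        if c.condition_dim:
            if cond is None:
                raise ValueError("conditional model requires a condition value")
            ctx.append(self.normalizer(float(cond)))
        elif cond is not None:
            raise ValueError("unconditional model given a condition value")
        cols = [z.zh] + [np.full((N, 1), v) for v in ctx]
        H = self._linear("embed_h", Tensor(np.concatenate(cols, axis=1))).silu()

        # geometric constants of this graph
        node_vec_np, edge_vec_np = lift_noisy_vectors(z.zx, edges,
                                                      with_pseudo=c.use_frames)
        dist = np.linalg.norm(edge_vec_np[:, 0, :], axis=1, keepdims=True)
        e_feat = self._linear("embed_e", Tensor(np.concatenate([dist, dist**2], 1))).silu()
        # (V, n_src) @ (N, n_src, 3) -> (N, V, 3)
        chi = bmm(self.params["lift_node.W"], Tensor(node_vec_np))
        xi = Tensor(edge_vec_np) * self.params["lift_edge.W"].reshape(1, Ve, 1)
        frames_T = _frames_batch(z.zx, edges).transpose(0, 2, 1) if c.use_frames else None

        for l in range(c.n_layers):
            chi_i = gather_rows(chi, send)
            chi_j = gather_rows(chi, recv)
            parts = [
                gather_rows(H, send),
                gather_rows(H, recv),
                e_feat,
                _vec_norm(chi_i),
                _vec_norm(chi_j),
                _vec_norm(xi),
            ]
            if c.use_frames:
                ft = Tensor(frames_T)
                for vecs, width in ((chi_i, V), (chi_j, V), (xi, Ve)):
                    parts.append(bmm(vecs, ft).reshape(E, width * 3))
            msg = self._linear(f"layer{l}.msg1",
                               self._linear(f"layer{l}.msg0", concat(parts)).silu()).silu()
            if c.use_sma:
                msg = msg * self._linear(f"layer{l}.sma", msg).sigmoid()

            norm = 1.0 / max(N - 1, 1)
            agg = segment_sum(msg, send, N) * norm
            H = H + self._mlp(f"layer{l}.upd0", f"layer{l}.upd1", concat([H, agg]))

            basis = concat([chi_i, chi_j, xi], axis=1)  # (E, K, 3)
            # bounded invariant coefficients keep the reverse chain from
            # feeding back quadratically in the latent scale
            coeff = (self._linear(f"layer{l}.vec_coeff", msg).tanh() * 3.0
                     ).reshape(E, V, K)
            vec_msg = bmm(coeff, basis)  # invariant coeffs x equivariant basis
            agg_v = segment_sum(vec_msg, send, N) * norm
            gate = self._linear(f"layer{l}.vec_gate", H).sigmoid().reshape(N, V, 1)
            chi = chi + gate * agg_v

            if c.update_edges:
                e_feat = e_feat + self._linear(f"layer{l}.edge_upd",
                                               concat([e_feat, msg])).silu()

        eps_h = self._linear("out_h1", self._linear("out_h0", H).silu())
        w_out = self.params["out_x.W"].reshape(1, V, 1)
        eps_x = (chi * w_out).sum(axis=1)  # (N, 3)
        # smooth saturation at ~10 sigma: near-identity on the range standard
        # normal noise occupies, but keeps the reverse chain bounded for any
        # parameter values (the vector head saturates by norm, which is
        # rotation-invariant, so equivariance is untouched)
        eps_h = (eps_h * 0.1).tanh() * 10.0
        nrm = ((eps_x * eps_x).sum(axis=-1, keepdims=True) + 1e-12) ** 0.5
        eps_x = eps_x * ((nrm * 0.1).tanh() * 10.0 / nrm)
        eps_x = eps_x - eps_x.mean(axis=0, keepdims=True)  # re-project to zero CoG
        return eps_x, eps_h

    def predict(self, z: LatentState, t: int, cond: float | None = None
                ) -> NoisePrediction:
        """Inference-only forward pass returning plain arrays."""
        eps_x, eps_h = self.forward(z, t, cond)
        return NoisePrediction(eps_x=eps_x.data.copy(), eps_h=eps_h.data.copy())

    def as_denoiser_fn(self, cond: float | None = None):
        """Adapt to the (z, t) -> (eps_x, eps_h) callable the diffusion core uses."""

        def fn(z: LatentState, t: int):
            p = self.predict(z, t, cond)
            return p.eps_x, p.eps_h

        return fn

    # -- serialisation -----------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "n_feat": self.n_feat,
            "T": self.T,
            "normalizer": asdict(self.normalizer),
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GCPDenoiser":
        model = cls(DenoiserConfig(**d["config"]), n_feat=d["n_feat"], T=d["T"],
                    normalizer=PropertyNormalizer(**d["normalizer"]))
        for k, v in d["params"].items():
            model.params[k].data = np.asarray(v, dtype=np.float64)
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "GCPDenoiser":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
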