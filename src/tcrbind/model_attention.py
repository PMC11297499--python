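"""Reciprocal cross-attention binding model.

Three inputs — the peptide and the two assembled CDR chain sequences
(alpha and beta) — each pass through a learnable token embedding (plus
optional learned positional embedding), a multi-head self-attention layer,
and then a multi-head *reciprocal* attention layer in which each molecule
queries its binding partner:

* peptide queries the concatenation of the alpha and beta chains,
* the alpha chain queries the peptide,
* the beta chain queries the peptide.

Each branch output is projected per position, mean-pooled over real
positions, and projected again; the three branch vectors are concatenated
and fed through a two-layer head with a sigmoid.  The reciprocal layer's
normalized attention weights are returned alongside the prediction and are
the basis of the structural interpretation workflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autograd as ag
from ._autograd import Parameter, Tensor, concat, dropout, embedding, masked_softmax
from .encoding import ALPHABET, EncodedBatch, PaddingSpec


@dataclass(frozen=True)
class AttentionConfig:
    embed_dim: int = 64
    n_heads: int = 4
    branch_fc_dims: tuple = (64, 32)
    head_dims: tuple = (32, 1)
    dropout: float = 0.3
    positional: bool = True
    residual: bool = True  # residual after self-attention
    cross_residual: bool = True  # residual after reciprocal attention

    def __post_init__(self):
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.head_dims[-1] != 1:
            raise ValueError("final head dimension must be 1")


@dataclass
class AttentionMap:
    """Normalized per-head attention weights, query x key.

    ``weights`` has shape (B, n_heads, L_query, L_key); every row sums to 1
    over the valid (non-pad) key positions, and pad keys carry zero mass.
    """

    weights: np.ndarray
    query_role: str
    key_role: str

    def mean_over_heads(self) -> np.ndarray:
        return self.weights.mean(axis=1)


def _linear_init(rng, n_in, n_out):
    w = rng.normal(0.0, np.sqrt(1.0 / n_in), size=(n_in, n_out))
    return Parameter(w), Parameter(np.zeros(n_out))


class ReciprocalAttentionModel:
    """The attention component of the ensemble."""

    BRANCHES = ("pep", "a", "b")

    def __init__(self, spec: PaddingSpec, cfg: AttentionConfig = AttentionConfig(), seed: int = 0):
        self.spec = spec
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        d = cfg.embed_dim
        P: dict = {}
        lengths = {
            "pep": spec.slot_lengths["peptide"],
            "a": spec.chain_length(("cdr1a", "cdr2a", "cdr3a")),
            "b": spec.chain_length(("cdr1b", "cdr2b", "cdr3b")),
        }
        for br in self.BRANCHES:
            P[f"{br}.emb"] = Parameter(rng.normal(0, 0.1, size=(len(ALPHABET) + 1, d)))
            if cfg.positional:
                P[f"{br}.pos"] = Parameter(rng.normal(0, 0.1, size=(lengths[br], d)))
            # self-attention projections
            for proj in ("q", "k", "v", "o"):
                P[f"{br}.self.{proj}.w"], P[f"{br}.self.{proj}.b"] = _linear_init(rng, d, d)
            # reciprocal cross-attention projections
            for proj in ("q", "k", "v", "o"):
                P[f"{br}.cross.{proj}.w"], P[f"{br}.cross.{proj}.b"] = _linear_init(rng, d, d)
            # per-branch FCs
            d1, d2 = cfg.branch_fc_dims
            P[f"{br}.fc1.w"], P[f"{br}.fc1.b"] = _linear_init(rng, d, d1)
            P[f"{br}.fc2.w"], P[f"{br}.fc2.b"] = _linear_init(rng, d1, d2)
        dims = (cfg.branch_fc_dims[1] * 3,) + tuple(cfg.head_dims)
        for i in range(len(cfg.head_dims)):
            P[f"head{i}.w"], P[f"head{i}.b"] = _linear_init(rng, dims[i], dims[i + 1])
        self.params = P
        self.n_head_layers = len(cfg.head_dims)

    def parameters(self) -> list:
        return [self.params[k] for k in sorted(self.params)]

    # ------------------------------------------------------------- attention
    def _split_heads(self, x: Tensor) -> Tensor:
        B, L, d = x.shape
        H = self.cfg.n_heads
        return x.reshape(B, L, H, d // H).transpose(0, 2, 1, 3)  # (B,H,L,dh)

    def _merge_heads(self, x: Tensor) -> Tensor:
        B, H, L, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, L, H * dh)

    def _mha(self, prefix: str, q_in: Tensor, kv_in: Tensor, key_mask: np.ndarray):
        """Multi-head attention; returns (output, weights ndarray)."""
        P = self.params
        q = self._split_heads(q_in @ P[f"{prefix}.q.w"] + P[f"{prefix}.q.b"])
        k = self._split_heads(kv_in @ P[f"{prefix}.k.w"] + P[f"{prefix}.k.b"])
        v = self._split_heads(kv_in @ P[f"{prefix}.v.w"] + P[f"{prefix}.v.b"])
        dh = q.shape[-1]
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))  # (B,H,Lq,Lk)
        mask = np.asarray(key_mask)[:, None, None, :]  # broadcast over heads, queries
        w = masked_softmax(scores, mask)
        out = w @ v  # (B,H,Lq,dh)
        out = self._merge_heads(out)
        out = out @ P[f"{prefix}.o.w"] + P[f"{prefix}.o.b"]
        return out, w.data

    def _embed(self, br: str, idx: np.ndarray) -> Tensor:
        x = embedding(self.params[f"{br}.emb"], idx)
        if self.cfg.positional:
            x = x + self.params[f"{br}.pos"]
        # zero out pad positions so padding never injects signal
        return x * Tensor((idx != 0).astype(float)[:, :, None])

    def self_attend(self, br: str, idx: np.ndarray, mask: np.ndarray) -> Tensor:
        """Embedding + multi-head self-attention (with residual) for one input."""
        if not mask.any(axis=1).all():
            raise ValueError("all-pad input sequence")
        x = self._embed(br, idx)
        out, _ = self._mha(f"{br}.self", x, x, mask)
        return x + out if self.cfg.residual else out

    def reciprocal_attend(self, br: str, q_repr: Tensor, kv_repr: Tensor, kv_mask: np.ndarray,
                          key_role: str, query_role: str):
        """Cross-attention of one branch over its binding partner."""
        out, w = self._mha(f"{br}.cross", q_repr, kv_repr, kv_mask)
        rep = q_repr + out if self.cfg.cross_residual else out
        return rep, AttentionMap(w, query_role=query_role, key_role=key_role)

    # --------------------------------------------------------------- forward
    def forward(self, batch: EncodedBatch, train_rng: np.random.Generator | None = None):
        """Return (probabilities Tensor, dict of the three AttentionMaps)."""
        cfg = self.cfg
        h_pep = self.self_attend("pep", batch.pep_idx, batch.pep_mask)
        h_a = self.self_attend("a", batch.a_idx, batch.a_mask)
        h_b = self.self_attend("b", batch.b_idx, batch.b_mask)

        kv_ab = concat([h_a, h_b], axis=1)
        mask_ab = np.concatenate([batch.a_mask, batch.b_mask], axis=1)
        r_pep, map_pep = self.reciprocal_attend(
            "pep", h_pep, kv_ab, mask_ab, key_role="cdra|cdrb", query_role="peptide"
        )
        r_a, map_a = self.reciprocal_attend(
            "a", h_a, h_pep, batch.pep_mask, key_role="peptide", query_role="cdra"
        )
        r_b, map_b = self.reciprocal_attend(
            "b", h_b, h_pep, batch.pep_mask, key_role="peptide", query_role="cdrb"
        )

        vecs = []
        for br, rep, mask in (("pep", r_pep, batch.pep_mask), ("a", r_a, batch.a_mask),
                              ("b", r_b, batch.b_mask)):
            P = self.params
            h = (rep @ P[f"{br}.fc1.w"] + P[f"{br}.fc1.b"]).relu()
            # masked mean pool over real positions
            m = mask.astype(float)
            h = (h * Tensor(m[:, :, None])).sum(axis=1) * Tensor(
                (1.0 / m.sum(axis=1))[:, None]
            )
            h = (h @ P[f"{br}.fc2.w"] + P[f"{br}.fc2.b"]).relu()
            h = dropout(h, cfg.dropout, train_rng)
            vecs.append(h)
        h = concat(vecs, axis=1)
        for i in range(self.n_head_layers):
            h = h @ self.params[f"head{i}.w"] + self.params[f"head{i}.b"]
            if i < self.n_head_layers - 1:
                h = h.relu()
                h = dropout(h, cfg.dropout, train_rng)
        prob = h.reshape(-1).sigmoid()
        return prob, {"peptide": map_pep, "cdra": map_a, "cdrb": map_b}

    def predict(self, batch: EncodedBatch, chunk: int = 512) -> np.ndarray:
        out = []
        for i in range(0, len(batch), chunk):
            sel = np.arange(i, min(i + chunk, len(batch)))
            p, _ = self.forward(batch.take(sel))
            out.append(p.data)
        return np.concatenate(out)

    # ------------------------------------------------------------- checkpoint
    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.params.items():
            p.data = state[k].copy()

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, spec: PaddingSpec, cfg: AttentionConfig = AttentionConfig()) -> "ReciprocalAttentionModel":
        data = np.load(path, allow_pickle=False)
        model = cls(spec, cfg)
        model.load_state_dict({k: data[k] for k in data.files})
        return model


def peptide_cdrb_scores(
    maps: dict,
    batch: EncodedBatch,
    example: int = 0,
    aggregation: str = "mean_heads",
    region: str = "chain",
) -> np.ndarray:
    """Extract the peptide x CDR-beta attention score matrix for one example.

    Takes the peptide-as-query reciprocal map, whose key axis is the
    concatenation of the alpha- and beta-chain sequences; slices out the
    beta block, drops pad rows/columns via the masks, and aggregates over
    heads (arithmetic mean by default; ``aggregation="head:i"`` selects a
    single head).  ``region="cdr3"`` restricts the columns to the CDR3-beta
    segment.
    """
    amap = maps["peptide"]
    if amap.query_role != "peptide":
        raise ValueError("expected the peptide-as-query attention map")
    w = amap.weights[example]  # (H, Lq, Lk)
    if aggregation == "mean_heads":
        if w.shape[0] == 0:
            raise ValueError("cannot aggregate over zero heads")
        m = w.mean(axis=0)
    elif aggregation.startswith("head:"):
        m = w[int(aggregation.split(":")[1])]
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    La = batch.a_mask.shape[1]
    beta_block = m[:, La:]  # key axis = [alpha | beta]
    pep_real = batch.pep_mask[example].astype(bool)
    b_real = batch.b_mask[example].astype(bool)
    scores = beta_block[pep_real][:, b_real]
    if region == "cdr3":
        segs = {name: (start, length) for name, start, length in batch.b_segments[example]}
        start, length = segs["cdr3b"]
        # positions within the real-residue axis
        real_pos = np.flatnonzero(b_real)
        keep = [i for i, p in enumerate(real_pos) if start <= p < start + length]
        scores = scores[:, keep]
    return scores
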