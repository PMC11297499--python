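"""Convolutional paired-chain binding model.

Seven parallel convolution branches — one each for the peptide and the six
CDR loops — each apply a 1-D convolution with kernel size 2 over the
one-hot sequence, max pooling with kernel size 2, flattening, and a fully
connected projection.  The seven branch vectors are concatenated and
passed through a three-layer fully connected head ending in a sigmoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from ._autograd import Parameter, Tensor, concat, dropout
from .encoding import ALPHABET, SLOTS, EncodedBatch, PaddingSpec


@dataclass(frozen=True)
class CNNConfig:
    conv_channels: int = 32
    kernel_size: int = 2  # fixed by the architecture
    pool_size: int = 2  # fixed by the architecture
    branch_fc_dim: int = 32
    head_dims: tuple = (64, 16, 1)
    dropout: float = 0.3
    activation: str = "relu"

    def __post_init__(self):
        if self.head_dims[-1] != 1:
            raise ValueError("final head dimension must be 1")


def _linear_init(rng, n_in, n_out):
    w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
    return Parameter(w), Parameter(np.zeros(n_out))


class PairedChainCNN:
    """The CNN component of the ensemble."""

    def __init__(self, spec: PaddingSpec, cfg: CNNConfig = CNNConfig(), seed: int = 0):
        self.spec = spec
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        C = cfg.conv_channels
        k = cfg.kernel_size
        self.params: dict = {}
        concat_dim = 0
        for slot in SLOTS:
            L = spec.slot_lengths[slot]
            conv_out = L - k + 1
            pooled = conv_out // cfg.pool_size
            if pooled < 1:
                raise ValueError(f"slot {slot} too short for conv+pool (L={L})")
            self.params[f"{slot}.conv.w"], self.params[f"{slot}.conv.b"] = _linear_init(
                rng, 20 * k, C
            )
            self.params[f"{slot}.fc.w"], self.params[f"{slot}.fc.b"] = _linear_init(
                rng, pooled * C, cfg.branch_fc_dim
            )
            concat_dim += cfg.branch_fc_dim
        dims = (concat_dim,) + tuple(cfg.head_dims)
        for i in range(len(cfg.head_dims)):
            self.params[f"head{i}.w"], self.params[f"head{i}.b"] = _linear_init(
                rng, dims[i], dims[i + 1]
            )
        self.n_head_layers = len(cfg.head_dims)

    def parameters(self) -> list:
        return [self.params[k] for k in sorted(self.params)]

    # ----------------------------------------------------------------- forward
    def conv_branch(self, x: np.ndarray, slot: str, train_rng=None) -> Tensor:
        """One branch: conv(k=2) -> ReLU -> maxpool(k=2) -> flatten -> FC -> ReLU.

        ``x`` is a (B, 20, L) one-hot stack; the output is (B, branch_fc_dim)
        regardless of the slot length.
        """
        B, _, L = x.shape
        k = self.cfg.kernel_size
        # kernel-2 conv as a windowed matmul: stack the k shifted views
        xt = Tensor(x)
        views = [xt[:, :, i : L - k + 1 + i] for i in range(k)]
        win = concat(views, axis=1)  # (B, 20*k, L-k+1)
        win = win.swapaxes(1, 2)  # (B, L-k+1, 20*k)
        h = (win @ self.params[f"{slot}.conv.w"] + self.params[f"{slot}.conv.b"]).relu()
        h = h.swapaxes(1, 2)  # (B, C, L-k+1)
        h = h.maxpool1d(self.cfg.pool_size)
        h = h.reshape(B, -1)
        h = (h @ self.params[f"{slot}.fc.w"] + self.params[f"{slot}.fc.b"]).relu()
        return h

    def forward(self, batch: EncodedBatch, train_rng: np.random.Generator | None = None) -> Tensor:
        """Probability of binding per record, strictly inside (0, 1).

        Pass a Generator as ``train_rng`` to enable dropout (training mode);
        evaluation mode (None) is deterministic.
        """
        missing = [s for s in SLOTS if s not in batch.one_hots]
        if missing:
            raise ValueError(f"batch lacks one-hot inputs for {missing}")
        branches = [self.conv_branch(batch.one_hots[s], s) for s in SLOTS]
        h = concat(branches, axis=1)
        for i in range(self.n_head_layers):
            h = h @ self.params[f"head{i}.w"] + self.params[f"head{i}.b"]
            if i < self.n_head_layers - 1:
                h = h.relu()
                h = dropout(h, self.cfg.dropout, train_rng)
        return h.reshape(-1).sigmoid()

    def predict(self, batch: EncodedBatch, chunk: int = 512) -> np.ndarray:
        """Evaluation-mode probabilities as a plain array."""
        out = []
        for i in range(0, len(batch), chunk):
            sel = np.arange(i, min(i + chunk, len(batch)))
            out.append(self.forward(batch.take(sel)).data)
        return np.concatenate(out)

    # ------------------------------------------------------------- checkpoint
    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, p in self.params.items():
            p.data = state[k].copy()

    def save(self, path) -> None:
        meta = {"spec": self.spec.to_json(), "cfg": repr(self.cfg), "alphabet": ALPHABET}
        np.savez(path, __meta__=np.array([str(meta)]), **self.state_dict())

    @classmethod
    def load(cls, path, spec: PaddingSpec, cfg: CNNConfig = CNNConfig()) -> "PairedChainCNN":
        data = np.load(path, allow_pickle=False)
        model = cls(spec, cfg)
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return model
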