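"""Numeric encodings of paired-chain TCR-epitope records.

Two encodings feed the two model families:

* per-sequence one-hot matrices (20 x slot-length) for the convolutional
  model — one matrix each for the peptide and the six CDR loops;
* padded integer token sequences with masks for the attention model, where
  the three CDR loops of each chain are combined into a single "chain
  sequence", either by padding each loop to its slot length and then
  concatenating (``pad_then_concat``, the training default) or by
  concatenating the raw loops first and padding the result
  (``concat_then_pad``, used by the structural interpretation workflow so
  that chain positions map one-to-one onto residues).

The amino-acid alphabet is the 20 standard residues in alphabetical
one-letter order; token index 0 is reserved for padding.  The index map is
frozen here and serialized with every model checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_TO_INDEX = {aa: i + 1 for i, aa in enumerate(ALPHABET)}  # 0 = pad
INDEX_TO_AA = {i + 1: aa for i, aa in enumerate(ALPHABET)}

#: canonical slot names, in fixed order
SLOTS = ("peptide", "cdr1a", "cdr2a", "cdr3a", "cdr1b", "cdr2b", "cdr3b")
CHAIN_A_SLOTS = ("cdr1a", "cdr2a", "cdr3a")
CHAIN_B_SLOTS = ("cdr1b", "cdr2b", "cdr3b")


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class PaddingSpec:
    """Frozen per-slot maximum lengths plus the chain-assembly mode."""

    slot_lengths: dict  # slot name -> padded length
    mode: str = "pad_then_concat"  # or "concat_then_pad"

    def __post_init__(self):
        if self.mode not in ("pad_then_concat", "concat_then_pad"):
            raise EncodingError(f"unknown padding mode {self.mode!r}")
        missing = [s for s in SLOTS if s not in self.slot_lengths]
        if missing:
            raise EncodingError(f"slot lengths missing for {missing}")

    def chain_length(self, slots=CHAIN_B_SLOTS) -> int:
        """Total padded length of an assembled chain sequence."""
        return sum(self.slot_lengths[s] for s in slots)

    def to_json(self) -> str:
        return json.dumps(
            {"slot_lengths": self.slot_lengths, "mode": self.mode, "alphabet": ALPHABET}
        )

    @classmethod
    def from_json(cls, s: str) -> "PaddingSpec":
        d = json.loads(s)
        if d.get("alphabet", ALPHABET) != ALPHABET:
            raise EncodingError("checkpoint alphabet does not match this build")
        return cls(slot_lengths=d["slot_lengths"], mode=d["mode"])


def fit_padding_spec(dataset, margin: int = 0, mode: str = "pad_then_concat") -> PaddingSpec:
    """Freeze per-slot lengths from training data: max observed + margin."""
    if len(dataset) == 0:
        raise EncodingError("cannot fit a padding spec on an empty dataset")
    lengths = {s: 0 for s in SLOTS}
    for rec in dataset.records:
        for s in SLOTS:
            lengths[s] = max(lengths[s], len(getattr(rec, s)))
    return PaddingSpec({s: n + margin for s, n in lengths.items()}, mode=mode)


def one_hot(seq: str, length: int) -> np.ndarray:
    """20 x length one-hot matrix; padding columns are all-zero."""
    if len(seq) > length:
        raise EncodingError(f"sequence of length {len(seq)} exceeds slot length {length}")
    m = np.zeros((len(ALPHABET), length), dtype=np.float64)
    for i, aa in enumerate(seq):
        try:
            m[AA_TO_INDEX[aa] - 1, i] = 1.0
        except KeyError:
            raise EncodingError(f"invalid residue {aa!r}") from None
    return m


def decode_one_hot(m: np.ndarray) -> str:
    """Inverse of :func:`one_hot` (real columns only)."""
    out = []
    for col in m.T:
        if col.sum() == 0:
            continue
        out.append(ALPHABET[int(col.argmax())])
    return "".join(out)


@dataclass
class TokenSequence:
    """Padded integer-encoded sequence with mask and segment provenance.

    ``segment_map`` lists ``(segment_name, start, length)`` spans covering
    exactly the real (non-pad) positions, so chain sequences can be decoded
    back into their constituent CDR loops.
    """

    indices: np.ndarray  # int, 0 = pad
    mask: np.ndarray  # 1 = real residue
    segment_map: list = field(default_factory=list)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.mask = np.asarray(self.mask, dtype=np.int64)
        if self.indices.shape != self.mask.shape:
            raise EncodingError("indices and mask shapes differ")
        if not np.array_equal(self.mask == 0, self.indices == 0):
            raise EncodingError("mask must be 0 exactly at pad positions")

    def __len__(self) -> int:
        return len(self.indices)

    def decode(self) -> str:
        return "".join(INDEX_TO_AA[i] for i in self.indices if i != 0)

    def decode_segments(self) -> dict:
        out = {}
        for name, start, length in self.segment_map:
            span = self.indices[start : start + length]
            out[name] = "".join(INDEX_TO_AA[i] for i in span if i != 0)
        return out


def encode_tokens(seq: str, length: int, name: str = "seq") -> TokenSequence:
    if len(seq) > length:
        raise EncodingError(f"{name}: sequence of length {len(seq)} exceeds slot {length}")
    idx = np.zeros(length, dtype=np.int64)
    for i, aa in enumerate(seq):
        try:
            idx[i] = AA_TO_INDEX[aa]
        except KeyError:
            raise EncodingError(f"{name}: invalid residue {aa!r}") from None
    mask = (idx != 0).astype(np.int64)
    return TokenSequence(idx, mask, [(name, 0, len(seq))])


def build_chain(cdr1: str, cdr2: str, cdr3: str, spec: PaddingSpec, chain: str = "b") -> TokenSequence:
    """Assemble one chain's three CDR loops into a single token sequence."""
    slots = CHAIN_B_SLOTS if chain == "b" else CHAIN_A_SLOTS
    cdrs = (cdr1, cdr2, cdr3)
    total = spec.chain_length(slots)
    if spec.mode == "pad_then_concat":
        idx = np.zeros(total, dtype=np.int64)
        segs = []
        offset = 0
        for slot, seq in zip(slots, cdrs):
            L = spec.slot_lengths[slot]
            if len(seq) > L:
                raise EncodingError(f"{slot}: length {len(seq)} exceeds slot {L}")
            for i, aa in enumerate(seq):
                idx[offset + i] = AA_TO_INDEX[aa]
            segs.append((slot, offset, len(seq)))
            offset += L
    else:  # concat_then_pad
        joined = cdr1 + cdr2 + cdr3
        if len(joined) > total:
            raise EncodingError(f"concatenated chain length {len(joined)} exceeds {total}")
        idx = np.zeros(total, dtype=np.int64)
        segs = []
        offset = 0
        for slot, seq in zip(slots, cdrs):
            for i, aa in enumerate(seq):
                idx[offset + i] = AA_TO_INDEX[aa]
            segs.append((slot, offset, len(seq)))
            offset += len(seq)
    mask = (idx != 0).astype(np.int64)
    return TokenSequence(idx, mask, segs)


@dataclass
class EncodedExample:
    """All numeric views of one record: seven one-hot matrices for the CNN
    path and three token sequences (peptide, chain alpha, chain beta) for
    the attention path."""

    one_hots: dict  # slot -> 20 x L matrix
    peptide: TokenSequence
    chain_a: TokenSequence
    chain_b: TokenSequence
    label: int | None = None


def encode_record(rec, spec: PaddingSpec) -> EncodedExample:
    one_hots = {s: one_hot(getattr(rec, s), spec.slot_lengths[s]) for s in SLOTS}
    return EncodedExample(
        one_hots=one_hots,
        peptide=encode_tokens(rec.peptide, spec.slot_lengths["peptide"], "peptide"),
        chain_a=build_chain(rec.cdr1a, rec.cdr2a, rec.cdr3a, spec, chain="a"),
        chain_b=build_chain(rec.cdr1b, rec.cdr2b, rec.cdr3b, spec, chain="b"),
        label=rec.label,
    )


@dataclass
class EncodedBatch:
    """Stacked arrays for a list of records, ready for a model forward pass."""

    one_hots: dict  # slot -> (B, 20, L)
    pep_idx: np.ndarray
    pep_mask: np.ndarray
    a_idx: np.ndarray
    a_mask: np.ndarray
    b_idx: np.ndarray
    b_mask: np.ndarray
    b_segments: list  # per-example segment maps of the beta chain
    labels: np.ndarray | None

    def __len__(self) -> int:
        return len(self.pep_idx)

    def take(self, sel: np.ndarray) -> "EncodedBatch":
        lab = None if self.labels is None else self.labels[sel]
        return EncodedBatch(
            {s: m[sel] for s, m in self.one_hots.items()},
            self.pep_idx[sel], self.pep_mask[sel],
            self.a_idx[sel], self.a_mask[sel],
            self.b_idx[sel], self.b_mask[sel],
            [self.b_segments[i] for i in np.atleast_1d(sel)] if isinstance(sel, np.ndarray) else self.b_segments,
            lab,
        )


def encode_batch(records, spec: PaddingSpec) -> EncodedBatch:
    """Encode a list of records into stacked arrays."""
    exs = [encode_record(r, spec) for r in records]
    if not exs:
        raise EncodingError("cannot encode an empty record list")
    labels = None
    if all(e.label is not None for e in exs):
        labels = np.array([e.label for e in exs], dtype=np.float64)
    return EncodedBatch(
        one_hots={s: np.stack([e.one_hots[s] for e in exs]) for s in SLOTS},
        pep_idx=np.stack([e.peptide.indices for e in exs]),
        pep_mask=np.stack([e.peptide.mask for e in exs]),
        a_idx=np.stack([e.chain_a.indices for e in exs]),
        a_mask=np.stack([e.chain_a.mask for e in exs]),
        b_idx=np.stack([e.chain_b.indices for e in exs]),
        b_mask=np.stack([e.chain_b.mask for e in exs]),
        b_segments=[e.chain_b.segment_map for e in exs],
        labels=labels,
    )
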