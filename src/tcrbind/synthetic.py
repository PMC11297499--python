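"""Synthetic paired-chain TCR-epitope repertoires with controllable signal.

The generator emulates the statistical features that make real
TCR-epitope data hard, without any biophysics:

* a configurable number of peptides, each with a cognate-TCR count drawn
  either uniformly or from a power law (the heavy-tailed peptide imbalance
  of public databases, where a few epitopes dominate);
* a peptide-specific 3-mer (by default) *motif* planted at a fixed offset
  inside CDR3-beta in a ``motif_strength`` fraction of that peptide's
  binders — the learnable signal linking receptor to epitope;
* optional *cross-reactive* TCRs listed under a second peptide;
* a negative-control pool whose residue composition is shifted away from
  the binder distribution by ``control_composition_shift`` (the bias that
  makes control-based negatives artificially easy to classify);
* optional *similarity linkage*: related peptides (point mutants of each
  other) carry related motifs, so sequence similarity between training and
  test peptides translates into transferable signal — the mechanism behind
  the observation that test peptides closest to the training set are
  predicted best.

Ground truth (which record carries which motif, and where) is returned so
tests can assert signal recovery, and structure fixtures can place
"contacts" at the planted positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ControlPool, Dataset, DistanceMap, TCRRecord
from .encoding import ALPHABET


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic benchmark.

    Defaults are the acceptance-scale repertoire: 20 peptides with 100
    cognate TCRs each and a fully penetrant 3-residue motif.
    """

    n_peptides: int = 20
    peptide_length: tuple = (9, 9)
    tcrs_per_peptide: int = 100
    imbalance_exponent: float = 0.0  # 0 = uniform counts; >0 = power-law tail
    cdr_length_ranges: dict = field(
        default_factory=lambda: {
            "cdr1a": (5, 7), "cdr2a": (5, 8), "cdr3a": (10, 16),
            "cdr1b": (5, 6), "cdr2b": (5, 7), "cdr3b": (12, 18),
        }
    )
    motif_strength: float = 1.0
    motif_length: int = 3
    motif_offset: int = 3  # position inside CDR3-beta
    cross_reactivity_rate: float = 0.0
    control_pool_size: int = 2000
    control_composition_shift: float = 0.3
    similarity_link: bool = False
    seed: int = 0

    def __post_init__(self):
        for name in ("motif_strength", "cross_reactivity_rate", "control_composition_shift"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorError(f"{name} must be in [0, 1], got {v}")
        if self.motif_offset + self.motif_length > self.cdr_length_ranges["cdr3b"][0]:
            raise GeneratorError("motif does not fit inside the shortest CDR3-beta")
        if self.n_peptides < 1 or self.tcrs_per_peptide < 1:
            raise GeneratorError("n_peptides and tcrs_per_peptide must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream assertions."""

    motif_of_peptide: dict  # peptide -> motif string
    motif_offset: int
    carries_motif: list  # per record: bool
    cross_reactive_pairs: list  # (peptide_a, peptide_b, six-CDR tuple)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 20, size=length))


def _peptides(cfg: GeneratorConfig, rng: np.random.Generator) -> list:
    lo, hi = cfg.peptide_length
    peps: list = []
    seen: set = set()
    while len(peps) < cfg.n_peptides:
        if cfg.similarity_link and peps and rng.random() < 0.5:
            # point mutant of an existing peptide -> small Levenshtein distance
            base = peps[int(rng.integers(0, len(peps)))]
            pos = int(rng.integers(0, len(base)))
            p = base[:pos] + ALPHABET[int(rng.integers(0, 20))] + base[pos + 1 :]
        else:
            p = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if p not in seen:
            seen.add(p)
            peps.append(p)
    return peps


def _motifs(cfg: GeneratorConfig, peptides: list, rng: np.random.Generator) -> dict:
    if cfg.similarity_link:
        # character-wise substitution cipher of the peptide prefix: similar
        # peptides get similar motifs, so signal transfers across mutants
        cipher = {a: ALPHABET[j] for a, j in zip(ALPHABET, rng.permutation(20))}
        return {p: "".join(cipher[c] for c in p[: cfg.motif_length]) for p in peptides}
    return {p: _random_seq(rng, cfg.motif_length) for p in peptides}


def _counts(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.imbalance_exponent <= 0:
        return np.full(cfg.n_peptides, cfg.tcrs_per_peptide, dtype=int)
    # power-law ranks scaled so the mean stays ~tcrs_per_peptide
    ranks = np.arange(1, cfg.n_peptides + 1, dtype=float)
    w = ranks ** (-cfg.imbalance_exponent)
    w = w / w.sum() * cfg.n_peptides * cfg.tcrs_per_peptide
    counts = np.maximum(1, np.round(w)).astype(int)
    return rng.permutation(counts)


def _random_tcr(cfg: GeneratorConfig, rng: np.random.Generator) -> dict:
    tcr = {}
    for slot, (lo, hi) in cfg.cdr_length_ranges.items():
        tcr[slot] = _random_seq(rng, int(rng.integers(lo, hi + 1)))
    return tcr


def _plant(cdr3b: str, motif: str, offset: int) -> str:
    return cdr3b[:offset] + motif + cdr3b[offset + len(motif) :]


def generate_repertoire(cfg: GeneratorConfig) -> tuple:
    """Generate (positive Dataset, ControlPool, GroundTruth).

    All records are label-1 binders; negatives are manufactured downstream
    by the sampling module, exactly as for real data.
    """
    rng = np.random.default_rng(cfg.seed)
    peptides = _peptides(cfg, rng)
    motifs = _motifs(cfg, peptides, rng)
    counts = _counts(cfg, rng)

    records: list = []
    carries: list = []
    seen_pairs: set = set()
    for p, n in zip(peptides, counts):
        made = 0
        while made < n:
            tcr = _random_tcr(cfg, rng)
            has_motif = rng.random() < cfg.motif_strength
            if has_motif:
                tcr["cdr3b"] = _plant(tcr["cdr3b"], motifs[p], cfg.motif_offset)
            rec = TCRRecord(
                p, tcr["cdr1a"], tcr["cdr2a"], tcr["cdr3a"],
                tcr["cdr1b"], tcr["cdr2b"], tcr["cdr3b"],
                label=1, origin="synthetic",
            )
            if rec.pair in seen_pairs:
                continue
            seen_pairs.add(rec.pair)
            records.append(rec)
            carries.append(has_motif)
            made += 1

    # cross-reactive TCRs: duplicate a binder under a second peptide, with
    # the second peptide's motif planted right after the first (when it fits)
    xr_pairs: list = []
    if cfg.cross_reactivity_rate > 0 and len(peptides) > 1:
        n_xr = int(round(cfg.cross_reactivity_rate * len(records)))
        cand = rng.choice(len(records), size=min(n_xr, len(records)), replace=False)
        for ci in sorted(int(c) for c in cand):
            rec = records[ci]
            others = [p for p in peptides if p != rec.peptide]
            p2 = others[int(rng.integers(0, len(others)))]
            off2 = cfg.motif_offset + cfg.motif_length
            cdr3b = rec.cdr3b
            if off2 + cfg.motif_length <= len(cdr3b):
                cdr3b = _plant(cdr3b, motifs[p2], off2)
            rec2 = TCRRecord(
                p2, rec.cdr1a, rec.cdr2a, rec.cdr3a, rec.cdr1b, rec.cdr2b, cdr3b,
                label=1, origin="synthetic",
            )
            if rec2.pair in seen_pairs:
                continue
            seen_pairs.add(rec2.pair)
            records.append(rec2)
            carries.append(True)
            xr_pairs.append((rec.peptide, p2, rec2.tcr))

    # control pool with Dirichlet-perturbed residue frequencies; shift 0
    # reproduces the uniform composition of the binders
    base = np.full(20, 1 / 20)
    perturbed = rng.dirichlet(np.full(20, 2.0))
    freqs = (1 - cfg.control_composition_shift) * base + cfg.control_composition_shift * perturbed
    pool_tcrs: list = []
    pool_seen: set = set()
    while len(pool_tcrs) < cfg.control_pool_size:
        tcr = {}
        for slot, (lo, hi) in cfg.cdr_length_ranges.items():
            L = int(rng.integers(lo, hi + 1))
            tcr[slot] = "".join(
                ALPHABET[i] for i in rng.choice(20, size=L, p=freqs)
            )
        t = (tcr["cdr1a"], tcr["cdr2a"], tcr["cdr3a"], tcr["cdr1b"], tcr["cdr2b"], tcr["cdr3b"])
        if t in pool_seen:
            continue
        pool_seen.add(t)
        pool_tcrs.append(t)

    ds = Dataset(records, {"generator_seed": cfg.seed})
    truth = GroundTruth(motifs, cfg.motif_offset, carries, xr_pairs)
    return ds, ControlPool(pool_tcrs), truth


def generate_structure_fixture(
    rec: TCRRecord,
    truth: GroundTruth,
    seed: int,
    complex_id: str = "synthetic",
    close_range: tuple = (4.0, 9.0),
    far_range: tuple = (12.0, 40.0),
) -> DistanceMap:
    """Synthetic peptide x CDR-beta distance map for one binder.

    The CDR-beta axis is the concatenation CDR1b + CDR2b + CDR3b (matching
    the concat-then-pad chain encoding).  Pairs between any peptide residue
    and a planted-motif position draw distances from ``close_range``
    (within the <10 A "close" class by construction); all other pairs draw
    from ``far_range``.
    """
    rng = np.random.default_rng(seed)
    cdrb = rec.cdr1b + rec.cdr2b + rec.cdr3b
    motif = truth.motif_of_peptide.get(rec.peptide)
    if motif is None:
        raise GeneratorError(f"peptide {rec.peptide} unknown to the ground truth")
    start = len(rec.cdr1b) + len(rec.cdr2b) + truth.motif_offset
    motif_cols = set(range(start, start + len(motif)))
    d = rng.uniform(*far_range, size=(len(rec.peptide), len(cdrb)))
    for j in motif_cols:
        d[:, j] = rng.uniform(*close_range, size=len(rec.peptide))
    return DistanceMap(complex_id, rec.peptide, cdrb, d)
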