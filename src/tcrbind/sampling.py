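"""Dataset-construction machinery: cross-validation splits, negative-pair
generation, per-peptide down-sampling, and leakage auditing.

Two split modes are supported.  A *random* split distributes positive pairs
uniformly across k folds.  A *strict* (peptide-disjoint) split first
partitions the distinct peptides across folds and sends every pair to its
peptide's fold, so a peptide never appears in two folds — the setting that
measures generalization to unseen epitopes.

Negatives are manufactured per partition, never across partitions, to
avoid the leakage that arises when a TCR positive in one partition is
re-used as a negative in another:

* *shuffled* negatives pair a peptide with TCRs that bind other peptides
  of the same partition (exact positive pairs are excluded — the
  false-negative guard operates at the exact-pair level);
* *control* negatives pair a peptide with TCRs drawn from an unlabeled
  background pool;
* *mixed* negatives combine both at stated ratios.

All operations are deterministic functions of their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data_io import ControlPool, Dataset, TCRRecord


class SplitError(ValueError):
    pass


@dataclass(frozen=True)
class SplitPlan:
    """Assignment of each record (by position) to one of k folds."""

    k: int
    fold_of_record: tuple
    mode: str  # "random" | "strict"
    seed: int

    def fold_indices(self, fold: int) -> list:
        return [i for i, f in enumerate(self.fold_of_record) if f == fold]

    def fold_sizes(self) -> list:
        return [len(self.fold_indices(f)) for f in range(self.k)]

    def apply(self, ds: Dataset) -> Dataset:
        return ds.with_partitions(self.fold_of_record)


@dataclass(frozen=True)
class CVAssignment:
    """The (test, validation, train) fold triples of the modified nested CV:
    one inner loop per outer loop instead of a full inner rotation."""

    k: int
    triples: tuple  # of (test_fold, val_fold, tuple(train_folds))


@dataclass(frozen=True)
class NegativeSpec:
    strategy: str  # "shuffle" | "control" | "mixed"
    ratio: tuple  # (positives, negatives), e.g. (1, 5)
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("shuffle", "control", "mixed"):
            raise SplitError(f"unknown negative strategy {self.strategy!r}")
        p, n = self.ratio
        if not (isinstance(p, int) and isinstance(n, int) and p > 0 and n >= 0):
            raise SplitError(f"ratio must be positive integers, got {self.ratio}")

    @property
    def per_positive(self) -> int:
        p, n = self.ratio
        if n % p:
            raise SplitError(f"ratio {self.ratio} is not an integer count per positive")
        return n // p


def _require_positives(ds: Dataset, op: str) -> None:
    if any(r.label != 1 for r in ds.records):
        raise SplitError(f"{op} expects a positives-only dataset")


def random_kfold(ds: Dataset, k: int, seed: int) -> SplitPlan:
    """Uniformly split positive pairs into k folds of near-equal size."""
    _require_positives(ds, "random_kfold")
    if k < 2:
        raise SplitError("k must be >= 2")
    n = len(ds)
    if n < k:
        raise SplitError(f"cannot split {n} records into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return SplitPlan(k, tuple(int(f) for f in folds), "random", seed)


def strict_split(ds: Dataset, k: int, seed: int) -> SplitPlan:
    """Peptide-disjoint split: peptides are shuffled and dealt round-robin
    across folds; every pair follows its peptide."""
    _require_positives(ds, "strict_split")
    peptides = ds.peptides()
    if len(peptides) < k:
        raise SplitError(f"{len(peptides)} distinct peptides < k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(peptides))
    fold_of_pep = {peptides[j]: i % k for i, j in enumerate(order)}
    folds = tuple(fold_of_pep[r.peptide] for r in ds.records)
    return SplitPlan(k, folds, "strict", seed)


def nested_cv_plan(k: int) -> CVAssignment:
    """k outer loops; validation fold = cyclic successor of the test fold;
    the remaining k-2 folds train."""
    if k < 3:
        raise SplitError("nested CV needs k >= 3")
    triples = []
    for t in range(k):
        v = (t + 1) % k
        train = tuple(f for f in range(k) if f not in (t, v))
        triples.append((t, v, train))
    return CVAssignment(k, tuple(triples))


# ------------------------------------------------------------- negatives


def shuffle_negatives(
    fold_records: list,
    spec: NegativeSpec,
    forbidden_pairs: set | None = None,
    strict: bool = False,
) -> list:
    """Generate shuffled negatives within one partition.

    For each positive (peptide p, TCR t), draw up to ``spec.per_positive``
    TCRs that bind *other* peptides of the same partition and pair them
    with p as label-0 records.  A drawn pair never duplicates a positive
    pair from ``forbidden_pairs`` (default: the positives of this
    partition) and negatives are unique.  If a peptide's partition lacks
    enough eligible TCRs, the shortfall is warned about (or raised when
    ``strict``).
    """
    if spec.strategy != "shuffle":
        raise SplitError("shuffle_negatives requires strategy='shuffle'")
    positives = [r for r in fold_records if r.label == 1]
    if forbidden_pairs is None:
        forbidden_pairs = {r.pair for r in positives}
    rng = np.random.default_rng(spec.seed)
    r_per = spec.per_positive

    # TCR -> set of peptides it binds, within this partition
    peptides_of_tcr: dict = {}
    for rec in positives:
        peptides_of_tcr.setdefault(rec.tcr, set()).add(rec.peptide)
    all_tcrs = sorted(peptides_of_tcr)  # stable order for determinism

    out: list = []
    emitted: set = set()
    shortfall: dict = {}
    for rec in positives:
        p = rec.peptide
        eligible = [
            t for t in all_tcrs
            if p not in peptides_of_tcr[t]
            and (p, t) not in forbidden_pairs
            and (p, t) not in emitted
        ]
        n_draw = min(r_per, len(eligible))
        if n_draw < r_per:
            shortfall[p] = shortfall.get(p, 0) + (r_per - n_draw)
        if n_draw == 0:
            continue
        chosen = rng.choice(len(eligible), size=n_draw, replace=False)
        for ci in sorted(int(c) for c in chosen):
            t = eligible[ci]
            emitted.add((p, t))
            out.append(
                TCRRecord(p, *t, label=0, partition=rec.partition, origin="shuffled_negative")
            )
    if shortfall:
        msg = (
            f"shuffle_negatives: could not reach ratio 1:{r_per} for "
            f"{len(shortfall)} peptide(s); total shortfall "
            f"{sum(shortfall.values())} negative(s)"
        )
        if strict:
            raise SplitError(msg)
        warnings.warn(msg)
    return out


def control_negatives(fold_records: list, pool: ControlPool, spec: NegativeSpec) -> list:
    """Pair each partition peptide with TCRs drawn from the control pool.

    For a peptide with m positives at ratio 1:r, m*r distinct pool TCRs are
    drawn (without replacement within that peptide's draw) and labeled 0.
    """
    if spec.strategy != "control":
        raise SplitError("control_negatives requires strategy='control'")
    if len(pool) == 0:
        raise SplitError("control pool is empty")
    positives = [r for r in fold_records if r.label == 1]
    rng = np.random.default_rng(spec.seed)
    r_per = spec.per_positive

    by_pep: dict = {}
    for rec in positives:
        by_pep.setdefault(rec.peptide, []).append(rec)
    out: list = []
    for p in sorted(by_pep):
        need = len(by_pep[p]) * r_per
        if need > len(pool):
            raise SplitError(
                f"control pool of {len(pool)} cannot supply {need} distinct TCRs for {p}"
            )
        chosen = rng.choice(len(pool), size=need, replace=False)
        part = by_pep[p][0].partition
        for ci in sorted(int(c) for c in chosen):
            out.append(
                TCRRecord(p, *pool.tcrs[ci], label=0, partition=part, origin="control_negative")
            )
    return out


def mixed_negatives(
    fold_records: list,
    pool: ControlPool,
    shuffle_ratio: tuple,
    control_ratio: tuple,
    seed: int,
    forbidden_pairs: set | None = None,
) -> list:
    """Union of shuffled and control negatives at their stated ratios
    (e.g. shuffling 1:3 plus controls 1:2 for a combined 1:5)."""
    out: list = []
    if shuffle_ratio[1] > 0:
        out += shuffle_negatives(
            fold_records,
            NegativeSpec("shuffle", tuple(shuffle_ratio), seed),
            forbidden_pairs=forbidden_pairs,
        )
    if control_ratio[1] > 0:
        out += control_negatives(
            fold_records, pool, NegativeSpec("control", tuple(control_ratio), seed + 1)
        )
    return out


def balance_downsample(ds: Dataset, cap: int, seed: int) -> Dataset:
    """Keep at most ``cap`` positives per peptide, chosen uniformly at
    random; peptides under the cap keep all their pairs.  The choice does
    not depend on the input row order."""
    _require_positives(ds, "balance_downsample")
    if cap < 1:
        raise SplitError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    kept: list = []
    for p in ds.peptides():  # sorted -> order independent
        idx = ds.peptide_index[p]
        recs = sorted((ds.records[i] for i in idx), key=lambda r: r.tcr)
        if len(recs) > cap:
            chosen = rng.choice(len(recs), size=cap, replace=False)
            recs = [recs[int(c)] for c in sorted(chosen)]
        kept.extend(recs)
    return Dataset(kept, {**ds.metadata, "downsampled_cap": cap})


# ---------------------------------------------------------------- auditing


@dataclass
class LeakageReport:
    """Result of a train/test leakage audit."""

    conflicting_pairs: list  # exact pairs appearing with both labels across sets
    shared_pairs: list  # exact pairs appearing (same label) in both sets
    shared_peptides: list  # strict mode only
    mode: str

    @property
    def clean(self) -> bool:
        if self.mode == "strict":
            return not self.conflicting_pairs and not self.shared_peptides
        return not self.conflicting_pairs


def audit_leakage(train: Dataset, test: Dataset, mode: str = "random") -> LeakageReport:
    """Detect information leakage between partitions.

    Flags exact (peptide, six-CDR) pairs appearing with conflicting labels
    across the two sets (the shuffling hazard), and, under ``strict`` mode,
    peptides shared between the sets at all.
    """
    train_pairs: dict = {}
    for r in train.records:
        train_pairs.setdefault(r.pair, set()).add(r.label)
    conflicts, shared = [], []
    for r in test.records:
        labels = train_pairs.get(r.pair)
        if labels is None:
            continue
        if any(l != r.label for l in labels):
            conflicts.append(r.pair)
        if r.label in labels:
            shared.append(r.pair)
    shared_peps = []
    if mode == "strict":
        shared_peps = sorted(
            {r.peptide for r in train.records if r.label == 1}
            & {r.peptide for r in test.records if r.label == 1}
        )
    return LeakageReport(conflicts, shared, shared_peps, mode)


def build_cv_dataset(
    positives: Dataset,
    plan: SplitPlan,
    negative: str = "shuffle",
    ratio: tuple = (1, 5),
    pool: ControlPool | None = None,
    mixed_ratios: tuple | None = None,
    seed: int = 0,
) -> Dataset:
    """Assemble a full labeled CV dataset: assign folds to positives, then
    generate negatives independently within each fold.

    The false-negative guard for shuffled negatives uses the positive pairs
    of the *entire* dataset, so a generated negative never collides with a
    positive of any partition.
    """
    _require_positives(positives, "build_cv_dataset")
    assigned = plan.apply(positives)
    forbidden = {r.pair for r in assigned.records}
    out: list = list(assigned.records)
    for fold in range(plan.k):
        fold_recs = [assigned.records[i] for i in plan.fold_indices(fold)]
        if not fold_recs:
            continue
        fseed = seed * 1000 + fold
        if negative == "shuffle":
            negs = shuffle_negatives(
                fold_recs, NegativeSpec("shuffle", ratio, fseed), forbidden_pairs=forbidden
            )
        elif negative == "control":
            negs = control_negatives(fold_recs, pool, NegativeSpec("control", ratio, fseed))
        elif negative == "mixed":
            sh, ct = mixed_ratios
            negs = mixed_negatives(fold_recs, pool, sh, ct, fseed, forbidden_pairs=forbidden)
        else:
            raise SplitError(f"unknown negative strategy {negative!r}")
        out.extend(replace(n, partition=fold) for n in negs)
    return Dataset(out, {**positives.metadata, "negatives": negative, "k": plan.k})
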