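"""Reading, validating and writing paired-chain TCR-epitope data.

File formats follow the convention of the public NetTCR-style benchmark
tables: delimited text with a header row and columns

    ``peptide, A1, A2, A3, B1, B2, B3, binder[, partition]``

holding the epitope peptide, the six CDR loops (CDR1/2/3 of the alpha and
beta chains), the binary binding label, and an optional cross-validation
fold index.  Negative-control TCR pools use the same six CDR columns
without peptide or label.  Residue-distance matrices between a peptide and
a CDR-beta chain are stored as a numeric matrix preceded by a two-line
header carrying the two sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoding import ALPHABET

_ALPHABET_SET = set(ALPHABET)

#: default file columns, NetTCR-repo style
DEFAULT_DIALECT = {
    "peptide": "peptide",
    "cdr1a": "A1",
    "cdr2a": "A2",
    "cdr3a": "A3",
    "cdr1b": "B1",
    "cdr2b": "B2",
    "cdr3b": "B3",
    "label": "binder",
    "partition": "partition",
}

CDR_FIELDS = ("cdr1a", "cdr2a", "cdr3a", "cdr1b", "cdr2b", "cdr3b")

ORIGINS = ("positive_db", "shuffled_negative", "control_negative", "synthetic")


class DataError(ValueError):
    """Malformed input data."""


class ConfigError(ValueError):
    """Missing or inconsistent configuration (e.g. absent columns)."""


def validate_sequence(seq: str, where: str = "sequence") -> str:
    """Uppercase and check a sequence against the 20-letter alphabet."""
    if not isinstance(seq, str) or not seq:
        raise DataError(f"{where}: empty or non-string sequence")
    s = seq.upper()
    bad = set(s) - _ALPHABET_SET
    if bad:
        raise DataError(f"{where}: invalid residue(s) {sorted(bad)} in {seq!r}")
    return s


@dataclass(frozen=True)
class TCRRecord:
    """One paired-chain TCR paired with a peptide and a binding label."""

    peptide: str
    cdr1a: str
    cdr2a: str
    cdr3a: str
    cdr1b: str
    cdr2b: str
    cdr3b: str
    label: int
    partition: int | None = None
    origin: str = "positive_db"

    def __post_init__(self):
        for f in ("peptide",) + CDR_FIELDS:
            object.__setattr__(self, f, validate_sequence(getattr(self, f), f))
        if self.label not in (0, 1):
            raise DataError(f"label must be 0 or 1, got {self.label!r}")
        if self.origin not in ORIGINS:
            raise DataError(f"unknown origin {self.origin!r}")

    @property
    def tcr(self) -> tuple:
        """The six-CDR tuple identifying the receptor."""
        return tuple(getattr(self, f) for f in CDR_FIELDS)

    @property
    def pair(self) -> tuple:
        """(peptide, six-CDR tuple) — the identity used for leakage checks."""
        return (self.peptide, self.tcr)


@dataclass
class Dataset:
    """An ordered collection of records with a peptide lookup index."""

    records: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self._reindex()

    def _reindex(self):
        self.peptide_index: dict = {}
        for i, rec in enumerate(self.records):
            self.peptide_index.setdefault(rec.peptide, []).append(i)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def peptides(self) -> list:
        return sorted(self.peptide_index)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    def positives(self) -> "Dataset":
        return Dataset([r for r in self.records if r.label == 1], dict(self.metadata))

    def subset(self, indices) -> "Dataset":
        return Dataset([self.records[i] for i in indices], dict(self.metadata))

    def with_partitions(self, folds) -> "Dataset":
        """Return a copy whose records carry the given fold indices."""
        if len(folds) != len(self.records):
            raise DataError("fold assignment length mismatch")
        recs = [replace(r, partition=int(f)) for r, f in zip(self.records, folds)]
        return Dataset(recs, dict(self.metadata))

    def drop_duplicate_positives(self) -> "Dataset":
        """Collapse exact duplicate (peptide + six CDR) positives, warning once."""
        seen: set = set()
        kept = []
        dropped = 0
        for r in self.records:
            key = (r.pair, r.label)
            if r.label == 1 and key in seen:
                dropped += 1
                continue
            seen.add(key)
            kept.append(r)
        if dropped:
            warnings.warn(f"{dropped} duplicate positive record(s) collapsed")
        return Dataset(kept, dict(self.metadata))


@dataclass
class ControlPool:
    """Unlabeled TCRs (six-CDR tuples) from donors without known specificity."""

    tcrs: list  # list of six-tuples
    n_duplicates_removed: int = 0

    def __len__(self) -> int:
        return len(self.tcrs)


@dataclass
class DistanceMap:
    """Pairwise residue distances (Angstrom) between a peptide and a CDR-beta
    chain, shaped |peptide| x |CDR-beta|."""

    complex_id: str
    peptide_seq: str
    cdrb_seq: str
    d: np.ndarray

    def __post_init__(self):
        self.peptide_seq = validate_sequence(self.peptide_seq, "peptide_seq")
        self.cdrb_seq = validate_sequence(self.cdrb_seq, "cdrb_seq")
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.shape != (len(self.peptide_seq), len(self.cdrb_seq)):
            raise DataError(
                f"{self.complex_id}: distance matrix shape {self.d.shape} does not match "
                f"sequence lengths ({len(self.peptide_seq)}, {len(self.cdrb_seq)})"
            )
        if (self.d < 0).any():
            raise DataError(f"{self.complex_id}: negative distances present")


# ---------------------------------------------------------------- datasets


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_dataset(path, dialect: dict | None = None, on_invalid: str = "error") -> Dataset:
    """Read a delimited paired-chain dataset.

    Parameters
    ----------
    dialect
        Mapping from canonical field names (``peptide``, ``cdr1a`` ...
        ``label``, ``partition``) to the file's column headers; defaults to
        the NetTCR-style ``peptide, A1..B3, binder, partition``.
    on_invalid
        ``"error"`` (default) raises listing offending row numbers;
        ``"drop"`` removes invalid rows with a warning.
    """
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.empty and df.columns.size == 0:
        raise DataError(f"{path}: empty file")
    required = [dia[f] for f in ("peptide",) + CDR_FIELDS + ("label",)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {missing}")
    has_partition = dia["partition"] in df.columns

    records, bad_rows = [], []
    for i, row in df.iterrows():
        try:
            part = None
            if has_partition and pd.notna(row[dia["partition"]]):
                part = int(float(row[dia["partition"]]))
            rec = TCRRecord(
                peptide=row[dia["peptide"]],
                cdr1a=row[dia["cdr1a"]], cdr2a=row[dia["cdr2a"]], cdr3a=row[dia["cdr3a"]],
                cdr1b=row[dia["cdr1b"]], cdr2b=row[dia["cdr2b"]], cdr3b=row[dia["cdr3b"]],
                label=int(float(row[dia["label"]])),
                partition=part,
            )
            records.append(rec)
        except (DataError, TypeError, ValueError) as e:
            bad_rows.append((i + 2, str(e)))  # +2: header + 1-based
    if bad_rows:
        msg = "; ".join(f"row {n}: {m}" for n, m in bad_rows[:10])
        if on_invalid == "error":
            raise DataError(f"{path}: {len(bad_rows)} invalid row(s): {msg}")
        warnings.warn(f"{path}: dropped {len(bad_rows)} invalid row(s): {msg}")
    ds = Dataset(records, {"source": str(path)})
    return ds.drop_duplicate_positives()


def write_dataset(ds: Dataset, path, dialect: dict | None = None) -> None:
    """Write a dataset as delimited text with a stable column order."""
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    cols = {
        dia["peptide"]: [r.peptide for r in ds.records],
        dia["cdr1a"]: [r.cdr1a for r in ds.records],
        dia["cdr2a"]: [r.cdr2a for r in ds.records],
        dia["cdr3a"]: [r.cdr3a for r in ds.records],
        dia["cdr1b"]: [r.cdr1b for r in ds.records],
        dia["cdr2b"]: [r.cdr2b for r in ds.records],
        dia["cdr3b"]: [r.cdr3b for r in ds.records],
        dia["label"]: [r.label for r in ds.records],
        dia["partition"]: ["" if r.partition is None else r.partition for r in ds.records],
    }
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path), index=False)


def read_control_pool(path, dialect: dict | None = None) -> ControlPool:
    """Read an unlabeled control-TCR pool; exact duplicate six-tuples are
    removed (the removal count is kept on the pool)."""
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    required = [dia[f] for f in CDR_FIELDS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {missing}")
    seen, tcrs, dups = set(), [], 0
    for i, row in df.iterrows():
        t = tuple(validate_sequence(row[dia[f]], f"row {i + 2} {f}") for f in CDR_FIELDS)
        if t in seen:
            dups += 1
            continue
        seen.add(t)
        tcrs.append(t)
    if dups:
        warnings.warn(f"{path}: {dups} duplicate control TCR(s) removed")
    return ControlPool(tcrs, n_duplicates_removed=dups)


def write_control_pool(pool: ControlPool, path, dialect: dict | None = None) -> None:
    dia = dict(DEFAULT_DIALECT)
    if dialect:
        dia.update(dialect)
    cols = {dia[f]: [t[i] for t in pool.tcrs] for i, f in enumerate(CDR_FIELDS)}
    pd.DataFrame(cols).to_csv(path, sep=_sep_for(path), index=False)


# ------------------------------------------------------------ distance maps


def write_distance_map(dm: DistanceMap, path_or_file) -> None:
    fh = path_or_file if hasattr(path_or_file, "write") else open(path_or_file, "w")
    try:
        fh.write(f"# complex={dm.complex_id} peptide={dm.peptide_seq}\n")
        fh.write(f"# cdrb={dm.cdrb_seq}\n")
        for row in dm.d:
            fh.write("\t".join(f"{x:.4f}" for x in row) + "\n")
    finally:
        if fh is not path_or_file:
            fh.close()


def read_distance_map(path) -> DistanceMap:
    with open(path) as fh:
        h1 = fh.readline().strip()
        h2 = fh.readline().strip()
        try:
            meta = dict(tok.split("=", 1) for tok in h1.lstrip("# ").split())
            cdrb = h2.lstrip("# ").split("=", 1)[1]
        except (IndexError, ValueError):
            raise DataError(f"{path}: malformed distance-map header") from None
        d = np.loadtxt(fh, ndmin=2)
    return DistanceMap(meta.get("complex", "?"), meta["peptide"], cdrb, d)


def distances_from_coordinates(pep_coords: np.ndarray, cdrb_coords: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances between two per-residue coordinate sets."""
    a = np.asarray(pep_coords, dtype=np.float64)
    b = np.asarray(cdrb_coords, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] != 3 or b.ndim != 2 or b.shape[1] != 3:
        raise DataError("coordinates must be (n, 3) arrays")
    diff = a[:, None, :] - b[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def distance_map_from_pdb(
    path,
    peptide_chain: str,
    beta_chain: str,
    atom: str = "CA",
    complex_id: str | None = None,
    beta_residue_range: tuple | None = None,
) -> DistanceMap:
    """Build a peptide x CDR-beta distance map from a PDB file.

    ``atom`` selects the representative atom per residue: an atom name such
    as ``"CA"`` or ``"CB"``, or ``"min"`` for the minimum heavy-atom
    distance of each residue pair.  ``beta_residue_range`` optionally
    restricts the beta chain to a (start, end) author-numbering interval
    (inclusive), e.g. the CDR3 loop.
    """
    from Bio.PDB import PDBParser
    from Bio.SeqUtils import seq1

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(complex_id or "complex", path)
    model = next(iter(structure))

    def chain_residues(chain_id):
        if chain_id not in model:
            raise DataError(f"{path}: chain {chain_id!r} not found")
        res = [r for r in model[chain_id] if r.id[0] == " "]
        if not res:
            raise DataError(f"{path}: chain {chain_id!r} has no standard residues")
        return res

    pep_res = chain_residues(peptide_chain)
    beta_res = chain_residues(beta_chain)
    if beta_residue_range is not None:
        lo, hi = beta_residue_range
        beta_res = [r for r in beta_res if lo <= r.id[1] <= hi]
        if not beta_res:
            raise DataError(f"{path}: no beta-chain residues in range {beta_residue_range}")

    def seq_of(residues):
        return validate_sequence(
            "".join(seq1(r.get_resname()) for r in residues), "PDB sequence"
        )

    pep_seq, beta_seq = seq_of(pep_res), seq_of(beta_res)

    if atom == "min":
        d = np.empty((len(pep_res), len(beta_res)))
        for i, ri in enumerate(pep_res):
            ai = np.array([a.coord for a in ri if a.element != "H"])
            for j, rj in enumerate(beta_res):
                aj = np.array([a.coord for a in rj if a.element != "H"])
                d[i, j] = np.sqrt(((ai[:, None] - aj[None]) ** 2).sum(-1)).min()
    else:
        def rep_coord(r):
            if atom not in r:
                raise DataError(
                    f"{path}: residue {r.get_resname()}{r.id[1]} lacks atom {atom!r}"
                )
            return r[atom].coord

        pep_xyz = np.array([rep_coord(r) for r in pep_res])
        beta_xyz = np.array([rep_coord(r) for r in beta_res])
        d = distances_from_coordinates(pep_xyz, beta_xyz)

    return DistanceMap(complex_id or str(path), pep_seq, beta_seq, d)
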