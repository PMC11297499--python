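"""Training loop, ensembling, and the evaluation suite.

Both models train with mini-batch Adam on binary cross-entropy; after each
epoch the ROC-AUC on the validation partition is recorded and the weights
of the best-validation-AUC epoch are kept (early stopping on patience).
The ensemble prediction is the arithmetic mean of the two component
probabilities.

Evaluation reports ROC-AUC, PR-AUC (average precision), and the five
cutoff metrics — accuracy, precision, specificity, recall, F1 — at a 0.5
cutoff (score >= cutoff is called positive), overall and per peptide, plus
the Lmin analysis: for each test peptide, the minimum Levenshtein distance
to any training peptide, related to that peptide's ROC-AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .encoding import EncodedBatch


class EvalError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "bce"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise EvalError("max_epochs must be >= 1")
        if not 1 <= self.patience <= self.max_epochs:
            raise EvalError("patience must be in [1, max_epochs]")


def roc_auc(labels, scores) -> float:
    """ROC-AUC: probability that a random positive outscores a random
    negative, ties counting one half (Mann-Whitney form)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise EvalError("ROC-AUC undefined for single-class labels")
    return float(roc_auc_score(y, np.asarray(scores)))


def pr_auc(labels, scores) -> float:
    """PR-AUC by the step-wise average-precision convention."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise EvalError("PR-AUC undefined for single-class labels")
    return float(average_precision_score(y, np.asarray(scores)))


@dataclass
class MetricReport:
    roc_auc: float
    pr_auc: float
    accuracy: float
    precision: float
    specificity: float
    recall: float
    f1: float
    cutoff: float
    tp: int
    tn: int
    fp: int
    fn: int
    undefined: list = field(default_factory=list)  # metrics with zero denominators
    per_peptide: dict = field(default_factory=dict)  # peptide -> (auc|nan, n_pos)

    def as_dict(self) -> dict:
        return {
            "roc_auc": self.roc_auc, "pr_auc": self.pr_auc, "accuracy": self.accuracy,
            "precision": self.precision, "specificity": self.specificity,
            "recall": self.recall, "f1": self.f1, "cutoff": self.cutoff,
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
        }


def confusion_metrics(labels, scores, cutoff: float = 0.5) -> MetricReport:
    """Cutoff-based classification metrics plus the two AUCs.

    A metric whose denominator is zero is reported as NaN and listed in
    ``report.undefined`` rather than silently coerced to 0.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise EvalError("empty evaluation input")
    calls = s >= cutoff
    tp = int(np.sum(calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    fp = int(np.sum(calls & (y == 0)))
    fn = int(np.sum(~calls & (y == 1)))

    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return math.nan
        return num / den

    acc = (tp + tn) / y.size
    prec = ratio(tp, tp + fp, "precision")
    spec = ratio(tn, fp + tn, "specificity")
    rec = ratio(tp, tp + fn, "recall")
    if math.isnan(prec) or math.isnan(rec) or (prec + rec) == 0:
        undefined.append("f1")
        f1 = math.nan
    else:
        f1 = 2 * prec * rec / (prec + rec)
    try:
        auc, ap = roc_auc(y, s), pr_auc(y, s)
    except EvalError:
        undefined += ["roc_auc", "pr_auc"]
        auc = ap = math.nan
    return MetricReport(auc, ap, acc, prec, spec, rec, f1, cutoff, tp, tn, fp, fn, undefined)


def per_peptide_auc(labels, scores, peptides) -> dict:
    """ROC-AUC within each peptide's records; single-class peptides are NaN.

    Returns ``{peptide: (auc, n_pos)}``.
    """
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    peps = np.asarray(peptides)
    out = {}
    for p in np.unique(peps):
        m = peps == p
        n_pos = int(y[m].sum())
        try:
            out[str(p)] = (roc_auc(y[m], s[m]), n_pos)
        except EvalError:
            out[str(p)] = (math.nan, n_pos)
    return out


def ensemble_predict(p_cnn, p_att):
    """Arithmetic mean of the two component probabilities."""
    return (np.asarray(p_cnn, dtype=float) + np.asarray(p_att, dtype=float)) / 2.0


# ------------------------------------------------------------------ training


@dataclass
class TrainHistory:
    val_auc: list
    best_epoch: int
    best_val_auc: float


def train(model, train_batch: EncodedBatch, val_batch: EncodedBatch, cfg: TrainConfig):
    """Train a model in place; returns (best state_dict, TrainHistory).

    Epoch selection maximizes validation ROC-AUC; training stops after
    ``patience`` epochs without improvement.  The model is left holding the
    best-epoch weights.
    """
    from ._autograd import Adam, bce_loss

    if train_batch.labels is None or val_batch.labels is None:
        raise EvalError("train/val batches must carry labels")
    if len(np.unique(val_batch.labels)) < 2:
        raise EvalError("validation set must contain both classes for ROC-AUC selection")

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    n = len(train_batch)
    best_state, best_auc, best_epoch = model.state_dict(), -np.inf, -1
    history = []
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch_size):
            sel = order[i : i + cfg.batch_size]
            mb = train_batch.take(sel)
            out = model.forward(mb, train_rng=rng)
            prob = out[0] if isinstance(out, tuple) else out
            loss = bce_loss(prob, mb.labels)
            opt.zero_grad()
            loss.backward()
            opt.step()
        val_auc = roc_auc(val_batch.labels, model.predict(val_batch))
        history.append(val_auc)
        if val_auc > best_auc:
            best_auc, best_epoch, best_state = val_auc, epoch, model.state_dict()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.load_state_dict(best_state)
    return best_state, TrainHistory(history, best_epoch, best_auc)


# ------------------------------------------------------- sequence similarity


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (substitution, insertion, deletion)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def lmin(test_peptide: str, train_peptides) -> int:
    """Minimum Levenshtein distance from a test peptide to the training set."""
    peps = list(train_peptides)
    if not peps:
        raise EvalError("lmin requires a non-empty training peptide set")
    return min(levenshtein(test_peptide, p) for p in peps)


@dataclass
class LminSummary:
    min_lmin: int
    max_lmin: int
    mean_auc_at_min: float
    mean_auc_at_max: float
    n_at_min: int
    n_at_max: int


def lmin_auc_summary(per_pep_auc: dict, lmin_of_peptide: dict) -> LminSummary:
    """Mean per-peptide ROC-AUC among the peptides attaining the minimum
    Lmin versus those attaining the maximum Lmin (NaN AUCs excluded)."""
    keys = [p for p in per_pep_auc if p in lmin_of_peptide]
    usable = [p for p in keys if not math.isnan(per_pep_auc[p][0])]
    if not usable:
        raise EvalError("no peptides with defined AUC and Lmin")
    lvals = {p: lmin_of_peptide[p] for p in usable}
    lo, hi = min(lvals.values()), max(lvals.values())
    at_lo = [per_pep_auc[p][0] for p in usable if lvals[p] == lo]
    at_hi = [per_pep_auc[p][0] for p in usable if lvals[p] == hi]
    return LminSummary(lo, hi, float(np.mean(at_lo)), float(np.mean(at_hi)),
                       len(at_lo), len(at_hi))
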