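"""End-to-end benchmark workflows on synthetic repertoires.

Each function generates a repertoire under stated conditions, builds a
cross-validated dataset with manufactured negatives, trains the model(s)
on one outer loop of the modified nested cross-validation (test fold 0,
validation fold 1, training folds 2..k-1), and measures held-out
performance.  A single outer loop is evaluated to keep the benchmark
minutes-scale; the split machinery itself provides the full k-loop plan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data_io import Dataset
from .encoding import PaddingSpec, encode_batch, fit_padding_spec
from .model_attention import AttentionConfig, ReciprocalAttentionModel
from .model_cnn import CNNConfig, PairedChainCNN
from .sampling import build_cv_dataset, nested_cv_plan, random_kfold, strict_split
from .synthetic import GeneratorConfig, generate_repertoire, generate_structure_fixture
from .train_eval import (
    TrainConfig,
    ensemble_predict,
    lmin,
    lmin_auc_summary,
    per_peptide_auc,
    roc_auc,
    train,
)

#: benchmark-scale training settings (small nets; epoch budgets sized so the
#: planted signal saturates, with early stopping on validation ROC-AUC)
CNN_TRAIN = TrainConfig(learning_rate=2e-3, batch_size=128, max_epochs=30, patience=8)
ATT_TRAIN = TrainConfig(learning_rate=2e-3, batch_size=256, max_epochs=45, patience=15)
CNN_CFG = CNNConfig(conv_channels=16, branch_fc_dim=16, head_dims=(64, 16, 1), dropout=0.1)
ATT_CFG = AttentionConfig(embed_dim=32, n_heads=2, branch_fc_dims=(32, 16),
                          head_dims=(24, 1), dropout=0.1)


@dataclass
class FoldData:
    train: Dataset
    val: Dataset
    test: Dataset
    spec: PaddingSpec


def split_fold(full: Dataset, k: int, outer: int = 0, mode: str = "pad_then_concat") -> FoldData:
    """Materialize one outer loop of the nested CV from a partitioned dataset."""
    plan = nested_cv_plan(k)
    t, v, tr = plan.triples[outer]
    by_fold = {f: [r for r in full.records if r.partition == f] for f in range(k)}
    train_ds = Dataset([r for f in tr for r in by_fold[f]])
    val_ds = Dataset(by_fold[v])
    test_ds = Dataset(by_fold[t])
    spec = fit_padding_spec(full, margin=0, mode=mode)
    return FoldData(train_ds, val_ds, test_ds, spec)


def _train_models(fold: FoldData, seed: int, models=("cnn", "attention")) -> dict:
    tr = encode_batch(fold.train.records, fold.spec)
    va = encode_batch(fold.val.records, fold.spec)
    te = encode_batch(fold.test.records, fold.spec)
    out = {"labels": te.labels, "trained": {}}
    if "cnn" in models:
        cnn = PairedChainCNN(fold.spec, CNN_CFG, seed=seed)
        train(cnn, tr, va, replace(CNN_TRAIN, seed=seed))
        out["cnn"] = cnn.predict(te)
        out["trained"]["cnn"] = cnn
    if "attention" in models:
        att = ReciprocalAttentionModel(fold.spec, ATT_CFG, seed=seed + 1)
        train(att, tr, va, replace(ATT_TRAIN, seed=seed + 1))
        out["attention"] = att.predict(te)
        out["trained"]["attention"] = att
    return out


def planted_signal_benchmark(seed: int, motif_strength: float = 1.0,
                             models=("cnn", "attention")) -> dict:
    """Held-out performance on the default 20-peptide x 100-TCR repertoire
    with shuffled negatives at 1:2 under a random 5-fold split."""
    cfg = GeneratorConfig(motif_strength=motif_strength, seed=seed)
    positives, _, _ = generate_repertoire(cfg)
    plan = random_kfold(positives, k=5, seed=seed + 10)
    full = build_cv_dataset(positives, plan, negative="shuffle", ratio=(1, 2), seed=seed + 20)
    fold = split_fold(full, k=5)
    res = _train_models(fold, seed, models)
    out = {"n_test": int(len(res["labels"])), "motif_strength": motif_strength}
    for m in models:
        out[f"auc_{m}"] = roc_auc(res["labels"], res[m])
    if len(models) == 2:
        ens = ensemble_predict(res["cnn"], res["attention"])
        out["auc_ensemble"] = roc_auc(res["labels"], ens)
    return out


def seen_unseen_gap(seed: int, similarity_link: bool = False, model: str = "cnn") -> dict:
    """ROC-AUC under a random (seen-epitope) vs strict peptide-disjoint
    (unseen-epitope) split of the same repertoire, plus the Lmin analysis
    on the strict split."""
    cfg = GeneratorConfig(similarity_link=similarity_link, seed=seed)
    positives, _, _ = generate_repertoire(cfg)
    out = {"similarity_link": similarity_link}
    for mode in ("random", "strict"):
        if mode == "random":
            plan = random_kfold(positives, k=5, seed=seed + 10)
        else:
            plan = strict_split(positives, k=5, seed=seed + 10)
        full = build_cv_dataset(positives, plan, negative="shuffle", ratio=(1, 2),
                                seed=seed + 20)
        fold = split_fold(full, k=5)
        res = _train_models(fold, seed, (model,))
        out[f"auc_{mode}"] = roc_auc(res["labels"], res[model])
        if mode == "strict":
            train_peps = {r.peptide for r in fold.train.records if r.label == 1}
            test_labels = res["labels"]
            test_peps = [r.peptide for r in fold.test.records]
            pp = per_peptide_auc(test_labels, res[model], test_peps)
            lmins = {p: lmin(p, train_peps) for p in pp}
            out["lmin_summary"] = lmin_auc_summary(pp, lmins)
    out["gap"] = out["auc_random"] - out["auc_strict"]
    return out


def interpretation_benchmark(seed: int, n_complexes: int = 48,
                             test_variant: str = "paired") -> dict:
    """Train the attention model (concat-then-pad encoding) on a planted-
    motif repertoire, then compare attention on close vs far residue pairs
    of synthetic structure fixtures whose contacts sit at motif positions."""
    from .interpretation import run_interpretation

    cfg = GeneratorConfig(seed=seed)
    positives, _, truth = generate_repertoire(cfg)
    plan = random_kfold(positives, k=5, seed=seed + 10)
    full = build_cv_dataset(positives, plan, negative="shuffle", ratio=(1, 2), seed=seed + 20)
    fold = split_fold(full, k=5, mode="concat_then_pad")
    res = _train_models(fold, seed, ("attention",))
    model = res["trained"]["attention"]

    # structure fixtures from training-partition binders: the structural
    # complexes overlap the data the model was fitted on, mirroring how the
    # real structure set overlaps the public training data
    rng = np.random.default_rng(seed + 99)
    binders = [r for r in fold.train.records if r.label == 1]
    chosen = rng.choice(len(binders), size=min(n_complexes, len(binders)), replace=False)
    records, dmaps = [], []
    for i, ci in enumerate(sorted(int(c) for c in chosen)):
        rec = binders[ci]
        dmaps.append(generate_structure_fixture(rec, truth, seed=seed + 1000 + i,
                                                complex_id=f"synth{i}"))
        records.append(rec)
    comparison, _ = run_interpretation(model, records, dmaps, fold.spec,
                                       test_variant=test_variant)
    return {
        "auc_attention": roc_auc(res["labels"], res["attention"]),
        "mean_close": comparison.mean_close,
        "mean_far": comparison.mean_far,
        "t_statistic": comparison.statistic,
        "p_value": comparison.p_value,
        "test_variant": test_variant,
        "n_complexes": len(records),
        "per_complex": comparison.per_complex,
    }
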