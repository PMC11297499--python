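"""Train both models on planted-motif data and evaluate the ensemble.

Each synthetic binder carries a peptide-specific 3-residue motif inside
CDR3-beta, so a working model should separate binders from shuffled
negatives almost perfectly on held-out data; the printed ROC-AUCs show how
much of that planted signal each architecture recovers.
"""

import warnings

from tcrbind import GeneratorConfig, build_cv_dataset, confusion_metrics, \
    ensemble_predict, generate_repertoire, random_kfold
from tcrbind.encoding import encode_batch
from tcrbind.model_attention import ReciprocalAttentionModel
from tcrbind.model_cnn import PairedChainCNN
from tcrbind.train_eval import TrainConfig, train
from tcrbind.workflows import ATT_CFG, CNN_CFG, split_fold

warnings.filterwarnings("ignore")

cfg = GeneratorConfig(n_peptides=10, tcrs_per_peptide=50, seed=0)
positives, _, _ = generate_repertoire(cfg)
plan = random_kfold(positives, k=5, seed=1)
full = build_cv_dataset(positives, plan, negative="shuffle", ratio=(1, 2), seed=2)
fold = split_fold(full, k=5)  # test fold 0, validation fold 1, train folds 2-4

tr = encode_batch(fold.train.records, fold.spec)
va = encode_batch(fold.val.records, fold.spec)
te = encode_batch(fold.test.records, fold.spec)

cnn = PairedChainCNN(fold.spec, CNN_CFG, seed=0)
_, hist = train(cnn, tr, va, TrainConfig(learning_rate=2e-3, max_epochs=80, patience=25))
print(f"CNN: best epoch {hist.best_epoch}, val ROC-AUC {hist.best_val_auc:.3f}")

att = ReciprocalAttentionModel(fold.spec, ATT_CFG, seed=1)
_, hist = train(att, tr, va, TrainConfig(learning_rate=3e-3, max_epochs=150, patience=50))
print(f"attention: best epoch {hist.best_epoch}, val ROC-AUC {hist.best_val_auc:.3f}")

p_cnn, p_att = cnn.predict(te), att.predict(te)
rep = confusion_metrics(te.labels, ensemble_predict(p_cnn, p_att))
print(f"held-out ensemble: ROC-AUC {rep.roc_auc:.3f}, PR-AUC {rep.pr_auc:.3f}, "
      f"accuracy {rep.accuracy:.3f} at cutoff {rep.cutoff}")
# ROC-AUC near 1.0 means the planted peptide-motif association was recovered.
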