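# Methods

## Problem

Given a peptide epitope and a paired-chain T-cell receptor described by its
six CDR loops (CDR1/2/3 of the α and β chains), predict whether the receptor
binds the peptide. The practically hard regime is *pan-specific* prediction:
a single model that scores any peptide, including peptides absent from
training ("unseen epitopes"). Two structural features of public data make
evaluation treacherous: negatives must be manufactured (binding databases
record positives only), and the distribution of cognate-TCR counts per
peptide is heavy-tailed, so naive evaluation is dominated by a few frequent
peptides.

## Models

**Convolutional model.** Each of the seven sequences (peptide + six CDRs)
is one-hot encoded over the 20-letter alphabet (alphabetical order, no
padding channel; pad columns are all-zero) into a 20 × L matrix, L being the
frozen per-slot maximum training length. Each sequence passes through its
own branch: 1-D convolution with kernel size 2, ReLU, max pooling with
kernel size 2 (floor division for odd lengths), flattening, and one fully
connected layer to a fixed branch width. The seven branch vectors are
concatenated and passed through three fully connected layers ending in a
sigmoid. Defaults: 32 conv channels, branch width 32, head 224→64→16→1,
ReLU, dropout 0.3 on head layers, no normalization layers.

**Reciprocal-attention model.** Inputs are the peptide and the two chain
sequences, each chain being its three CDR loops either padded per loop and
concatenated (training default) or concatenated and then padded (the
structural-interpretation convention, where chain positions map one-to-one
onto residues). Each input gets a learnable token embedding plus a learned
positional embedding (configurable off), a multi-head self-attention layer,
then a multi-head *reciprocal* cross-attention layer wired as: peptide
queries (CDRα ∥ CDRβ); CDRα queries the peptide; CDRβ queries the peptide.
Pad keys receive exactly zero attention mass and each row of every head's
weight matrix sums to one over valid keys. Per branch, the attended
representation is projected per position (ReLU), mean-pooled over real
positions, projected again; the three branch vectors are concatenated and
passed through a two-layer sigmoid head. Defaults: embedding width 64, 4
heads, branch projections 64→32, head 96→32→1, dropout 0.3. Residual
connections are applied after both attention layers (configurable off);
without them the model fails to optimize at these widths, so the residual
path is kept even though it means attention weights are not the only route
by which partner information enters a branch.

**Ensemble.** The arithmetic mean of the two models' probabilities.

Both models are trained with mini-batch Adam on binary cross-entropy; after
every epoch the validation ROC-AUC is recorded and the weights of the best
epoch are restored (early stopping on patience). No loss re-weighting is
applied under class imbalance. All randomness (initialization, batch order,
dropout) flows from explicit seeds; training is bit-reproducible per
platform. The numerical engine is a small reverse-mode autograd written on
numpy, with float64 arithmetic throughout.

## Dataset construction

*Splits.* A random k-fold split deals positive pairs uniformly (fold sizes
within 1); a strict split deals *peptides* round-robin after a seeded
shuffle, so folds are peptide-disjoint (this balances peptide counts, not
record counts — balancing records would correlate folds with peptide
frequency). The modified nested cross-validation uses one inner loop per
outer loop: test fold i, validation fold (i+1) mod k, remaining k−2 folds
train.

*Negatives.* Shuffled negatives pair a peptide with TCRs binding other
peptides of the same partition, never across partitions; the false-negative
guard excludes exact (peptide, six-CDR) collisions with any positive of the
full dataset but does not model cross-reactivity beyond exact duplicates.
When a partition cannot supply the requested ratio the shortfall is warned
about and under-sampled (a strict flag raises instead). Control negatives
draw from an unlabeled background pool without replacement within each
peptide's draw. Mixed negatives combine both at stated ratios. Per-peptide
down-sampling keeps min(count, cap) pairs chosen uniformly, independent of
input order.

*Auditing.* The leakage audit flags exact pairs carrying conflicting labels
across partitions and, in strict mode, any peptide shared between
partitions at all.

## Evaluation

ROC-AUC (Mann–Whitney form, ties count ½) and PR-AUC (step-wise average
precision) are computed with scikit-learn; the cutoff metrics — accuracy,
precision, specificity, recall, F1 — threshold at score ≥ 0.5. Zero
denominators are reported as NaN with an explicit flag, never silently 0.
Per-peptide ROC-AUC is computed within each peptide's records. Lmin of a
test peptide is its minimum Levenshtein distance (edlib) to the training
peptides; the Lmin summary compares mean per-peptide AUC among peptides
attaining the minimum vs maximum Lmin.

## Interpretation

For the structural analysis the attention model is trained with the
concat-then-pad encoding; the peptide-as-query reciprocal map is averaged
over heads (configurable: single head, β-as-query) and its CDRβ key block
extracted, pad rows/columns dropped. Residue pairs with distance < 10 Å are
*close*, > 25 Å *far*; the 10–25 Å band is excluded. Per complex, the mean
attention score of each class is computed; across complexes the two groups
are compared with a t-test. Three variants are implemented — unpaired
equal-variance Student's (the library default), Welch, and paired — because
the choice is a genuine degree of freedom that materially affects the
p-value. The benchmark workflow uses the *paired* variant: each complex
contributes one close mean and one far mean, and pairing removes the
between-complex variation in overall attention level.

Three empirical findings shaped the interpretation benchmark. First, head
count: with four heads the per-head maps disagree (some heads concentrate
on planted contact columns, others away from them) and the head-averaged
map washes out, so the benchmark attention model uses two heads, where the
averaged map retains the localization; the head count of the full-size
default model is unchanged. Second, fixture provenance: structure fixtures
are built from binders of the *training* partitions, mirroring the fact
that public complex structures overlap the public training data, and the
attention maps are sharpest on pairs the model was fitted on. Third,
power: the per-complex contrast has substantial variance because the model
localizes strongly on some complexes and weakly on others, so the
benchmark evaluates 48 synthetic complexes — fixtures are generated, not
collected, and this size gives the t-test adequate power for an effect of
the observed magnitude.

A caveat stated plainly: across independent training runs the *direction*
of the effect (more attention on close pairs) is highly consistent, but
its *strength* varies considerably — some trained models route most
peptide-chain information through attention paths that do not align with
the planted contacts, and then the contrast, while usually still positive,
is not significant. Attention-based interpretability of this architecture
is therefore a property of a trained model, not a guarantee of the
architecture; the benchmark documents the phenomenon under its stated
conditions rather than universally. Distances can be
read from matrix files or computed from PDB coordinates with a selectable
representative atom (Cα default; Cβ or minimum heavy-atom distance
selectable), since no single convention is canonical.

## Synthetic data generator

The generator emulates the statistical structure of curated benchmark data
without any biophysics:

- peptides are i.i.d. 9-mers (configurable length range); cognate-TCR
  counts are uniform by default or power-law with a configurable exponent
  (heavy-tailed peptide imbalance);
- each peptide owns a 3-residue motif planted at offset 3 of CDR3β in a
  `motif_strength` fraction of its binders — the learnable signal;
- with `similarity_link`, half the peptides are point mutants of earlier
  peptides and motifs are a character-wise substitution cipher of the
  peptide prefix, so peptide similarity implies motif similarity (this is
  what makes the Lmin–AUC relationship reproducible in silico);
- a configurable fraction of TCRs is cross-reactive (listed under a second
  peptide, with that peptide's motif planted adjacently when it fits);
- the control pool draws residues from a Dirichlet-perturbed frequency
  vector; shift 0 reproduces the binder composition, larger shifts recreate
  the compositional bias that makes control-based negatives artificially
  easy;
- structure fixtures place all (peptide position, motif position) pairs at
  Uniform(4, 9) Å and everything else at Uniform(12, 40) Å, so planted
  contacts are always "close" and non-contacts never are.

Defaults (20 peptides × 100 TCRs, motif strength 1, motif length 3, control
pool 2000 at shift 0.3) are the conditions of the acceptance benchmarks.
CDR length ranges (CDR1 5–7, CDR2 5–8, CDR3α 10–16, CDR3β 12–18) follow the
typical loop-length distributions of curated paired-chain data.

What the generator does *not* emulate: V(D)J recombination statistics,
realistic amino-acid usage, MHC restriction, length–peptide dependence, and
soft sequence redundancy. Passing the benchmarks therefore demonstrates
that the machinery works and that the architectures can recover
peptide-conditional sequence signal; it does not certify performance on
real repertoires.

## Benchmark problem sizes and settings

The end-to-end benchmarks evaluate one outer loop of the nested
cross-validation (test fold 0, validation fold 1, trainining folds 2–4) at
20 peptides × 100 TCRs with shuffled negatives at 1:2 — 6 000 records, of
which 3 600 train and 1 200 test. Benchmark model sizes are reduced (CNN: 16
channels, branch width 16; attention: width 32, 2 heads, branch 32→16) and
training runs at learning rate 2·10⁻³ with early stopping (CNN ≤ 30 epochs,
attention ≤ 45, patience 8/15); the attention model shows a characteristic
plateau before the cross-attention "clicks", which is why its epoch budget
is larger. These sizes keep a full battery in the tens of minutes on one
CPU while leaving generous margins on every asserted property.

## Numerical choices and degenerate inputs

- Thresholding: score ≥ cutoff calls positive (must be fixed for bit-stable
  confusion counts).
- Masked softmax subtracts the row max over valid keys and renormalizes over
  valid keys only; an all-pad key row is an error, not a NaN.
- Pooling floor: max pooling drops a trailing odd element.
- Sigmoid inputs are clipped at ±60 before exponentiation; BCE adds 1e-9
  inside the logs. Probabilities are therefore strictly inside (0, 1).
- Duplicate positives (identical peptide + six CDRs) collapse to one record
  with a warning; nonstandard residues (X, B, Z, *, lowercase after
  normalization fails) are rejected by default, with a drop-rows option.
- Ties in ROC-AUC count one half by the Mann–Whitney convention.

## Known limitations

- The false-negative guard is exact-pair only; a cross-reactive TCR paired
  with a second peptide it genuinely binds would still be labeled negative,
  as in the real construction procedure.
- Sequence-similarity redundancy reduction between folds is out of scope;
  the strict split guarantees peptide disjointness, not peptide
  dissimilarity.
- The t-test on per-complex means treats complexes as independent; shared
  peptides across complexes violate this mildly, here and in the real
  analysis.
- Training hyperparameters of the original tools this design family
  descends from are not public; the defaults here are declared, not claimed
  to match any external implementation.
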