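# Methods

## Problem and model

Hot-spot residues are interface residues whose mutation to alanine changes
the binding free energy of a protein–protein complex by more than
2 kcal/mol. `hotspot1d` casts their identification as binary classification
of fixed-size sequence windows: the window of width *w* centered on a
candidate residue, with each position described by a *D*-dimensional feature
vector, is the classifier's whole input. The model therefore assumes that
the information determining hot-spot character is local in sequence — an
assumption inherited from the window design, not a fact about interfaces
(spatial neighbors in the folded complex may be sequence-distant).

### Labeling

`label_from_ddg` applies the strict rule ΔΔG > 2 kcal/mol → hotspot. The
comparison is strict: a residue measured at exactly 2.0 kcal/mol is a
non-hotspot. Annotations may instead carry an explicit label; when both are
present they must agree. Wild-type letters in annotation tables are checked
against the sequence and a mismatch is an error by default, downgradable to
a warning because curated corpora contain residue-numbering discrepancies.

### Featurization

Two per-residue representations are built in:

- **one-hot**, 21 columns: the 20 standard amino acids in alphabetical
  one-letter order, with the catch-all symbol `X` (any non-standard letter:
  B, Z, J, U, O, `*`, …) in the last column. The ordering is arbitrary for
  learning but fixed and documented for reproducibility.
- **precomputed embeddings**: an HDF5 container keyed by protein id, one
  L×D float matrix per protein (a whitespace-delimited text matrix per
  protein is accepted as a fallback). Row counts are validated against
  sequence lengths at load. Concatenating a 4096-dim learned embedding with
  the one-hot encoding yields the 4117-dim representation the full
  pipeline is designed around. Running a language model is deliberately out
  of scope — only the output matrix contract matters here.

### Windowing

Windows have odd width, default 33; widths outside the studied sweep range
21–41 require an explicit flag. Out-of-range positions are all-zero rows —
not edge replication, and the `X` column is *not* set, so a padded row is
distinguishable from every real residue row. Windows are built only at
annotated residues (dense per-residue windowing exists for whole-sequence
prediction), in (protein_id, position) order so downstream splits are
reproducible.

## Imbalance handling

The measured corpus ratio is ≈ 1:63. Three mechanisms are composed:

- **Interval (stride) subsampling**: every 63rd negative from the
  deterministically ordered pool. Subsets at distinct offsets are pairwise
  disjoint; subsets are truncated to a fixed size (the positive count) so
  that all offsets yield equal-size sets even though the strict stride
  yield varies by ±1. The base subset (offset 0) joins the positives to
  form a balanced corpus; offsets 1..4 expand the training negatives and
  are disjoint from the base subset — and hence from validation and test —
  by construction. A leakage check on (protein_id, position) keys enforces
  this at assembly time.
- **SMOTE**: synthetic minority rows `X_old + r (X_n − X_old)` with
  `r ~ U(0,1)` open-interval, `X_n` uniform over the `k = 5` nearest
  minority neighbors (Euclidean, self excluded; `k` follows the original
  SMOTE publication since the pipeline description leaves it unstated).
  SMOTE operates on flattened `w·D` window vectors so synthetic examples
  are valid CNN inputs; exactly enough rows are synthesized to balance the
  classes. A test hook pins `r` to 0 or 1 to expose the segment endpoints.
- **Class weights**: `w_c = N / (2 N_c)` applied per-sample in the loss, as
  the no-oversampling alternative. Weighted class totals are equal by
  construction.

Splits take 1/5 of the corpus as test and 1/5 of the remainder as
validation, rounding half away from zero (698 → 140 test, 558 → 112
validation), unstratified by default with a stratified option.

## Classifier

A 1-D CNN over the window axis. Convolution kernels span the full feature
depth and slide only along the window axis with stride 1 and zero "same"
padding; each of the three blocks is conv → ReLU → max-pool 2 with 64, 16, 4
filters and kernels 7, 5, 3. After the blocks: one dropout (rate 0.5),
flatten, dense 8 with ReLU, dense 1 with sigmoid. For *w* = 33 the pooled
lengths are 16, 8, 4 (pooling truncates odd remainders); building a model
whose window would pool to length 0 is an error naming the minimum width.

Depth is configurable in {2, 3, 4, 5}: added layers are copies of the middle
block (16 filters, kernel 5); depth 2 removes that middle block, keeping the
entry (64/7) and exit (4/3) blocks. Dropout placement (once, after the last
pooling block) is a design choice; only the rate was prescribed.

Training minimizes binary cross-entropy with RMSprop (ρ = 0.9, ε = 1e-7,
learning rate 1e-3 — standard defaults, since only the optimizer family was
prescribed). After every epoch, validation F1 at threshold 0.5 is computed;
the best-scoring weights are checkpointed and training stops after 20
epochs without strict improvement or at 200 epochs (batch size 32; all four
values are surfaced in config and recorded in run logs because they are not
implied by the architecture). The classification threshold is 0.5.
Undefined F1 (no predicted or no true positives) counts as 0 for early
stopping. The whole procedure — Glorot initialization, shuffling, dropout
masks — is driven by a single seeded generator, so identical config + seed
reproduces identical histories bit for bit.

The network, including the backward passes and optimizer, is implemented in
numpy (`nn.py`); gradients are verified against central finite differences
in the test suite.

## Evaluation

Accuracy, recall, precision, F1 and specificity from exact confusion
counts; ROC/AUC by trapezoidal integration with tied scores grouped
(scikit-learn's implementation behind the module surface; the test suite
checks it against exhaustive Mann–Whitney pair counting). Specificity is
TN/(TN+FP), the standard definition. A metric with a zero denominator is
reported as absent (`None` / `--`), never as 0, so model comparisons are not
silently biased by degenerate slices.

## Synthetic data: what it does and does not show

`generate_proteins` plants one copy of a short motif (default `WCHKY`, an
arbitrary fixed 5-mer over distinctive letters) in each random sequence and
labels the motif-center residue as the hotspot; off-motif residues are
sampled as negatives to a configurable ratio. Defaults — 150 proteins of
length 80–120, 5% per-position motif substitution noise, no background
label noise, ratio 1:63 — are chosen so that the corpus has the same
imbalance structure as the measured data while remaining solvable from
windows alone. ΔΔG values are drawn consistent with each label (hotspots
2 + Exp(1.5) kcal/mol, negatives U(−1, 2)), so the ddG-labeling path is
exercised end to end.

Because the Bayes-optimal decision depends only on window content, a
window classifier can recover the rule almost perfectly (held-out AUC ≈ 1);
passing this recovery check demonstrates that featurization, windowing,
balancing, training and evaluation compose correctly — it says nothing
about accuracy on real interfaces, where the signal is weaker, non-local
and entangled with structure. The label-permutation control (training
labels shuffled, same settings) verifies the opposite direction: with no
signal, held-out AUC stays near 0.5. The control is scored on the test
partition only — under the null, the validation set is biased upward
because early stopping selects the checkpoint that maximizes validation F1.

One observed limitation of dense whole-sequence prediction: the classifier
is trained only on annotated-residue windows, so scores for arbitrary
residues (especially heavily padded windows near sequence ends) are poorly
calibrated and hover near the threshold.

## Numerical and design notes

- Positions are 1-based in every file format and in example metadata;
  0-based indices are internal, converted exactly once at the I/O boundary.
- Split sizes round half away from zero; selection is a seeded permutation.
- Stride subsets are truncated (not resampled) to the target size; a
  request exceeding the stride yield is an error reporting the achievable
  size.
- SMOTE requires strictly more than `k` minority rows; `r` is drawn on the
  open interval (a draw of exactly 0 is remapped, so duplicates of `X_old`
  arise only via the test hook).
- Window caches and model checkpoints are `.npz` artifacts created at run
  time; split manifests, annotation tables, histories, metrics and
  predictions are plain text (TSV/JSON).
- Problem sizes in tests and in the acceptance script (tiny window
  datasets for assembly arithmetic, the 150-protein default corpus for
  recovery) are the package's chosen study conditions: large enough to
  exercise every code path and exhibit the published set sizes exactly,
  small enough to run comfortably on a laptop CPU.

## Known limitations

- Sequence-local windows only; no structural neighborhoods.
- The pretrained-embedding path is exercised with synthetic matrices; no
  published embedding model is bundled or downloaded.
- Redundancy filtering of input corpora (e.g. at 30% identity) is the
  caller's responsibility; annotation tables are taken as given, including
  any reconciliation of conflicting ΔΔG measurements.
- The numpy CNN is single-threaded and sized for window inputs; it is not a
  general deep-learning stack.
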