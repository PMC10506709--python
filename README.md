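# hotspot1d

Prediction of protein–protein interaction **hot-spot residues** from sequence
windows with a small 1-D convolutional neural network.

Hot spots are the minority of interface residues that contribute most of a
complex's binding free energy: alanine-scanning mutagenesis defines them as
residues whose mutation raises the binding free energy by more than
2 kcal/mol (ΔΔG > 2). Identifying them matters for understanding interfaces
and for drug-target design, but experimental scanning is slow, and measured
corpora are severely imbalanced — roughly one hot spot per 63 non-hot-spots.

`hotspot1d` implements the full modeling pipeline as a tested library plus a
CLI:

- **Featurization** — each residue of a protein becomes a feature vector:
  a 21-dimensional one-hot encoding (20 standard amino acids + a catch-all
  `X`), optionally concatenated with a precomputed per-residue embedding
  matrix from a pretrained protein language model (e.g. 4096-dim vectors,
  giving the 4096 + 21 = 4117-dim representation). Pretrained embeddings
  enter as keyed HDF5 matrix containers; no language model is run here.
- **Windowing** — a sliding window of odd width *w* (default 33, sweep range
  21–41) centered on each annotated residue; positions beyond the sequence
  ends are zero-padded rows, so every example is an identical *w* × *D*
  matrix.
- **Imbalance handling** — deterministic interval (stride) subsampling of the
  ordered negative pool, plus SMOTE synthesis of minority examples:
  `X_new = X_old + r · (X_n − X_old)` with `X_n` one of the `k` nearest
  minority neighbors and `r ~ U(0, 1)`. Class weighting
  (`w_c = N / (2 N_c)`) is provided as the in-loss alternative.
- **Classifier** — a 1-D CNN over the window axis: three conv blocks
  (64/16/4 filters, kernels 7/5/3, ReLU, same padding, max-pool 2), dropout
  0.5, a dense layer of 8 units and a sigmoid output, trained with RMSprop
  on binary cross-entropy with early stopping on validation F1. Depth is
  configurable (2–5 layers; extra layers clone the middle block). The
  network, including backpropagation and the optimizer, is implemented in
  numpy and is fully deterministic under a seed.
- **Evaluation** — accuracy, recall, precision, F1, specificity
  (TN/(TN+FP)) and ROC/AUC, with undefined metrics reported as absent.
- **Synthetic fixtures** — a motif-planted corpus generator (hotspot =
  planted motif center) and Gaussian feature clouds, so every stage is
  testable without downloads.

## Worked example

The five CLI commands chain on a synthetic corpus (40 proteins, one planted
motif each, 12 non-hotspots per hotspot):

```bash
hotspot1d simulate --outdir run --n-proteins 40 --imbalance-ratio 12 --seed 7
# wrote 40 proteins, 40 hotspots, 480 non-hotspots -> run
hotspot1d prepare --outdir run --fasta run/proteins.fasta \
    --annotations run/annotations.tsv --width 33 --seed 7
# train 368 (pos 184), validation 13, test 16 -> run
hotspot1d train --datadir run --outdir run --seed 7
# best epoch 4 (validation F1 1.0000); model -> run/model.npz
hotspot1d evaluate --datadir run --outdir run
# Data set        Acc   Recall      Pre       F1      Spe      AUC
# validation   1.0000   1.0000   1.0000   1.0000   1.0000   1.0000
# test         0.9375   1.0000   0.8750   0.9333   0.8889   1.0000
hotspot1d predict --fasta run/proteins.fasta --model-path run/model.npz --outdir run
```

`prepare` windows every labeled residue, takes the stride subset of
negatives that matches the positive count, splits 1/5 test and 1/5
validation, expands the training negatives with further stride subsets and
balances with SMOTE — here 184 positives vs 184 negatives (368 training
examples). `train` early-stops once validation F1 stops improving and keeps
the best checkpoint. `evaluate` prints the metric table above (on 16 test
windows the model makes one false-positive call). `predict` scores every
residue of every input sequence and writes a TSV of
`protein_id  position  residue  score  label`.

Each command also accepts `--config config.yaml` (flat keys, flags win) and
writes a `<command>_log.json` recording the effective configuration, seed
and library versions; reruns with the same config and seed are
byte-identical.

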