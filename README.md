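# seqbind

Sequence-based prediction of protein–ligand binding residues.

Most accurate binding-site predictors rely on solved structures of close
homologs. When no such structure exists, the only usable signal is in the
sequence and its evolutionary profile. `seqbind` implements a
sequence-only predictor for structural bioinformaticians and method
assessors: it labels binding residues from structures (for training and
truth), encodes residues from PSI-BLAST profiles and AAindex property
scales, classifies them with an ensemble of random forests trained on
balanced data sets, and scores predictions with CASP-style per-target
metrics.

## Method

For residue *i* with profile row `SP_i` (20-dim, row-stochastic) and a
property scale `AAP_j`, the descriptor is

```
f_ij = std20( SP_i ⊙ AAP_j )          (population std, divisor 20)
```

A window of length W centred at *i* concatenates these scalars for the W
neighbours over all P selected properties → a W·P feature vector
(7 × 34 = 238). Property scales are filtered greedily so no surviving pair
has |Pearson CC| ≥ 0.5.

Because binding residues are rare (~4 %), the negatives are split into
n = 15 disjoint subsets; each subset plus *all* positives trains one random
forest, and the ensemble score is the fraction of forests voting
"binding". Predictions from N window lengths are combined as

```
Pred_comb = mean(Pred_1..N) − std(Pred_1..N)
```

which penalizes disagreement between window sizes. Metrics are
Sen/Spe/Acc/Prec/F1 (%) and the Matthews correlation coefficient, per
target and macro-averaged by ligand chemical class, with per-target
Z-scores across predictors and a Bernoulli random baseline.

See `docs/methods.md` for conventions, parameters and limitations.

## Worked example

Recover the confusion matrix of a 216-residue metal-binding target from
its printed summary (binding ratio 6.48 %, Sen 100.00 %, Prec 73.68 %) and
recompute all metrics:

```python
from seqbind.evaluation import confusion_from_summary, metrics_from_counts

c = confusion_from_summary(216, 6.48, 100.00, 73.68)
print("counts:", c)
rep = metrics_from_counts(c)
print(f"Sen {rep.sen:.2f}%  Spe {rep.spe:.2f}%  Prec {rep.prec:.2f}%  "
      f"F1 {rep.f1:.2f}%  MCC {rep.mcc:.2f}")
```

prints

```
counts: ConfusionCounts(tp=14, fp=5, tn=197, fn=0)
Sen 100.00%  Spe 97.52%  Prec 73.68%  F1 84.85%  MCC 0.85
```

i.e. the predictor found all 14 binding residues with 5 false positives
among 216 residues, giving MCC 0.85 — the value published for this target.

An end-to-end run on synthetic data (generate → encode → train → predict →
evaluate):

```sh
seqbind run --workdir demo --seed 1
cat demo/evaluation/summary.json
```

or label binding residues of a structure directly:

```sh
seqbind label --pdb my.pdb --mode vdw --tolerance 0.5 --out labels.tsv
```

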