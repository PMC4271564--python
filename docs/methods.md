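# Methods

## Problem and model

`seqbind` predicts, from sequence information alone, which residues of a
protein chain bind a small-molecule or metal ligand. Ground truth comes
from structures: a residue is a binding residue when at least one of its
heavy atoms lies within a distance rule of any ligand heavy atom. Two rule
conventions are implemented — a fixed cutoff (default 5.0 Å) and the sum of
the two atoms' van der Waals radii plus a tolerance (default 0.5 Å). The
vdW convention yields ≈3.9 % positive residues on typical assessment sets,
the fixed 5 Å rule ≈9 %; this imbalance drives the design of the learner.

The predictor has three stages:

1. **Encoding.** Each residue carries a 20-dimensional evolutionary
   profile row (PSI-BLAST weighted percentages normalized to sum to 1, or a
   pseudo-profile when no PSSM exists). For a property scale `AAP_j`
   (20 values from AAindex1) the residue descriptor is the standard
   deviation over the 20 amino acids of the element-wise product
   `profile_row ⊙ AAP_j`. A sliding window of odd length W stacks these
   scalars for the W neighbours across all P selected properties, giving a
   W·P-dimensional feature vector (238 for W = 7, P = 34). Scales are
   de-redundantized by a greedy filter: pairs with |Pearson CC| ≥ 0.5 are
   "related"; scales are ranked by partner count and taking a scale removes
   its partners until no related pair survives.
2. **Balanced random-forest ensemble.** The negative pool is split into
   n (default 15) disjoint subsets; each subset joins *all* positives to
   form one balanced training set, and one random forest (default 500
   trees, `int(log2(J)+1)` features per split) is trained per set. The
   ensemble score of a residue is the fraction of forests voting positive;
   a vote threshold v (majority ⌈n/2⌉ by default, unanimity v = n also
   supported) turns scores into calls.
3. **Window combination.** Scores from N window lengths (default
   {5, 7, 9, 11, 17, 27, 37, 47, 57}) are merged as
   `combined = mean − std` (population std), which equals the mean only
   when all windows agree and otherwise penalizes disagreement; calls are
   made at a decision threshold (default 0.5, equivalent to majority voting
   when windows agree).

Evaluation follows community-assessment conventions: per-target confusion
counts; Sen/Spe/Acc/Prec/F1 (percent) and MCC; unweighted per-target macro
averages with optional grouping by ligand chemical class
(metal / non-metal / hybrid); per-target Z-scores across predictors
(population σ); a Bernoulli random baseline averaged over 100 runs; and a
reconstruction routine that recovers the unique integer confusion matrix
from a printed (N, ratio %, Sen %, Prec %) summary row, validated by a
0.5-point round-trip check.

## Numerical and convention choices

- **Amino-acid order**: all 20-vectors use alphabetical one-letter order
  internally; PSSM columns and AAindex I-block rows are remapped on parse.
- **Standard deviations**: population form (divisor 20 for the feature
  reduction, divisor N for the window combination and Z-scores),
  configurable via `ddof`. The population form keeps the fixed-size
  20-vector reduction scale-equivariant.
- **Window padding**: positions beyond the chain termini contribute feature
  value 0 (the natural "no information" value for a non-negative std
  feature); edge replication is available via `padding="edge"`.
- **Column layout**: window-offset-major, property-minor; a layout
  fingerprint is stored with every feature matrix and model and checked at
  predict time.
- **Degenerate metrics**: Prec with no predicted positives → 0; MCC with a
  zero factor under the root → 0; F1 with Prec+Sen = 0 → 0.
- **AAindex NA policy**: entries with missing values are dropped by
  default (mean imputation behind a flag). Scales are used as published,
  not z-scored.
- **Greedy filter determinism**: ranking ties break lexicographically by
  accession; survivors are returned sorted by accession, which makes the
  filter a fixed point of itself.
- **Zero PSSM rows** (residues with no alignment information) fall back to
  the one-hot row of the query residue.
- **Contact rule**: highest-occupancy alternate locations, first MODEL
  only, hydrogens and waters excluded. The bundled radius table uses Bondi
  (1964) values, supplemented for metals absent from Bondi with Batsanov
  (2001); unknown elements raise unless a fallback radius is configured.
- **Seed fan-out**: one global seed derives per-stage and per-forest seeds
  by CRC32 hashing of a component tag, keeping all derived seeds below
  2^31 and the stages individually reproducible.

## Synthetic benchmark

Real assessment data (structures plus deep PSI-BLAST profiles) cannot be
shipped, so the generator emulates the three statistical features the
method exploits:

- per-residue labels i.i.d. Bernoulli with ratio 0.05 (≥1 positive per
  chain enforced), matching the observed imbalance scale;
- binding positions enriched in Asp/Gly/His (probability 0.6), matching
  the observed composition bias;
- profile rows drawn from a symmetric Dirichlet(α = 0.5) background —
  sparse rows, as in profiles of proteins with few homologs — while
  binding rows draw from a Dirichlet concentrated on the observed residue
  with total mass scaled by (1 + s). At s = 0 positive and negative rows
  are exchangeable; s ≥ 100 is implemented as the exact one-hot limit.

Defaults: 60 chains of length 150, ratio 0.05, s = 2.0. What this model
deliberately omits: spatial clustering of binding sites along the chain and
in 3-D, chain-length variation, realistic profile column covariance, and
any relation between ligand identity and site composition. Passing the
recovery benchmark therefore shows that the pipeline detects a planted
conservation/composition signal under realistic imbalance — not that it
attains any particular accuracy on real proteins.

The planted-signal benchmark holds out the last 20 of the 60 chains
(40 train / 20 test) and reports pooled held-out MCC. The headline check
runs the full default pipeline (9 windows, 15 subsets, 500 trees):
held-out MCC ≈ 0.69 at seed 7. The repeated-seed checks (shuffled-label
null control and the monotone signal sweep over s ∈ {0, 1, 2, 4}, five
seeds each) use a reduced configuration — windows {5, 7, 9}, 50 trees —
chosen as the benchmark's standard problem size for multi-run sweeps; the
measured margins are wide (sweep means ≈ 0.02 / 0.55 / 0.80 / 0.89,
shuffled-control mean ≈ 0.03).

The on-disk suite writer emits the exact external formats the pipeline
reads (FASTA, labels TSV, two-block ASCII PSSMs, AAindex flat file).
Integer PSSM percentages use largest-remainder rounding so each row sums
to exactly 100, bounding the parse round-trip error by 0.01 per entry.

## Known limitations

- Ligand chemical classification is a HET-code lookup with a configurable
  default; exotic codes fall to "non-metal" with a warning.
- The greedy correlation filter reproduces the published *procedure*; the
  identity of the 34 scales selected from the full AAindex database depends
  on the database release and is not asserted.
- The exact positive counts of the original assessment sets depend on the
  (unpublished) vdW radius table used there; the bundled table reproduces
  the rule, not necessarily those counts.
- `combine_windows` operates on vote-fraction scores; combining hard 0/1
  calls is possible by passing binary vectors but makes the std term
  degenerate when members agree.
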