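# Methods

## Model and assumptions

`idlscore` scores peptide–GPCR pairs with a linear soft-margin SVM over
combination features and attributes the decision value back to residues.
The approach assumes:

* **Interaction is decided by sequence-local determinants** — short peptide
  motifs meeting specific receptor residues at aligned transmembrane (TM)
  positions.  Conformational effects, post-translational modification and
  expression differences are outside the model.
* **A shared generic numbering exists.**  Every receptor in a corpus is
  annotated with the same totally ordered list of Ballesteros–Weinstein
  positions (a position ↔ 1-based sequence index table, gaps allowed).  The
  annotation is consumed as input; computing TM alignments is out of scope.
  Loop and terminal residues are absent from the annotation and therefore
  carry no descriptor elements and no scores.
* **Linearity.**  The decomposition is exact *because* the model is linear;
  nonlinear kernels would break the per-residue attribution and are
  deliberately not offered.

### Descriptors

Peptide descriptor (PD): binary occurrence indicators over the vocabulary
of all distinct 5-mer windows in the training peptides, frozen at training
time; unseen motifs at prediction time are ignored (the model has no
weights for them).  Occurrence is binary ("exists"), but every occurrence
contributes its five covered residue positions to the motif → residue map
used by the decomposition.  Multiple occurrences therefore widen a motif's
attribution without changing its descriptor element.

Receptor descriptor: per reference position, the five Sandberg z-scales of
the aligned residue (dimensionless physicochemical principal-component
scales; shipped as `data/zscales_sandberg.tsv`), zeros at gaps.  No
standardization is applied by default: the z-scales are already variance-
comparable, and leaving them raw keeps descriptor elements interpretable in
table units.

### Decomposition

With `dist = Σ w_ij pD_i gD_j + b`:

* `IDL(M)` sums the terms of position *M*'s five elements.  The element
  blocks partition *j*, so `Σ_M IDL(M) = dist − b` to machine precision;
  this is asserted at 1e−9 in the tests.
* `IDL(N)` sums the full term of every motif covering residue *N*.  Motif
  terms are counted once per covered residue, so
  `Σ_N IDL(N) = Σ_i c_i t_i` where `c_i` is the covered-residue count —
  equal to `5 · (dist − b)` exactly when every motif occurs once.
* The intercept `b` is a property of the decision axis, not of any residue,
  and is excluded from all scores; `dist − b` is the conserved quantity.
* Scores are raw decision-axis contributions (dimensionless); no
  normalization across peptides or receptors is applied.

## Training protocol

* Negatives: when a corpus carries only positives, swap negatives are
  generated — each pairs the peptide and receptor of two different positive
  records, excluding known positives, in equal number to the positives.
  Class balance is therefore structural; no class weighting is used.
* SVM: `LinearSVC`, C = 1.0 default, tolerance 1e−6, fixed `random_state`;
  ties at dist = 0 classify as non-interacting (conservative calls).
* Feature selection: a seeded genetic algorithm over binary masks of the
  combination features (fitness = 5-fold CV ROC AUC − 0.01 × selected
  fraction; population 50, generations 20, tournament size 3, uniform
  crossover p = 0.5, per-bit mutation 1/n).  It is **off by default**: on
  corpora of tens of peptides the combination grid reaches ~10⁵ features,
  where a bit-mask GA of this size cannot move meaningfully and its
  CV-fitness cost dwarfs the SVM fit itself.  It is effective and tested at
  the scale it suits (dozens of candidate features); enable via
  `TrainConfig(feature_selection=GAConfig(...))`.

## Determinant nomination

`compare_paralogs` implements the one-vs-one rule: a position is nominated
when its score on the active receptor exceeds `tau_pos` (default 0) and its
score on the inactive receptor is at most `tau_neg` (default 0), ranked by
the score delta.  The thresholds are configurable; the defaults encode the
sign interpretation (positive = contributes to the interaction call).

This comparison is clean for true paralogs because identical residues
contribute identically and cancel in the delta.  Synthetic receptors are
*unrelated* random sequences: every position differs between any two
receptors, so a one-vs-one delta carries noise at all P positions.
`determinant_screen` is the robust variant for that setting: receptors are
classified as active/inactive panels purely from the observed labels
(ligand peptides = positive with > 25 % of receptors; active receptors =
positive with > 50 % of ligand peptides; inactive = ≤ 25 %), profiles are
averaged per panel, and the report is the panel delta.  Averaging over ~10
receptors per panel suppresses the position noise a single random partner
injects.  The panel fractions sit midway between the values the planted
rule produces for true members (~50 % / ~95 %) and for non-members
(~0–5 %), so classification is insensitive to the noise rate.

Mutation-effect evaluation scores each annotated mutation by the wild-type
receptor's `IDL(M)` at the mutated position ("a high positive score
predicts that mutating this position decreases the interaction") and
reports the ROC AUC with `decreasing` as the positive class, never flipped.
Records spanning several receptors can be pooled into one ranking (default)
or averaged per receptor.

## Synthetic corpora

The generator emulates the determinant structure the method targets: a pair
interacts iff the peptide carries a planted 5-mer motif AND the receptor
presents required residues at designated generic positions; labels flip
with probability ε.  Defaults: peptide lengths 8–16 (typical endogenous
peptide range), motif planted in 50 % of peptides, the full determinant set
in 50 % of receptors, every peptide × receptor pair labeled.  An additive
rule variant (label probability = fraction of satisfied conditions) models
determinants that act independently rather than synergistically.

Reference position lists are generated at the conserved TM spans (helix
anchors 1.35, 2.38, 3.22, 4.62↲, 5.35, 6.30, 7.51↲), so defaults always
contain the TM termini used by the full-length filter.

What the generator does **not** emulate: sequence homology between
receptors (they are independent draws, not paralog families), motif
degeneracy or partial matches, peptide physicochemistry beyond exact motif
identity, and any dose–response structure.  Passing the recovery benchmark
therefore shows the pipeline recovers *planted, exact* determinants under
label noise — not that it resolves the subtler signals of real corpora.

## Benchmark problem sizes

The replicated recovery study (`recovery_benchmark`) uses 60 peptides × 20
receptors over 40 positions, ε = 0.05, one rule (1 motif + 2 determinant
positions), 20 replicates: per replicate, held-out ROC AUC from a 75/25
pair split, then a refit on all pairs feeds the determinant screen and
top-5 recovery of the planted positions is scored.  These sizes keep a full
run in the tens of seconds while leaving the per-replicate recovery problem
genuinely noisy (10-receptor panels, 5 % flipped labels).

## Numerical choices and degenerate inputs

* Decomposition identities are exact linear-algebra regroupings; tests
  assert them at 1e−9 absolute.
* Delta ranking uses a stable sort; exact ties keep reference order.
* Non-canonical residues (X, B, Z) are rejected at load; gap positions
  decompose to exactly zero; peptides shorter than the 5-mer window are
  rejected.
* Swap-negative generation enumerates the candidate set exactly and fails
  with the deficit when fewer distinct candidates than positives exist
  (e.g. complete-bipartite positives).
* All stochastic stages (corpus generation, pair splits, negative
  generation, GA, CV folds, SVM solver) take explicit integer seeds; the
  pipeline manifest hashes every numeric output for rerun verification.

## Known limitations

* The motif vocabulary is closed-world and exact-match; a single
  substitution in a determinant motif is invisible to the model.
* Weights on ~10⁵ combination features estimated from ~10³ pairs are
  individually noisy; single-pair IDL profiles inherit that noise, which is
  why the panel screen, not the one-vs-one comparison, is the recommended
  readout on non-paralog receptor sets.
* The AUC evaluator assumes the wild-type profile is computed for the
  peptide whose recognition the mutation records describe; mixing records
  from different ligands of one receptor into one call is not meaningful.
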