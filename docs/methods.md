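# Methods

## Problem and model

`antioxpred` classifies proteins as antioxidant or non-antioxidant from
four information channels: the amino-acid sequence itself, a predicted
three-state secondary structure (helix H, strand E, coil C), per-residue
relative solvent accessibility (RSA, the accessible surface area normalized
by the residue's area in an extended Ala-X-Ala tripeptide, in [0, 1]), and
a PSI-BLAST position-specific scoring matrix (PSSM).  The package consumes
these channels as files; it never runs the upstream predictors or aligners
that produce them.

Each protein of length L is mapped to a fixed 759-dimensional hybrid
vector:

* **SSI (21)** — secondary-structure descriptors.  Content F_j = N_j / L
  for j ∈ {H, E, C}; transition frequencies T_{i,j} = N_{i,j} / (L − 1)
  over all nine ordered state pairs, where N_{i,j} counts adjacent
  positions (s_k = i, s_{k+1} = j); average and normalized-maximal run
  lengths per state (AvgSeg_i, NMaxSeg_i = max run / L); and order
  statistics F_i = (Σ_j p_{i,j}) / (L(L − 1)) with p_{i,j} the 1-based
  position of the j-th occurrence of state i.
* **RSA (28)** — mean and population standard deviation of the RSA trace;
  counts of buried and exposed runs (a residue is exposed iff RSA ≥
  threshold, default 0.25); min/max run length per state; and the mean RSA
  of each of the 20 amino acids over the positions carrying it.
* **CTD (310)** — composition (20 fractions), transition (190 unordered
  adjacent-pair frequencies over (L − 1), pairs in lexicographic order),
  and distribution: for each amino acid present, the 1-based positions of
  its 1st, ⌈0.25 n_a⌉-th, ⌈0.50 n_a⌉-th, ⌈0.75 n_a⌉-th and n_a-th
  occurrence, each divided by L.
* **PSSM (400)** — the L×20 log-odds profile collapsed to 20×20 by summing
  all rows whose sequence residue is the same amino acid, flattened
  row-major in the canonical alphabetical ordering.

Feature selection is Relief followed by incremental feature selection
(IFS).  Relief scores feature p by iterating over instances: the weight is
decreased by the scaled distance to the nearest same-class neighbor (hit)
and increased by the scaled distance to the nearest other-class neighbor
(miss), each divided by the number of sampled instances m.  IFS evaluates
every prefix of the weight-ranked feature list by cross-validated accuracy
and keeps the smallest prefix attaining the maximum.

Classification is a two-stage ensemble.  Ten base classifiers are each
scored by stratified 10-fold CV accuracy and ranked; nested prefixes of
that ranking are evaluated as average-probability ensembles, and the
smallest prefix attaining the maximum accuracy is refit on the full
training table.  Prediction fuses members by the unweighted mean of their
positive-class probabilities, calling a sample positive iff the mean is
≥ 0.5 (ties positive).

Evaluation uses Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc, the Matthews
correlation coefficient, and the ROC AUC (Mann–Whitney form, ties counted
half).

## Numerical and design choices

* **Canonical ordering.**  All 20-wide structures use the alphabetical
  single-letter ordering A,C,D,…,Y; PSSM file columns are re-mapped to it
  at parse time so a column index always denotes the same residue.
* **1-based positions** for the SSI order block and CTD distribution
  block; the distribution normalizer is L, and quantile occurrence indices
  are ⌈q·n_a⌉ clamped to ≥ 1, so the 5-tuple reduces to the 1st and
  n_a-th occurrences at its anchors.
* **Empty-category convention.**  Every statistic over an empty set (no
  run of a state, amino acid absent) is 0, never NaN: vectors are always
  finite and fixed-length.
* **SSI vs CTD transition counting.**  SSI transitions use all 9 ordered
  pairs; CTD transitions use the 190 unordered pairs counted in both
  directions.  These are the only conventions consistent with the
  advertised block widths (21 and 310).
* **RSA std** is the population form (divide by L): the vector describes
  the chain, it does not estimate a parameter.  The exposed threshold
  defaults to 0.25, the conventional two-state RSA cut; it is
  configurable.
* **PSSM block** sums raw log-odds with no squashing or length
  normalization.  The unbounded scale is handled downstream: a per-feature
  z-score standardizer (fit on training data only — inside each CV fold's
  training split during CV) precedes all distance-based learners.
* **Relief.**  The coordinate difference uses the absolute value of the
  min–max-scaled gap; a signed difference would cancel across updates and
  could not measure feature quality.  One nearest hit and one nearest miss
  (k = 1), every instance sampled once (m = n) in a seed-shuffled order,
  Manhattan distance, neighbor ties broken by lowest sample index.
  Min–max scaling is internal, making weights invariant under increasing
  affine rescalings of any feature.  An instance whose class has no other
  member contributes only its miss term, with a warning.
* **Ranking ties** (features and classifiers) break toward the lower
  original index / earlier registry position; IFS and subset selection
  break accuracy ties toward the smaller subset.  Everything downstream is
  therefore a deterministic function of inputs and the seed.
* **Cross-validation.**  Folds are stratified by a shuffled per-class
  round-robin deal (per-class counts differ by ≤ 1 across folds, works
  down to leave-one-out, deterministic under the seed).  Reported CV
  metrics are pooled (micro): confusion counts are summed over folds and
  the metrics computed once, which stays well-defined with unbalanced
  folds; per-fold metrics are also retained.  The AUC is computed from the
  pooled out-of-fold scores.
* **MCC** with any zero denominator factor is defined as 0 and flagged.

## Base-classifier registry

The ten defaults approximate a classical heterogeneous committee with
scikit-learn implementations: random forest (100 trees); linear-kernel SVC
with sigmoid probability calibration (`CalibratedClassifierCV`,
`ensemble=False`); 1-nearest-neighbor (degenerate 0/1 probabilities); an
unpruned CART tree; categorical naive Bayes over 5-bin quantile-discretized
features (a discrete Bayes-network analog); RBF-kernel SVC with the same
calibration; a depth-2 tree (decision-table stand-in); AdaBoost over
stumps; a natively implemented voting-feature-intervals classifier (VFI:
per-feature, per-class [min, max] training intervals; each feature splits a
unit vote equally among the classes whose interval contains the test value;
votes are summed and normalized, falling back to uniform when no interval
fires); and Gaussian naive Bayes.  Hyperparameters are fixed at these
documented defaults with one global seed; the registry is pluggable, and
the selected ensemble typically reduces to the top few members anyway.

## Synthetic data

The generator fabricates all four channels so the pipeline is testable
without Porter/PaleAle/PSI-BLAST runs.  Defaults mirror a balanced
100 + 100 training set with lengths uniform on [50, 200].  Sequences are
i.i.d. draws from a softmax over per-amino-acid log-weights (uniform base;
the positive class adds `composition_shift`).  Secondary structure is a
sticky first-order Markov chain (stay probability 0.7) whose emission
distribution per protein is a Dirichlet draw (base α = (3, 2, 4) for
H, E, C; positives add `ss_content_shift`).  RSA values are Beta draws with
mean 0.35 (+`rsa_shift` for positives) and concentration 8.  Pseudo-PSSM
rows are 5× one-hot indicators of the true residue plus Gaussian noise
(σ = `pssm_noise`), rounded to integers — format- and alignment-consistent
by construction, with no claim to biological realism.

The shifted preset enriches positives in cysteine (+1.0 log-weight) and
methionine (+0.6), leans their structure toward helix (+2.0 on α_H, −0.5
on α_E) and raises mean RSA by 0.12 — a caricature of the redox-active,
surface-exposed character expected of antioxidant proteins.  These are
deliberately strong effects: passing end-to-end tests demonstrates that
the pipeline recovers planted signal and stays at chance on null data, not
that it would attain any particular accuracy on real proteins, which carry
homology structure, correlated channels and far subtler class differences.

## Experiment sizes

The synthetic end-to-end experiment trains on 100 + 100 proteins and tests
on a disjoint 50 + 50 bundle; feature selection keeps the top-150 Relief
features (the scale of the optimum reported for the real benchmark) rather
than scoring all 759 IFS prefixes with the full ensemble, which the API
supports but which is disproportionate for a synthetic smoke test.  The
planted-feature recovery experiment uses 20 seeds of 50 + 50 proteins with
a +3.0 cysteine log-weight shift and asks whether `ctd.c.C` reaches the
Relief top 10 of 759.  The null experiment runs the 4-member ensemble
under 10-fold CV on a 100 + 100 zero-shift bundle and compares accuracy to
the 95% binomial band around 0.5 at n = 200.

## Known limitations

* The published benchmark results are not reproducible here: they require
  the curated protein set plus Porter 4.0, PaleAle 4.0 and
  PSI-BLAST-against-nr annotations, which are consumed, not computed.
  The worked metric values shipped in the tests are exact reconstructions
  of the reported confusion matrices, not re-runs.
* WEKA's SMO, BayesNet, Decision Table, RBFNetwork and VFI are
  approximated by the analogs above; no bit-exact equivalence is claimed.
* The Relief variant (k = 1, m = n) is one deterministic member of the
  Relief family; ReliefF-style multi-neighbor averaging is out of scope.
* Sigmoid calibration of the SVC members is a choice, not a given; other
  calibrations change fused probabilities slightly.
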