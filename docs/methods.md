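# Methods

## The model

`pathmm` ranks protein-level missense substitutions by combining two
sources of evidence:

1. **Sequence conservation** from profile hidden Markov models.  Each
   protein carries an *ab initio* profile covering its full length;
   curated domain models (Pfam-A, SUPERFAMILY, Pfam-B) may additionally be
   annotated onto residue ranges.  For a substitution at residue *i*, every
   covering model contributes a candidate match state, and the state whose
   emission distribution diverges most from a background amino-acid
   composition — measured by the Kullback–Leibler divergence
   D(p‖q) = Σ_a p_a ln(p_a/q_a), in nats — is selected.  That state
   supplies P_w and P_m, the emission probabilities of the wild-type and
   mutant residues.

2. **Pathogenicity weights** summarizing how tolerant each model is to
   mutation.  Training substitutions mapping onto a model are counted on a
   pathogenic side (d) and a neutral side (n); the weights are the
   in-model relative frequencies W_d = d/(d+n), W_n = n/(d+n).

The score of a substitution is

    score = ln[ ((1 − P_w)(W_n + 1)) / ((1 − P_m)(W_d + 1)) ]

Negative scores indicate damage: a highly conserved wild type (P_w → 1)
or a mutation-intolerant, disease-burdened model (W_d ≫ W_n) both push
the score down.  Scores below a threshold (default 0, the natural sign
boundary of the log ratio; a score exactly at the threshold counts as
tolerated) are predicted *damaging*.  The `(W + 1)` form keeps the score
finite for any weights in [0, 1], and a model with no training data
(W_d = W_n = 0) degrades gracefully to the pure conservation term
ln((1 − P_w)/(1 − P_m)).

### Disease-specific weighting

Pathogenic training variants carry one or more of 17 root disease-concept
tags (blood, blood_coagulation, developmental, digestive, ear_nose_throat,
endocrine, eye, genitourinary, heart, immune, metabolic, musculoskeletal,
nervous_system, psychiatric, reproductive, respiratory, skin).  Two
weighting schemes are supported:

* **inherited** — all disease-labelled variants are pathogenic-side,
  neutral polymorphisms neutral-side;
* **disease_specific(c)** — only variants tagged with concept *c* are
  pathogenic-side; *all other variants, including other diseases'
  mutations, are treated as neutral*.

The disease-specific scheme penalizes only variants falling in proteins
and domains whose mutation burden is specific to the concept under study,
which is what reduces false-positive calls on other diseases' variants.

A **naive baseline** ln((W_n + 1)/(W_d + 1)) omits conservation entirely.
All variants on a model then share one score, so the baseline degenerates
whenever weights are balanced; it is kept as the comparator that isolates
the contribution of conservation.

### Leave-one-out weights

When a scored variant is itself part of the weight-training set, its own
unit contribution is removed from the side it incremented before its
weights are formed.  `loo_adjust` followed by `weights_from_counts` is
exactly equivalent to recomputing weights on the dataset minus that
variant (property-tested).

## Interpretation choices the sources left open

* **"Most informative model" is evaluated position-locally**: the KL
  divergence of the covering match state, not a model-wide average, so
  that informativeness, P_w and P_m all refer to the same state.  Exact
  ties fall to the more curated source (Pfam-A > SUPERFAMILY > Pfam-B >
  ab initio), then to model id, making selection deterministic and
  permutation-invariant.
* **"Relative frequencies" are per-model**: W_d is the pathogenic share of
  the substitutions mapping onto that model, which is the only reading
  under which a gene's own intolerance penalizes its variants while a
  hypervariable gene's variants go unpenalized.
* **A variant increments every covering model**, so a domain and its host
  protein's ab initio model each accumulate their own counts.

## Evaluation

* **Class-normalized statistics.**  The six summary statistics (accuracy,
  precision, sensitivity, specificity, NPV, MCC) are computed after
  rescaling each class of the confusion matrix to unit mass:
  tp′ = s, fn′ = 1 − s, fp′ = f, tn′ = 1 − f with s the sensitivity and f
  the false-positive rate.  Sensitivity and specificity are unchanged;
  accuracy becomes balanced accuracy (s + (1 − f))/2; MCC reduces to
  (s − f)/√((s + f)(2 − s − f)); precision and NPV become independent of
  class imbalance.  This convention reproduces, at two decimals, every
  published accuracy/precision/NPV/MCC value in the packaged benchmark
  fixture from its raw counts, whereas raw-count formulas do not (raw
  precision on the musculoskeletal disease-specific matrix is ≈0.57
  against the printed 0.95).  `raw_stats` is provided alongside for the
  unnormalized view.  Report rounding is decimal half-up at 2 dp.
* **ROC/AUC** by sweeping all distinct score thresholds (lower score =
  stronger damaging call), trapezoidal integration, ties grouped into a
  single step — numerically identical to the Mann–Whitney concordance
  probability with half credit for ties (oracle-tested to 1e-12).  The
  implementation delegates the sweep to scikit-learn's `roc_curve` with
  `drop_intermediate=False`.
* **Cross-validation** re-estimates weights from the training folds only
  and pools held-out predictions.  The fold unit defaults to the
  *variant*: pathogenicity weights live on a protein's own models, so
  holding out whole proteins zeroes the weights of every held-out variant
  and measures conservation alone (that mode is kept available as
  `fold_unit="protein"`).  Variant-level k-fold is the natural k-fold
  generalization of the leave-one-out adjustment and is the setting under
  which CV and LOO agree.

## The synthetic data generator

`simulate(FixtureConfig(...))` builds a self-contained cohort:

* **Profiles**: per protein, match-state emissions are drawn from a
  symmetric Dirichlet with concentration 1/`sharpness` per residue —
  larger `sharpness` gives peakier, more conserved states (the
  high-sharpness limit approaches point masses, KL → ln 20 ≈ 3.0 nats
  against a uniform background; Monte-Carlo tested).  Default
  `sharpness = 2.0` yields a realistic mix of conserved and diverse
  positions.  0–3 domain models of span 15–40 are packed uniformly into
  the free gaps of each protein.
* **Susceptible sets**: proteins are split into disjoint blocks, one per
  configured concept plus one unassigned block.
* **Variants**: concept-tagged pathogenic variants are placed in their
  concept's susceptible block with probability `weight_bias` (default
  0.9), at positions sampled proportionally to conservation, mutating the
  consensus residue to the least-emitted one.  Neutral polymorphisms are
  placed uniformly over proteins, biased toward diverse positions
  (weight ∝ e^−KL), mutating to a commonly emitted alternative — mirroring
  the observation that conservation-only methods call diverse-region
  variants benign.  Defaults: 300 focal-concept, 300 other-disease and
  600 neutral variants on 40 proteins of length 80–200, uniform
  background.  `weight_bias = 0` gives uniform placement: every model's
  counts approach the global pathogenic/neutral ratio, weights balance,
  and the naive baseline collapses to chance while the weighted score
  retains the conservation signal.

What the generator does **not** emulate: real profiles estimated from
homolog alignments (phylogenetic correlation, site-rate heterogeneity,
alignment uncertainty), shared domain families across proteins, realistic
amino-acid background composition, or annotation noise in concept labels.
Passing tests on these fixtures therefore demonstrate the internal
consistency and discriminative mechanics of the method, not clinical-grade
accuracy on real cohorts.

## Numerical choices

* Emission probabilities are floored at 1e-9 after parsing and (1 − P)
  factors at 1e-9 inside the score, so all logarithms are finite.
* Emission rows are renormalized to sum to 1 within 1e-6 on read; the
  writer prints log-probabilities at 10 decimals so a write/read round
  trip preserves emissions to better than 1e-9.
* Only the 20 canonical amino acids are modelled; profiles or variants
  with degenerate symbols are rejected.
* Weight estimation is exact integer counting; no pseudocounts beyond the
  score's built-in `+1`.
* Deterministic tie-breaks everywhere (model selection priority, stable
  sorts in rankings, seeded shuffles in CV and simulation) make every
  output reproducible byte-for-byte from its config and seed.

## Problem sizes

The packaged study conditions (40 proteins, 1,200 variants, 20-fold CV)
run in a few seconds on one CPU; they are large enough for the planted
disease-specific signal to dominate sampling noise (concept-vs-rest AUC
well above 0.85 under the default bias) while staying convenient for
routine re-runs.

## Known limitations

* Dominating weights can overwhelm the conservation term for models with
  extreme disease burden; rankings should be read alongside the reported
  per-variant informativeness (the chosen state's KL divergence), which is
  emitted in every score table for exactly this purpose.
* Published AUC values for external tools cannot be recomputed from
  confusion matrices alone and are carried through the benchmark fixture
  untouched.
* The classification threshold used by external benchmark rows is
  unknown; threshold-based comparisons against them start from their
  printed confusion counts, not from re-scoring.
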