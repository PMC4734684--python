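# Methods

## Model

`phosphobind` treats the binding affinity of a hexapeptide phosphomotif
(P−3P−2P−1–pS/T–P+1P+2P+3, one terminal variable, the other wildcard) as a
linear function of 54 sequence-derived features,

    f(X) = β₀ + Σⱼ Xⱼ βⱼ ,

fit with the elastic-net penalty

    minimize  RSS + λ Σⱼ [ ½(1−α) βⱼ² + α |βⱼ| ] ,

which interpolates between a ridge-type fit (α = 0, penalty λ/2·‖β‖²) and
the LASSO (α = 1). The linear form is an assumption, not a biophysical law:
it buys interpretable coefficients and fast per-query refits at the cost of
ignoring higher-order epistasis between positions beyond what the
auto-cross-covariance terms capture.

Prediction is *dynamic*: each query motif gets its own training set,
hyperparameters and fit. This matches the sampling rule's intent — a motif
sharing no side-chain category with the query at any aligned position is
treated as uninformative and excluded. A config switch
(`RunConfig.shared_hyperparameters`) instead selects one (α, λ) pair on the
full training set and reuses it per query, since either protocol is
defensible; per-query re-selection is the default.

## Reference tables

The five-category partition (positive R/H/K; negative D/E; polar-uncharged
S/T/N/Q; hydrophobic A/I/L/M/F/W/Y/V; special C/G/P) and the 20×9 property
matrix (H1 hydrophobicity, H2 hydrophilicity, H3 hydrogen bond, V side-chain
volume, P1 polarity, P2 polarizability, SASA, NCI net charge index, MASS)
ship as TSV package data validated by checksum. Two deliberate
preservations:

* the property table prints identical P1/P2/SASA/NCI values for Q and R;
  this is kept verbatim rather than "corrected", since the downstream
  encoding is defined on the printed table;
* standardization of each property column uses the population SD (divisor
  n = 20): the 20 amino acids are the entire population, not a sample. The
  divisor is recorded on the result (`NormalizedPropertyTable.ddof`) so the
  alternative is a one-line change.

## Features

Block one (27 values): the standardized property values of the three
variable residues, position-major. Block two (27 values): for each property
j and position pair (m, n) ∈ {(1,2), (1,3), (2,3)}, the product of the two
positions' deviations from the three-position mean of property j. The
deviations enter on the standardized scale, consistent with standardizing
the properties before any feature is formed. Because deviations from a mean
sum to zero, the three pair terms per property sum to −½ Σᵢ(xᵢ−x̄)²: jointly
non-positive, zero exactly for constant triples — a property-tested
invariant. Only same-property couplings are used; cross-property covariances
would triple the feature count for little benefit at these training sizes.
The phospho-center (pS vs pT) and the wildcard terminal contribute nothing.

### Identifiability on the restricted library

The building-block sublibrary admits only 5 residues at the outermost
position and 10 at the inner two. Its 500×54 feature matrix has rank 50:
individual coefficients are not identifiable there, and the full 20-amino-
acid design (rank 54) is needed for coefficient-level recovery claims.
Consequently, recovery experiments on the restricted library report
`signal_rmse` (fitted vs true noiseless signal — the identifiable quantity)
alongside the raw `coef_max_error`, and the coefficient-recovery test uses a
full-rank design.

## Fitting and hyperparameter search

Features are z-scored on each training set before penalization, the
intercept is unpenalized, and coefficients are mapped back to the original
feature scale. The solver is scikit-learn coordinate descent; on this
objective the mapping is exact (`l1_ratio = α`, sklearn penalty λ/(2N);
Ridge penalty λ/2 at α = 0, solved by SVD along the whole path). Tests pin
the solver to independent oracles: the penalized normal equations for
ridge, `numpy.linalg.lstsq` at λ = 0, and noiseless sparse recovery.

λ is searched on a geometric path of `n_lambdas` values (default 100) from
λ_max — the smallest λ zeroing all coefficients at the given α, computed as
2·max|Xᵀy_c|/max(α, 10⁻³) on the standardized design — down to
`lambda_min_ratio`·λ_max (default 10⁻⁴). Ten-fold CV folds are assigned by
shuffling indices with the run seed and dealing round-robin, so the split is
a deterministic function of the seed. λ is taken at the minimum pooled CV
squared error with ties going to the larger λ (more regularization); α over
the 11-value grid with ties going to the smaller α (ridge-like fits are
stabler on correlated features). No one-standard-error rule is applied.
Affinities are regressed on the raw intensity scale; no log transform is
applied, and predictions are clipped at zero by default since microarray
intensities are non-negative.

Degenerate inputs: constant-y training data yields a zero-slope model
rather than an error; constant feature columns pass through standardization
with SD forced to 1 and receive zero coefficients; a query whose relevance
filter would come back empty falls back to the full candidate list with a
logged warning (impossible for in-library queries, possible for arbitrary
20-amino-acid queries).

## Metrics

`pcc` implements 1 − SSE/SST literally and keeps the name "PCC" for
continuity, although it is a coefficient-of-determination-type statistic,
not the product-moment correlation: it is 1 for a perfect predictor, 0 for
the constant-mean predictor, and unboundedly negative for worse ones. The
true Pearson r is computed alongside as `pearson_r`. `rmse` applies the
square root (consistent with a perfect predictor scoring RMSE = 0).
Leave-one-out verification is computed per terminal; each held-out motif is
predicted by a model trained on the remaining same-terminal records after
relevance filtering.

## Specificity analyses

Top-k extraction breaks affinity ties lexicographically on the encoded
motif string for determinism. Position weight matrices are per-position
relative frequencies over the six variable positions; a position never
covered by the input motifs is flagged absent (NaN), not zero-filled. The
"affinity-weighted" mode weights each motif by its (predicted) affinity
before normalizing — the letter-height convention of sequence-logo figures —
and the unweighted frequency mode is the default; the choice is a flag
because no formula for the weighting is canonical. Consensus binders are
the intersection of all isoforms' top-k lists; isoform-specific binders are
motifs in the target's list and no other's. k defaults to 100 for
1,000-motif runs and 500 for 16,000-motif runs, exposed as a flag.

The similarity score against a reference binder counts, per aligned
position, 3 for an identical residue, 1 for a same-category residue, 0
otherwise (total ≤ 9). Its randomization test draws null motifs uniformly
per position — from all 20 amino acids by default, or from caller-supplied
alphabets (e.g. the building blocks) — and reports p = #(null ≥ observed) /
n_iter without a +1 correction, matching the granularity of p-values
reported at 1,000 iterations. The null is deliberately configurable because
the choice of alphabet materially changes the tail probabilities.

## Synthetic data

The generator emulates the *structure* the method assumes, not the
empirical intensity distribution of the original (unpublished) microarray:

* **linear-sparse** — affinity = 2000 + Xβ* + ε with 8 nonzero coefficients
  drawn N(0, 200²) at seeded positions, ε Gaussian with SD set to 5% of the
  noiseless signal's SD over the 500-motif library (the default experiment
  condition; other fractions via `noise_frac`).
* **consensus** — affinity = 1000 + Σ position effects + ε (SD 50), with
  +500 planted on Arg@P−3 and Pro@P+2 over N(0, 30²) background effects,
  emulating the known RXXpSXP-type consensus.

Negative draws are clipped at 0 (rare at these settings); a log-normal
variant is available via `nonneg="lognormal"`. Because the generating model
of linear-sparse mode is exactly the model class being fit, passing
recovery tests demonstrates correctness of the machinery — sampling,
featurization, CV, fitting, metrics — not real-data accuracy: real
affinities contain epistasis, heteroscedastic noise and distributional
skew that these simulations do not model, and no claim about the original
microarray metrics follows from them.

## Problem sizes in tests and experiments

Unit and property tests run on reduced problem sizes chosen as the smallest
that still exercise the property: λ-paths of 6–20 values, 3-value α grids
where the grid itself is not under test, and seeded query subsets
(`RunConfig.n_queries`) for leave-one-out runs. The full-library acceptance
run — all 500 leave-one-out queries, 11 α values, 10 folds — uses a 20-value
λ path, which changes selected λ only within the flat region of the CV
curve. Determinism contracts (same seed → identical folds, selections,
simulations) are tested explicitly.

## Known limitations

* Real binding data for the seven isoforms is not available, so all
  quantitative accuracy statements are on synthetic data.
* The per-query protocol refits ~11 × 10 CV paths per prediction; a
  16,000-query run is minutes-scale, not interactive.
* The linear model cannot represent interactions beyond same-property
  pair couplings; motifs whose binding depends on three-way context will be
  systematically mis-predicted.
* Coefficient interpretation on restricted libraries is limited by the
  rank deficiency discussed above.
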