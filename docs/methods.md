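# Methods

This note documents the models, conventions and numerical choices behind
epiforge, and what the synthetic data used by the tests does and does not
establish.

## Coordinates and epitope enumeration

Protein coordinates are 1-based with closed intervals, matching the
`<WT><pos><MUT>` missense notation (`E542K` = glutamate 542 → lysine).
`apply_mutation` refuses a substitution whose stated wild-type residue does
not match the sequence — a mismatch almost always means the wrong isoform
was supplied, and silently overwriting would corrupt every downstream
coordinate.

Candidate epitopes are all windows of the requested lengths (9/10-mers for
Class I, 15-mers for Class II) whose span contains the mutated position.
Windows that would cross a terminus are dropped rather than padded, because
binding predictors require exact-length peptides; a mutation within L−1
residues of a terminus therefore yields fewer than L windows of length L.
Duplicate peptides arising from sequence repeats are kept as distinct
candidates (they have distinct coordinates); de-duplication happens only in
report views, keyed by (peptide, allele). Only missense substitutions are
supported — frameshifts and indels are out of scope.

## Physicochemical descriptors

Implemented natively from the published constant tables (shipped in
`_proptables.py` with provenance notes):

- **Instability index** — Guruprasad dipeptide weights,
  (10/L)·Σ DIWV(xᵢ, xᵢ₊₁). Stable means < 40.
- **GRAVY** — mean Kyte–Doolittle hydropathy.
- **Aliphatic index** — Ikai: X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in
  mole percent.
- **Isoelectric point** — bisection on [0, 14] of the Henderson–
  Hasselbalch net charge under the Bjellqvist pKa set, including the
  residue-specific N-/C-terminal pKa exceptions; tolerance |charge| < 1e−4.
  Unlike some calculators we do not clamp the search bracket, so strongly
  acidic peptides can legitimately report pI below 4.
- **Half-life** — mammalian (reticulocyte) N-end-rule lookup on the
  N-terminal residue, in hours. Only the mammalian column is shipped; the
  1 h filtration threshold is a mammalian criterion, so yeast/E. coli
  values would never be consulted.

The test suite cross-checks the first four against an independent reference
implementation (biopython's ProtParam) and direct table-sum oracles.

## Feature collection and binding labels

External predictors are abstracted behind a backend contract: per-pair
binding affinity plus five per-epitope features (immunogenicity,
antigenicity, allergenicity, toxicity, IFN-γ), each either a number on the
tool's own scale or a binary label. Two backends ship:

- **MockBackend** — every value is a pure function of
  (seed, peptide, allele, feature) via a stable blake2b hash, mapped to the
  documented scale (binding affinity log-uniform on [10, 50000] nM; Class I
  immunogenicity on [−0.3, 0.4], Class II on [0, 100] with lower = better;
  antigenicity on [−1, 2]; allergenicity on [0, 1]; binaries thresholded at
  configurable rates, default 10% toxic and 50% IFN-γ-positive).
- **TableBackend** — replays a long-format CSV
  (`peptide,allele,feature,value`) exported from real tools; a missing pair
  is a hard error naming the pair.

Binding labels partition (0, ∞) with inclusive upper bounds: ≤ 50 nM
STRONG, ≤ 500 NORMAL, ≤ 5000 WEAK, above N/A. Pairs labelled N/A are
dropped from the candidate list by default — the final reports concern
binder pairs — with a `drop_na_pairs=False` switch to retain them.

Allele names are canonicalized to the reference-set spelling
(`HLA-A*02:01`; paired-chain Class II as `HLA-DQA1*05:01/DQB1*03:01`),
accepting the common dialects without `HLA-`, without `*`, or with a
prefix on the second chain.

## Scoring

Features are normalized per MHC class: z-score then min–max to [0, 1] for
immunogenicity, antigenicity and allergenicity; allergenicity (both
classes) and Class II immunogenicity are inverted (1 − x) so that the
preferred direction is toward 1; binding affinity enters as ε = ln(nM)
with no further rescaling (only the log transform is part of the model).
Normalization parameters are fitted once on a table and persisted with the
model; new data outside the fitted min–max range is clipped back to [0, 1]
when scoring (but *not* during cross-validation, where clipping would bias
the test folds). A zero-variance feature column normalizes to a constant
0.5 with a warning rather than failing.

The logistic family models the log-odds of a positive T-cell response and
reports the inverse-logit probability; the linear family reports the
unclamped affine value. Fits are unregularized (maximum-likelihood
logistic; ordinary least squares linear). Near-perfect separation is
reported as a warning — the fit still returns, but the weights are not
identifiable. The published weights for both families and classes ship as
named constant models; since the original training-set normalization
parameters are not published, pipelines using the constant models fit
normalization on the candidate feature table they are scoring.

The beta–binomial "potential" for linear-family training data is the
posterior mean under a Beta(1, 1) prior: (responded + 1)/(tested + 2).
The prior is configurable; the uniform prior is the natural default when
the upstream method does not state one.

"5-fold cross-validation with a 70:30 split" is internally inconsistent as
a k-fold prescription; `evaluate_cv` therefore performs five independent
random 70:30 train/test splits and reports means (plain k-fold is
available via `scheme="kfold"`). Logistic models report accuracy at the
0.5 threshold and rank-based (tie-corrected) AUC; linear models report
test R². A test fold with a single outcome class is redrawn.

## Ranking and filtration

Ranking operates on epitope/HLA pairs, grouped per (point mutation, MHC
class) — the two classes use different scoring functions, so a joint
ranking would be meaningless. Within a group pairs are ordered by
probability descending with a total tie-break (lower binding affinity,
then peptide, then allele name), making the output invariant to input
order; the top 20 receive ranks 1..20. Filtration runs *after* the top-k
cut, in the stated workflow order, so a mutation can end with zero
surviving pairs; thresholds are strict (exactly 40 / exactly 1 h are
excluded). The IFN-γ requirement applies only to Class II rows because the
upstream IFN-γ predictor is trained on Class II data only. Aliphatic
index, GRAVY and pI are reported, never filtered.

## Population coverage

The coverage model follows the standard genotype construction: at each
locus an individual draws two alleles independently with the population
frequencies (unlisted residual mass acts as a null allele); a heterozygote
(a, b) presents h(a) + h(b) epitope/HLA combinations and a homozygote
(a, a) presents h(a) — an allele's combinations are distinct objects and
are not doubled by homozygosity. Loci are independent, so the total-hit
distribution is the convolution of per-locus distributions; this is pinned
in the tests by a brute-force enumeration of all diploid genotypes.
PC90 = n + (S(n) − 0.9)/(S(n) − S(n+1)) with S(n) = P(hits ≥ n) and n the
largest count with S(n) ≥ 0.9 (n = 0 allowed); this interpolation
reproduces the reference pairing of a 81.81% single-hit coverage with
PC90 = 0.55.

Class I uses loci {A, B}; Class II {DR, DQ, DP}, with paired α/β-chain
alleles treated as single haplotype units at their locus. The packaged
list of coverage-unsupported Class II alleles (every non-DRB1 allele of
the reference set) is excluded from Class II maps before coverage, with
every removal logged; a user-supplied list can replace it. Allele
frequencies are user-supplied CSVs (`population,locus,allele,frequency`) —
no third-party frequency database is bundled, for licensing and versioning
reasons; a synthetic Dirichlet-based world-like table ships for tests and
demos.

**Optimization** reduces the epitope list to a minimum-cardinality subset
whose allele *union* is unchanged. Coverage depends on the allele union
only, so it is exactly preserved while redundancy (and hence the average
hit) drops — the objective chosen because the reference workflow reports
identical filtered and optimized coverages with reduced average hits. Up
to 20 epitopes the search is exhaustive over subset sizes (bitmask set
cover); ties between minimum covers are broken by higher total epitope
score, then lexicographically. Above 20 a greedy largest-uncovered-gain
heuristic with the same tie-breaks is used, and the mode is recorded in
the optimization log.

## Synthetic data

The generator mirrors the statistical shape of the real inputs without
copying any external database:

- tool scores are bimodal (uniform on [0, 0.1] ∪ [0.9, 1]), as
  classifier-style predictors produce;
- training binding affinities are a 50:50 binder/non-binder mixture
  (log-uniform 10–500 nM and 2–50 µM), as training sets assembled from
  positive and negative assay results are;
- training outcomes are Bernoulli draws from the model at known weights
  defined on the normalized feature scale, so a refit estimates exactly
  those numbers (intercept identifiability is the weakest link, since ε is
  uncentered; the recovery check uses n = 2000);
- the demo protein is a seeded random 1100-mer constrained to carry the
  wild-type residue of every packaged mutation (a synthetic stand-in — the
  real oncogene sequence is deliberately not bundled);
- allele frequencies are Dirichlet proportions scaled to 85% listed mass
  per locus, leaving a realistic unlisted residual.

Consequently, passing tests establish the correctness of the pipeline's
*mechanics* (enumeration, normalization, scoring algebra, ranking and
filtration logic, coverage mathematics, optimization) — not the predictive
validity of any real-tool feature values, which enter only through the
table backend. The headline pair counts of the original PIK3CA application
depend on live web predictors and are therefore not reproduced here.

Problem sizes in the shipped tests and acceptance script (49 mutations,
~45k mock pairs, n = 2000 training rows, 200 coverage-oracle and 300
set-cover instances) were chosen so the full suite runs in seconds on one
core while still exercising every group-by and convolution path at
realistic scale.

## Known limitations

- Only missense point mutations; no indels, frameshifts or splice
  variants.
- The constant scoring models carry no normalization parameters, so their
  probabilities are comparable within a run but not across feature
  backends.
- Coverage assumes Hardy–Weinberg equilibrium and linkage equilibrium
  across loci; real populations deviate.
- The greedy optimizer (above 20 epitopes) is not guaranteed minimal,
  though the allele union — and hence coverage — is always preserved.
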