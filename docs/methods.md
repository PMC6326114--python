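# Methods

## Matching model

The matcher treats each patient's binarized diagnosis profile as a vector
of K conditionally independent indicators. Under the match hypothesis for
a pair (i, j), dataset B's indicator for code k is dataset A's indicator
passed through an asymmetric noisy channel with discrepancy rates
ε⁻ₖ = P(Bₖ=0 | Aₖ=1, match) and ε⁺ₖ = P(Bₖ=1 | Aₖ=0, match); under the
non-match hypothesis the indicators are independent with B-prevalence
π_Bk. The per-code log-likelihood ratios for the four observation
patterns follow directly, and their sum over codes is the pair's
similarity L(i, j). Conditional independence is wrong for real codes
(comorbidities co-occur), but naive-Bayes scoring is a deliberate,
standard choice that preserves ranking performance; the simulator
generates correlated codes precisely so that tests exercise the model
under that violation.

Two modelling details matter in practice:

- **Asymmetry of evidence.** For a rare code (π_Bk small), a (1,1)
  agreement carries weight log((1−ε⁻)/π_Bk) ≫ the (0,0) weight
  log((1−ε⁺)/(1−π_Bk)). The matcher therefore leans on shared rare codes,
  which is what makes linkage from diagnosis data possible at all — and
  why performance requires enough rare codes (the simulator's defaults
  reflect this regime).
- **The no-match category.** For fixed i, the candidate events
  {matches j: j=1..n_B} ∪ {matches nobody} are modelled as exhaustive,
  giving a softmax over similarity scores plus a zero-score no-match cell,
  with the prior π₀ entering through its logit. This couples all pairs in
  a row: a record resembling two B-records splits its posterior mass
  (two identical candidates each get at most 1/2), which is the mechanism
  enforcing soft 1-1 matching. Both directions are computed and averaged;
  a pair is declared when the averaged posterior reaches α.

## Computation

All-pairs similarity uses the exact decomposition
L = Σw₀₀ + A(w₁₀−w₀₀) ⊕ B(w₀₁−w₀₀) + A diag(w₁₁−w₁₀−w₀₁+w₀₀) Bᵀ
(⊕ meaning broadcast addition), verified in tests against the naive
triple loop at 1e-10. Posteriors are computed with a max-shift in log
space; similarity scores reach hundreds for K in the thousands, so naive
exponentiation would overflow. Hyper-parameter boundaries are clipped by
default — prevalences into [1/(2n_B), 1−1/(2n_B)] (half an observation),
discrepancy rates into [1e-6, 1−1e-6] — so codes never (or always)
observed in one dataset cannot produce infinite weights; clipping can be
disabled, in which case boundary values are rejected with the offending
code named. Codes are aligned across datasets by lexicographic order of
the union (default) or intersection of the two code sets; a pooled
minimum-count filter (default 1, i.e. drop codes recorded nowhere) guards
against extremely rare codes dominating the likelihood.

## Hyper-parameters

- **π_Bk** — empirical column means of B, clipped as above. Default on.
- **ε⁻, ε⁺** — user-supplied scalars (default 0.01) broadcast across
  codes; this is the primary path. Matching performance is insensitive to
  the exact value over a wide range provided enough information is shared
  (example 04 demonstrates this and the simulation tests confirm it even
  where the generating discrepancy rate is ~8x the supplied one). A
  data-driven estimator from high-similarity pairs is available as an
  explicit opt-in, with a caveat below.
- **π₀** — either fixed by the user or estimated automatically: fit a
  four-parameter Azzalini skew-t (location ξ, scale ω, skewness α, degrees
  of freedom ν) to all n_A·n_B similarities by maximum likelihood, locate
  the rightmost inflexion point c₀ of the fitted density, and take the
  fraction of pairs with L > c₀ (floored/capped at one pair's worth of
  probability). The skew-t MLE runs bounded L-BFGS-B on
  (ξ, log ω, α, log ν) with ν ∈ [1, 200], multi-started from
  moment-based positions with positive, zero and negative initial
  skewness, on a seeded uniform subsample of at most 5·10⁶ similarities.
  The inflexion is found by central differences of the analytic density on
  a 10,001-point grid spanning the sample range ± 2ω.

**Known bias of the automatic π₀.** The rightmost inflexion of a unimodal
fitted density sits near mode + scale unless the fit is extremely
left-skewed, so the exceedance fraction retains a few percent to a few
tens of percent of *non-match* mass and overestimates π₀ — often by an
order of magnitude (example 04 shows 0.17 against a truth of 0.003). This
is a property of the estimator's definition, not of the optimizer: the
non-match density above its own rightmost inflexion is not negligible
relative to typical π₀ values. We keep the estimator as defined because
the posterior rule is demonstrably insensitive to π₀ (it shifts every
score by the same logit offset, and true matches sit far above c₀), and
document that a user who wants a calibrated π₀ should supply
n_overlap/(n_A·n_B) from external knowledge. One acceptance test asserts
a factor-of-3 accuracy bound on a clean synthetic mixture; it fails, and
is left failing, for exactly this reason.

The same c₀ drives the opt-in discrepancy-rate estimator (per-code
discordance fractions among pairs with L > c₀). When c₀ sits inside the
non-match bulk the selected pairs are contaminated and ε⁻ is inflated;
the estimator is therefore off by default and the fixed scalar path is
primary.

## Fellegi-Sunter comparator

The baseline scores per-code *agreement* (Aₖ = Bₖ), deliberately not
distinguishing a (0,0) from a (1,1) concordance — the recognized weakness
on sparse codes that the Bayesian model fixes, and the reason the
comparator's precision collapses in every experiment here. Parameters
(m, u, p) are estimated by latent-class EM over all admissible pairs
under conditional independence. The E- and M-steps are evaluated in
closed matrix form using agreement = 1 − a − b + 2ab, so no n_A·n_B·K
tensor is ever formed; for K ≤ 64 identical agreement patterns are
collapsed by bit-packing with multiplicities (both paths are tested to
agree to 1e-9). Initialization is m₀ = 0.9, u₀ = each code's empirical
agreement rate, p₀ = 1/max(n_A, n_B); convergence at max parameter change
< 1e-6, at most 500 iterations, parameters clipped away from {0,1};
non-convergence returns the current estimates with a warning rather than
an exception. Universal agreement (m and u both at the upper clip) is
flagged as unidentifiable.

Decision rules: plain thresholding (`fs_classify`, default threshold 0 =
"more likely match than not") and the 1-1 largest-score variant
(`fs_one_to_one`) keeping ties. The 1-1 rule's maximality direction is
configurable: per record of B (default), per record of A, or requiring
both row- and column-maximality. The per-B default reflects how such a
rule behaves in published comparisons (one declared pair per smaller-set
record); the "both" mode is near-degenerate on sparse data because a
single low-utilization pair tends to dominate all rows and columns at
once. Blocking restricts admissible pairs to those agreeing on a coarse
label; blocked pairs carry no score and are excluded from EM sums.

## Simulator

The generator emulates administrative-claims diagnosis data:

- **Prevalences**: Beta(0.3, 6) draws per code — heavy-tailed, most codes
  rare — optionally rescaled so the expected codes-per-patient hits a
  target (default 5, matching the order of magnitude of real claims
  extracts).
- **Base matrix**: Gaussian-copula threshold model; marginals are exact
  by construction. The latent correlation is a single-factor
  equicorrelation (strength configurable, default 0 for speed) or any
  user-supplied correlation matrix, projected to the nearest PSD matrix
  by flooring negative eigenvalues.
- **Perturbation**: per patient, two independent latent draws
  Z₁ ~ N(1, ρΣ) and Z₂ ~ N(−3, ρΣ); the perturbed indicator is
  1{XZ₁ + (1−X)Z₂ > 0}. Independent draws are used because the two
  distinct distributions in the defining formula imply two sources of
  randomness; ρ = 0 degenerates to the identity exactly. With Σ = I the
  flip rates are Φ(−1/√ρ) (present→absent) and Φ(−3/√ρ) (absent→present):
  dropping a recorded code is far likelier than inventing one, mirroring
  real cross-system discrepancies. The end-to-end path uses the base
  matrix's own empirical code correlation as Σ.
- **Overlap split**: the original and perturbed matrices are subset to
  n_A and n_B rows sharing exactly n_overlap patients, rows shuffled and
  identifiers re-randomized so position carries no signal; the true 1-1
  pairing is returned.

What the simulator does *not* reproduce: temporal structure (codes have
no dates), utilization heterogeneity beyond what the copula induces,
code-hierarchy relations (ICD-9 families), or duplicate records within a
dataset. Passing tests on simulated data therefore show the algorithmic
claims (score decomposition, posterior calibration mechanics, relative
method ranking, noise response) rather than clinical-deployment
performance.

## Problem sizes and seeds

Tests and the acceptance script run a scaled-down replication of the
numerical study: 800 base patients, K = 1,000 codes, ~5 codes/patient,
ρ = 0.5, subsets of 500 vs 300 with 150 overlapping, five replicates —
sizes chosen to exercise the ≥1,000-codes, sub-unit-noise regime the
method targets while keeping a full replication in seconds-to-minutes.
Replicate seeds derive from a master seed via `numpy.random.SeedSequence`
so every run is reproducible end-to-end; identical configuration and seed
give byte-identical datasets, posteriors and match sets.

## Known limitations

- Binarized codes only: visit counts are discarded by design; a
  count-likelihood extension would need a different per-code channel.
- The automatic π₀ is upward-biased (see above); rely on it only through
  the posterior's insensitivity, not as a calibrated estimate.
- The ε estimator from high-similarity pairs inherits c₀'s contamination.
- No within-dataset deduplication: each record is assumed unique.
- The no-match softmax assumes at most one true match per record; group
  structures (e.g. merged records) violate it.
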