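# Methods

This note documents the statistical model behind `cnarisk`, the defaults
that matter, the numerical choices, and what the synthetic test-bench
does and does not demonstrate.

## Data model

The copy-number input is a gene-region × sample matrix of GISTIC
threshold calls C ∈ {−2, −1, 0, +1, +2} (−2 homozygous deletion, −1
heterozygous loss, 0 diploid, +1 one-copy gain, +2 high-level
amplification). The clinical input is per-sample right-censored survival
(time in days, event = death) plus optional cofactors. Samples are
matched by barcode after truncation to the patient level (default 12
characters, the TCGA convention; configurable). Rows without valid
time/event are excluded from all analysis; missing cofactor values are
kept and excluded per-analysis only.

Binarization into the four modes is: soft_del = [C ≤ −1],
deep_del = [C = −2], soft_amp = [C ≥ +1], deep_amp = [C = +2]. Deep
indicators are subsets of the corresponding soft indicators, and no cell
is both a deletion and an amplification. The recurrence filter (≥ 4
altered patients, configurable) is applied *per mode*, on each mode's own
indicator: a gene with ten soft but two deep carriers must not enter deep
screening with n = 2. A global pre-filter on C ≠ 0 is available as an
option for users who prefer filtering before binarization.

## Screening

For gene g with binary carrier indicator x, the two-group log-rank
statistic is computed from observed-minus-expected carrier deaths across
distinct event times, with the hypergeometric variance
Σ_j d_j (n_{1j}/n_j)(1 − n_{1j}/n_j)(n_j − d_j)/(n_j − 1) (this form
handles ties). Because carriers are typically a small minority, the
χ²(1) approximation misstates tail probabilities; the p-value is instead
taken from the **conditional permutation null**: the statistic's
distribution over uniform reassignments of the k carrier labels among
the n samples, conditioning on k.

* When C(n, k) ≤ `exhaustive_threshold` (default 2000) every carrier
  subset is enumerated and the p-value is exact:
  p = #{subsets with statistic ≥ observed} / C(n, k).
* Otherwise `n_perm` Monte-Carlo draws (default 2000) are used with the
  add-one correction p = (1 + #{≥ observed}) / (1 + n_perm), which keeps
  the test valid and makes the null p-value distribution uniform on the
  achievable grid.

The statistic is squared, so p-values are two-sided; the risk
*direction* is recovered from the sign of the Cox coefficient. Within
one screen, genes with equal carrier count k share the same conditional
null, so the null sample is generated once per distinct k, seeded by
(pipeline seed, k). This makes per-gene results independent of gene
order and of which other genes are present. Asymptotic-χ² and Cox-Wald
screening engines are available as alternatives.

The per-gene coefficient β is the maximum partial-likelihood log hazard
ratio of the indicator, fit by Newton iteration on the binary-covariate
Cox partial likelihood with Efron tie handling (Breslow available).
Monotone-likelihood fits (no events among carriers or among
non-carriers, or an iteration escaping the ceiling) are clamped at
|β| = 10 and flagged, so coefficient sums stay finite; non-convergent
fits are excluded from signatures. The implementation is cross-checked
against `lifelines` and agrees with R `survival::coxph` to ~1e-7.

Screening retains genes at raw p ≤ α (default 0.05) with **no
multiple-testing correction** — a deliberate reproduction of the
screening protocol this package implements; Benjamini–Hochberg q-values
are emitted in the output table for reference only.

## Signatures

Per sample and mode: `sum_beta_high` = Σ β over carried screened genes
with β > 0, and `sum_beta_low` = Σ |β| over carried screened genes with
β < 0. The low-risk side uses |β| because the comparison is between
magnitudes of evidence; summing signed negatives would make the low-risk
side lose always. Labels:

* **single-data** (per mode, 4 models): H if `sum_beta_high` >
  `sum_beta_low`, L for the reverse, NA on ties (relative tolerance
  1e−9; exact float equality is fragile) or when both sums are zero.
* **MaxSum** (soft, deep): direction totals added across amplification
  and deletion scores of the same depth, larger total wins, tie → NA.
* **Combinations** (soft, deep): the pair (amp label, del label),
  written "H/L" etc.; at most 9 groups. Groups smaller than
  `min_group_size` are flagged non-interpretable.

Eight models per cohort, with fixed identifiers
`single_{soft,deep}_{del,amp}`, `maxsum_{soft,deep}`,
`combinations_{soft,deep}`. A mode with empty screening yields an
all-NA model (logged, never an error).

## Evaluation

Kaplan–Meier estimation uses `lifelines`. The k-group log-rank test is
the score vector of per-group observed-minus-expected events with its
hypergeometric covariance; one group is dropped and the quadratic form
solved (pseudo-inverse on singular covariances), giving χ²(k−1). With
two groups this reduces algebraically to the screening statistic (tested
to 1e−9).

Model ranking sorts by overall log-rank p ascending, after setting aside
*degenerate* models (< 2 occupied groups). A model is *penalized* when
any occupied group holds fewer than `min_group_frac` (default 2%) of the
cohort, or when its extreme groups are not separated at pairwise
p ≤ 0.05. "Extreme groups" are operationalized as the groups with the
lowest and highest crude event rate (events/n) — a deterministic rule
that also covers pair-labelled Combinations groups. Ties break by fewer
groups, then by the fixed model-id order, making the ranking a total
order. The selected model is the top unpenalized one; when every model
is degenerate or penalized there is no selection but the table is still
reported.

Cofactor analyses use the NA (no-risk) group as the Cox reference level
throughout. Stratified analysis dichotomizes numeric cofactors at a cut
(default 60, for age), pools sparse clinical levels through configurable
maps (defaults merge T3/T4, N2/N3, stage iii/iv), and reports per-stratum
β with 95% CI for each risk group vs NA; a group with no events in a
stratum is non-estimable and its samples are left out of that stratum's
fit. The multivariate model fits risk-group dummies jointly with all
selected cofactors on complete cases, dropping constant or collinear
columns (greedy rank check, first occurrence wins) with a warning. Both
analyses are read-only on the assignments they consume.

## Synthetic cohorts

`simulate_cohort` emulates: sparse integer threshold calls (background
carrier fractions ~ Beta(2, 38), i.e. mostly 2–10% carriers; random
sign; each altered cell deep with probability `deep_fraction` = 0.3),
planted genes whose carriers (drawn exactly, without replacement) get
their mode's value (soft-planted carriers are upgraded to ±2 with
probability `soft_deep_admixture` = 0.2), proportional hazards
h(t) = h0(t)·exp(Σ β·indicator + cofactor effects) with an exponential
(default, median 1095 days ≈ 3 years) or Weibull baseline,
administrative censoring at 3650 days plus exponential random censoring
(mean 3000 days, together yielding ~60–70% observed events), and
age/sex/stage cofactors with configurable hazard effects (zero by
default). The reference planted scenario is n = 300 samples, 200 gene
regions, five deep-amplification genes at β = 1.5 with 8% carriers —
large enough that screening power is essentially 1 while false positives
remain visible at α = 0.05.

What the generator does **not** emulate: genomic correlation along
chromosomes (real CNAs come in segments spanning many adjacent gene
regions, so real screens produce blocks of correlated hits),
non-proportional hazards, informative censoring, cohort substructure,
and measurement noise in the GISTIC calls themselves. Passing tests
therefore demonstrate the statistical machinery under the model's own
assumptions, not performance on any real tumor cohort.

## Problem sizes and numerical choices

The test-bench works at desk scale: the permutation-oracle comparison
uses cohorts of n ≤ 10 with 2–3 carriers (50,000 Monte-Carlo draws
against full enumeration); type-I calibration uses 2,000 null cohorts of
n = 200 with k = 10 carriers and 999 permutations each; Cox recovery uses
n = 1,000 with ~50% events; the end-to-end scenario is the n = 300
reference cohort. The vectorized permutation engine evaluates a batch of
carrier assignments as one suffix-sum pass over the sorted risk sets,
which is what makes these replicate counts cheap.

Degenerate inputs are handled explicitly: zero-variance log-rank
configurations raise; single-group or zero-event genes are skipped with
a log entry; empty screens propagate as all-NA models; empty sample
intersections at alignment are errors. All pipeline randomness derives
from a single integer seed (per-k null streams spawned via
`SeedSequence`), and identically seeded runs produce byte-identical
output files.

## Known limitations

* The screening protocol intentionally uses uncorrected p ≤ 0.05; with
  ~20,000 gene regions per real cohort the retained sets contain many
  false positives whose coefficient sums partially cancel — adequate for
  group assignment, not for interpreting individual genes.
* Clamped monotone-likelihood coefficients (|β| = 10) can dominate a
  sample's coefficient sum; such genes are flagged in the screen output.
* The conditional permutation null conditions on the carrier count only,
  not on the censoring pattern within carriers.
* Combinations models can produce clinically meaningless micro-groups;
  the ranking penalty demotes but does not delete them.
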