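# Methods

## The problem

A summed questionnaire score is only meaningful if the items measure one
construct. Cronbach's α is routinely reported as if it certified this, but
internal consistency is a necessary, not sufficient, condition for
unidimensionality: long scales built from two distinct constructs still
reach α > 0.9. `dimcoef` implements a second, dimensionality-sensitive
screen — the dimension coefficient (DC) — alongside Horn's parallel
analysis (PA), and a simulation experiment that measures how well each
rule, and their combination, recovers the true dimensionality of scales
generated under a controlled two-trait design.

## Simulation model

Datasets are drawn from the Rasch rating scale model (RSM) for 5-category
items. Person abilities for the second trait are a trigonometric rotation
of the first:

    theta2 = theta1 * cos(a) + z * sin(a),   a = arccos(rho),

with `theta1`, `z` i.i.d. N(0, 1), so corr(theta1, theta2) = rho exactly in
the population and theta2 remains standard normal for any angle. The first
floor(k/3) items (minimum 1) load on trait A, the remaining two thirds on
trait B. Category probabilities follow the RSM kernel
`P(X = x) ∝ exp(Σ_{j≤x} (θ − δ − τ_j))` with an empty sum for the bottom
category.

Fixed design choices (the model leaves them open; they are set once and
documented here):

- **Thresholds** τ = (−1.5, −0.5, 0.5, 1.5) logits, shared by all items:
  symmetric and equally spaced, so all five categories are used across the
  difficulty range. Configurable.
- **Difficulties** on a deterministic evenly spaced grid over [−2, +2]
  logits (endpoints inclusive). This reads "uniformly distributed in
  difficulty" as exact coverage of the stated range; an i.i.d.
  random-uniform mode is available behind
  `random_uniform_difficulties=True`. The deterministic grid makes every
  cell of the experiment reproducible from its seed alone and removes one
  source of between-cell variance.
- **Abilities** standard normal; only "normal" is required, N(0, 1) is the
  natural scale fixing.
- **Trait split** floor(k/3) contiguous items to trait A. Because the
  difficulty grid is ordered, trait-A items occupy the easy end; this
  difficulty/trait confounding is part of the design and contributes
  secondary structure that parallel analysis reacts to.

The experiment grid is trait correlations {0.3, 0.5, 0.7, 0.9, 1.0} ×
item lengths 5, 10, …, 100 × sample sizes 50, 100, …, 1000 — the only
arithmetic consistent with "20 scenarios from 5 to 100" and "20 sample
sizes from 50 to 1000" — giving 2000 datasets per master seed.

**Seeding.** One master seed is expanded through named
`numpy.random.SeedSequence` streams: stream (1, i) for scenario i's
simulation (further split into trait/bank/response substreams), stream
(2, n, k, v) for the PA reference of shape n × k, variant v. Any grid cell
is therefore reproducible in isolation, and per-scenario integer seeds are
kept below 2^31.

## The dimension coefficient

DC summarizes first-eigenvalue dominance of the inter-item Pearson
correlation matrix. The default (`method="gap"`) is the contrast between
the two leading eigenvalues measured in excess of the third:

    DC = (λ1 − λ2) / (λ1 + λ2 − 2·λ3).

Rationale. In a design with at most two latent traits, every eigenvalue
beyond the second reflects sampling noise, so λ3 benchmarks the noise
ceiling; λ1 − λ3 and λ2 − λ3 are the parts of the two leading components
that rise above it. DC = 1 when the second eigenvalue is indistinguishable
from noise (one dimension) and DC = 0 when the two leading eigenvalues are
equal (two balanced dimensions). Under a two-block correlation structure
with between-block correlation ρ and blocks of relative size p : (1 − p),
the population value is sqrt((1 − 2p)² + 4p(1 − p)ρ²) — exactly ρ for
equal blocks, and sqrt(1 + 8ρ²)/3 for the 1/3 : 2/3 split used here
(0.44, 0.58, 0.74, 0.91, 1.00 at ρ = 0.3 … 1.0). DC therefore reads as an
eigenvalue-only estimate of the interrelation between the two strongest
dimensions, which is what makes the fixed cutoff **DC ≥ 0.70** a natural
mirror of the ground-truth convention "interrelation ≥ 0.7 is one
dimension". For two-item scales λ3 is taken as 0, reducing DC to |r|.

The simpler share form λ1/(λ1 + λ2) (`method="share"`, range [0.5, 1]) is
retained for comparison. It is *not* used for classification: under the
1/3 : 2/3 split its large-k population value is (1 + s)/2 with
s = sqrt(1 + 8ρ²)/3, which exceeds 0.70 even at ρ = 0.3, so a 0.70 cutoff
cannot separate the truth classes no matter how the response model is
parameterized.

Cronbach's α uses sample variances with the n − 1 denominator. Composite
reliability is `(Σλ_i)² / ((Σλ_i)² + Σ(1 − λ_i²))` from standardized
loadings. All correlations are Pearson; polychoric alternatives are out of
scope.

## Parallel analysis

Observed eigenvalues are compared component-wise with eigenvalues of
uncorrelated standard-normal data of the same n × k shape. Two reference
rules: the component-wise 95th percentile across replicates (default 100;
the experiment uses 20), and the eigenvalues of a single "individual"
random dataset. A mean-across-replicates alternative and a discretized
5-category reference mode exist for sensitivity analysis. Retention counts
leading components whose observed eigenvalue strictly exceeds its
reference and stops at the first failure; the PA classification calls "one
factor" iff exactly one component is retained. Reference tables depend
only on the data shape, so one table per (n, k) is computed per master
seed and shared across the correlation strata — mirroring how a per-shape
lookup table of random eigenvalues would be used in practice.

## Decision rules and evaluation

Ground truth labels a dataset one-dimensional iff its generating trait
correlation is ≥ 0.7 (boundary inclusive). The DC rule is DC ≥ 0.70, the
PA rule is n_retained = 1, and the combined rule is
`IF(PA = 1, 1, IF(DC ≥ 0.7, 1, 0))` — the logical OR. Two consequences are
structural, not empirical: combined positives are a superset of both
components' positives, and every combined-negative has DC < 0.70, so the
specificity of the DC rule against combined labels is exactly 1 on any
run.

AUC is the Mann–Whitney rank estimate (ties count half), identical to the
exhaustive pairwise count and verified against it in the tests. Operating
cutoffs are chosen by the Youden index over observed score values with
"score ≥ t" orientation; ties break toward the smaller cutoff. No binormal
smoothing, no confidence intervals.

## Unit-based reports

`unit_report` computes α and DC per (unit, domain) from a wide survey
table with 1–5 coded items (mapped internally to 0–4). Respondents with
any missing item in a domain are excluded from that domain (listwise
deletion within the domain); units with fewer than `min_n = 10` remaining
respondents are flagged `below_min_n`, and zero-variance domains are
flagged `degenerate` rather than patched — a low or incomputable value is
treated as a data-quality signal, not an error to hide.

The synthetic survey generator emulates a multi-unit workplace-culture
questionnaire: many units of varying size (including units below the
minimum-n filter), several domains of 5-point items, each domain answered
under the RSM from one trait (clean units) or from two traits at
correlation 0.3 (contaminated units). It does **not** emulate missing
data patterns, response styles (acquiescence, straight-lining), cluster
effects between units, or item wording effects; recovery results on the
fixture show that DC ranks planted contamination correctly under RSM
assumptions, not that it is robust to those real-world artifacts.

## Problem sizes and numerical notes

The acceptance checks and `scripts/acceptance.py` run the complete
2000-scenario grid with 20 PA replicates per shape (about half a minute on
one core); module tests use reduced grids (2–4 values per axis). The
reliability-landscape check uses the stride-4 subgrid (lengths 20…100 step
20, sizes 200…1000 step 200), chosen as the even-coverage reduction of the
design. Eigenvalues come from `numpy.linalg.eigvalsh` on the symmetric
correlation matrix and are clipped at 0 (the matrix is PSD up to
round-off); degenerate cells (a constant item column, possible at extreme
difficulty in tiny samples) are flagged and kept as rows rather than
resampled, preserving the row-count contract of a run.

## Known limitations

- The gap-form DC assumes at most two substantive dimensions when reading
  λ3 as noise; with three or more strong factors it will overstate
  unidimensionality of the leading pair.
- PA labels here derive from natively computed random references;
  published analyses that took reference eigenvalues from external
  lookup tables will agree with DC more weakly or strongly depending on
  how those tables were generated (see the README's reproduction notes).
- Pearson correlations on 5-category items attenuate relative to
  polychoric correlations and pick up difficulty factors; this is
  intentional (spreadsheet-feasible practice) but means DC values are not
  comparable against polychoric-based analyses.
- The truth definition is a design convention (ρ ≥ 0.7 with a 1/3 : 2/3
  split "is" one dimension); sensitivity/specificity numbers are relative
  to that convention, not to an absolute notion of dimensionality.
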