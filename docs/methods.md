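# Methods

## Sequence coding

A gesture *sequence* is a maximal run of gestures by one signaller to one
recipient in one context with consecutive gaps of at most 30 s (inclusive);
gaps are measured timestamp-to-timestamp, the natural dialect for
event-coded logs without durations.  Classification is a pure function of
the gap vector:

| events | gaps                      | class       |
|--------|---------------------------|-------------|
| 1      | —                         | single      |
| ≥ 2    | all < 1 s                 | rapid       |
| ≥ 2    | at least one ≥ 1 s        | persistence |

The canonical response-waiting window is 1–5 s.  Gaps in (5 s, 30 s] fall
between the waiting window and the sequence window; by default any
within-sequence gap ≥ 1 s counts as response waiting, which keeps the
30 s independence rule authoritative for segmentation.  The
`strict_wait_window` switch instead splits sequences at gaps > 5 s, for
sensitivity analysis.  Boundary conventions are inclusive throughout: a gap
of exactly 1.0 s is waiting, a gap of exactly 30.0 s stays in-sequence.
A rapid burst followed by a waiting pause and more gestures is one
persistence sequence (the signaller did wait), not a hybrid.

Timing alone decides the class; whether the pause followed a *failure* to
respond is not operationalized, matching how event logs are coded in
practice.  Multi-recipient (broadcast) gestures are expanded to one event
per recipient before segmentation so that matrices stay dyadic.

## Dyadic matrices

With row A the focal observer and each within-10 m scan representing one
2-min exposure interval:

* CA_AB = (C_AB × 60) / (P10_AB × 2) — sequence initiations per hour of
  co-proximity.  The denominator is minutes of observed co-proximity, so
  the quantity is dimensionally a rate per hour.  Computed per sequence
  class and per response category (present, absent, activity change,
  vocalisation, visual/tactile gesture), one matrix each.
* PROX_AB = 60 × P10_AB / party_AB — minutes within 10 m per hour in the
  same party, bounded in [0, 60] by P10 ≤ party.

A sequence is attributed to the scan interval containing its first gesture,
matched on the signaller being the focal; sequences whose recipient was not
within 10 m at that scan are excluded from the counts and tallied.

Dyads never observed within 10 m have an undefined rate; the default sets
it to 0 and flags it (`DyadTallies.zero_exposure_mask`), because MRQAP
needs complete matrices.  `drop_zero_exposure` deletes those dyads listwise
from every vector in a model instead.

Similarity matrices are binary and symmetric: same sex; age difference of
at most 5 years (from ages at study time, not birth-year bins);
reproductively active pairing (male × cycling female — in the attribute
vocabulary used here only cycling females can be in oestrus); and
mother–offspring kinship.

## MRQAP with Double-Dekker semi-partialling

Matrices are vectorized over the n(n−1) off-diagonal cells in fixed
row-major dyad order.  Point estimates are OLS with an intercept (fitted,
never tested); standardized coefficients are reported from z-scored
vectors.  Inference per predictor i:

1. regress X_i dyad-wise on the remaining predictors (raw scale — p-values
   must not depend on an arbitrary standardization step);
2. re-form the residuals as an n × n matrix;
3. apply a random node relabeling simultaneously to its rows and columns;
4. substitute the permuted residual matrix for X_i, refit, record β*_i.

p_i = (1 + #{|β*_i| ≥ |β_i|}) / (1 + n_perm): two-sided, never 0, never
above 1; ties count toward rejection (the conservative reading of “as
large or as small”).  Each predictor draws permutations from an independent
spawned stream of the model seed, so results do not depend on evaluation
order.  When n! ≤ 5040 (n ≤ 7) sampling is replaced by exhaustive
enumeration over all n! relabelings — exact, and the engine's primary
correctness oracle in the test suite.  The refit uses the
Frisch–Waugh–Lovell identity (only the substituted column changes), and
relabelings are applied by fancy-indexing the off-diagonal cells, so the
whole null distribution is a handful of matrix products.

Classical OLS standard errors are emitted for reference only; they are not
permutation-valid and are labelled as such.

Node-level models use outcome permutation: node labels are exchangeable
under the null, so shuffling the outcome across nodes is a valid reference
scheme that leaves the covariate structure intact.  Degree centralities are
weighted row sums (behaviour given) and column sums (behaviour received).
The node-level centrality model regresses proximity outdegree on the out-
and in-degrees of the three sequence-class rate matrices plus controls:
proximity time to cycling females, proximity time to maternal kin, and the
focal's sex and age (entered separately by default; a `composite` coding —
male × z-scored age in one column — is available because published
node-level tables sometimes spend a single row on “sex/age”, an ambiguity
we surface to the user rather than resolve silently).

## Reliability

Unweighted Cohen's kappa (categories are nominal), κ = (p_o − p_e)/(1 −
p_e) with chance agreement from the coders' marginal products.
Per-response-type reliability binarizes each category to present/absent per
sequence and computes one κ per category plus one for overall response
presence.  Both coders constant on the same category gives p_e = 1 with
perfect agreement; κ is defined as 1 there.

## Synthetic generator

The generator emulates the observational design, not chimpanzee behaviour:

* **Community**: 12 adults, 6 male; 3 of the 6 females cycling; ages drawn
  uniformly from 15–46 y (the adult span of the packaged subject table);
  exactly 3 mother–son pairs planted (6 ordered kin dyads, the count the
  packaged table reports), with a mother's age kept ≥ son + 12 y.
* **Sociality**: i.i.d. log-normal (σ = 0.6) per unordered dyad,
  symmetrized — positive and right-skewed like observed proximity
  durations.  Its z-scored log drives everything else.
* **Association**: per scan, each non-focal is in-party with probability
  expit(logit(0.5) + z) and within 10 m (given in-party) with probability
  expit(logit(0.4) + z).  The 0.4 base gives ≈ 24 min within 10 m per
  party-hour, matching the field-scale mean (≈ 23 min/h).  Effort defaults
  to 25 nine-scan follows per focal (450 min each, inside the published
  per-subject range); real designs' uneven effort can be mimicked with
  per-focal multipliers.
* **Gestures**: sequence initiations are Poisson within each 2-min
  co-proximity interval at class rates 1.27 (single), 0.45 (rapid), 0.11
  (persistence) per proximity-hour — the field-scale dyadic means.  The
  persistence rate is multiplied by exp(effect × z); the spec of raw
  sociality in the exponent is scale-unstable for a log-normal latent, so
  the standardized log is used.  The default effect 0.62 was calibrated
  once (40-replicate scan) so the standardized persistence→proximity
  partial association is ≈ 0.3 at this design size, and is not revisited.
* **Timing margins**: rapid gaps U[0.1, 0.8] s, persistence gaps
  U[1.5, 4.5] s, sequences of one dyad > 40 s apart, at most two sequences
  per dyad-interval (excess initiations, probability < 10⁻⁴ at default
  rates, are dropped).  Every planted class therefore sits strictly inside
  its defining region and re-coding recovers the labels exactly.
* **Responses** are annotations on the sequence, not simulated behaviour
  streams: per class, a category draw with vocalisation dominant after
  rapid sequences (0.60), activity change after persistence (0.50), and a
  mix after singles — the planted sign structure downstream models should
  recover.

A green end-to-end test therefore establishes that the pipeline recovers
known dyad-level structure from data with the right observational geometry
and field-scale magnitudes.  It does not establish robustness to what the
generator omits: observer error, context misclassification, diurnal and
party-size dynamics, uneven habituation, or behavioural contagion.

## Numerical and statistical notes

* Exhaustive p-values are exact proportions over all n! relabelings (the
  identity is in the set, so p > 0); sampled p-values use the +1/+1
  estimator.  Tie comparison uses a 10⁻¹² relative band so that
  permutations fixing the statistic count as ties regardless of float
  route.
* Rank-deficient designs abort with the names of the collinear predictors
  (greedy QR diagnostic); constant outcomes abort.
* A permuted residual vector falling numerically in the span of the other
  predictors would make the refit statistic undefined; its β* is set to 0
  (it cannot count as extreme).
* **Exposure coupling, a real property of rate-per-exposure designs**: the
  communication rate and the proximity outcome are estimated from the same
  finite scan sample.  For rare classes (persistence ≈ 0.11/h) the rate's
  sampling spikes scale inversely with exposure while exposure tracks
  sociality, so the rate network is *dependent* on the proximity network
  even when the underlying communication rate is flat.  In simulations
  with sociality driving proximity but no communication effect, the H1
  persistence test rejects at ≈ 10–15% instead of 5% — the permutation
  test is correctly detecting this dependence, not a defect.  Calibration
  holds (≈ 4–5%) when the networks are genuinely independent.  Users should
  interpret small positive coefficients on rare-event rates with this in
  mind; masking zero-exposure dyads does not remove the coupling.
* All randomness flows through seeded numpy Generators; identical seeds
  give byte-identical CSV outputs and identical p-values.
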