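# Methods

## Model

The unit of observation is a matriline: an isofemale line propagated by a
single female each generation. Its infection status with respect to two
distinguishable strains of a maternally transmitted virus takes one of four
values, in canonical order `uninfected`, `strain1`, `strain2`, `coinfected`.
Under the independence hypothesis each strain carried by the mother is
transmitted to the daughter kept for the next generation with its
single-infection efficiency (`p1`, `p2`), unaffected by the other strain.
This yields a row-stochastic 4×4 transition matrix in which the uninfected
state is absorbing and a mother never transmits a strain she does not carry.
Two consequences used as analytic anchors throughout the package: the
marginal retention of strain *i* after *n* generations from any carrier
founder is `p_i^n` (independent of the other strain's rate), and a coinfected
founder is still coinfected after *n* generations with probability
`(p1·p2)^n`.

Assumptions inherited from the experimental design: one female per line and
generation (so lines are independent realizations of the chain); horizontal
transmission negligible during the segregation experiment (superparasitism is
rare when females are isolated); PCR scoring error treated as zero by default
(an empirical check across generations found apparent losses were always
confirmed later, so the false-negative rate is small; an optional
`false_negative` parameter exists for sensitivity analyses and applies to
observation only, never to the underlying carriage).

## Monte-Carlo segregation test

The test statistic is the number of coinfected lines at the final generation.
The null distribution is built by simulating the complete experiment
(default: 40 coinfected founder lines, 4 generations) many times under
independence; per-strain Bernoulli retention is used for the draws, which is
exactly equivalent to sampling each daughter's status from the corresponding
matrix row (the equivalence is proved on the row probabilities and asserted
statistically in the tests). The empirical p-value uses the add-one
correction per tail, `(r + 1)/(n_sims + 1)` with `r` the number of simulated
counts at least as extreme as the observation, and the two-sided value is
twice the smaller tail, capped at 1. This rule is strictly positive,
conservative for discrete asymmetric nulls, and standard for Monte-Carlo
tests; the uncorrected proportion is reported alongside for transparency.
The default of 1000 simulations reflects the original design; analyses of
the observed count of 11 use 10,000 to stabilize the extreme tail.

Parameter values used for published-scale runs are the printed single-
infection rates `p1 = 0.96`, `p2 = 0.943`, taken as given rather than
re-derived (the underlying offspring counts are not available). The observed
count is taken as 11 of 40: the reported "27.5% of infected lines" is not an
integer of the 34 infected lines, whereas 11/40 = 27.5% exactly.

## Inference

Transmission rates are binomial proportions with exact Clopper–Pearson
intervals (95% by default); the interval method is a package choice, as the
original analyses print raw percentages only. The co-transmission test
compares `k` coinfected offspring of `n` scored against the independence
product `p0 = p1·p2` with an exact binomial test using the
minimum-likelihood two-sided rule — the sum of `Binomial(n, p0)` point
masses no larger than the observed one, with the same relative tie tolerance
(`1 + 1e-7`) as R's `binom.test`, for reproducibility of published p-values.
Degenerate nulls (`p0` of 0 or 1) return a p-value of 0 or 1 rather than an
error. The protection ratio is the ratio of the point acquisition rates into
uninfected versus already-infected recipients; a zero denominator is flagged
and returned as infinity.

## Genotyping

An individual's status is a pure function of its PCR fragment lengths: a
band within tolerance of the 399-bp reference amplicon marks strain 1,
within tolerance of the 288-bp deletion variant marks strain 2, both mark
coinfection. The default tolerance of 10 bp is a gel-resolution judgment;
any value below 55 bp keeps the two amplicons unambiguous, and a band
matching both references raises an error rather than guessing. The deletion
arithmetic is generic: an in-frame deletion (length divisible by 3) removes
`deletion/3` codons from the predicted protein (111 bp ⇒ 288 bp amplicon,
205 → 168 aa); frameshifting deletions yield no protein-length prediction.
The display export orders individuals coinfected first, then single
infections, then uninfected, as a stable sort so that equal-status
individuals keep their input order (chosen over a hard tie-break on
identifiers so that curated input orderings survive).

## Synthetic data

The generators emulate the three experimental designs the analysis consumes.
Defaults are the study conditions: transmission efficiencies 0.96/0.943;
segregation with 40 lines and 4 generations; vertical experiments sized in
mothers × offspring (the original scored roughly 46–100 offspring per
condition from 10–20 mothers; the default clutch is 5 scored daughters per
mother); horizontal trials with 7 vials per condition. The base
horizontal-transfer probability defaults to 0.75 and the protection
multiplier to 0.45, bracketing the observed 71–78% acquisition into
uninfected recipients and 26–33% into infected ones (the roughly twofold
reduction). Competition is a symmetric multiplier `gamma` on both strains'
transmission while the mother is coinfected — the simplest mechanism
consistent with reduced co-transmission and no competitive asymmetry — and
`gamma = 1` collapses the segregation generator exactly onto the Monte-Carlo
null (identical draws under the same seed). Horizontal transfer is modeled
per offspring; a per-vial logit-normal random effect (`vial_sd`, default
off) is available for clustered designs. Coinfected donors transmit both
strains jointly with the unreduced base probability, mirroring the
observation that co-transfer is not penalized. What the generators do *not*
emulate: host-population dynamics, egg-distribution and behavioral traits,
within-host viral load — so passing tests validate the statistical pipeline,
not those biological layers.

## Numerical and design choices

* Probabilities are validated to [0, 1]; row sums and state-vector sums to
  an absolute 1e-12. `propagate` renormalizes after its matrix products
  (corrections at the 1e-15-per-step level) so long propagations remain
  valid distributions.
* All randomness flows through `numpy.random.Generator`. The Monte-Carlo
  null draws all replicates from one seeded generator with a fixed
  replicate-major layout: reproducible given the seed, and fast because the
  whole null is vectorized.
* The type-I calibration study runs the full pipeline — generate vertical
  data under independence, estimate rates, build the null from the
  estimates, test a freshly generated segregation experiment. Its estimation
  arm uses 20 mothers × 100 offspring per strain: a delta-method calculation
  shows plug-in noise shifts the null mean by about `4·40·q/p · sd(p̂)`
  lines (q = `(p1 p2)^4`), so ~2000 offspring per strain keeps that shift
  below a quarter of the test statistic's own standard deviation (~3 lines).
  At the original estimation scale (~100 offspring per strain) the plug-in
  null is noticeably noisier and the nominal test becomes anti-conservative
  — a caveat that applies to any plug-in Monte-Carlo test of this design.
* Test problem sizes (10,000 null replicates for tail statements, 2000
  calibration replicates, 500-replicate power curves) were chosen so
  Monte-Carlo standard errors are small relative to the margins being
  asserted.

## Limitations

The chain models vertical transmission only; horizontal acquisition lives in
the generators, not the null model. The matrix is hard-coded for two strains
(the per-strain Bernoulli formulation in the simulator is the natural
generalization path). Competition is symmetric and constant across
generations; asymmetric or density-dependent competition would need a
different alternative model. Empirical p-values inherit Monte-Carlo
granularity (minimum `2/(n_sims+1)` two-sided).
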