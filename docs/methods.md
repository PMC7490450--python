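# Methods

## Quantification model

All Ct arithmetic assumes the ideal amplification efficiency of 2 (one cycle
= one doubling); no efficiency correction is estimated or applied. Replicates
are averaged on the Ct (log) scale before any fold-change computation, the
convention for ΔΔCt workflows. A reaction that never crosses the detection
threshold is represented by a no-amplification sentinel (NaN); `NA`,
`Undetermined` and empty cells in Ct CSVs map to it.

**Percent-m6A.** The three-condition RIP-qPCR (input, IgG IP, anti-m6A IP)
is reduced to a percentage as IgG-subtracted percent-of-input:

    c     = Ct_input + log2(f)            f = input fraction, default 1
    %m6A  = 100 · max(0, 2^(c − Ct_m6A) − 2^(c − Ct_IgG))

clipped at 100 by default. A sentinel Ct in an IP condition counts as zero
recovery; a sentinel input is an error. Subtracting the IgG recovery removes
nonspecific background; raw percent-of-input is available through
`QuantConfig(subtract_igg=False)` because published workflows differ on this
point. The input fraction defaults to 1 (input treated as 100% equivalents)
and should be set to the actual aliquot fraction for real data. The
percentage is monotone: non-increasing in Ct_m6A, non-decreasing in Ct_IgG.

**IP fold enrichment** for RISC-component CLIP experiments is
`2^(Ct_IgG − Ct_IP)`. A non-amplifying IgG control with a finite IP Ct means
no measurable background and returns +inf with a logged warning; the
symmetric case returns 0.

## Scoring rules

The αFM score sums three independent ±1 terms: +1 when αKG ≤ cohort median,
+1 when FTO ≤ median, +1 when METTL3 > median (each marker in its
methylation-promoting half), −1 otherwise, so the score is always odd and in
{−3, −1, +1, +3}. The compound worked examples that circulate for this score
are internally inconsistent; the per-marker decomposition is the unique
formulation that respects each marker's stated direction and yields a total
order, and it is the one implemented.

Stratification: group 1 requires %m6A strictly above the cutoff (default
10%), so a value exactly at the cutoff falls to groups 2/3, which split on
expression ≤ median vs >. The FTO-low/αKG-low subgroup requires both markers
strictly below their medians. The poor-prognosis signature is the union
"%m6A > cutoff OR expression ≤ median" (groups 1 and 2). Medians are always
recomputed on the cohort being scored — the rules are rank-based and
invariant under strictly increasing transforms of any marker column.

## Statistics

Implemented from their defining formulas (scipy supplies only t and
chi-square tail areas):

* Pearson r with t = r·sqrt((n−2)/(1−r²)) on n−2 df, two-sided p; requires
  n ≥ 3 and nonzero variance in both vectors.
* Equal-variance two-sample Student's t with pooled variance on
  n_a + n_b − 2 df (Welch deliberately not used); two-sided p.
* Kaplan-Meier product-limit estimator; at tied times events are processed
  before censorings, i.e. a subject censored at an event time is still at
  risk for that event.
* Two-group log-rank: per distinct event time, observed events in arm A vs
  the hypergeometric expectation and variance from the 2×2 margins; the
  squared standardized sum is chi-square with 1 df.

Two-sided p-values throughout, and no multiple-testing correction anywhere;
the analysis report flags this in its metadata. Kaplan-Meier and log-rank
agree with lifelines to 1e-6 on random censored data (cross-checked in the
test suite; lifelines is not a runtime dependency).

## Synthetic cohort generator

The generator emulates the joint structure the analysis is designed to
detect, in a 32-patient GBM-like cohort by default:

* Regulator levels (αKG, FTO, METTL3) are log-normal with unit median
  (σ = 0.5 on the log scale). Effects enter through the underlying standard
  normal draws, i.e. per SD of the latent scale, which makes the planted
  couplings invariant to the level parameterization.
* Methylated fraction on the logit scale:
  m = logistic(−2.2 + 1.0·z_METTL3 − 0.8·z_FTO − 0.8·z_αKG + ε),
  ε ~ N(0, 0.7); %m6A = 100·m. The logit keeps the percentage in (0, 100)
  and makes the planted signs recoverable by rank-free statistics.
* Expression: log-normal (σ = 1.0) with location shifted by 0.5 per SD of
  cohort-standardized methylation. The coupling defaults positive
  (methylation-stabilization hypothesis) and its sign is configurable, since
  the direction is an assumption, not a measurement.
* XIAP = max(0, 2.5 − 1.2·dose + N(0, 0.3)) with dose = expression·(1 − m):
  only unmethylated copies repress. DEVDase = max(0, 2.0 − 0.8·XIAP +
  N(0, 0.3)): XIAP blocks caspase activity. Baselines were chosen so the
  readouts stay positive at typical doses; ELISA-like readouts are floored
  at 0.
* Survival: exponential with baseline median 14 months; the hazard is
  multiplied by 2.5 for patients meeting the poor-signature rule on their
  *true* (latent) values. Exponential rather than Weibull because the
  downstream test is the distribution-free log-rank. Censoring: with
  probability 0.2 a patient is censored at a uniform fraction of their
  latent event time, achieving the target censoring fraction in expectation.
* Optional Ct-level tables invert the quantification exactly: Ct anchors are
  20 cycles (housekeeping), 25 (miRNA in the reference tissue), an IgG
  background of 10⁻³ of input, and Gaussian Ct noise of 0.15 cycles per
  replicate, 3 replicates. At zero noise the quantification round-trip is
  exact; at the default noise the recovered percentage has ≈8.5% relative
  sd (ln2 · sqrt(2/3) · 0.15 · sqrt(2)), so the typical round-trip error is
  under 10% and nearly all patients land within 25%. Patients with a true
  %m6A of 0 emit sentinel Cts in the anti-m6A rows.

Determinism: a cohort is a pure function of its config (seed included);
identical configs give bit-identical tables.

**What the generator does not emulate.** Real cohorts have correlated
regulators, batch effects, non-exponential hazards, measurement error in the
ELISA readouts, and informative censoring; none of these are modeled.
Passing the recovery tests shows the pipeline detects the planted structure
at realistic sample sizes — it does not validate the biological claims on
real data, and the generator's heterogeneity (e.g. the max/min expression
ratio, the count of patients above the 10% cutoff) is qualitative, not
calibrated to any particular cohort.

**A note on beta directionality.** Because the latent draws are symmetric
around zero, scaling an eraser coefficient does not lower the *mean*
percentage (the eta distribution's mean is unchanged, and by convexity of
the logistic below 0.5 the mean percentage weakly rises with spread); what
strengthens is the negative *correlation* between the eraser level and
%m6A. The directional-fidelity tests therefore assert the correlation
directions, which is also what the pipeline's statistics measure.

## Numerical choices and degenerate inputs

* Medians use the mean-of-central-pair convention for even n.
* Boundary conventions: "low" is ≤ median for αFM markers and expression,
  but strictly < median for the FTO-low/αKG-low subgroup; %m6A exactly at
  the cutoff is not group 1. These mirror the strict/non-strict phrasing of
  the rules being implemented.
* Perfect correlation (|r| = 1) returns p = 0 with an infinite t statistic
  rather than a division error.
* A log-rank comparison with zero hypergeometric variance (all events where
  one arm is exhausted) returns statistic 0, p = 1 rather than 0/0.
* Reals are serialized with Python's shortest round-trip representation, so
  write→read of a cohort or report is lossless; re-analyzing a run's own
  per-patient CSV reproduces every statistic to 1e-9.
* Validation is strict and never coerces: out-of-range %m6A, non-positive
  survival times, duplicate patient or well keys, and unknown qPCR
  conditions all fail the read with a named error.

## Problem sizes in the test and acceptance runs

Monte-Carlo checks use 100 seeds at the cohort sizes they probe (n = 32 for
subgroup power, n = 500 for sign recovery, n = 300 for survival power), 400
seeds for the null log-rank calibration, and 1000 replicates for the null
Pearson calibration — sizes at which the binomial error of an estimated
rate is small relative to the asserted bands. The full suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

* The percent-m6A definition (IgG-subtracted percent-of-input) is one of
  several defensible reductions of three-condition RIP-qPCR data; raw
  percent-of-input is available via configuration, but antibody efficiency
  and two-round IP losses are not modeled, so absolute percentages should be
  read as lower-bound estimates.
* No Cox regression or hazard-ratio confidence intervals; the survival
  analysis is limited to Kaplan-Meier curves and the log-rank test.
* Motif scanning reports every adenosine in a matched window; it does not
  predict which position carries the mark, nor duplex thermodynamics.
* Under the default generator settings the FTO-low/αKG-low subgroup t test
  at n = 32 has ≈72% power at α = 0.05 — a reminder that median-split
  subgroup comparisons in 32-patient cohorts are underpowered even when the
  underlying effect is real.
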