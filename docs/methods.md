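# Methods

`cnburden` re-implements, as a tested pipeline with simulated ground truth, a
copy-number-burden analysis of advanced prostate cancer: shallow
whole-genome-sequencing read counts over fixed 500-kb bins are turned into
loss/neutral/gain segment calls; the percent of the autosomal genome altered
(the *burden*, or percent genome altered, PGA) is the central per-tumour
statistic; and the cohort analyses ask how burden relates to metastatic
state, to the loss/gain composition and apparent order of alterations, to
multi-region heterogeneity, and — through non-linear Cox models — to
time-to-event outcomes.

## Synthetic cohort generator

The generator produces cohorts with the statistical structure the analyses
assume, with known truth for every quantity the pipeline later estimates.

**Copy-number events.** A catalogue of 30 recurrent prostate-cancer events on
GRCh37 coordinates (module `cnburden.regions`): early segmental losses (8p,
13q, 16q, 6q, 2q), intermediate focal tumour-suppressor losses (10q23/PTEN,
17p13/TP53, 13q14/RB1, 9p21, 18q, 22q …) plus the first gains, and late
events including 5q21 loss (CHD1) and the 8q21-24 gains (cMYC). A tumour
draws a Poisson number of events (state-dependent means: M0N0 9, M0N1 11,
M1 low 13, M1 high 14) without replacement. The k-th added event is a gain
with probability `min(0.55, 0.08·max(0, k−3))` — monotone non-decreasing, so
low-burden tumours are loss-dominated by construction — and within a
direction events are weighted by a base weight times a stage preference that
shifts from early toward late as events accumulate. Strict stage exhaustion
is deliberately avoided: with 17 early/intermediate losses in the catalogue
it would make late losses unreachable at realistic event counts, removing
exactly the late-region signal the region-ordering analyses study. Defaults
were chosen to reproduce the ordinal structure and approximate magnitudes of
published advanced-prostate-cancer cohorts (simulated index-core burden
median ≈ 13%, M0 ≈ 10% vs M1 ≈ 15%; real cohorts report ≈ 18%, 13.8% vs
20.9%); exact frequencies per locus are not calibrated.

**Read counts.** A bin with integer copy state `s` (2 = neutral) in a core
with tumour cellularity `c` (uniform on 40–100%) has expected count
`depth_mean · (1 + c·(s−2)/2)`; counts are negative binomial with
overdispersion `dispersion` (`var = m + dispersion·m²`, default 0.1,
FFPE-like; 0 gives the Poisson limit). Default `depth_mean` is 100 reads per
500-kb bin. Relative noise is dispersion-dominated above ~50 reads/bin, so
conclusions are insensitive to the depth scale. No GC/mappability bias or
replication-timing wave is simulated; counts are "pre-corrected" by
construction.

**Multi-region cores.** ~37% of patients get 2–13 cores (2 + Poisson(2.2),
median 4). Early-stage events are truncal in every core by construction;
other events are truncal with probability 0.7; non-truncal events are
present in each core independently with probability 0.6. The index core is
the highest-cellularity core (ties → lowest core id), standing in for the
histopathological index-core rule, which is not computable from sequence
data.

**Outcomes.** Five endpoints (OS, PCSS, FFS, PFS, MPFS) are exponential with
log-hazard `g(burden) + state offset`, administratively censored at 7 years.
Default `g(B) = 0.8·ln B` — a saturating effect: steep relative-hazard
increase from low burden, flattening at high burden. Per-outcome baselines
(OS 0.012 … FFS 0.030 per year) give event fractions comparable to an
advanced-disease cohort at 7 years of follow-up. Outcomes are drawn
independently per endpoint (no shared frailty), so cross-endpoint
correlation in real data is not emulated. For `B = 0` under the ln shape a
fixed `zero_shift` (0.1%) is substituted; positive burdens are never
shifted, so closed-form hazard ratios between positive burdens are exact.

**What passing tests do and do not show.** The generator reproduces the
targeted structure (ordered accumulation, state-dependent burden,
truncal/private architecture, non-linear hazards) but not library artefacts,
GC waves, subclonal fractional states or whole-genome doubling. Recovery
results therefore validate the estimators under the stated noise model, not
under every failure mode of FFPE material.

## Copy-number calling

Per sample: log2 ratios of bin counts to the sample median over usable
autosomal bins (zero counts floored at a pseudo-count of 0.5; samples with
< 100 usable bins or non-positive median are rejected). Sex-chromosome bins
are carried but flagged non-autosomal and excluded from all burden
denominators.

**Segmentation** is exact penalized least-squares changepoint detection
(optimal partitioning by dynamic programming, O(n²) per chromosome): it
minimizes total within-segment RSS plus a penalty per additional segment,
so a split is accepted only where it reduces RSS by more than the penalty,
and — unlike greedy binary segmentation — the returned breakpoints provably
attain the minimal RSS among all placements of the same cardinality (the
property the oracle-equivalence tests check). The default penalty is
`2·log(n_chrom)·σ̂²` per chromosome, with `σ̂` the robust noise SD from the
median absolute difference of adjacent bins (Gaussian-consistent scaling,
pooled genome-wide). The penalty's log factor uses the chromosome's bin
count because chromosomes are segmented independently: the multiplicity the
BIC-type term guards against is per-sequence. Ties in the dynamic program
resolve toward fewer segments, so noise-free constant signal yields one
segment per chromosome.

**Calling** applies fixed log2 thresholds (defaults −0.15 / +0.15,
boundary-inclusive) to segment means *re-centered on the sample's neutral
level*, estimated as the bin-count-weighted median of segment means. The
re-centering matters: the log of overdispersed counts is left-skewed, so
after median normalization neutral segments sit ≈ −0.09 in log2 at the
default noise level, and raw thresholds would call whole chromosomes lost
on depth fluctuation alone. Mixture-model callers absorb this offset
implicitly; the weighted median makes it explicit and deterministic
(`center=0` restores raw thresholding). Adjacent same-call segments are
merged with bin-weighted means. Fixed thresholds behave like mixture
calling only for cellularity ≳ 40%, matching the generator's range; below
that, alterations are progressively missed.

**QC** is the mean segment SD: the per-segment sample SD (n−1) of bin
residuals from the segment mean, averaged with equal weight per segment
(single-bin segments contribute 0).

## Burden and cohort analyses

Burden is `100 × altered usable autosomal bins / usable autosomal bins`
(`by_bin`, default; with constant-width bins this is percent genome
altered), or the percent of segments altered (`by_segment`). Loss% and
gain% use the same denominator, so `loss + gain = burden` exactly.

Quartiles of index-core burden use linear-interpolation percentiles with
boundary values in the lower quartile. The loss-vs-gain test pools altered
bins per quartile and tests the equal-direction null; the default is the
exact binomial test of loss probability ½, which is the correctly
calibrated exact test of that null — the observed-vs-expected 2×2
hypergeometric framing (available as `method="fisher"`) conditions on
margins that halve the null variance and over-rejects by design.
Benjamini–Hochberg adjustment runs across the four quartiles. Region
carriage (≥ 1 called segment of matching direction overlapping ≥ 1 bin of a
named region) feeds frequency-by-group tables, the two-sample
Kolmogorov–Smirnov association of carriage with burden (carrier frequency
> 20%, exact KS when both groups ≤ 25, BH across regions), within-patient
prevalence (patients with ≥ 2 cores and ≥ 1 carrier core), and the
multi-region dispersion analysis (sample SD of per-core burden;
Kruskal–Wallis M0 vs M1; Spearman correlations with index burden and core
count). Group comparisons in the clinical battery use rank-sum or
Kruskal–Wallis as named in the output, with univariable OLS regressions of
√burden on each clinical variable.

## Survival modelling

Cox proportional-hazards models (lifelines, Efron ties) with the burden
functional form selected by first-degree fractional polynomials: burden is
scaled by 1/10, transformed by each power in {−2, −1, −0.5, ln, 0.5, 1, 2,
3}, and the likelihood-best power is kept over the linear form only when
the 1-df likelihood-ratio comparison has p < 0.10 (the closed test also
reports the 2-df comparison against omitting burden). Log-likelihood ties
below 1e−8 resolve toward linear, then catalogue order; powers that fail to
converge are skipped with a warning, never silently selected. If any burden
is zero, half the smallest positive burden is added to all values (logged).
The covariate-free null partial likelihood is computed in closed form
(Efron; each event time with d tied events and risk-set size n contributes
−Σⱼ log(n−j)) and is cross-checked against lifelines' likelihood-ratio
statistic in the tests.

Multivariable fits adjust for grading group (indicator-coded, groups 1–3
pooled when jointly sparse), metastatic state (M0N0 reference), log PSA,
age and cellularity. The metastatic-state interaction model freezes the
selected functional form, adds transform × state terms (3 df) and tests by
LRT. Relative-hazard curves are `exp(β·(f(b) − f(ref)))`; with a shared
burden effect the per-state curves differ only by proportional offsets, so
state-specific curves are produced from the interaction model's per-state
coefficients when requested — the two displays answer different questions
and neither is asserted as canonical. Kaplan–Meier curves per burden
quartile report the 4-year estimate read from the step function. The
pipeline falls back to unadjusted fits when events < 5 per covariate
(events-per-variable guard).

## Problem sizes in the validation battery

The acceptance script and the acceptance tests use: 1,000 random small
chromosomes (≤ 25 bins) for the segmentation oracle and 1,000 random cases
each for the exact-test and KS oracles; one 300-patient cohort at 50
reads/bin for burden recovery (~700 cores); 500 replicates at n = 150 for
the null FP(1) calibration and 100 replicates at n = 300 for the ln-truth
recovery; 1,000 scaled-down cohorts (quartile totals 150–450 altered bins)
for the loss-gain calibration; and one default 300-patient cohort for the
structure signatures. These sizes keep each Monte-Carlo standard error
small relative to its tolerance band (bands: 3 binomial SEs around nominal
rates; a 2-point slack on quartile gain-share steps; 3-point slack on
adjacent KM estimates, with Q1 − Q4 ≥ 10 points).

## Known limitations

* No GC/mappability correction; real shallow-WGS counts need one upstream.
* Integer copy states only: no subclonal fractions, no whole-genome
  doubling (the depth-of-coverage approach is blind to ploidy shifts by
  construction).
* Cross-sectional ordering proxies (quartile composition, KS association)
  do not establish temporal order.
* The exact per-sample concordance with any particular published caller is
  not promised — agreement is at the level of the burden statistic and the
  cohort analyses.
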