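# Methods

`droughtring` implements the quantitative-genetic analysis of drought
response in an open-pollinated (OP) conifer progeny trial, driven by a
synthetic-data generator so that the full pipeline runs with no external
data. This note records the models, the generator's assumptions, the
numerical choices, and the limits of what the tests demonstrate.

## Study design being emulated

Four test sites planted in 1982; at each site 224 OP families divided into
19 sets, each set randomized in five blocks as four-tree family row plots at
2.5 x 2.5 m spacing, so a family contributes 20 trees per site. A genotyped
subset of 40 families with ~10 trees per family per site carries the
high-resolution phenotypes (ring series, gall-rust score 0–6, delta13C, wood
density, height and DBH at age 35). OP families are treated as maternal
half-sibs: the seed parent is known, pollen parents are unknown and assumed
unrelated, giving an expected additive relationship of 0.25 within family.
Families are partitioned into near-equal sets (224 is not divisible by 19;
set sizes differ by at most one).

## Ring widths from density profiles

Profiles are sampled every 0.0254 mm. Within a ring the generator lays an
earlywood plateau (default 350 kg/m3, 60 % of the ring) followed by a
latewood plateau (650 kg/m3); the latewood-to-earlywood drop at the ring
boundary is the detection signal. The detector places a boundary wherever
the one-step density decrease exceeds `drop_fraction` (default 0.5) times
the profile's 10th–90th percentile contrast, merges candidates closer than
`min_width_mm` (default 0.2 mm) keeping the steepest drop, and converts
boundary spacing to widths. Widths are therefore quantized to the sampling
step; the zero-noise round trip is exact against the generator's quantized
truth. Dating anchors the outermost complete ring at 2016 (cores collected
mid-2017; the partial ring is excluded).

Cross-dating is a simplified segment-correlation check, not a port of the
classical program: each series is detrended by first-differencing log
widths (parameter-free high-pass), correlated against the leave-one-out mean
chronology over half-overlapping segments (default 10 years), and segments
below `min_corr` are flagged. A one-year dating shift in one series among
correctly dated neighbours is reliably flagged at the defaults.

## Drought indices

With BAI_t = pi (r_t^2 − r_{t−1}^2) from cumulative ring widths:

- resistance(event) = BAI_event / mean(BAI, 4 years before);
- resilience(event) = mean(BAI, 4 years after) / mean(BAI, 4 years before);
- decline = mean(BAI 1997–2001) / mean(BAI 2012–2016), the long-term index —
  values near 1 mean sustained growth, values > 1 long-term reduction. 2015,
  itself a dry year, stays inside the last window by design.

Windows touching years outside the series yield missing values; windows are
never shortened. Resilience grouping uses a strict > 0.8 threshold per
event. Drought events default to {2002, 2010} from configuration; a CMI < 0
detector exists as a diagnostic but never chooses events on its own.

The competition index is sum_i (d_i/d) * arctan(d_i/dist_i) over alive
neighbours within 7.1 m (two rows/columns of the grid), with DBH in cm and
distance in m fed to arctan without unit conversion — implemented exactly as
the source formula prints it, and flagged in the docstring because the mixed
units make the index scale-dependent.

## Climate

Monthly temperature follows a sinusoid (mean 2.4 °C, amplitude 14.5 °C at
latitude 54.5°) with year effects; precipitation follows a summer-wet
monthly profile around 535 mm/yr. The climate moisture index is annual
precipitation minus annual Hargreaves (1985) reference evapotranspiration,
with extraterrestrial radiation from the FAO-56 formula at mid-month. The
Hargreaves coefficient is recalibrated to 0.0013 (from the textbook 0.0023),
a standard regional adjustment; with it, normal years sit near CMI +130 mm,
matching the boreal-foothills water balance at this precipitation. Drought
years are forced by rescaling that year's precipitation to 75 % of its PET,
so CMI < 0 holds by construction.

## The growth generator

Ring width for tree i in year y is

    w = w_max * hump(age) * site * drought * competition * lognormal noise,

with a Hugershoff-type age trend hump(age) = ((age/17) e^{1−age/17})^1 that
peaks in the 1997–2001 window for a 1982 planting. Drought enters through
three channels, each with a genetic and a plastic (environmental) part:

- event year: log width drops by max(0.35 − g_resist + e, 0);
- recovery: the four post-event years drop by 0.6 * 0.55^(k−1) * D_rec,
  where D_rec = 0.32 − g_recov + rust and competition terms + e_rec;
- persistence: all later years drop by 0.85 * D_per, with D_per driven by a
  separate `persist` genotype correlated 0.8 with recovery.

The persistence channel is what creates a heritable long-term decline, and
its partial decoupling from recovery keeps the emergent resilience–decline
genetic correlation strongly negative (about −0.9 at zero noise) without
being a structural −1. The plastic terms (SD 0.15 event, 0.35 recovery) set
the emergent heritabilities: with the defaults, the decline index is the
most heritable drought trait (~0.2–0.35 on the full design) and resistance
the least, with all index heritabilities inside 0.05–0.5. Gall-rust scores
(ordinal 0–6) come from a latent severity loaded negatively on the recovery
genotype, which in turn feeds back into the recovery deficit — infection
reduces resilience in the generator as in the data it emulates. A genetic
growth-rate multiplier (`growth` channel) plus 0.8 cm DBH measurement noise
give height and DBH realistic additive signal.

One consequence worth stating: any non-flat age trend makes the indices of
an undisturbed tree differ from 1 (basal area rises with radius even at
constant ring width). The identity "all indices equal 1" therefore holds
for constant-BAI series — asserted exactly in the tests — while generator
tests compare against the closed-form age-trend baseline.

Breeding values are gene-dropped through the pedigree: founders are
multivariate normal with covariance D^{1/2} R_g D^{1/2}; an offspring gets
half of each known parent's value plus a Mendelian deviation, an unknown
parent contributing an independent half-founder draw. This reproduces the
half-sib covariance sigma_a^2/4 and parent-offspring sigma_a^2/2 exactly
(verified against an allele-dropping Monte-Carlo oracle). An elevation cline
(slope −5.5e-4 per m on the recovery and persistence genotypes, origins
uniform on 945–1280 m) injects local adaptation sized to give family-BV
regressions R^2 near 0.2.

## Relationship matrices and family correction

A is built by the tabular recursion over a topologically sorted pedigree
(cycles rejected with the offending chain). G follows VanRaden's first
method, G = ZZ'/(2 sum p(1−p)), with sample allele frequencies by default
(base-population frequencies can be supplied), mean-imputation of missing
dosages, and MAF/missingness filters. Note that sample-frequency centring
makes founder off-diagonals average −1/(n−1), not 0 — the tests check both
conventions.

Family correction assigns each tree to the family maximizing its mean G to
the family's members (self excluded); maxima below 0.125 — half the
half-sib expectation — leave the tree unassigned, and ties keep the original
label. On the default contamination scenario (5 % mislabels, 500 SNPs, 40
families) essentially all mislabels are corrected; genuinely contaminated
families can legitimately fall below the floor and lose members to the
unassigned pool.

## The animal model

The individual-tree mixed model is

    trait = mu + Provenance + Block + Block:Set + additive + residual,

with the additive effect's covariance proportional to A (or G). Per-site
fits omit Site; combined fits add it as a fixed effect. Plot effects are
never fitted (a single tree per four-tree plot is sampled). Heritability is
reported with the full denominator

    h2 = sa2 / (sa2 + s_Block2 + s_BlockSet2 + se2),

which is the convention this analysis follows even though the design
variances in the denominator are unconventional; `denominator =
"conventional"` gives sa2/(sa2+se2). Genetic correlations come from
pairwise bivariate fits (full 2x2 additive and residual covariance,
trait-specific design variances); a full multi-trait fit would estimate the
same quantities at far greater engineering cost. Significance uses the
|r| > 2 SE rule.

### Estimation

EM-REML in the projection-matrix form (monotone in the restricted
likelihood by construction — asserted in tests), run to a relative
log-likelihood change below 1e-8 (max 1000 iterations), followed by one
average-information (AI) round that both polishes the solution and supplies
the information matrix whose inverse gives standard errors; delta-method SEs
follow for h2 and r. Variances are floored at 1e-10 of the phenotypic
variance.

The implementation eigendecomposes the additive kernel once per dataset and
folds the low-rank block/set factors in by a Woodbury identity, so every
iteration costs O(n q^2) for q design levels rather than O(n^3), and the
decomposition is reusable across traits and simulation replicates sharing a
pedigree. BLUPs come from back-solving u = A[:, obs] P y sigma_a2, which
also yields parent (family) breeding values without records. On balanced
designs the estimates match the Henderson ANOVA closed forms to 1e-6.

A faster AI-Newton mode (3 EM warm-up steps, then AI steps with step-halving
and EM fallback; boundary components with inward gradients are pinned out of
the Newton update) serves the site-mean models and the SEM components, where
no particular algorithm is prescribed; both modes reach the same optimum.

Estimated marginal site means use trait = Site (cell means) + block + set
random effects; all pairwise contrasts are tested against the studentized
range distribution with residual (containment-style) degrees of freedom
n − k, and a compact letter display summarizes groups. With two sites the
Tukey p reduces exactly to the two-sided t-test p. Normality screening uses
D'Agostino's test; failing traits take sqrt or log, whichever minimizes
absolute skewness on the valid domain. Phenotypic correlations are
pairwise-complete Pearson with Bonferroni adjustment over the tested pairs.

## Piecewise SEM

The causal hypothesis is a DAG over competition, gall rust, delta13C, wood
density, resilience to each event, decline, height and DBH (height–DBH
errors correlated). Each endogenous node gets a linear mixed model with its
parents as fixed effects and site/block/set/family random intercepts;
standardized coefficients are b sd(x)/sd(y). The d-separation basis set
takes one claim per non-adjacent pair, conditioned on the parents of the
downstream node only; correlated-error pairs and exogenous–exogenous pairs
(whose association the model leaves free) are excluded. Fisher's C =
−2 sum ln p on 2k degrees of freedom gives the global fit; claims rejected
at 0.05 are reported as candidate missing links. Component p-values use a
normal approximation to the Wald t — adequate at n ~ 10^3 and verified by
the calibration experiment (global p uniform over 200 replicates when the
data really come from the DAG). The ordinal gall-rust score is modeled as
Gaussian, a deliberate simplification.

When the SEM is fit to the growth generator's output, the global test
typically rejects and reports extra links: the generator is a nonlinear
growth model whose cumulative-size traits (height, DBH) depend on the
drought channels directly, not only through decline. That is the method
working as designed — detecting real model-data mismatch — and is the
expected behaviour of the default pipeline report, not a defect.

## Local adaptation

Family (dam) breeding values are regressed on elevation of origin by OLS;
slope, R^2 and the slope p-value are reported. Under a null generator the
R^2 distribution matches its theoretical mean 1/(n−1) and p is uniform; with
the default cline, resilience/decline regressions land near R^2 0.1–0.3 at
40 families. Other climate-of-origin covariates pass through untouched for
user-side exploration.

## Problem sizes and runtime choices

The default pipeline (4 sites x 40 families x ~10 trees/family/site,
~1600 phenotyped trees, 500 SNPs) runs end-to-end in a few minutes on one
CPU. The test suite's recovery experiments use n ~ 2000 (200 families for
the h2 = 0.30 experiment, 20 replicates sharing one kernel decomposition;
100 families for the r_g = −0.8 bivariate experiment) and 200 replicates of
a 450-tree design for the SEM calibration — sizes chosen so each experiment
has enough power to detect real bias while the whole suite stays in the
minutes range.

## Known limitations

- No process-based ecophysiology: drought enters as log-scale multipliers,
  not via water balance or carbon allocation; no spatial autocorrelation of
  soils, and mortality is independent Bernoulli rather than clustered
  (the wildfire-type mortality of real sites is not spatially structured
  here).
- Multi-trait analyses are pairwise bivariate; a joint >2-trait fit is out
  of scope.
- The SEM treats every response as Gaussian and uses large-sample Wald
  p-values; with few groups per random factor the claim tests can be
  slightly miscalibrated.
- Sire reconstruction is not attempted; family correction only reassigns
  maternal (seed-parent) groups.
- Ring widths are quantized to the 0.0254 mm sampling step, a ~1 %
  relative effect on typical rings that the index ratios largely cancel.
- Passing recovery tests show the estimators are correct under the
  generator's assumptions (half-sib structure, Gaussian effects,
  multiplicative lognormal noise); they cannot show robustness to real-data
  pathologies such as cross-dating errors, non-random mortality, or
  pedigree errors beyond the simulated contamination type.
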