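# Methods

`metapopabc` implements likelihood-free demographic inference for a
metapopulation sampled under two complementary designs: a **single-deme
sample** (SID; several diploids from one deme) and a **scatter sample**
(SCD; one diploid per deme, sensu Wakeley). The contrast between the two
gene genealogies carries the demographic signal: within-deme
("scattering-phase") coalescences are fast and recent, between-deme
("collecting-phase") coalescences are slow, and their ratio is governed
by the composite parameter Nm — the product of deme effective size and
migration rate.

## Demographic models

Six models share one declarative registry (`metapopabc.models`). Times
are generations backwards from the present; sizes are diploid effective
sizes; conversion to years (generation time 7 y) happens only at
reporting.

| model | parameters | description |
|---|---|---|
| COS | N | constant size |
| CHG1 | N_mod, N_anc, T_c | one instantaneous size change |
| CHG2 | N_mod, N_int, N_anc, T_c2 < T_c1 | two size changes |
| FIM | Nm, N_anc, T_i | non-equilibrium finite island model, 100 demes founded from one ancestral deme at T_i |
| FIM_BOTT | + I_bott, T_bott | FIM with an I_bott-fold drop of Nm at T_bott |
| CHG1_BOTT | + I_bott, T_bott | CHG1 with an I_bott-fold drop of Ne at T_bott |

FIM priors follow the study design: Nm ~ U(0.05, 250), N_anc ~
U(100, 100 000), T_i ~ U(100, 200 000). The unstructured models' priors
are package defaults on the same scales (sizes U(100, 100 000), times
U(100, 200 000)); ordering constraints (T_c1 > T_c2, T_i > T_bott,
T_c > T_bott) are enforced by rejection sampling, which preserves the
marginal supports.

Two genuinely open choices, and how they were resolved:

* **Deme size under FIM.** Only the composite Nm is inferential. The
  simulator needs N_deme and m separately, so N_deme is a recorded
  nuisance drawn per simulation from loguniform(100, 10 000) and
  m = Nm/N_deme. Integrating over N_deme makes the Nm inference robust
  to the split, at the cost of wider posteriors.
* **What an "Nm reduction" means for FIM_BOTT.** Implemented as a
  reduction of the migration rate (deme sizes unchanged), with
  `deme_size` and `both` switches. A deme-size reduction would shrink
  each sampled individual's deme and make the scatter design detect the
  bottleneck instantly through within-individual pair coalescence — the
  opposite of the resilience a metapopulation actually shows (measured:
  at T_bott = 100, I_bott = 1000 the deme-size variant nearly doubles
  the SCD doubleton share; the migration variant leaves the SCD spectrum
  unchanged while the SID spectrum progressively loses singletons).

## Coalescent engine

Unstructured epochs are an exact piecewise-constant Kingman coalescent.
The island phase uses a two-timescale structured coalescent
(`metapopabc._engine`): demes holding two or more lineages are simulated
exactly (within-deme coalescence; emigration with correct occupied/empty
destination probabilities), while co-location episodes between two
*singleton* lineages — which resolve on the fast within-deme timescale —
are collapsed into instantaneous Bernoulli coalescences at the effective
pairwise rate 2m/((D−1)(1+4Nm)). Both the omitted episode durations and
the finite-D corrections are O(1/D) relative errors; with D = 100 the
engine agrees with closed-form island-model expectations (E[T2] = 2ND
same deme, 2ND + (D−1)/(2m) different demes) and with msprime's exact
structured coalescent to within Monte-Carlo error, which the test suite
verifies. The payoff is speed: ~50–150 µs per genealogy at the study's
parameter ranges, where an exact event-by-event simulation generates
10⁴–10⁶ migration events per locus. msprime remains the simulation path
for unstructured models with intra-locus recombination, and the
independent oracle in tests.

Mutations are infinite-sites on a finite sequence: Poisson numbers of
mutations per branch, each creating a new biallelic site at a distinct
position (multiple hits re-drawn), so triallelic sites never arise —
mirroring the variant filters of the real pipeline. Diploids pair
lineages 2k and 2k+1; under structured sampling both lineages of an
individual come from the same deme, because the sampling unit is the
individual shark.

Per-locus mutation and recombination rates come from hyperpriors. The
study's hyperprior families are not published in the main text, so the
defaults are package choices, stated here once: µ ~ lognormal(median
3 × 10⁻⁹/bp/generation, σ = 0.25) — the median makes the fitted optimum
(Nm ≈ 40, N_anc ≈ 31 000, T_i ≈ 59 000) produce ~2–3 SNPs per 600 bp
locus, the observed order — and r fixed at 0. The ABC summaries
(aggregated folded SFS and S) are insensitive to intra-locus
recombination in expectation; r only narrows across-locus variance.
A non-zero r is supported for the unstructured models (via msprime) and
tested; the island engine treats loci as non-recombining.

## Summary statistics and filters

The ABC summary vector is the folded site frequency spectrum of the n
diploids (minor-allele copy classes 1..n, over the 2n chromosomes) plus
the total number of segregating sites S. The vector handed to the ABC
machinery is **proportions + S** (counts + S would count S twice; a
`counts` switch keeps both auditable). Monomorphic datasets get a zero
vector. Ties at exactly 50% frequency fold into the highest class once.

Raw VCFs pass through the study's site filters, in order: minimum depth
6× in every sample → triallelic → heterozygous calls in more than 80% of
samples → any missing call. Removals are attributed to the first failing
filter; the order affects only that attribution, never the survivors.
A strand-bias hook exists as a pass-through (simulations carry no strand
information).

## ABC machinery

* **Rejection**: Euclidean distance on per-statistic standardized
  summaries (median/MAD across the reference table; MAD falls back to SD
  then to 1 for degenerate columns), retaining the k closest rows with
  ties broken by row order. Standardisation makes rejection invariant to
  affine rescaling of any statistic.
* **Local linear regression** (Beaumont-style): each parameter, on the
  log scale when strictly positive, is regressed on the summary
  deviations with Epanechnikov weights over distance; adjusted value =
  fit at the observed summaries + residual, mapped back inside the prior
  support. The folded-SFS proportions sum to one, so exactly collinear
  columns are dropped by pivoted QR before the weighted least squares; a
  genuinely singular design falls back to unadjusted values with a
  warning.
* **Model choice**: pool all models' simulations, retain the k_total
  closest (25 000 at full scale, scaled down proportionally here), fit a
  weighted multinomial logistic regression of model label on the
  standardized summaries, and evaluate it at the observed point. A model
  absent from the retained set gets probability 0 with a warning.
* **Posterior summaries**: weighted median and equal-tailed 2.5/97.5%
  quantiles (midpoint-interpolated), mode by Gaussian KDE with Silverman
  bandwidth; the ancestral/modern ratio ("resize") is added for the
  step-change models.

## ABC-skyline

Each retained CHG1/CHG2 (or COS) draw defines a step function Ne(t);
pointwise weighted medians and 95% intervals over a common time grid
give the skyline. The grid is the union of fixed recent points
{0, 25, 50, 100, 200, 300, 400, 500} generations and draws from an
exponential truncated at the 97.5% quantile of the mean TMRCA across
loci (rate 3/bound, 50 random points by default — the exact rate and
count are unpublished, so these are package defaults chosen to
concentrate points toward the present). The TMRCA bound is re-simulated
from retained posterior draws (`skyline.tmrca_bound`). Intervals are
equal-tailed by default with an HPD switch; the two conventions are both
reported in the literature and differ little for unimodal posteriors.

## Validation studies and their desk-scale sizes

All studies run from the same knobs that reach the full published scale
(100 000-row tables, ~1000 loci, 1000 pods). The shipped defaults are
desk-scale, chosen once: reference tables of 2 500–5 000 rows × 120 loci
of 600 bp; 500 retained draws; 100 pods for interval coverage and
cross-validation; 18 pods per scheme for the skyline contrast; 200 pods
per bottleneck grid cell (per-pod Nm medians shift by ~0.25 SD in the
hardest sentinel cell, so smaller cells are underpowered). With these
sizes the whole suite plus the acceptance script completes on one CPU in
well under an hour.

* **Cross-validation of estimation**: pods from the joint prior,
  re-analysed like data; relative bias = median over pods of
  (estimate − truth)/truth, reported for mode and median. Dimensionless
  and robust; the study's own normalisation is unpublished.
* **Cross-validation of model choice**: argmax confusion matrix over
  prior pods.
* **Posterior predictive check**: replicate S from weighted posterior
  draws; two-sided Bayesian p-value by min-tail doubling with the
  (1 + #extreme)/(n + 1) convention.
* **Bottleneck grid**: {100×, 1000×} × {10, 50, 100, 200, 500, 1000}
  generations, both schemes, each cell against its matched no-bottleneck
  baseline; "signal detected" is operationalized as the cell's median
  recent Ne falling below the 2.5% quantile of the baseline's per-pod
  recent Ne, plus a one-sided Mann-Whitney test on per-pod Nm medians.

## What the synthetic data do and do not emulate

The generator reproduces the study's shapes — 9-diploid scatter and
11-diploid single-deme designs, ~1000 independent ~600 bp loci, no
missing genotypes after filtering, planted filter violations with a
ground-truth manifest — and the genealogical structure of a
non-equilibrium island metapopulation. It does not model read-level
error, coverage variation, strand bias, linked selection, or any spatial
arrangement of demes (no stepping-stone or range-expansion geometry).
Passing tests therefore demonstrate the correctness and power of the
inferential machinery under the stated models, not robustness to
model misspecification in real capture data.

## Numerical choices and degenerate inputs

Seeds thread through `numpy.random.Generator` everywhere; identical
seeds give byte-identical datasets. Weighted quantiles drop zero-weight
draws and interpolate at cumulative-weight midpoints. Epanechnikov
weights vanish at the retention boundary; boundary rows get the smallest
positive weight so the retained set never silently shrinks. KDE modes
fall back to the weighted median if the kernel matrix is singular.
Monomorphic pods are legal (zero summary vector). I_bott < 1 is
rejected with an explicit message; I_bott = 1 produces schedules
structurally equal to the un-bottlenecked models. Fixed recent grid
points beyond the TMRCA bound are dropped with a warning.

## Known limitations

* The island engine's O(1/D) approximation slightly shortens
  between-deme coalescence times (≈1% at D = 100); at D ≤ ~20 the exact
  structured coalescent should be preferred.
* Nm above ~10 is only weakly identified by folded-SFS summaries at
  desk scale (the spectrum saturates toward the strong-migration limit),
  so Nm posteriors lean on the prior there; interval coverage remains
  calibrated, and this matches the wide upper credible bounds the
  full-scale study reports.
* Intra-locus recombination is not simulated for island models.
* The real capture data have no public accession, so no numbers from
  the study's Tables 2–3 on the shark data are reproduced; the
  validation suite covers the arithmetic, the oracles and the
  qualitative findings instead.
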