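# Methods

## The score

The genomic-instability measure implemented here counts **large-scale
genomic alterations (LGAs)**: copy-number breakpoints between two adjacent
segments of the same chromosome arm, each at least `min_lga_len = 10 Mb`
long, whose mean log2 copy ratios differ by at least `delta = 0.25`.
The 10 Mb floor is the defining scale of the score — focal events and
centromeric transitions carry no HRD signal and are excluded by
construction (segmentation is strictly per-arm, and short flanks never
qualify). Each of six window models (non-overlapping tilings at 5, 25, 50,
100, 500 and 1000 kb) produces its own LGA count; the integrated **GIA**
is the median of the six, half-integers rounded up. The window list is
configurable and logged with every run.

Two deliberate substitutions relative to the assay this emulates, both
forced by underspecification of the original and both recorded here as the
package's own design choices:

* *Tiling vs sliding windows.* The window models are non-overlapping
  tilings. Overlapping windows would make "one LGA count per model"
  ill-defined (a single true breakpoint appears in several overlapping
  windows); tiling is the standard shallow-WGS reading and keeps every
  count well-defined.
* *Median integration instead of a learned integrator.* The per-model
  counts are combined by a rounded median — robust to the coarse models'
  known undercounting at low purity, deterministic, and parameter-free.

## Coverage profiles

Raw per-bin counts are filtered (zero count → `zero_count`; GC outside
[0.28, 0.72] → `gc_extreme`), optionally GC-corrected by dividing each
count by the median count of its GC decile (deciles over retained bins —
deterministic and assertable, unlike loess smoothing), then divided by the
median corrected count and log2-transformed. The retained log2 ratios are
re-centered so their median is exactly 0 (for an even number of bins the
interpolated median of the logs is not exactly the log of the median
ratio). A sample losing more than 50% of its bins fails QC and is reported
**ND** (undetermined) rather than scored; ND propagates through
classification and is excluded — with a logged count — from any
method-comparison table.

## Segmentation

Per arm, the change-points minimise

    sum_segments SSE(segment) + beta * (number of change-points),
    beta = penalty_scale * sigma^2 * log(n)

with `sigma = 1.4826 * MAD(successive differences) / sqrt(2)` (Gaussian
scaling; differencing cancels the piecewise-constant signal) and
`penalty_scale = 3.0`. The minimiser is exact: PELT prunes candidates that
can provably never be optimal but returns the same global optimum as
O(n²) optimal partitioning, which the test suite verifies change-point for
change-point on hundreds of random profiles. Ties in the recursion go to
the leftmost candidate; σ is floored at 1e-8 so a noiseless flat arm yields
a single segment; arms with fewer than two retained bins become one
flagged trivial segment. Adjacent segments closer than
`merge_threshold = 0.10` in mean are then merged smallest-gap-first
(leftmost pair on ties) with bin-weighted means.

`delta = 0.25`, `merge_threshold = 0.10` and `penalty_scale = 3.0` are not
published constants of the original assay; they are this package's
defaults, chosen so that ground-truth recovery holds over the rated
operating range (see below) and exposed in the configuration precisely
because they are choices.

## Classification

Three-class call: HRN ≤ 14, HRM 15–19, HRD ≥ 20. The source inequalities
("LGA > 20", "15 < LGA < 19", "LGA < 14") leave 14, 15, 19 and 20 formally
unassigned; the closed bands above make the classes exhaustive and match
the published band captions (GIA 15–19 for the mild class). Two-class
call: positive iff GIA ≥ 15, identical to collapsing HRM into HRD.
Reference (0–100) scores band as N ≤ 42, M 43–55, D ≥ 56, with clinical
positivity at ≥ 42; a score of exactly 42 is band N *and* positive — the
published band edge and positivity cutoff genuinely overlap there, so the
package reports both facts instead of silently reconciling them (no
bundled sample sits at 42).

## Concordance statistics

Cohen's κ is computed from the contingency table as `(po − pe) / (1 − pe)`
with the conventional verbal scale (< 0 none, ≤ 0.20 slight, ≤ 0.40 fair,
≤ 0.60 moderate, ≤ 0.80 substantial, else almost perfect). Its p-value
uses the large-sample null standard error — adequate for screening, coarse
at n = 20, and therefore documented as approximate. PPA is the
both-positive count over the reference rater's positive total, kept as an
exact fraction and rounded to a percent only for display. Spearman ρ
(average ranks, t-approximation p) and Fisher's exact test go through
scipy; scipy's two-sided Fisher convention — sum the probabilities of all
margin-fixed tables no more probable than the observed — is the one
intended here, and the tests pin it against full hypergeometric
enumeration.

## Survival analysis

Kaplan–Meier estimation and the k-group log-rank test use lifelines.
"Mean survival" is the KM **restricted mean**, the area under the survival
step function up to the largest observed time: an unrestricted mean is
undefined when the curve does not reach zero, and with no censoring the
restricted mean equals the arithmetic mean of event times (a tested
identity). This definition changes the number relative to a naive mean of
observed times whenever censoring is present, which is why it is stated
prominently. Medians are the earliest time with S(t) ≤ 0.5, reported as
not reached otherwise. The univariate Cox model is fitted in-package by
Newton–Raphson on the Breslow partial likelihood (simplest exact-gradient
tie handling; Efron is not implemented), converging to score < 1e-8;
complete separation is detected (diverging β or flat likelihood) and
refused. Days are the internal unit; months are days / 30.4375.

## Synthetic data: what it emulates and what it does not

The generator produces ground-truthed sWGS samples on a reduced karyotype
(6 chromosomes × p+q arms, 40 + 60 Mb, 600 Mb total — large enough for
dozens of ≥ 10 Mb segments, small enough for second-scale tests; the full
hg19 arm table, exact chromosome lengths with approximate cytoband
centromeres, is packaged for realistic-scale runs):

* **Truth profiles.** LGA breakpoints are allocated across arms within
  per-arm capacity (an arm of length L holds at most ⌊L/12 Mb⌋ − 1
  breakpoints; segments are drawn ≥ 12 Mb so bin-edge quantisation never
  pushes a flank under the 10 Mb floor). Copy ratios follow a one-step
  random walk over {0.5, 1.0, 1.5} (copy numbers 1/2/3 at diploid
  baseline), so every true step is ≥ log2(1.5) ≈ 0.585 and remains ≥ 0.25
  after purity dilution (`obs = log2((p·r₂+1−p)/(p·r₁+1−p))`) down to
  purity 0.4 — the truth stays recoverable across the rated range without
  per-sample tuning. Optional sub-10 Mb focal distractors insert
  breakpoints that must *not* be counted. The true LGA count is
  recomputable from the segments alone and is asserted at generation time.
* **Counts.** Expected bin count ∝ `purity·ratio + (1 − purity)`, scaled
  to `coverage × bin_length`, modulated by a smooth unimodal GC-bias
  multiplier (peak at GC 0.5, amplitude 0.3 by default), with
  negative-binomial noise (`dispersion = 20`, i.e. a ~22% relative noise
  floor regardless of bin size — FFPE sWGS is overdispersed relative to
  Poisson; the infinite-dispersion limit is Poisson).
* **Study conditions.** Defaults: 20 samples, purity ~ U(0.4, 0.9),
  coverage ~ U(0.4, 0.8)×, LGA targets 0–20 on the reduced karyotype.
* **Clinical layer.** Cohort classes drawn 65/20/15% HRD/HRM/HRN (the
  published cohort's approximate composition), reference scores uniform
  within the class-matched band, PFS exponential per class with means
  2893/1217/631 days (95.04/39.97/20.73 months at 30.4375 days/month),
  an independent Bernoulli censoring flag (20% by default), and OS as PFS
  plus an exponential tail (mean 365 days).

Not modelled: mappability/blacklist structure, replication timing,
FFPE artifacts beyond overdispersion and GC bias, subclonality, whole-genome
doubling, and any coupling between purity and clinical outcome. Passing
the recovery tests therefore shows the *method* recovers known truth under
the stated noise model — not that the score is clinically valid on real
FFPE libraries.

## Verified properties and sizes

The test suite checks, among others: exact PELT/oracle agreement (200
random profiles, n ≤ 50); end-to-end GIA recovery within ±2 of truth for
≥ 90% of 100 simulated samples at default settings (observed: 100%);
Fisher vs enumeration on random tables with N ≤ 40; KM/Cox identities
(restricted mean = arithmetic mean without censoring; hazard ratio 3
recovered within 10% at 500/arm; Breslow fit matching lifelines on
tie-free data); and byte-identical reruns of the full CLI pipeline under a
fixed seed. The acceptance script uses 60 simulated samples for the
recovery rate and 200 profiles for the oracle sweep — sizes at which the
Monte-Carlo properties are stable while the whole script stays fast.

## Known limitations

* The κ p-value is asymptotic; at n = 20 it is indicative only.
* The coarse window models (0.5/1 Mb) systematically undercount at low
  purity (few bins per 10 Mb flank); the median integration absorbs this,
  but GIA from coarse-only window lists is biased low.
* The hg19 centromere boundaries are cytoband midpoints, adequate for arm
  assignment at ≥ 5 kb bins but not base-accurate.
* Cox supports a single covariate (the HRD-class indicator); no
  multivariate adjustment.
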