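# Methods

## Scoring rubrics and decision rules

The IVD rubric has 6 items graded 0/1/2 (maximum 12); the DD rubric has 3
(maximum 6). Records may carry item-level grades or pre-aggregated
totals + flags; when items are present the aggregates are derived
(`total = sum`, IVD flag = any item 0, DD flag = any item 2) and the two
dialects are interchangeable — verified exhaustively over all 3^6 and 3^3
grade vectors.

Two decision rules are implemented for the DD severity gate because the
source material words it two ways:

* `strict_gt3` (default): severe iff total > 3 or any item graded 2. This
  rule reproduces the 15 AF / 11 NP eligibility counts of the bundled
  cohort and is used everywhere downstream.
* `ge3`: severe iff total ≥ 3 or any item graded 2. This variant
  reproduces the reported "38% severe" cohort fraction (21/56 = 37.5%).

The IVD clear rule is strictly total > 6 (a total of exactly 6 is
*unknown*): only that reading reproduces the 17/16 clear counts on the
bundled cohort.

Per-donor deduplication keeps, per donor and compartment, the eligible
sample with the highest IVD total (ties: lowest DD total, then lowest
sample id). The source material does not record which duplicate-donor
sample was actually profiled, so the tie-break is this package's own
deterministic convention; the donor-level outputs (donor union, mean age,
age range, gender split) are provably invariant to it and are covered by a
test. The mean donor age is reported both exactly and rounded
(half-away-from-zero) to whole years.

## Rank correlation

`spearman` delegates to the tie-corrected (average-rank) Spearman
implementation of scipy and attaches the two-sided p-value from the t
approximation on n − 2 degrees of freedom — the default of common
statistics packages at this sample size (n = 28 per compartment). Exact
permutation p-values are deliberately out of scope. Interpretation bands
on |r|: < 0.2 very weak, < 0.4 weak, < 0.6 moderate, < 0.8 strong,
otherwise very strong.

One caveat is pinned in the acceptance suite: the bundled per-sample
scoring table and the published correlation summary it accompanies are
mutually inconsistent in three NP cells (IVD×MRI, DD×age, DD×MRI). All
four AF cells and the headline NP IVD-vs-age cell (r = −0.57, p = 0.001,
moderate) recompute to 2 d.p.; for the three inconsistent cells the
package necessarily reports the values the per-sample data implies
(+0.09, +0.32, −0.00), cross-checked against an independent
rank-then-Pearson oracle.

## The pairwise DEG screen

The original chips were processed by a proprietary vendor pipeline. The
screen's logic — not that pipeline — is the substance here, so the
per-pair statistics are re-founded on an explicit, reproducible model:

* **Detection**: a gene is *detected* on a chip iff its summary signal is
  at or above a configurable detection floor (default 100 linear units).
* **SLR**: the median over the P probe-level replicates (default P = 11,
  echoing typical probe-set sizes) of log2(AF probe / NP probe). The
  median mirrors the robust one-step estimator family the vendor software
  uses. FC = 2^SLR identically.
* **p-value**: two-sided Wilcoxon signed-rank of the per-probe log ratios
  against zero. The exact null distribution of W+ is computed by the
  classic dynamic-programming recursion (coefficients of
  ∏_{k=1..n} (1 + x^k)) for up to 25 pairs and cached per n, which lets
  the ~10^5 tests of a full screen run vectorised in well under a second;
  beyond 25 pairs a normal approximation with tie correction is used.
  Exact zeros are dropped before ranking (Wilcoxon's treatment); ties in
  |ratio| produce half-integer W, which is mapped onto the integer grid
  conservatively (floor for the lower tail, ceiling for the upper). The
  implementation is tested against full 2^n sign enumeration and against
  scipy's exact method.
* **Change call**: *increased* iff FC > threshold (default 2) and
  p < alpha (default 0.05); *decreased* symmetrically with FC < 1/threshold.
  Whether the original change calls also gated on a p-margin is not
  documented; alpha is therefore configurable.
* **DEG criterion**: a gene is retained with direction AF-up when the
  fraction of all |AF|×|NP| pairs called increased reaches the consistency
  threshold (default 0.8); NP-up symmetric. FC mean ± SD are computed over
  all pairs, with NP-up genes reported on the NP/AF scale so both lists
  read FC > 1. When no probe-level replicates are available the change
  call rests on the FC margin alone and p is NaN.

Candidate tiers rank each direction by mean FC (ties broken by gene id),
drop a user-supplied exclusion list (standing in for the manual literature
triage of top-ranked genes), window to the top k (25 AF / 16 NP), and
filter: AF candidates need FC ≥ 24.4, median p < 0.05 and NP
detection% = 0; NP candidates need FC ≥ 3.0, NP detection% = 100 and mean
NP signal ≥ 2× the detection floor — the latter two operationalise
"stable signal detection", since no gene is exclusively expressed in NP.

The DEG counts of the original genome-wide screen (319 total, 267 AF-up,
52 NP-up) are not reproducible without the unreleased array data; the
screen is instead validated on synthetic matrices with planted truth
(recall and precision ≥ 0.9 at the default noise level; exact equality
with a brute-force pair-counting oracle at zero noise; null
false-positive rate ≤ 1%).

## Marker panel

Ranges are the plain (min, max) of the observed relative-expression values
among clear samples of the marker's own tissue, on the values as provided
(scale-agnostic); at least two values per marker are required. Calls:
NA if missing, ++ above the range, + inside it (boundaries inclusive),
− below it or exactly zero ("no expression").

Marker match = 100 × positives / non-NA calls, rounded half-up to integer
percent; ++ counts as positive and NA is excluded from the denominator —
both forced by the bundled call table (a 100% row containing ++ and NA,
and a 40% row with 2 positives of 5 available). Verdicts:

* **AF** iff every available AF marker is positive (match = 100) with at
  least `min_available` = 3 non-NA AF calls. An AF verdict does not
  require NP silence: one confirmed AF sample in the bundled table has NP
  match 40%.
* **NP** iff AF match = 0 and NP match ≥ `np_match_min` = 83 (i.e. at
  least 5 of 6 available). 83 is the unique integer threshold that
  reproduces the bundled table's 5/3/8 verdict split (it excludes the
  NP-origin sample at 50%); it is configurable.
* otherwise **undefined**.

## qPCR

Relative expression = E_t^(−Cq_t) / √(E_r1^(−Cq_r1) · E_r2^(−Cq_r2)), the
standard published equivalent of efficiency-corrected relative
quantification against two reference genes, computed in log space to
avoid underflow. Per-assay efficiencies are configurable in (1, 2.2]
(default 2.0 — the true assay efficiencies are not documented, so
efficiency-dependent results are property-tested, not value-matched).
Triplicates are aggregated by arithmetic Cq mean with no outlier
rejection. A target that never amplified is relative expression 0,
feeding the panel's − call; an undetected reference makes the sample
unquantifiable (error). The construction is invariant to reference order
and to global loading shifts (subtracting c cycles everywhere at E = 2).

AF-vs-NP group differences use the two-sided Mann-Whitney U test: exact
(scipy) when min(n) ≤ 10, total ≤ 25 and there are no cross-group ties —
verified against full labeling enumeration for all group sizes up to
(5, 5) — and the tie-corrected normal approximation otherwise. Reported U
is min(U_a, U_b). Significance tiers: * p < 0.05, ** p < 0.01.

## Synthetic data

The generators are pure functions of (config, seed) via numpy's PCG64.

**Score sheets** draw each sample's latent tier from a categorical mix
over {clear, unknown} × {mild, severe}; the default proportions
(0.46/0.13/0.16/0.25) mirror the observed cohort composition (59% clear,
38% severe under the inclusive rule). Item grades are drawn and then
minimally repaired so each tier provably realises its classes under the
default rules; tier semantics are defined with respect to `strict_gt3`.
Default cohort shape: 28 discs across 17 donors, ages 36–77, cervical
levels C3/4–C6/7, MRI grades 3–4.

**Expression matrices** default to 1,000 genes on 11 AF + 9 NP chips with
11 probes per set — the study's group sizes at a gene count that keeps a
full screen in seconds. Null genes share lognormal group means; AF-up
genes (default 50) are on/off: NP mean at half the detection floor, AF
mean = FC × NP mean with FC lognormal around median 10; NP-up genes
(default 20) are a shift: NP mean = FC × AF mean, FC lognormal around
median 4 (echoing the low NP-side fold-change ceiling), with the AF level
well above the floor so NP detection is stable. Planted folds are clipped
away from the FC-threshold boundary (≥ 4 AF-up, ≥ 2.5 NP-up) so the
planted truth is unambiguous at zero noise. Chip-level and probe-level
noise are multiplicative lognormal (σ = 0.25 each by default, both scaled
off together at σ = 0); probe affinities are probe-specific but shared
across chips, so they cancel in pairwise per-probe ratios exactly as
sequence-specific affinities do. The per-chip summary signal is a 10%
trimmed mean of the probes. Not emulated: PM/MM probe chemistry, spatial
chip artifacts, cross-hybridisation, or normalisation effects — passing
screen tests therefore demonstrates the screen's statistical logic, not
robustness to real array artifacts.

**Cq tables** place marker abundances (from the expression truth's marker
assignment: the first planted genes of each direction stand for the named
panel markers) on a realistic 15–35 cycle window relative to constant
reference abundances, add a per-sample loading offset (which the
normalisation must cancel) and N(0, σ_Cq) replicate noise (default
σ_Cq = 0.15, a typical replicate scatter), and leave AF-exclusive markers
undetected in NP samples. Cq values are written with 4 decimals, so
round-trips through the text format are exact only to that quantisation.

## Numerical choices

* Percentages for display round half-up (away from zero); internal values
  keep full precision.
* Ranking ties in candidate selection break lexicographically by gene id
  for deterministic output.
* Degenerate inputs are errors, not silent results: empty cohorts,
  constant vectors in correlation, groups of fewer than 3 in the U test,
  fewer than 5 probes per set, fewer than 2 range-fitting values,
  undetected references.
* The exact signed-rank null is only valid without ties in |ratio|;
  tie-induced half-integer W is resolved conservatively (see above) and,
  with continuous signals, occurs with probability zero.

## Known limitations

* The genome-wide DEG counts and the specific marker discovery of the
  original study cannot be reproduced: the underlying array data were
  never deposited. The screen's validation is entirely synthetic-truth
  based.
* The published correlation summary is partly inconsistent with the
  published per-sample data it summarises (three NP cells); the package
  sides with the per-sample data.
* The range classifier assumes relative-expression values comparable
  across samples; batch effects between fitting and test cohorts are not
  modelled.
* MRI grading and item grading are inputs produced by a human rater; no
  image analysis is attempted.
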