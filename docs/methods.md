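# Methods

## Problem and model

The pipeline screens per-sample CNV segment calls from a multi-panel
case-control study for rare deletions/duplications over-represented in
cases, then quantifies association by carriership. The underlying model is
deliberately simple: each individual either carries at least one CNV
overlapping a candidate region or does not, carriership is independent
across individuals (related samples are assumed removed upstream), and the
per-panel data reduce to 2×2 tables of carrier/non-carrier × case/control.
All inference is exact and conditional on the table margins; no
dosage/trend modelling is attempted because rare CNV carriers are almost
always single-copy gains or losses.

## Coordinates and sizes

Everything in memory and in reports is 1-based inclusive; BED input
(0-based half-open) is converted on read and the conversion is its own
inverse. A segment's length is `end − start + 1`. Reported kb sizes are
rounded to one decimal below 100 kb and to the nearest integer at or above
100 kb, which reproduces the conventional "15.8 kb / 119 kb / 134 kb"
style of reporting. Whether a printed breakpoint pair is end-inclusive is
usually unknowable from a publication; both conventions round to the same
kb values at these sizes, so the inclusive choice is a documented
convention, not an inference.

## Sample QC

* **Array metrics** — fail iff MAPD > 0.4 or contrastQC < 0.4, strict
  inequalities (a sample sitting exactly at a threshold passes). Samples
  without metrics pass with a logged warning: the rule is a veto, not an
  imputation. Negative MAPD is a validation error.
* **Batch call-count fence** — within each batch, T = Q75 + 1.5·(Q75 − Q25)
  of per-sample call counts; strictly greater counts are flagged.
  Quantiles use linear interpolation between order statistics (the common
  default in mainstream statistical environments; the estimator is
  configurable and echoed in the report). "Batch" is the phenotype file's
  batch column, defaulting to one batch per panel. The fence is computed
  once from all samples, so flagging is order-independent; reports carry
  the per-batch thresholds so a re-screen can freeze them (idempotence).
  The fence is only meaningful when per-sample counts sit well away from
  zero — with counts concentrated at 0 the fence degenerates to T = 0 and
  flags any sample with a single call. The pipeline therefore exposes
  per-stage toggles (`batch_outlier_qc`, `array_metric_qc`), and noise-free
  simulation experiments run with the fence off.
* **qPCR replicates** — discard iff confidence < 0.95, z-score ≥ 2.65
  (inclusive), or fewer than 3 of 4 technical replicates are valid. The
  z-score's reference population (plate, assay, batch) is the caller's
  responsibility; the filter consumes it as given.

## Call and region filters

* **Probe support** — keep a call iff ≥ 5 supporting probes *and* mean
  inter-probe spacing ≤ 1 kb, where spacing = (span between first and last
  probe)/(n − 1) over probes inside the call. The spacing clause removes
  sparse, low-confidence calls; it can be disabled
  (`spacing_rule=False`) because some call sets are pre-filtered upstream.
  When a probe track is supplied, probe counts are recomputed from it and
  override the record; a call on a chromosome absent from the track drops
  with a "no probes" diagnostic.
* **Gap span** — drop a region iff assembly-gap bp inside it strictly
  exceed non-gap bp (a gap of exactly half keeps).
* **Common CNVs** — drop a region iff any known common CNV has reciprocal
  overlap ≥ 0.5 with it (`min(shared/|A|, shared/|B|)`); the threshold is
  configurable and recorded, since published screens typically did this
  step by eye with no stated cutoff. Type-labelled common intervals only
  match regions of the same type.
* **Region probe count** — drop a region with < 10 probes across its full
  span. Counting across the span (rather than a shared core) is the
  documented choice.

These filters are pure functions of independent inputs, so they commute;
each emits a verdict row naming the rule and the diagnostic values, making
every exclusion traceable.

## Screening

Same-type calls on the same chromosome that share ≥ 1 bp are merged
transitively (single linkage) into candidate regions whose span is the
union of members. Single linkage is used because screening merges events
into genomic segments without a similarity threshold; a reciprocal-overlap
clustering would need a parameter no published rule supplies. Carriers are
distinct samples with any overlapping member call (a `min_carrier_overlap`
fraction of the call length is available, default 0). Selection: (≥ 3 case
carriers, 0 controls) or (≥ 5 case carriers, exactly 1 control); > 2
controls always excludes. Exactly 2 control carriers fall between the
published clauses; the gap is resolved conservatively as *not selected*
with its own reason code, so the case is auditable.

## Association

The two-sided Fisher exact p-value uses the minimum-likelihood convention:
with margins fixed, sum the probabilities of all tables whose probability
does not exceed the observed table's. It is computed in exact integer
arithmetic — binomial weights C(n₁,a′)·C(n₂,m₁−a′) compared and summed over
a common denominator C(N,m₁) — so tied tables (e.g. the mirror table of a
symmetric margin set) are included exactly, with no floating-point
tolerance. The suite cross-checks against both a factorial/rational
brute-force enumeration (exhaustively for all tables with N ≤ 60) and
scipy's implementation.

Odds ratios are unconditional sample ORs ad/bc (this is the estimator that
reproduces published values such as 8.71 from 5/897 vs 1/1563); OR = +∞
exactly when there are case carriers but no control carriers, undefined
when both carrier cells are zero. The 95% CI uses the Woolf log-OR normal
approximation, with Haldane–Anscombe +0.5 on all cells only when some cell
is zero, which yields the familiar finite-lower-bound "(x – Inf)" interval
for infinite point estimates. Bonferroni correction is min(1, m·p) with m
defaulting to the number of regions carried into follow-up.

Cross-panel combination offers two labelled stand-ins: `pooled_fisher`
(exact test on the element-wise pooled table; ignores stratification) and
`stratified_permutation` (phenotype labels permuted within each panel,
statistic = total case carriers, p = (1 + #{permuted ≥ observed})/(1 + B);
within a panel a label permutation makes the permuted count hypergeometric,
which is how it is sampled, so the test is exact-in-distribution and
one-sided toward enrichment). The published mega-analysis combination
(M.A.R.V.) is defined outside this codebase and is **not** re-implemented;
every combined output is labelled with the method that produced it.
Consistent with that, the published *combined* p-values and ORs are not
reproduction targets here — the pooled-table Fisher test gives different
(typically smaller) values, as the analysis driver shows.

## Breakpoint interpretation

* **Shared motif scan** — all maximal k-mers (4 ≤ k ≤ 20) occurring within
  a 50 bp window ending at each breakpoint; a k-mer is suppressed only if
  it lies inside a longer shared k-mer at the same relative offset. N never
  matches.
* **Microhomology** — the longest common prefix of the sequences beginning
  at `del_start` and `del_end + 1` (the bases assignable to either side of
  the junction in the deleted allele), capped at 100 bp.
* **Flanking-repeat homology** — banded ungapped comparison of the two
  flanks: exact 12-mer seeds select diagonals; on each diagonal the
  maximal-scoring segment (match +1, mismatch −3) is taken and trimmed to
  matching ends, which confines the hit to the homologous core instead of
  letting a running-identity criterion drift into unrelated sequence. A
  repeat-annotation BED can bypass this search when annotation is
  available.
* **Classification** — NAHR iff a flank-to-flank homologous segment of
  ≥ 100 bp at ≥ 85% identity exists (near-identical flanking repeats, the
  Alu-mediated signature); else MMEJ iff microhomology 2–10 bp; else NHEJ
  iff ≤ 1 bp; else UNCLASSIFIED. These thresholds follow common
  rearrangement-mechanism conventions; published screens assert NAHR
  qualitatively, so the thresholds are explicit configuration echoed in
  every report, not claims.

## Synthetic cohorts

The generator's defaults are the emulated study conditions: six panels at
the study's post-QC sizes (discovery 902/1564; German qPCR replication
453/1377; UK 2394/4886; Norwegian 252/272; Lithuanian 445/1140; an
in-silico control-only set of 4505) and three planted risk CNVs sized like
the three replicated events (15,761 bp DEL, 118,888 bp DUP, 133,901 bp DUP)
at the published combined carrier frequencies (0.43%/0.11%, 0.13%/0.01%,
0.22%/0.03% in cases/controls). Carriership is independent Bernoulli per
sample. Chromosomes are short synthetic coordinate spaces (a few Mb);
nothing downstream depends on real genome size.

Noise components, with defaults chosen once as realistic array-CNV
conditions where no published value exists:

* **Probe grid** — regular 500 bp spacing, a round figure at the dense end
  of genome-wide copy-number probe spacing, which lets planted regions pass
  the ≤ 1 kb spacing and ≥ 10 probe rules as real calls at these loci would.
* **Boundary jitter** — sd 2 kb per breakpoint, i.e. a few probes of
  uncertainty, rounded to the nearest probe position because array
  resolution quantizes boundaries.
* **Passengers** — 3 expected background calls per sample, recurring at 40
  background loci placed ≥ 200 kb from planted intervals. Modelling the
  background as recurrent polymorphic loci (rather than uniform placement)
  keeps per-sample call counts realistic — so the batch fence has a
  sensible distribution to work on — without flooding the small simulated
  space and contaminating planted regions with coincidental carriers.
* **False positives** — 0.2 per sample, uniformly placed, 2–4 supporting
  probes, so the probe-support filter removes them.
* **Outliers** — 1% of samples receive ~30–50 extra background calls,
  placing them far above any batch fence.

What the generator does **not** emulate: probe-level intensities (log-R /
B-allele traces) and hence the manual raw-data inspection step of real
screens; platform-specific sensitivity differences between array and qPCR
panels (qPCR-panel calls carry probe support from the same synthetic grid);
linkage between variants; population structure within a panel. Passing
tests therefore demonstrate the correctness of the screening/statistics
machinery under the stated sampling model, not the calling accuracy of any
upstream CNV caller on real intensity data.

The junction generator plants, on demand: a motif immediately 5′ of both
breakpoints (with a forced mismatch just before each copy, so motif scans
report exactly the planted string), a microhomology as a shared prefix of
the deleted segment and the right flank (with a forced mismatch at the next
base), and a repeat copied into both flanks and mutated to a target
identity by substituting exactly ⌊(1 − identity)·L⌋ positions.

## Determinism, problem sizes and numerical choices

Every stochastic component takes an explicit seed (numpy `default_rng`);
identical config + seed reproduces outputs byte for byte, including
pipeline run directories. The test and acceptance workloads use desk-scale
problem sizes chosen to exercise each claim: exhaustive Fisher-oracle
equivalence over all 635,375 tables with N ≤ 60; screening recovery on a
noise-free 1000-case/1500-control panel with three planted CNVs at 1%/0%;
frequency recovery over 200 seeds at the combined-study scale (4445 cases,
13635 controls); null calibration over 400 exact-test replicates and 200
stratified-permutation replicates at 499 permutations. Permutation p-values
use the add-one estimator (1 + #{≥ obs})/(1 + B), which is valid (never
anti-conservative) at any B; the CLI refuses B < 100 as meaningless.

## Known limitations

* The genome-wide discovery counts of a real study (how many regions
  survive screening and inspection) depend on raw intensity data and manual
  review, and are out of scope; the automated common-CNV/gap/probe filters
  are the documented stand-in for manual inspection.
* The 2-control screening case and the probe-spacing clause are resolved by
  documented choices (see above) because the published rules are ambiguous;
  both are configurable.
* The stratified permutation combination is one-sided toward case
  enrichment and is not a depletion test.
* Flanking-repeat detection is ungapped; diverged repeats with indels will
  be reported as shorter segments, biasing against NAHR calls near the
  length threshold.
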