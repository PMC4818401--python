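# rarecnv

A tested pipeline for **rare copy-number-variant (CNV) case-control
screening**, of the kind used to hunt rare deletions and duplications that
are over-represented in patients with a complex disease (the motivating
application is a multi-panel ulcerative-colitis cohort). It covers the full
desk-side analysis chain downstream of CNV calling:

1. **Sample QC** — array noise-metric thresholds (fail iff MAPD > 0.4 or
   contrastQC < 0.4), batch-wise call-count outlier removal with the Tukey
   upper fence *T* = Q75 + 1.5·(Q75 − Q25), and qPCR replicate QC
   (discard iff confidence < 95%, *z* ≥ 2.65, or < 3 of 4 replicates).
2. **Call/region filters** — probe support (≥ 5 probes, mean spacing
   ≤ 1 kb), assembly-gap span, known-common-CNV reciprocal overlap
   (default ≥ 0.5 drops), and a ≥ 10-probes-per-region rule.
3. **Screening** — single-linkage clustering of overlapping same-type calls
   into candidate regions; a region is selected when it has ≥ 3 case
   carriers and 0 control carriers, or ≥ 5 case carriers and exactly 1
   control carrier; ≥ 2 control carriers always exclude it.
4. **Association** — per-panel 2×2 carriership tables
   (carrier/non-carrier × case/control), two-sided Fisher exact *p*-values
   computed in exact integer arithmetic (minimum-likelihood convention),
   sample odds ratios *ad/bc* with Woolf CIs, pooled tables, Bonferroni
   correction, and a clearly labelled panel-stratified permutation
   combination.
5. **Breakpoint interpretation** — event sizes, shared junction motifs,
   junction microhomology, flanking-repeat homology, and a
   NAHR / MMEJ / NHEJ mechanism classification.
6. **Cohort simulation** — a generator of multi-panel case-control cohorts
   with planted risk CNVs at phenotype-specific carrier frequencies,
   recurrent background CNVs, boundary jitter quantized to probe positions,
   low-probe false positives, outlier samples, and a ground-truth table, so
   every stage is testable end to end without external data.

Coordinates are 1-based inclusive throughout (BED input is converted on
read); a segment's length is `end − start + 1`.

## Layout

- `src/rarecnv/` — the library: `io`, `simulate`, `sample_qc`,
  `call_filters`, `region_screen`, `association`, `breakpoints`,
  `pipeline`, `cli`.
- `analysis/` — numbered drivers that run the analyses and write their
  tables under `results/`:
  `01_published_table_statistics.py`, `02_simulate_cohort.py`,
  `03_screen_and_associate.py`, `04_breakpoint_mechanisms.py`.
- `rarecnv` console script — subcommands `simulate`, `qc`, `filter`,
  `screen`, `assoc`, `breakpoint`, `run`, `report`.

## Worked example

Recomputing the association statistics for the published carrier tables
(5/897 case carriers/non-carriers vs 1/1563 controls in the discovery panel
for the 13q32.1 deletion, and so on):

```bash
$ python analysis/01_published_table_statistics.py
Del13q32.1   discovery            P = 0.027  OR = 8.71 (1.02-74.69)
Del13q32.1   german_replication   P = 0.005  OR = 8.58 (1.72-42.64)
Del13q32.1   pooled               P = 0.0004957  OR = 7.75
Del13q32.1   combined case carriers: 19/4445 = 0.43%
Dup8q24.3    discovery            P = 0.018  OR = Inf (0.84-Inf)
Dup8q24.3    combined case carriers: 10/4448 = 0.22%
```

`P = 0.027` is the exact two-sided probability of a carrier table at least
as unlikely as the observed one under fixed margins; `OR = 8.71` is the
sample odds ratio (5×1563)/(897×1); an infinite OR means no control
carriers were observed. `0.43%` is the pooled case-carrier frequency 19/4445.

Simulation and screening end to end (a rare planted duplication realizes
3 discovery case carriers and 0 controls, so it clears the screening rule;
the other two planted CNVs realize too few discovery carriers — the normal
fate of rare variants in a finite discovery panel):

```bash
$ python analysis/03_screen_and_associate.py --seed 11
planted risk CNVs and their realized discovery carrier counts:
  sim1:1000000-1015760:DEL: 1 cases / 2 controls in discovery -> below the screening rule
  sim2:2000000-2118887:DUP: 3 cases / 0 controls in discovery -> eligible
  sim3:3000000-3133900:DUP: 1 cases / 0 controls in discovery -> below the screening rule

40 candidate regions built, 1 selected

== DUP sim2:1,999,500-2,121,500 (122,001 bp) ==
   selected: cases>=3,controls=0
panel                    cases cc/N     freq   ctrls cc/N     freq          P       OR
discovery                     3/875    0.34%       0/1513    0.00%     0.0491      Inf
...
combined                     8/4316    0.19%      1/13354    0.01%   8.89e-05    24.80
combined (stratified_permutation) p = 0.0007   Bonferroni (m=1): 0.0007
```

Junction interpretation of a synthetic 15,761 bp deletion fixture with a
planted GATCAC motif at both breakpoints and 300 bp flanking repeats at 90%
identity:

```bash
$ python analysis/04_breakpoint_mechanisms.py
nahr_like_del15.8kb: 15,761 bp (15.8 kb), microhomology 0 bp, repeat 293 bp @ 91%,
    top shared motifs ['GATCAC', ...] -> NAHR
mmej_like_del15.8kb: ... microhomology 5 bp ... -> MMEJ
nhej_like_del15.8kb: ... microhomology 0 bp ... -> NHEJ
```

## What this package does not do

It consumes already-called CNV segments: there is no CEL/intensity parsing,
no array normalization, no computation of MAPD/contrastQC, and no
genotype-dosage association (carriership only). The published study-wide
combination method (M.A.R.V.) is external to this codebase; the pooled
Fisher and stratified-permutation combinations provided here are labelled
stand-ins, never presented as M.A.R.V. values. See `docs/methods.md` for
the model, parameter defaults and known limitations.
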