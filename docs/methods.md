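# Methods

This note documents the models behind `homeoscan`: what is simulated, how
each inference stage works, which parameters matter, and where the design
was genuinely open.

## The biological model

The organism is an allotetraploid (AABB). Genotype state is tracked per
*chromosome set* — a homeologous A/B chromosome pair — as a pair of copy
numbers `(a, b)` with euploid value (2, 2). The events of interest replace
`(2, 2)` over an interval by:

| state | (a, b) | mechanism |
| --- | --- | --- |
| ABBB / AAAB | (1,3) / (3,1) | homeologous exchange |
| AAAA / BBBB | (4,0) / (0,4) | tetrasomy via homeologous exchange |
| B-deletion / A-deletion | (2,0) / (0,2) | terminal breakage (one homeolog pair lost) |
| trisomy A / B | (3,2) / (2,3) | supernumerary chromosome |

Events arise in one plant and, when heritable, propagate to every
descendant in a single-seed-descent pedigree; a transient event appears in
one plant only. Some terminal regions are unbalanced in *every* plant
(ancestral, fixed in the reference line); they are background, not
instability.

## Synthetic cohort

`generate_pedigree` reproduces the study layout: one founder, six
generation-1 seeds split 3/3 across two greenhouses, a six-way expansion at
generation 2, then single-seed descent with gradual lineage loss
(survivor counts 36, 34, 33, 32, 24 at generations 3–7) and two
generation-6 plants expanded to 16 progeny each — 233 plants in total.
Only the total (233), the generation-1 layout and the expansion are fixed
by the emulated design; the intermediate survivor counts are a consistent
choice. Lineages containing the canonical event/expansion plants are
protected from simulated loss so the scenario is reproducible by label.

`simulate_array` renders, per (marker, sample) cell, the A-signal fraction
θ and a total intensity. θ is a **censored** normal: `clip(N(a/(a+b), σ_θ),
0, 1)` — clipping, not renormalized truncation, because real signal
fractions pile up at the rails; intensity is `N((a+b)/4, cv·(a+b)/4)`
clipped positive. Markers carry a random orientation (a `B_high` marker's
raw score counts B alleles); control samples follow their known
compositions (diploid parents at (4,0)/(0,4); 1:1, 3:1, 1:3 mixtures at
(2,2), (3,1), (1,3)); generation-1 plants are duplicated as replicate
pairs.

Noise defaults (the assay's error structure is unpublished; these are
calibration choices, all exposed in config):

| parameter | default | rationale |
| --- | --- | --- |
| θ standard deviation | 0.03 | per-cell mis-score probability ≈ 3·10⁻⁵, consistent with confidence-filtered calls |
| intensity CV | 0.05 | keeps euploid cells far from the 0.7 deletion-flag threshold |
| per-cell mis-score | 2·10⁻⁴ | sized so the control/replicate quality rules retain ≥ 99% of clean markers |
| bad-marker fraction | 0.02 | whole-marker failures for the cascade to remove |
| missing-call rate | 5·10⁻⁴ | with 233+ samples the complete-scoring filter retains (1−r)^n of markers; r must be small for a usable panel |
| B-oriented fraction | 0.4 | arbitrary mix of probe orientations |

A config switch (`deletion_miscall`, on by default) reproduces the array's
observed behavior on single-homeolog deletions: a (2,0) region renders at
the 3:1 θ expectation (an apparent AAAB run) while intensity still halves,
so only the low-intensity flag betrays the deletion until sequencing
resolves it. Whole-marker failures are simulated by giving the marker a
single wrong composition's θ for *every* sample — such markers show uniform
controls but zero parent separation, which is exactly what the control
filter removes.

`simulate_wgs` draws, per diagnostic site, a total depth
`Poisson(depth·(a+b)/4)` thinned `Binomial(total, a/(a+b))` into A and B
reads, and always includes a synthetic-tetraploid baseline sample (euploid
at every site). Default depth 30 matches the emulated sequencing design.

What the generator does **not** emulate: probe-level chemistry and
normalization artifacts, mapping bias at diagnostic sites, segmental
(sub-interval) noise correlation, and real marker spacing (ten 10-Mb sets
at 140 markers/set stand in for the genome). Passing tests therefore
demonstrate correctness of the inference rules under the stated statistical
model, not robustness to array chemistry.

## Dosage calling

The default caller assigns each cell the score with the nearest θ
expectation (equivalently fixed bins with edges at 0.125, 0.375, 0.625,
0.875). Exact-edge ties break toward the euploid score 2, which keeps the
caller exactly symmetric under subgenome relabeling (θ → 1−θ, s → 4−s). An
optional per-marker five-component Gaussian-mixture caller (means
initialized at the expectations) provides posterior confidences; calls
below the confidence minimum (default 0.95) become missing. Cells with
intensity < 0.7 are flagged deletion-consistent; deletions are *not* called
at this stage — the flag travels with the call and is resolved against WGS.

At θ-sd 0.05 the fixed-bin caller's accuracy on an equal mix of the five
classes has the closed form `(3(2Φ(2.5)−1) + 2Φ(2.5))/5 ≈ 0.9901`
(interior classes err two-sided, censored edge classes one-sided); the test
suite verifies the Monte-Carlo estimate against this form.

## Filter cascade

Stages apply in order, and the report telescopes (each stage's output count
is the next stage's input count):

1. **complete scoring** — no missing cell among lineage samples;
2. **control consistency** — uniform values within each control group,
   parent separation ≥ 2 score units, 3:1 ≠ 1:3 mixtures, 1:1 modal = 2;
3. **replicate concordance** — every duplicated pair equal (missing counts
   as discordant);
4. **modal rule** — lineage modal score 2, or membership in a positional
   run of ≥ 2 markers deviating in the same *subgenome* direction.
   Direction is judged in A-counting space (using the parent controls to
   mirror B-oriented markers): raw scores alternate 0/4 across a real
   unbalanced region covered by mixed-orientation markers, while the
   subgenome direction is coherent;
5. **orientation** — markers flipped (s → 4−s) where the A-parent modal is
   below the B-parent modal; equal parent modals are unorientable and
   dropped.

Modal ties break toward 2, then toward the value nearest 2 — conservative
toward the euploid null. Two sample-level exclusions are supported: an
explicit array-QC failure list, and a scattered-noise rule that drops
samples whose fraction of *isolated* non-modal cells (deviations that are
part of no ≥ 2-marker same-direction positional run) exceeds
mean + 4 sd across samples. Counting only isolated deviations means a
genuine multi-marker event never penalizes its carrier; the threshold form
follows the quantile-style rule the design left open, since no number is
published.

## Event detection and rates

Per plant and chromosome set, maximal runs of ≥ `min_run` (default 2)
consecutive markers sharing one non-2 score become calls (1 → ABBB,
3 → AAAB, 0 → BBBB, 4 → AAAA), spanning first to last marker position,
half-open. A run with ≥ 50% low-intensity flags becomes
`DELETION_CANDIDATE` whatever its apparent score, covering both the honest
(2,0) → score-4 rendering and the miscalled score-3 rendering.

Background separation supports two modes: prevalence (a call overlapping
same-composition calls in > 50% of plants is ancestral) or an explicit
reference profile. Candidates are resolved against the pedigree by an
ancestor walk: a candidate matching an ancestor's overlapping
same-composition candidate is `inherited`, otherwise `novel` — one
independent origin. Matching is at any-overlap, same-chromosome-set
resolution. The rate is `100·origins/plants` rounded half away from zero to
one decimal; the denominator is the full cohort (233), matching the
convention that the rate is quoted per plant grown, not per plant retained
in the final matrix.

## WGS window dosage

Per sample, each usable site (baseline counts > 0 on both alleles) gets
`u_x = 2·raw_x/baseline_x`; a single per-sample scalar `s = 2/median((u_a+u_b)/2)`
fixes the genome-wide median at the euploid value, so uniform depth
rescaling cancels exactly. Windows (default 1 Mb) with ≥ 20 sites are
assigned the composition whose expected pair is nearest to the window's
medians in Chebyshev distance, within 0.35 copies; otherwise
`UNCLASSIFIED`. Medians rather than means are used as window centers for
robustness; note the per-site ratio estimator has a known O(1/depth)
upward bias in its *mean* (~1% at depth 200), which the median-based
classifier does not inherit at any practically relevant magnitude. Window
size, minimum site count and tolerance are design choices sized so that
30× depth puts the window-level standard error well under the tolerance;
the per-site-then-scalar normalization is one consistent realization of a
baseline normalization whose exact estimator was an open choice. Trisomy
pairs (3,2)/(2,3) are in the match set because supernumerary-chromosome
configurations occur in re-analyzed populations.

Reconciliation lets overlapping classified windows vote (majority): equal
compositions confirm the array call; an `AA_DELETION` majority under an
AAAB/AAAA/`DELETION_CANDIDATE` array run relabels it `DELETION_B` (and
mirror-image for `BB_DELETION`); anything else is recorded as a conflict
with the array label kept.

## Numerical and degenerate-input choices

- One integer seed drives every run; named sub-streams are derived through
  `SeedSequence` so stages are independently reproducible.
- All-missing markers are emitted as all-missing, not errors; non-finite
  (infinite) signals and inconsistent θ/intensity missingness are errors.
- Zero-noise parameters are valid (they define the exact-recovery
  conditions); negative noise parameters are errors.
- A constant genotype matrix yields an all-zero PCA, not a crash; PCA is
  reporting only.
- Tabular outputs use fixed float formats, making repeated runs
  byte-identical for a fixed config and seed.

## Problem sizes used by the test suite

The default verification cohort is the full 233-plant design with ~1400
markers (seconds per replicate); the noisy-cohort sensitivity check runs 20
seeded replicates; WGS checks use 2000 diagnostic sites per 10-Mb set at
depth 30. These sizes make the suite's statistical assertions (3-SE bands,
≥ 95% sensitivity, ≥ 99% window agreement) well-powered while keeping a
full run under a minute apart from the replicate scan.

## Known limitations

- The array model is statistical, not chemical; systematic probe effects
  (GC bias, cross-hybridization) are out of scope.
- Inheritance tracing assumes every plant is genotyped; with gaps in the
  pedigree's genotyping an origin may be assigned one generation late
  (the ancestor walk keeps it a single origin).
- The prevalence rule for background assumes background regions are shared
  by a majority; a background region segregating in half the cohort would
  need the reference-profile mode.
- Window classification near event boundaries mixes two compositions
  within one window; such windows may be `UNCLASSIFIED` and are excluded
  from voting rather than guessed.
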