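# homeoscan

Detection of spontaneous large-scale chromosomal instability in a selfed
allotetraploid lineage, from tetraploid SNP-array dosage data and from
whole-genome-sequencing allele depths.

## The problem

Cultivated peanut (*Arachis hypogaea*) is an allotetraploid, AABB: two
near-complete diploid chromosome complements, the A-subgenome from
*A. duranensis* and the B-subgenome from *A. ipaënsis*, paired as ten
homeologous *chromosome sets* (A01+B01 = set 01, and so on). Although the
crop is usually considered genetically stable, occasional recombination
between the subgenomes (homeologous exchange) and chromosome breakage still
occur. In a pedigree-controlled experiment — a single highly selfed plant
advanced seven generations by single-seed descent in pollinator-free
greenhouses — these events can be detected, placed on the pedigree, and
counted: regions that switch from the balanced AABB state to ABBB, AAAB,
AAAA or BBBB, and terminal deletions that leave only one subgenome's pair
(AA-- or --BB).

`homeoscan` implements that detection pipeline end to end for researchers
working on polyploid genome stability:

1. **Dosage calling** — per marker and sample, the array's A-allele signal
   fraction θ is scored on the tetraploid scale 0–4 (expected θ = 0, ¼, ½,
   ¾, 1 for 0–4 copies of the counted allele); total intensity below 0.7 of
   the euploid expectation flags a possible lost homeolog pair.
2. **Marker filtering** — the quality cascade: complete scoring across the
   cohort; consistent control behavior (diploid A- and B-genome parents at
   least two score units apart, 1:1 / 3:1 / 1:3 DNA mixtures scoring as
   AABB / AAAB / ABBB); concordant duplicated samples; and the modal rule —
   a marker is kept if its cohort modal score is 2 or if at least two
   consecutive markers deviate toward the same subgenome. Scores are then
   oriented so that they always count A-subgenome alleles
   (BBBB = 0 … AAAA = 4).
3. **Event detection** — maximal positional runs of ≥ 2 markers with the
   same non-2 score become composition calls; cohort-wide calls are
   ancestral background; the rest are traced through the pedigree so each
   independent origin is counted once (descendants inherit, transient
   events still count once). The instability rate is
   100 · origins / plants, rounded half away from zero to one decimal.
4. **WGS window dosage** — allele depths at A/B-diagnostic sites are
   normalized against a synthetic-tetraploid 1:1 baseline
   (norm = 2·s·raw/baseline, with s fixing the genome-wide median at the
   euploid value 2), aggregated into 1-Mb windows, and each window's median
   (norm_A, norm_B) is matched to the nearest expected composition —
   including (2,0)/(0,2) single-homeolog deletions and (3,2)/(2,3)
   trisomies. Window calls arbitrate the array calls, resolving the array's
   blind spot where a terminal deletion is rendered as an AAAB run.
5. **Synthetic cohorts** — a first-class generator reproduces the study
   design (233 plants over seven generations, controls, duplicated
   generation-1 samples, implanted truth events, binomial read sampling),
   so every stage is testable against a known truth ledger without any
   external data.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort; each step writes its tables under `results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_genotype_and_filter.py
python analysis/03_detect_events.py
python analysis/04_wgs_confirmation.py
python analysis/05_rates_summary.py
```

Step 03 prints the origin ledger and the rate:

```
independent novel origins:
  T.3.3.1.1_G1: DELETION_CANDIDATE on chromosome set 01 [35,714-2,892,858), 38 markers
  T.3.5.1.1.1.1_G2: ABBB on chromosome set 05 [35,714-9,964,286), 118 markers
  T.3.3.1.1.1.1.11_G1: ABBB on chromosome set 02 [35,714-9,964,286), 120 markers
rate: 3/233 plants = 1.3%
```

Reading: three independent instability origins were detected among 233
plants — a terminal deletion candidate first seen in the generation-4 plant
`T.3.3.1.1_G1` and inherited by its descendants, a transient whole-set ABBB
in a generation-6 plant, and a whole-set ABBB in a generation-7 plant —
giving an instability rate of 1.3% of plants. Step 04 then shows the WGS
arbitration: the chromosome-set-01 region the array scored as a flagged
AAAB-like run is relabeled as a true B-homeolog terminal deletion
(`DELETION_B`) in all three sequenced carriers, while both ABBB calls are
confirmed:

```
              plant  chrom_set  array_composition wgs_composition final_composition   verdict
T.3.3.1.1.1.1.11_G1          1 DELETION_CANDIDATE     AA_DELETION        DELETION_B relabeled
T.3.3.1.1.1.1.11_G1          2               ABBB            ABBB              ABBB confirmed
...
```

The same pipeline is available as a library (`import homeoscan`) and as a
CLI (`homeoscan simulate | call-dosage | filter | detect | wgs-dose |
reconcile | run-all`, each taking `--config`, `--seed`, `--out`).

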