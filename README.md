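# tetrascope

Tetrad-based mapping of meiotic recombination in yeast.

When a heterozygous diploid such as the *S. cerevisiae* isolate EM93 goes
through meiosis, all four products of each meiosis can be recovered together
as a tetrad and genotyped at thousands of heterozygous markers.  Every
marker then segregates 2:2 unless a gene conversion copied one allele over
the other (3:1 or 1:3), and every pair of adjacent 2:2 markers falls into
one of three tetrad classes — parental ditype (PD), tetratype (TT,  ≥1
crossover) or non-parental ditype (NPD, ≥2 crossovers).  From these
patterns, `tetrascope` reconstructs:

- **crossovers (COs)** with their minimum multiplicities (TT → 1, NPD → 2),
- **gene-conversion tracts**, split into crossover-associated (COAGC) and
  non-crossover (NCOGC) conversions by the tetrad class of their flanking
  markers,
- genome-wide **rates** with a coverage adjustment for unmarkered genome
  (`count × (1 + uncovered fraction)`), and the per-chromosome linear rate
  law `events/meiosis = a + b·Mb` fitted across the 16 chromosomes,
- **hotspots**: intervals with ≥2-fold more events than the homogeneous
  expectation (6.5 CO and 2.6 NCOGC per Mb per meiosis), merged over
  contiguous intervals; plus centromeric coldspot statistics,
- **crossover interference**: Fisher exact tests on adjacent ~50-kb bins,
- **map distances** via the Perkins formula
  `cM = 100 (3·NPD + TT/2) / n` and kb/cM,
- **conversion parity**: exact binomial tests of the 1:3 vs 3:1 balance at
  the most frequently converted polymorphisms, and their association with
  large sequence polymorphisms (LSPs),
- **LSP effects**: recombination suppression adjacent to heterozygous
  non-sub-telomeric LSPs, hotspot spacing across LSPs, and sub-telomeric
  comparisons.

Because the original microarray data cannot be regenerated, the package
ships a first-class meiosis simulator (`tetrascope.meiosis_sim`) that
produces tetrad genotype matrices and ground-truth event logs under the
study's conditions: Poisson event counts linear in chromosome length
(0.6 + 6.5·Mb COs, 0.04 + 2.6·Mb NCOGCs per meiosis), an obligate
crossover per chromosome, gamma-renewal crossover interference, centromeric
and LSP-local suppression, geometric conversion tracts with a parity
parameter, and two-cluster probe intensities with ~30-fold separation.

## Worked example

The numbered scripts under `analysis/` run the full pipeline on a simulated
120-tetrad cohort (outputs under `results/`):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_call_events.py
```

which prints:

```
genome: 2949 markers on 16 chromosomes, covered fraction 0.768
simulated 120 tetrads (seed 1): 10597 true COs, 3848 true conversion tracts
intensity round-trip on 3 tetrads: 0 miscalls, 2949/2949 markers pass QC
tetrads analysed: 120
detected COs: 8135
detected GCs: 1484 (98 COAGC + 1386 NCOGC)
uncovered genome fraction: 0.23
coverage-adjusted COs: 10021 (83.5 per meiosis)
eventless chromosome copies: 5 of 1920 (0.26%)
```

Reading the output: the marker map covers 77% of the genome, so of ~10,600
true crossovers only ~8,100 are detectable (the detected/true ratio tracks
the covered fraction), and multiplying back by 1.23 recovers ~84 crossovers
per meiosis.  Conversion tracts average 2 kb against a ~3-kb marker
spacing, so the detected NCOGC count is a minimum estimate.  Only 5 of the
1,920 chromosome copies show no detectable event, consistent with an
obligate crossover per chromosome.  The remaining scripts
(`03_recombination_landscape.py` … `06_lsp_effects.py`) produce the
hotspot/coldspot maps, interference scans, parity report and LSP analyses.

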