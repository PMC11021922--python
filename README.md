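# refugia

Population-genetic analysis of a coastally distributed seabird-style
sampling design: descriptive structure statistics for mitochondrial and
nuclear data, plus a structured-coalescent simulator and approximate
Bayesian computation (ABC) engine that compares three Pleistocene-refugium
demographic scenarios.

## What's inside

- `refugia.popgen` — observed-data statistics: haplotype collapsing,
  haplotype/nucleotide diversity, gamma-corrected Kimura-2-parameter
  distances, AMOVA Φ_ST / multilocus diploid F_ST with permutation tests,
  Ewens–Watterson and Chakraborty neutrality tests (conditional
  Ewens-sampling-formula simulation), Mantel isolation-by-distance tests
  on Slatkin-linearized F_ST vs log great-circle distance, and
  Benjamini–Yekutieli thresholds.
- `refugia.scenarios` — structured-coalescent simulation of three refugial
  histories (deep Aleutian split; single southern refugium with stepwise
  northward colonization; two refugia with secondary contact), uniform
  priors, and HKY+I+G sequence evolution (defaults: μ = 6.5×10⁻⁷/site/gen,
  I = 0.796, gamma shape = 0.733, 723 bp).
- `refugia.inference` — the 39-statistic DIYABC-style summary vector
  (8 single-sample stats × 3 regions + 5 two-sample stats × 3 pairs),
  reference-table construction, rejection + Epanechnikov-weighted
  multinomial-logistic model choice, and Type I/II validation with
  pseudo-observed datasets.
- `refugia.synth` — the 202-mtDNA / 194-nuclear sampling-design preset
  (22 sites, 11 locations, 3 regions), full synthetic study bundles
  (mtDNA FASTA + microsatellite/intron genotypes), and forward
  Wright–Fisher stepping-stone vs island gene-flow fixtures.
- `refugia.pipeline` / `refugia.cli` — config-driven, seeded, resumable
  orchestration of both analysis tracks.

## CLI

```bash
refugia simulate-study --scenario 1 --seed 7 --outdir bundle/
refugia amova      --fasta bundle/study.fasta --popmap bundle/popmap.tsv \
                   --n-perm 10000 --seed 1 --out amova.tsv
refugia neutrality --fasta bundle/study.fasta --popmap bundle/popmap.tsv \
                   --seed 1 --out table2.tsv
refugia mantel     --fasta bundle/study.fasta --popmap bundle/popmap.tsv \
                   --coords bundle/coords.tsv --seed 1 --out mantel.tsv
refugia abc-build  --n-per-scenario 10000 --subsample 60 --seed 1 --out ref.csv
refugia abc-choose --table ref.csv --fasta bundle/study.fasta \
                   --popmap bundle/popmap.tsv --out posteriors.tsv
refugia abc-validate --table ref.csv --n-pods 50 --seed 2 --out errors.tsv
refugia run-all    --config config.yaml
```

Observed mode takes local files (FASTA alignment, popmap/coords/genotype
TSVs); synthetic mode generates a study-shaped bundle first.  All outputs
are TSV tables with a `#` metadata header carrying the tool version, seed
and config hash; runs with the same config and seed are byte-identical.

## Formats

- FASTA alignments (Biopython dialect; IUPAC ambiguity read as missing)
- popmap TSV: `sample_id  site_code  location_code  region  subspecies`
- coords TSV: `site_code  lat  lon`
- genotype TSV: `sample_id  locus  allele1  allele2` (missing = `.`)
- reference tables: CSV with scenario, parameter and 39 statistic columns
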