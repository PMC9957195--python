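# satzone

Satellitome analysis toolkit for tandem-repeat (TR) chromosome markers:
catalogue building, repeat-landscape metrics with amplification dating,
cytogenetic band-table comparison, and hybrid-zone cline analysis — plus
seeded synthetic-data generators with known ground truth.

## What it does

- **`satzone.io_formats`** — domain types and readers/writers: consensus
  monomers (FASTA, with `Name-{RUL}` repeat-unit-length suffixes),
  divergence hits (RepeatMasker `.out`/`.align` dialects or a simple TSV),
  band tables, genotype tables and transect site tables (CSV).
- **`satzone.tr_catalog`** — rotation- and strand-aware global identity
  between circular monomers (dimerized to ≥200 nt), and single-linkage
  clustering into subfamilies (≥95% identity), families (≥80%) and
  superfamilies (<80% but residual local homology).
- **`satzone.landscape_metrics`** — repeat landscapes in half-open
  0.5%-divergence bins; DIVPEAK (peak divergence bin), RPS (relative peak
  size in a ±1% window), TSI (abundance fraction with same-repeat
  junctions) and amplification time `t = DIVPEAK / (2 × 1.11)` Mya.
- **`satzone.cytogenetic_map`** — FISH-pattern summaries (B/DB/D/NS),
  chromosome-spread histograms, per-chromosome family counts and
  differential (banded vs no-signal) marker discovery between two taxa.
- **`satzone.hybrid_zone`** — exact allele frequencies from genotype counts
  (Hardy–Weinberg autosomal triples or hemizygous X0-male pairs), cline
  profiles along a transect, the 0.5-crossing cline centre, and
  Gardner–Altman-style paired mean differences with seeded BCa bootstrap
  confidence intervals.
- **`satzone.synthetic_data`** — amplification-burst monomer populations,
  consensus libraries with planted family/subfamily structure, and transect
  genotype samples under a planted sigmoid cline.
- **`satzone.datasets`** — bundled CSV transcriptions of the published
  band tables (CPP/CPE), hybrid-zone genotype counts and transect sites.

## CLI

The `satzone` entry point groups the pipeline stages:

```sh
satzone catalog build --fasta consensuses.fa --subfamily-id 95 --family-id 80 --out catalog.tsv
satzone landscape --hits hits.tsv --family famA --library CPE --out landscape.tsv
satzone metrics --landscape landscape.tsv --rate 1.11
satzone bands summarize --bands cpp_bands.csv --taxon CPP
satzone bands diff --a cpp_bands.csv --taxon-a CPP --b cpe_bands.csv --taxon-b CPE
satzone cline --genotypes hz_genotypes.csv --sites transect_sites.csv --marker CpaTR100-295
satzone effect paired --x auto_freqs.txt --y x_freqs.txt --boot 5000 --seed 42
satzone simulate burst|library|transect --seed 1 --out outdir/
```

`effect paired` reports `mean(y − x)`; pass the X-linked marker's
frequencies as `--y` to get the conventional sign.

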