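# nucperiod

Quantify and compare periodic mutation rates in nucleosomal DNA.

Nucleosomes modulate both DNA damage formation and repair, leaving two
periodic fingerprints in somatic mutation rates: a **rotational**
periodicity at the ~10.2 bp DNA helical repeat (positions where the minor
groove faces the histone octamer versus away from it) and a
**translational** periodicity at the ~190 bp nucleosome repeat length
(nucleosome core versus linker DNA). The shape and strength of these
oscillations carry mechanistic information — e.g. which repair pathway is
being blocked by the nucleosome — so comparing them across cohorts
(mismatch-repair proficient vs. deficient tumors, chromatin states, cell
types) is a useful analytical tool for cancer genomics.

`nucperiod` is for genomics researchers with a genome FASTA, a nucleosome
dyad map (BED), and mutation data (ICGC simple-somatic-mutation TSV or an
extended BED carrying `ref>alt`, donor and cohort columns). It provides:

- **dyad-relative counting** of mutations at signed offsets within ±73 bp
  (one nucleosome) or ±1000 bp (nucleosome arrays) of each dyad center,
  via a sorted linear-time sweep;
- **trinucleotide-context normalization** (32 pyrimidine-centered classes)
  or normalization against a background dataset;
- **Lomb-Scargle periodograms** over periods 5–25 bp (rotational) or
  50–250 bp (translational) with oversampling 100, summarized by a
  signal-to-noise ratio:

  `SNR = P(peak period) / median{ P(T) : |T − peak| > 0.5 bp }`

  computed only when ≥ 5000 mutations map within dyad windows;
- **cohort comparisons**: count-preserving label-permutation tests on
  aggregate data (one-sided empirical p with the add-one convention),
  Wilcoxon rank-sum tests on per-tumor SNR distributions, count-matched
  subsampling, and peak-period spread summaries (median/SD/IQR);
- **synthetic-data generators** that inject cosine periodicities of known
  period and amplitude, so every stage is testable without controlled-access
  tumor data;
- a **CLI** (`nucperiod simulate|count|normalize|periodicity|stratify|compare|plot|run-all`)
  that writes TSV results, figures, and a JSON run manifest.

## Worked example

Simulate a phased nucleosome array with a strong injected rotational
signal, then run the full pipeline:

```sh
nucperiod simulate --out demo --chrom-length 60000 --spacing 190 \
    --n-mutations 50000 --amplitude 0.8 --seed 42
# wrote genome.fa, dyads.bed, mutations.bed to demo

nucperiod run-all --genome demo/genome.fa --dyads demo/dyads.bed \
    --mutations demo/mutations.bed --mode rotational \
    --normalization trinuc --out demo/run
# rotational: peak period 10.203 bp, SNR 962.17 (50000 mapped mutations)
```

The peak period recovers the injected 10.2 bp helical repeat to within the
frequency-grid resolution, and the SNR of ~962 says the peak power is
roughly a thousand times the median off-peak power — an extremely strong
periodicity, as expected at amplitude 0.8 with 50,000 mutations. The run
directory contains the raw and context-normalized counts tables
(`counts/`), a per-unit results table with peak period, peak power and SNR
(`reports/periodicity.tsv`), figures with their exact plotted series as
TSVs (`figures/`), and a `manifest.json` recording every input and
parameter. Comparing two labelled cohorts with a permutation test works the
same way through `nucperiod compare --cohort-a MSS --cohort-b MSI ...`.

As a library:

```python
from nucperiod import (AnalysisConfig, map_mutations_to_dyads,
                       run_periodicity_analysis, read_fasta_genome,
                       read_dyad_map, read_mutations)

genome = read_fasta_genome("demo/genome.fa")
dyads = read_dyad_map("demo/dyads.bed", genome)
muts = read_mutations("demo/mutations.bed", "extended_bed", genome)
counts = map_mutations_to_dyads(muts, dyads, radius=73, genome=genome)
pg = run_periodicity_analysis(counts, AnalysisConfig.rotational())
print(pg.peak_period, pg.snr)
```

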