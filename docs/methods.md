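# Methods

## The problem

Nucleosomes shape where somatic mutations accumulate. Two periodic effects
are well documented in tumor genomes: a **rotational** oscillation with the
~10.2 bp helical repeat of nucleosomal DNA (minor-groove-in versus
minor-groove-out positions differ in damage formation and repair access),
and a **translational** oscillation with the ~190 bp human nucleosome repeat
length (nucleosome-bound DNA versus linker DNA differ in repair
efficiency). `nucperiod` quantifies both from three inputs — a genome
FASTA, a nucleosome dyad map (BED), and mutation data — and compares the
strength of the periodicity between mutation cohorts.

## Pipeline

1. **Dyad-relative counting.** Every mutation within `radius` bp of a dyad
   center contributes one pairing at signed offset `mutation − dyad`. The
   rotational radius is 73 bp (the 147 bp wrapped in one nucleosome); the
   translational radius is 1000 bp, spanning several nucleosomes, and a
   mutation near k dyads is counted once per dyad — per-dyad aggregation is
   what makes the ~190 bp repeat visible in the summed profile. Both inputs
   are coordinate-sorted and swept with two monotone window pointers, so the
   cost is linear in inputs plus emitted pairings; sortedness is checked and
   violations raise with the offending positions. Dyads whose full window
   leaves the chromosome are dropped, so edge offsets are never biased by
   partial windows. Dyads are treated as strandless and offsets as signed
   genomic distances.

2. **Context normalization (optional).** Raw counts confound nucleosome
   biology with base composition. Each position's trinucleotide is collapsed
   to the 32 pyrimidine-centered classes (standard in mutation-signature
   work; required anyway because dyad maps carry no strand). Per-context
   mutation rates are estimated *within the counted windows themselves* —
   rate[c] = mutations in context c / occurrences of c over all windows —
   rather than genome-wide, which keeps the normalization independent of
   unsequenced or unmapped regions. The expectation at offset p is
   `sum_c rate[c] * freq[c][p]`, rescaled to conserve the observed total
   (the downstream statistic is scale-invariant, and conservation makes the
   rescaling testable to 1e-9). Positions with zero expectation are flagged
   undefined and excluded from the fit. Mutations whose triplet contains an
   ambiguous base are kept in raw counts but excluded from rate estimation.
   A user-supplied background count profile can replace the context model.

3. **Periodogram.** The offset-indexed series (normalized values where
   available, otherwise raw counts) is mean-subtracted and fit with a
   least-squares (Lomb-Scargle) periodogram — chosen over an FFT because
   normalization can leave undefined positions, making sampling effectively
   uneven. Powers use the standard least-squares normalization (fraction of
   centered sum-of-squares explained; a perfect sinusoid scores 1),
   evaluated via `scipy.signal.lombscargle` on a grid linear in frequency
   with spacing `1/(oversampling * span)`, oversampling 100, covering
   periods 5–25 bp (rotational) or 50–250 bp (translational). Ties in
   maximum power break deterministically toward the longer period. Analyses
   are refused unless at least 5000 distinct mutations map within dyad
   windows; below that the periodogram is too noisy to interpret.

4. **SNR.** Periodicity strength is the power at the peak period divided by
   the median power at all periods farther than 0.5 bp (on the period axis)
   from the peak. A flat periodogram therefore scores exactly 1. The same
   0.5 bp half-width is used in both modes.

5. **Cohort comparison.** Aggregate cohorts: a count-preserving label
   permutation test. Mutations are pooled; each replicate reassigns |A|
   records to pseudo-A uniformly without replacement and recomputes the full
   pipeline (counting, normalization, periodogram, SNR) for both
   pseudo-cohorts. The one-sided empirical p-value uses the add-one
   convention `p = (1 + #{null >= observed}) / (1 + n_perm)`, which never
   returns zero and gives p = 1/101 when 100 permutations are all exceeded.
   When cohort sizes differ, the null median of (large − small) SNR
   differences sits above zero because SNR grows with sample size; this is
   expected, not a bug. Per-tumor SNR distributions: Wilcoxon rank-sum,
   exact for tie-free samples with both n ≤ 20, otherwise the normal
   approximation with tie and continuity corrections (two-sided by
   default; the permutation test is one-sided A > B by default, both
   configurable). Peak-period spread is summarized as median, sample SD
   (n−1), and IQR with linear-interpolation quartiles. Count-matched
   subsampling re-runs the pipeline on random subsets of the larger cohort
   at the smaller cohort's size, separating signal strength from sample
   size.

## Synthetic data

The fixture generators exist so every stage is testable without controlled-
access tumor data. Mutations are drawn around randomly chosen dyads from a
cosine intensity `baseline * (1 + amplitude * cos(2*pi*p/period + phase))`
over offsets [−R, R]; amplitude ≤ 1 keeps the intensity non-negative, and
the cosine form matches the sinusoid the Lomb-Scargle statistic is tuned
to, giving a clean recovery oracle (injected period in, peak period out).
Genomes are i.i.d. bases at a chosen GC fraction; dyads are regularly
spaced with optional jitter and margins that keep all windows in bounds.

What the fixtures deliberately do **not** emulate: realistic mutational
signatures and their context spectra, nucleosome positioning uncertainty,
chromatin-state heterogeneity, strand asymmetries, and copy-number or
clonality structure. Passing tests demonstrate that the estimator recovers
known injected periodicities and that the statistics are calibrated under
the stated model — not that real tumor data meet those assumptions.

## Default study conditions in tests and the acceptance script

Rotational recovery uses ~500 dyads spaced 200 bp on a ~100 kb toy
chromosome with 1e5 mutations at amplitude 0.8 and period 10.2 bp;
translational recovery uses ~300 dyads spaced 190 bp (aligned with the
injected 190 bp period, as in a phased nucleosome array) with 2e5 mutations
at amplitude 0.6; the permutation test compares a strong cohort (amplitude
0.9, n = 20,000) against a flat cohort (n = 10,000) with 100 permutations.
Null-calibration simulations use a deliberately small pipeline (50 dyads,
400 mutations per cohort, oversampling 10, gate lowered to 100) so that 200
simulated tests with 99 permutations each stay cheap; p-value uniformity
does not depend on grid density or sample size.

## Numerical choices and edge cases

- Internal coordinates are 0-based half-open everywhere; ICGC TSV input
  (1-based inclusive) is shifted on load, BED is taken as-is.
- Multi-base dyad BED records resolve to `floor((start+end)/2)`.
- Ref alleles are validated against the genome; mismatching records are
  dropped, and a mismatch fraction above 0.1% aborts (wrong genome build).
- Constant series produce an all-zero periodogram with a warning rather
  than an error; an all-zero periodogram has SNR 1 by convention.
- Display smoothing (11 bp centered moving average, shrinking at edges,
  NaN-aware) is applied only to plotted translational profiles, never
  before the SNR or peak-period computation.
- `%.17g` float formatting makes counts tables round-trip bit-exactly.
- All randomness flows through `numpy.random.default_rng` seeds recorded in
  run manifests; permutation replicates reuse the context-frequency matrix,
  which depends only on the dyad map and genome, so the reuse is exact, while
  per-context rates are recomputed per replicate.

## Known limitations

- Mutation-cohort labels (e.g. MSS/MSI microsatellite status, signature
  assignments) must be supplied by the user; the package does not call them.
- No VCF/MAF ingestion; no per-strand asymmetry analysis; no analytic
  false-alarm probabilities for the periodogram.
- Domain stratification tests only the dyad center base against intervals,
  not the full nucleosome footprint.
- With the rotational scan bounded to 5–25 bp (50–250 bp translational), a
  true period outside the scan range is truncated to the nearest grid edge
  rather than flagged.
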