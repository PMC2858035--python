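# Methods

## Scope and data model

`tilede` quantifies strand-specific differential transcription from
high-density tiling microarray intensities.  All genomic intervals are
0-based half-open internally; 1-based inclusive conventions (GFF3) are
converted only in the readers/writers.  The probe unit is a short exact
DNA sequence (typically a 25-mer) with physical array coordinates
(x, y); probesets — the unit of summarization — are named groups of at
least `min_probes_per_set` probes, whether they represent an annotated
gene, a located PCR amplicon, or a segmented dTR.

Vendor binary formats are out of scope by design: probe definitions and
intensities enter as tab-separated tables, and the "CDF" produced is a
documented flat TSV (`probeset_id, probe_id, x, y, chrom, start, end,
strand`; rows ordered by probeset id, then position).  The `end` column
makes the write→read round trip exact without assuming a probe length.

## Probe filtering (CDF construction)

The five steps are composed in `build_cdf`:

1. **Sequence dedup.**  One probe per distinct sequence; the retained
   representative is the first in (y, x) array order (the choice is
   arbitrary for downstream results since duplicates are
   indistinguishable after mapping; a fixed rule keeps runs
   deterministic).
2. **Exact genome mapping.**  Karp–Rabin search over both strands.  The
   hash is a base-4 polynomial (one base per nucleotide) modulo the
   Mersenne prime 2^31 − 1, with one hash table per distinct pattern
   length.  Window hashes are evaluated column-wise with numpy (the
   j-th pass folds the j-th character of every window into the running
   hash), which computes the same hash function as the classical
   rolling recurrence in O(L) vectorized passes.  Every hash hit is
   verified by direct string comparison, so collisions cost time, never
   correctness.  Reverse-strand hits are found by searching each
   pattern's reverse complement against the forward genome.  `N` bases
   are encoded outside the alphabet and can never verify; matches whose
   start lies in a masked region (e.g. an rDNA locus) are suppressed.
   Uniqueness downstream is therefore assessed on the masked genome.
3. **Uniqueness filter.**  Probes with two or more matches, counted
   over both strands together, are discarded.  A palindromic probe
   matching one locus on both strands counts as two matches and is
   discarded: for strand-separated analysis such a probe's signal is
   uninterpretable.
4. **Annotation intersection.**  Default rule: the probe interval must
   lie fully inside a single exon, on the annotated strand
   (`strand_rule="require-sense"`).  Full containment is consistent
   with exact genomic matching: a probe spanning a splice junction
   matches neither exon as a genomic interval.  Probes assignable to
   more than one gene are dropped (probesets must partition probes).
   Both the containment and the strand rule are configurable;
   `"any-overlap"` and `"ignore"`/`"require-antisense"` cover
   expression-array-like designs where the convention is unknown.
5. **Probeset assembly.**  Genes with fewer than `min_probes_per_set`
   (default 4) assigned probes are excluded — fewer probes do not
   support a robust median-polish summary.  Exclusions are logged.

The per-step counts (`StepCounts`) are monotone non-increasing by
construction and are validated as such.

**Amplicon-referenced variant.**  `build_cdf_from_amplicons` locates
each amplicon sequence in the genome by the same exact search; an
amplicon found at exactly one locus becomes a single-exon
pseudo-feature, and steps 4–5 run against those features with
`strand_rule="ignore"` (amplicon targets are double-stranded PCR
products, so probes from either strand are eligible).  Amplicons not
found, or found at multiple loci, are skipped with a warning.

## Intensity processing

The summarization chain is the standard Robust Multiarray Average:

- **Background correction** models each array's observed intensity as
  S + N with S ~ Exp(α) and N ~ Normal(μ, σ), and replaces O by
  E[S | O], which is strictly positive and monotone.  The observed
  mixture is an exponentially modified Gaussian, so (μ, σ, α) are
  fitted per array by maximum likelihood (`scipy.stats.exponnorm`),
  initialized from a mode-based moment estimate (background mode by
  kernel density; σ from the spread below the mode, doubled; α from
  the mean excess above it) and falling back to that estimate if the
  fit degenerates.  The conditional expectation is evaluated through
  the scaled complementary error function for numerical stability far
  below the background.  Constant arrays pass through unchanged.
  Background correction is optional (a flag) for dTR quantification,
  whose segmentation input is defined on quantile-normalized signal
  only; it defaults to on for gene-level analysis.
- **Quantile normalization** gives every array the across-array mean of
  order statistics; tied values receive the average reference value at
  their tied ranks (linear interpolation on fractional average ranks).
  The transform is idempotent and preserves within-array order.
- **Median polish** (per probeset, on the log2 probe-by-array
  submatrix): alternating row/column median sweeps until the largest
  single adjustment in a sweep falls below 0.01 (log2 units) or 10
  sweeps have run — standard RMA practice; both are configurable.  The
  per-array summary is the overall effect plus the column effect.
- **Differential expression** is the treated−control difference of
  mean summarized log2 values, with a two-sided Welch t-test across
  replicate arrays.  With one replicate per condition the p-value is
  reported as missing (NaN).  There is no single field convention for
  p-values on summarized array expression; the Welch test on summarized
  values is this package's documented choice, and a moderated-variance
  test could be slotted in behind the same interface.  P-values are reported raw (no multiple-testing
  adjustment), matching the per-gene table convention of the field.

## dTR segmentation

Input: per (chromosome, strand) tracks of per-probe differential
signal, Δ = mean log2(treated) − mean log2(control), computed after
quantile normalization of each hybridization.  For each direction
(up: Δ > +t; down: Δ < −t) independently:

1. select probes with |Δ| above `min_probe_diff` (default 0.8 log2 —
   just under 2-fold at the probe level; strict inequality);
2. cluster consecutive selected probes whose gap (next start − previous
   end, half-open arithmetic) is less than `cluster_gap` (60 nt ≈ three
   tiling probes at a 20 nt step; strict);
3. keep clusters whose genomic span (last end − first start, i.e.
   including probe lengths) exceeds `min_region_len` (180 nt, strict)
   and whose mean Δ over member probes exceeds the threshold;
4. fuse surviving regions of the same direction closer than `fuse_gap`
   (120 nt, strict), iterated to a fixed point.  Fused regions inherit
   the union of member probes and are not re-tested against the length
   filter — fusion can only grow a region.

The region mean is taken over the *selected* member probes: the
algorithm admits only above-threshold probes, so sub-threshold probes
tiled inside the boundaries are never members.  The phrase "all the
probes included" is ambiguous on this point, so the other reading —
averaging every tiled probe inside the final boundaries — is available
behind `include_subthreshold_in_mean`/`all_probes_for_mean`.  Up and
down regions, and the two strands, are never mixed or fused together.

Detected regions are named `dTR<c><s><nnnn>`: 1-based chromosome index,
strand code (0 = "+", 1 = "−"), and a 4-digit ordinal per (chromosome,
strand) in positional order (e.g. the 92nd region on chromosome 1 "−"
is `dTR110092`).  The scheme follows the identifier format seen in
published dTR tables, whose exact numbering rule is undocumented, so
ids are format-compatible but not guaranteed to coincide.  Naming is
deterministic given the input.

Quantification builds one probeset per dTR from every uniquely mapping
probe fully contained in the region *on the region's strand* (the ≥ 4
probe rule applies, as for genes) and runs the same summarization and
differential test.  A 2-fold (|log2| ≥ 1) reporting filter is applied
post hoc to the quantified output, not inside segmentation.

**Annotation overlap** is positional, strand-blind (an antisense dTR
genuinely overlaps the sense ORF): using the ORF's genomic span,
`orf_within_dtr` (symbol `> name <`) when the ORF lies entirely inside
the region, `dtr_within_orf` (`< name >`) for the converse,
`partial_start` (`<name`) when the ORF enters from the left (its end is
inside the dTR), `partial_end` (`name>`) when it exits to the right.
Every overlapping gene yields one record, so a region crossing several
genes produces several table rows.

## Track export

bedGraph files are written per (strand, direction) from the same
differential tracks.  Positions with |Δ| below log2 of the display
threshold (default 1.75-fold) are omitted — the browser convention of
hiding sub-threshold noise.  Overlapping probe intervals from a tiling
design (step < probe length) are trimmed at the next probe's start so
each file contains sorted, non-overlapping intervals.

## Synthetic data

The default `SimulationSpec` emulates a compact fission-yeast-like
study: two 100 kb chromosomes, 60 non-overlapping genes of 600–2400 nt
(a quarter with two exons), 25-mer probes tiling both strands every
20 nt, two replicate arrays per condition, ten DE genes with |log2|
effects drawn from 1–2 (random sign), five planted intergenic
transcripts of 300–600 nt (expressed only when treated, effect
+1.5 log2) and one antisense transcript spanning a non-DE gene on the
opposite strand.  Intensities are multiplicative log-normal: log2
intensity = baseline (6.0) + per-probe affinity N(0, 0.3) + expression
boosts (sense-strand containment only; expressed genes +2.0) + per-array
noise N(0, 0.15).  The 20 nt step realizes "about three probes per
60 nt", the scale keeps a full pipeline run in seconds, and the noise
level sits near the replicate concordance reported for real arrays.

An `exonic` layout places probes only inside exons and supports planted
anomalies — duplicate sequences, repeated genomic segments deliberately
misaligned with the tiling grid (multi-mappers), probes absent from the
genome, unique intergenic probes — each verified at generation time so
filtering-step decrements can be asserted exactly.

What the generator does *not* emulate: hybridization physics,
cross-hybridization, GC/affinity sequence effects, saturation,
transcript isoforms or partial-length features.  Passing tests
demonstrate algorithmic correctness and quantitative recovery under the
stated noise model, not robustness to platform-specific artifacts.

## Numerical and degenerate-input choices

- Hash parameters: base 4, modulus 2^31 − 1; correctness never depends
  on them (verification), only speed.
- Patterns longer than every chromosome simply yield no matches.
- Empty probesets cannot be written; duplicate probes within a probeset
  are rejected.
- Quantile normalization of a single array is the identity.
- Median polish of a 1×1 matrix returns the value itself.
- Zero-variance t-tests (identical replicate summaries) report p = 1.
- Welch p-values require ≥ 2 replicates per condition; otherwise NaN.
- All generator randomness flows from a single integer seed through
  `numpy.random.default_rng`; identical seed ⇒ byte-identical outputs
  (provenance headers contain content checksums and basenames only,
  never absolute paths or timestamps).

## Known limitations

- **Threshold monotonicity is not guaranteed.**  Raising
  `min_probe_diff` deselects borderline probes, which can split one
  cluster into two regions; if the pieces are at least `fuse_gap`
  apart, both can survive, so a (chromosome, strand) track — and on
  some datasets the genome-wide total — can gain regions as the
  threshold rises.  Counts typically decrease, but the property is
  structural to cluster-and-fuse segmentation, not a theorem.
- Down-regulated genes whose treated signal approaches the background
  floor have over-stated |log2| after background correction (ratio
  compression at the floor) — directionally correct, magnitudes
  conservative to interpret.
- Exact matching only: probes with even one mismatch against the
  reference are discarded at step 2, which is intended behavior for
  CDF construction but means outdated probe sequences silently shrink
  coverage (the step counts make this visible).
- The uniqueness filter treats a probe as multi-mapping regardless of
  where the second hit lies, including palindromic self-hits.
- No mismatch-probe correction, no moderated-variance testing, no
  q-values; the browser/track layer does not serve a genome browser.
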