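# Methods

## Scope and model

`stirkit` implements a matched-control comparison framework for short
tandem intergenic regions (STIRs). The unit of analysis is an adjacent,
non-overlapping gene pair. Genes are flattened across isoforms (minimal
start, maximal end), restricted to a configurable length window
(default 5 kb – 800 kb) and a chromosome universe (default autosomes + X),
and paired with their nearest non-overlapping neighbor in each genomic
direction; each unordered pair is kept once. Orientation is a pure function
of the two strands: same strand → tandem, (−,+) in genomic order →
divergent, (+,−) → convergent. The STIR of a tandem pair is the interval
between the upstream gene's CPA site and the downstream gene's TSS, kept
when the gap is strictly between 0 and 2,000 bp. Coordinates are 0-based
half-open; bookended genes have gap 0 (one bedtools dialect reports 1).

Every STIR-level measurement is compared against two control classes built
from "isolated" genes (no neighbor within 5 kb on either strand, same
length window): *promoter controls* — regions of exactly the STIR's length
immediately upstream of the TSS of five genes matched to the downstream
tandem gene — and *3′ controls* — the same construction downstream of the
CPA site of five genes matched to the upstream tandem gene. Control
quintet values are averaged into one value per focal gene before any
paired test.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_len`, `max_len` | 5,000 / 800,000 bp | gene length bounds |
| `max_gap` | 2,000 bp | STIR gap cutoff (strict) |
| `min_tpm` | 2 TPM | expression filter (strict >) |
| co-expression quantile | 0.75 | percentile of abs. TPM differences |
| `k` | 5 | controls per tandem gene |
| `min_isolation` | 5,000 bp | control-universe isolation (strict >) |
| `n_bins` | 70 | body bins for composition profiles |
| `flank_bp`, `flank_bin_bp` | 1,000 / 50 bp | metagene flanks |
| pausing window | 200 bp | promoter-proximal window after the TSS |
| outlier quantiles | 0.0001 / 0.9999 | row filter on combined matrices |
| ratio cap / max missing | 10 / 17 | binding-ratio matrix clean-up |

## Statistical choices

- **Paired comparisons** use the Wilcoxon signed-rank test on paired
  differences (STIR vs quintet mean), zeros dropped, exact null for small
  n and normal approximation with continuity correction otherwise. With
  n = 6 all-positive differences the exact two-sided p is 2/2⁶ = 0.03125,
  which the tests assert. Degenerate all-zero differences give p = 1.
- **Proportion tests** are two-sided two-sample tests for equality of
  proportions with continuity correction (Yates-corrected chi-square on
  the 2×2 table). Bonferroni families are stated at each call site
  (4 nucleotides × 2 controls for overall composition; bins for profiles;
  factors × 2 controls for binding panels).
- **Percentile definition**: sort-and-linearly-interpolate ("type 7", the
  numpy default). Retention uses ≤ threshold. With |differences| 1..100
  the 75th percentile is 75.25.
- **Control matching distance** (the weighting is a design choice): genes
  are embedded as (log₂(TPM+1), log₂(intron+1)), z-scored against the
  control universe, and ranked by Euclidean distance with gene_id
  tie-break. This is scale-free and weights the two stated criteria
  equally; any other fixed weighting plugs into the same interface. One
  control gene may serve several focal genes.
- **Metagene binning**: bin b of a length-L body spans
  [⌊bL/n⌋, ⌊(b+1)L/n⌋) — deterministic, near-equal bins; bin values are
  means of per-base signal, minus-strand rows are computed on the reversed
  per-base vector so columns run 5′→3′ in transcription direction. The
  across-region summary is the median with SE = SD/√n. Requesting more
  body bins than the shortest region is allowed but yields empty-bin NaNs;
  callers lower the bin count to the minimum region length (the
  composition profiler does this automatically).
- **Pausing index**: the numerator is the raw 200-bp sum and the
  denominator the per-base gene mean, so a uniform track gives PI = 200
  (the window length). A `normalized=True` variant divides by the window,
  making a uniform track give PI = 1. Both conventions are exposed because
  the ratio is often described loosely; PI is invariant to scaling the
  track.
- **Motif scanning** counts overlapping matches (this matters for G-run
  motifs); DNA mode adds reverse-complement matches at the same
  coordinates, except that a self-reverse-complementary pattern is scanned
  once. The dinucleotide shuffle is the Eulerian-path (Altschul–Erickson)
  construction: endpoints fixed, exact dinucleotide count vector
  preserved, seeded. Empirical enrichment p-values use the
  (1 + exceedances)/(n + 1) estimator.
- **Clustering**: columns by 1 − Pearson r over pairwise-complete values
  (undefined correlations → distance 1, the in-range maximum), rows by
  pairwise-complete Euclidean distance rescaled by √(p/valid); complete
  linkage both ways; leaf order is made deterministic by putting the
  subtree containing the smaller minimum original index on the left at
  every merge.
- **KD ranking**: rank1 = ascending |m_up|, rank2 = descending |m_down|,
  rank3 = descending |m_down − m_up|, final order by ascending rank sum
  with name tie-break; experiments with undefined medians rank last. The
  default uses the magnitude of the downstream effect in rank2 because a
  downstream-specific regulator may act in either direction; a
  `signed=True` mode ranks by the signed downstream effect instead.

## The synthetic-data generator

The generator emulates the statistical structure of the study inputs so
that every pipeline stage has a recoverable planted truth. A single
integer seed feeds named substreams (one per generator), so adding a
generator never perturbs existing outputs; runs are bit-reproducible.

- **Geometry**: pair units (two genes with a sampled gap, default
  300–1,900 bp) and isolated genes laid along one chromosome with 6 kb
  spacers, so planted close pairs are exactly the gap < 2 kb pairs and
  isolated genes qualify for the control universe. Genes carry a 3-exon
  structure with controllable intron totals. All boundaries snap to a
  25 bp grid matching the signal-track step, so no track step straddles a
  gene or STIR boundary (otherwise boundary steps would leak gene-body
  signal asymmetrically into first/last body bins and break null
  calibration).
- **Expression**: log-normal TPM (median ≈ 12 TPM), 15% of genes left
  below the 2 TPM cutoff, tandem partners coupled on the log₂ scale
  (SD 0.5). Because the absolute difference distribution is continuous,
  the q75 rule retains 75% of expressed pairs by construction.
- **Sequence**: background at 46% GC, promoter-adjacent windows at 55%,
  STIRs at 58% (the study's observed class means); one G-rich motif
  (default GGGGCGGGG) planted at class prevalences 33% / 22% / 3%, at ~80%
  of the STIR length (near the downstream promoter) on the transcribed
  strand. Measured control prevalences run slightly above the planted
  rates because GC-rich background also produces chance hits.
- **Signal**: per-base Poisson rates — intergenic 0.2, gene body 1.0,
  promoter peak 5.0 over the first 200 bp, and a STIR accumulation ramp
  rising linearly from the CPA to the downstream TSS with amplitude
  5 × body rate (configurable; 0 gives an exact null). Antisense gets a
  low floor. Rates are realized in 25 bp steps as count/step, emitted as
  sense/antisense bedGraph.
- **Peaks**: Bernoulli per class (STIR 0.5, promoter 0.25, 3′ 0.1 —
  a planted minimal ratio of 2.0), placed inside the STIR or within 250 bp
  of the isolated genes' anchors so any length-matched control region
  overlaps them.
- **Knockdown panel**: 20 null factors plus one planted
  downstream-specific factor (m_up = 0, m_down = +0.5, per-gene noise
  SD 0.2). Null factors each draw one *concordant* effect
  c ~ N(0, 0.2) applied to both genes of every pair: real knockdown panels
  shift tandem genes together relative to controls far more often than
  they decouple them, and under a pure-noise null the planted factor's
  |m_up| rank is uniform among factors, which makes rank-1 recovery a
  coin flip rather than a property of the method.
- **Long reads**: sense-strand reads per gene; half of the upstream
  gene's reads span its CPA site, of which 90% extend ≥ 50 nt into the
  STIR (geometric tail); reads spanning exons of both genes occur at a
  configurable rate, default 0.

What the generator does **not** emulate: mappability and GC bias,
peak-width and signal autocorrelation structure, isoform-level expression,
overdispersed counts, splicing intermediates in long reads, or any
chromatin-state organization. Passing tests therefore demonstrate that the
estimators recover planted parameters under idealized sampling noise, not
that they are robust to real-data artifacts.

## Problem sizes

The test suite and `scripts/acceptance.py` run at desk scale chosen as the
package's own defaults: 150–500 pair units per check, 100 seeded
replicates for the knockdown-ranking recovery rate, 1,000 shuffles for the
motif null, 10,000 pairs for the co-expression retention check. These
sizes put binomial/percentile noise well inside the asserted tolerances.

## Known limitations

- The expression/intron weighting of control matching is a stand-in for an
  unstated convention; results that depend on exact control identity (not
  on the matched-distribution property) may differ under other weightings.
- Readers for bigWig are not included; tracks are consumed as bedGraph
  (any bigWig can be converted upstream).
- The readthrough classifier assumes one STIR per tandem pair and
  sense-strand read assignment; it does not model internal TSSs or
  unannotated transcripts inside the intergenic region.
- `build_metagene_matrix` truncates flanks at chromosome starts by reading
  zeros (with a diagnostic) rather than masking them.
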