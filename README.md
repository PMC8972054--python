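# stirkit

Analysis toolkit for **short tandem intergenic regions (STIRs)** — the
intervals between the cleavage/polyadenylation (CPA) site of a gene and the
transcription start site (TSS) of a closely spaced (< 2 kb) downstream gene
on the same strand. Such "tandem" gene pairs put a transcription-termination
region directly upstream of a promoter, and the intergenic sequence between
them shows distinctive features: G-rich motifs, specific protein binding,
and a strong accumulation of RNA polymerase II that peaks near the
downstream promoter.

`stirkit` is aimed at computational genomicists who want to run or extend
this style of matched-control analysis. It provides:

- **Pair classification** — flattening multi-isoform annotations to one
  interval per gene, classifying adjacent pairs as *tandem* (same strand),
  *divergent* (`←  →`) or *convergent* (`→  ←`), and binning them by gap
  distance (0-based half-open coordinates throughout).
- **Co-expression selection** — both genes > 2 TPM, then the absolute TPM
  difference below its own 75th percentile (the empirical-CDF rule), so
  ~75% of expressed pairs are retained.
- **Matched controls** — for each tandem gene, the five isolated genes
  (no neighbor within 5 kb) nearest in joint
  (log₂ expression, log₂ total intron length) space; control regions of
  exactly the focal STIR's length are taken upstream of each control's TSS
  ("promoter controls") or downstream of its CPA site ("3′ controls").
- **Sequence statistics** — binned nucleotide composition, repeat
  occupancy, overlapping IUPAC motif counts in RNA (sense-strand) or DNA
  (both strands) mode, prevalence/ratio ranking, and an exact
  dinucleotide-preserving (Eulerian-path) shuffle null.
- **Signal metagenes** — strand-aware scaled-body + fixed-flank profiles
  of bedGraph tracks, per-bin paired Wilcoxon signed-rank tests with
  Bonferroni correction, outlier-row filtering by extreme quantiles,
  STIR/control fold enrichment, and the Pol2 pausing index
  PI = Σ signal(TSS..TSS+200) / (Σ signal(gene) / gene length).
- **Peak enrichment** — binding prevalence (fraction of regions
  overlapping ≥ 1 peak), minimal STIR-to-control ratio, two-proportion
  tests and factor ranking.
- **Knockdown ranking** — per-gene effect Δ = log₂FC − mean(log₂FC of the
  5 controls), group medians m_up / m_down, and a three-rank sum that puts
  downstream-specific regulators first.
- **Binding-matrix clustering** — gene × experiment max-signal ratio
  matrices (capped at 10, sparse rows dropped) clustered with complete
  linkage (columns: 1 − Pearson r, rows: missing-aware Euclidean).
- **Synthetic data** — a generator that emits every input format the
  pipeline reads (GTF, FASTA, bedGraph, BED peaks, TSV expression/log₂FC,
  BED12 long reads) with *planted* structure, so every stage can be
  validated end-to-end without external downloads.

## Worked example

```python
import numpy as np
from stirkit import annotation_core as ac, coexpression as ce, peak_enrichment as pe
from stirkit import synthetic_data as sd

cfg = sd.SyntheticConfig(seed=1, n_tandem=300, n_isolated=60)
ann = sd.generate_annotation(cfg)

pairs = ac.pair_adjacent_genes(ann.genes)
counts = ac.bin_pairs_by_distance(pairs)
print("close tandem pairs:", counts["tandem"]["[0,2000)"])

stirs = ac.extract_stirs(
    [p for p in pairs if p.orientation == "tandem" and 0 < p.gap_bp < 2000]
)
print("STIRs:", len(stirs), "median length:", int(np.median([s.length for s in stirs])))

expr = sd.generate_expression(ann, cfg)
tandem = [p for p in pairs if p.orientation == "tandem" and 0 < p.gap_bp < 2000]
expressed = ce.filter_expressed_pairs(tandem, expr, "S1")
res = ce.select_coexpressed(expressed, expr, "S1")
print(f"expressed pairs: {len(expressed)}; q75 threshold: "
      f"{res.threshold_q75:.2f} TPM; co-expressed: {len(res.selected_pairs)}")

# binding prevalence from intersection counts (136/188 STIRs bound,
# 357 and 89 of 940 pooled control regions)
rec = pe.prevalence_and_ratio(
    np.r_[np.ones(136), np.zeros(52)],
    np.r_[np.ones(357), np.zeros(583)],
    np.r_[np.ones(89), np.zeros(851)],
    "AGO1",
)
print(f"AGO1 prevalence: STIR {100*rec.p_stir:.1f}%, promoter "
      f"{100*rec.p_prom:.1f}%, 3' {100*rec.p_3p:.1f}%; min ratio {rec.min_ratio:.2f}")
```

prints

```
close tandem pairs: 300
STIRs: 300 median length: 1062
expressed pairs: 239; q75 threshold: 8.36 TPM; co-expressed: 179
AGO1 prevalence: STIR 72.3%, promoter 38.0%, 3' 9.5%; min ratio 1.90
```

All 300 planted tandem pairs are recovered; the co-expression rule keeps
179/239 ≈ 75% of expressed pairs by construction of the percentile
threshold; and the binding-prevalence record reproduces the percentages
implied by the intersection counts, with the minimal STIR-to-control ratio
taken over the two control classes.

A command-line layer mirrors the library:

```bash
stirkit simulate --seed 3 --out data/
stirkit pairs --gtf data/genes.gtf --out pairs.tsv --stirs-bed stirs.bed
stirkit coexpress --gtf data/genes.gtf --expr data/tpm.tsv --sample S1 --out coexpr.tsv
```

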