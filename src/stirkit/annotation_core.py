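"""Gene-annotation handling: flattening, pair classification and STIR extraction.

A "tandem" gene pair is two adjacent genes on the same strand; the short
tandem intergenic region (STIR) is the interval between the cleavage and
polyadenylation (CPA) site of the transcriptionally upstream gene and the
transcription start site (TSS) of the downstream gene, here restricted to
gaps below 2 kb by default.

Coordinates are 0-based half-open (BED convention) throughout.  TSS = start
for + genes, end for - genes; CPA = end for +, start for -.  The gap of
bookended genes is 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: default gene length bounds, bp
MIN_GENE_LEN = 5_000
MAX_GENE_LEN = 800_000
#: default upper gap bound for a STIR, bp
STIR_MAX_GAP = 2_000
#: default gap bins for orientation x distance summaries, bp
DEFAULT_DISTANCE_EDGES = (0, 2_000, 5_000, 50_000, float("inf"))

TANDEM = "tandem"
DIVERGENT = "divergent"
CONVERGENT = "convergent"


def default_chromosomes() -> frozenset[str]:
    """Autosomes + X (chrY excluded by default; configurable everywhere)."""
    return frozenset([f"chr{i}" for i in range(1, 23)] + ["chrX"])


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """A flattened gene: one interval spanning all isoforms.

    ``transcripts`` holds per-isoform exon interval lists (sorted,
    non-overlapping within an isoform); ``mean_total_intron_length`` is the
    mean, across isoforms, of (isoform span - summed exon length).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    transcripts: list[list[tuple[int, int]]] = field(default_factory=list)
    mean_total_intron_length: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def cpa(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def exons(self) -> list[tuple[int, int]]:
        """Union of exon intervals over all isoforms (merged, sorted)."""
        ivs = sorted(iv for tx in self.transcripts for iv in tx)
        if not ivs:
            return [(self.start, self.end)]
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


@dataclass
class GenePair:
    """Two adjacent non-overlapping genes, left < right in genomic coordinates."""

    left_gene: GeneModel
    right_gene: GeneModel
    orientation: str
    gap_bp: int
    promoter_distance_bp: int
    distance_bin: str | None = None

    @property
    def chrom(self) -> str:
        return self.left_gene.chrom

    @property
    def upstream(self) -> GeneModel:
        """Transcriptionally upstream gene of a tandem pair."""
        if self.orientation != TANDEM:
            raise ValueError("upstream/downstream defined for tandem pairs only")
        return self.left_gene if self.left_gene.strand == "+" else self.right_gene

    @property
    def downstream(self) -> GeneModel:
        if self.orientation != TANDEM:
            raise ValueError("upstream/downstream defined for tandem pairs only")
        return self.right_gene if self.left_gene.strand == "+" else self.left_gene

    @property
    def strand(self) -> str:
        return self.left_gene.strand


#: region roles
ROLE_STIR = "STIR"
ROLE_PROMOTER_CONTROL = "promoter_control"
ROLE_THREE_PRIME_CONTROL = "three_prime_control"


@dataclass
class Region:
    """A strand-aware genomic interval with an analysis role."""

    chrom: str
    start: int
    end: int
    strand: str
    role: str
    anchor_gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError("region must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return "|".join(self.anchor_gene_ids) or f"{self.chrom}:{self.start}-{self.end}"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

TranscriptRecord = tuple[str, str, str, list[tuple[int, int]]]
"""(gene_id, chrom, strand, exon intervals) of one transcript."""


def flatten_transcripts(
    transcript_records: Iterable[TranscriptRecord],
    chromosomes: frozenset[str] | set[str] | None = None,
) -> list[GeneModel]:
    """Collapse per-transcript records into one flattened model per gene.

    The flattened interval runs from the minimum start to the maximum end over
    all of the gene's transcripts.  Records on chromosomes outside
    ``chromosomes`` (default autosomes + X) are dropped; genes whose records
    disagree on chromosome or strand are rejected with a logged diagnostic.
    """
    if chromosomes is None:
        chromosomes = default_chromosomes()
    by_gene: dict[str, list[TranscriptRecord]] = {}
    for rec in transcript_records:
        gene_id, chrom, strand, exons = rec
        if chrom not in chromosomes:
            continue
        if not exons:
            raise ValueError(f"{gene_id}: transcript without exons")
        by_gene.setdefault(gene_id, []).append(rec)

    intron_means = total_intron_length(
        rec for recs in by_gene.values() for rec in recs
    )
    genes: list[GeneModel] = []
    for gene_id, recs in by_gene.items():
        chroms = {r[1] for r in recs}
        strands = {r[2] for r in recs}
        if len(chroms) > 1 or len(strands) > 1:
            logger.warning(
                "gene %s has records on multiple chromosomes/strands; rejected",
                gene_id,
            )
            continue
        start = min(tx[3][0][0] for tx in recs)
        end = max(tx[3][-1][1] for tx in recs)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=recs[0][1],
                start=start,
                end=end,
                strand=recs[0][2],
                transcripts=[r[3] for r in recs],
                mean_total_intron_length=intron_means[gene_id],
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.end, g.gene_id))
    return genes


def total_intron_length(
    transcript_records: Iterable[TranscriptRecord],
) -> dict[str, float]:
    """Mean total intron length per gene, averaged over its isoforms.

    Per transcript the intron total is (span - summed exon length); a
    single-exon transcript contributes 0.
    """
    totals: dict[str, list[int]] = {}
    for gene_id, _chrom, _strand, exons in transcript_records:
        span = exons[-1][1] - exons[0][0]
        exonic = sum(e - s for s, e in exons)
        totals.setdefault(gene_id, []).append(span - exonic)
    return {g: float(np.mean(v)) for g, v in totals.items()}


def _orientation(left_strand: str, right_strand: str) -> str:
    if left_strand == right_strand:
        return TANDEM
    return DIVERGENT if left_strand == "-" else CONVERGENT


def pair_adjacent_genes(
    genes: Sequence[GeneModel],
    min_len: int = MIN_GENE_LEN,
    max_len: int = MAX_GENE_LEN,
) -> list[GenePair]:
    """Pair every gene with its nearest non-overlapping neighbor per direction.

    Pairs are deduplicated (each unordered pair emitted once), annotated with
    orientation, body gap and promoter distance, and filtered to genes within
    [min_len, max_len].  Ties on gap are broken by lexicographic gene_id.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene_ids in input")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    chosen: set[tuple[str, str]] = set()
    lookup: dict[str, GeneModel] = {g.gene_id: g for g in genes}
    for chrom_genes in by_chrom.values():
        by_start = sorted(chrom_genes, key=lambda h: (h.start, h.gene_id))
        starts = np.array([h.start for h in by_start])
        by_end = sorted(chrom_genes, key=lambda h: (h.end, h.gene_id))
        ends = np.array([h.end for h in by_end])
        for g in chrom_genes:
            # nearest non-overlapping neighbor to the right: minimal start
            # among starts >= g.end (ties resolved by gene_id via sort order)
            j = int(np.searchsorted(starts, g.end, side="left"))
            if j < len(by_start):
                chosen.add(tuple(sorted((g.gene_id, by_start[j].gene_id))))
            # to the left: maximal end among ends <= g.start; among equal
            # ends take the smallest gene_id
            k = int(np.searchsorted(ends, g.start, side="right")) - 1
            if k >= 0:
                while k > 0 and by_end[k - 1].end == by_end[k].end:
                    k -= 1
                chosen.add(tuple(sorted((g.gene_id, by_end[k].gene_id))))

    pairs: list[GenePair] = []
    for a_id, b_id in sorted(chosen):
        a, b = lookup[a_id], lookup[b_id]
        left, right = (a, b) if a.start <= b.start else (b, a)
        gap = right.start - left.end
        if gap < 0:
            continue  # overlapping
        if not (min_len <= left.length <= max_len and min_len <= right.length <= max_len):
            continue
        pairs.append(
            GenePair(
                left_gene=left,
                right_gene=right,
                orientation=_orientation(left.strand, right.strand),
                gap_bp=gap,
                promoter_distance_bp=abs(left.tss - right.tss),
            )
        )
    pairs.sort(key=lambda p: (p.chrom, p.left_gene.start, p.right_gene.start))
    return pairs


def bin_pairs_by_distance(
    pairs: Sequence[GenePair],
    bin_edges: Sequence[float] = DEFAULT_DISTANCE_EDGES,
) -> dict[str, dict[str, int]]:
    """Count pairs per orientation x half-open gap bin [lo, hi).

    Also writes the bin label onto each pair's ``distance_bin``.
    """
    edges = list(bin_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    labels = [
        f"[{int(lo)},{'inf' if hi == float('inf') else int(hi)})"
        for lo, hi in zip(edges, edges[1:])
    ]
    counts: dict[str, dict[str, int]] = {
        ori: {lab: 0 for lab in labels} for ori in (TANDEM, DIVERGENT, CONVERGENT)
    }
    for p in pairs:
        idx = int(np.searchsorted(edges, p.gap_bp, side="right")) - 1
        idx = min(idx, len(labels) - 1)
        if not (edges[idx] <= p.gap_bp < edges[idx + 1]):
            raise ValueError(f"gap {p.gap_bp} outside bin range")
        p.distance_bin = labels[idx]
        counts[p.orientation][labels[idx]] += 1
    return counts


def extract_stirs(
    tandem_pairs: Iterable[GenePair],
    max_gap: int = STIR_MAX_GAP,
) -> list[Region]:
    """STIR regions for tandem pairs with 0 < gap < ``max_gap``.

    The region spans [end(left), start(right)) and carries the pair's strand,
    so its transcriptional 5' end is the upstream gene's CPA site on either
    strand.  Anchors are [upstream_id, downstream_id].
    """
    regions: list[Region] = []
    for p in tandem_pairs:
        if p.orientation != TANDEM:
            raise ValueError("extract_stirs expects tandem pairs")
        if p.gap_bp <= 0 or p.gap_bp >= max_gap:
            continue
        regions.append(
            Region(
                chrom=p.chrom,
                start=p.left_gene.end,
                end=p.right_gene.start,
                strand=p.strand,
                role=ROLE_STIR,
                anchor_gene_ids=[p.upstream.gene_id, p.downstream.gene_id],
            )
        )
    return regions


# ---------------------------------------------------------------------------
# long-read readthrough classification
# ---------------------------------------------------------------------------

@dataclass
class LongRead:
    """A spliced long-read alignment (BED12-like)."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    blocks: list[tuple[int, int]]  # absolute aligned intervals


@dataclass
class ReadthroughSummary:
    """Fractions from the long-read analysis; None when the denominator is 0.

    dual_exon_read_fraction: reads (among reads mapping to either gene of a
        pair) whose aligned blocks overlap exons of both genes.
    dual_pair_fraction: pairs, among pairs with >= 10 reads on each gene,
        having >= 2 dual-overlap reads.
    cpa_extension_fraction: reads overlapping the upstream CPA site that
        extend >= ``min_extension`` nt into the STIR.
    gene_and_stir_fraction: upstream genes with >= 2 reads aligning to both
        the gene and the STIR.
    """

    dual_exon_read_fraction: float | None
    dual_pair_fraction: float | None
    cpa_extension_fraction: float | None
    gene_and_stir_fraction: float | None
    n_reads: int
    n_eligible_pairs: int
    n_cpa_reads: int
    n_upstream_genes: int


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def classify_long_reads(
    reads: Iterable[LongRead],
    pairs: Sequence[GenePair],
    stirs: Sequence[Region],
    min_extension: int = 50,
) -> ReadthroughSummary:
    """Classify sense-strand long reads against tandem pairs and their STIRs."""
    stir_by_pair = {tuple(r.anchor_gene_ids): r for r in stirs}
    trees: dict[str, IntervalTree] = {}
    pair_info = []
    for i, p in enumerate(pairs):
        if p.orientation != TANDEM:
            continue
        key = (p.upstream.gene_id, p.downstream.gene_id)
        stir = stir_by_pair.get(key)
        pair_info.append((p, stir))
        tree = trees.setdefault(p.chrom, IntervalTree())
        tree[p.left_gene.start:p.right_gene.end] = len(pair_info) - 1

    n_reads = dual_reads = 0
    per_pair_counts: dict[int, list[int]] = {}  # idx -> [n_up, n_down, n_dual]
    n_cpa = n_cpa_ext = 0
    gene_stir_reads: dict[int, int] = {}

    for read in reads:
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        for hit in tree[read.start:read.end]:
            idx = hit.data
            pair, stir = pair_info[idx]
            if read.strand != pair.strand:
                continue  # sense reads only
            up, down = pair.upstream, pair.downstream
            in_up = _overlap((read.start, read.end), (up.start, up.end)) > 0
            in_down = _overlap((read.start, read.end), (down.start, down.end)) > 0
            if not (in_up or in_down):
                continue
            n_reads += 1
            counts = per_pair_counts.setdefault(idx, [0, 0, 0])
            if in_up:
                counts[0] += 1
            if in_down:
                counts[1] += 1
            hits_up_exon = any(
                _overlap(b, e) > 0 for b in read.blocks for e in up.exons
            )
            hits_down_exon = any(
                _overlap(b, e) > 0 for b in read.blocks for e in down.exons
            )
            if hits_up_exon and hits_down_exon:
                dual_reads += 1
                counts[2] += 1
            # CPA-overlap: the read spans the upstream gene's 3' boundary
            cpa = up.cpa
            if read.start < cpa < read.end:
                n_cpa += 1
                if stir is not None:
                    ext = _overlap((read.start, read.end), (stir.start, stir.end))
                    if ext >= min_extension:
                        n_cpa_ext += 1
            if stir is not None and in_up:
                if _overlap((read.start, read.end), (stir.start, stir.end)) > 0:
                    gene_stir_reads[idx] = gene_stir_reads.get(idx, 0) + 1

    eligible = [c for c in per_pair_counts.values() if c[0] >= 10 and c[1] >= 10]
    n_upstream = len({i for i, _ in enumerate(pair_info)})
    frac = lambda num, den: (num / den) if den else None
    return ReadthroughSummary(
        dual_exon_read_fraction=frac(dual_reads, n_reads),
        dual_pair_fraction=frac(
            sum(1 for c in eligible if c[2] >= 2), len(eligible)
        ),
        cpa_extension_fraction=frac(n_cpa_ext, n_cpa),
        gene_and_stir_fraction=frac(
            sum(1 for v in gene_stir_reads.values() if v >= 2), len(pair_info)
        )
        if pair_info
        else None,
        n_reads=n_reads,
        n_eligible_pairs=len(eligible),
        n_cpa_reads=n_cpa,
        n_upstream_genes=n_upstream,
    )
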