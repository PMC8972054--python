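"""Gene flattening, pair orientation/distance classification, STIR
extraction and long-read classification."""

import numpy as np
import pytest

from stirkit import annotation_core as ac
from stirkit.annotation_core import LongRead

from conftest import make_gene, make_region


class TestFlatten:
    def test_single_transcript_identity(self):
        genes = ac.flatten_transcripts([("g1", "chr1", "+", [(100, 500)])])
        assert len(genes) == 1
        g = genes[0]
        assert (g.start, g.end) == (100, 500)

    def test_min_start_max_end_over_isoforms(self):
        genes = ac.flatten_transcripts(
            [
                ("g1", "chr1", "+", [(100, 500)]),
                ("g1", "chr1", "+", [(300, 900)]),
            ]
        )
        assert (genes[0].start, genes[0].end) == (100, 900)

    def test_gene_counts_preserved(self):
        genes = ac.flatten_transcripts(
            [
                ("a", "chr1", "+", [(0, 100)]),
                ("b", "chr1", "-", [(500, 900)]),
            ]
        )
        assert sorted(g.gene_id for g in genes) == ["a", "b"]

    def test_conflicting_records_rejected(self, caplog):
        genes = ac.flatten_transcripts(
            [
                ("g1", "chr1", "+", [(0, 100)]),
                ("g1", "chr2", "+", [(0, 100)]),
                ("ok", "chr1", "+", [(0, 100)]),
            ]
        )
        assert [g.gene_id for g in genes] == ["ok"]

    def test_excluded_chromosome_dropped(self):
        genes = ac.flatten_transcripts(
            [("g1", "chrY", "+", [(0, 100)]), ("g2", "chrX", "+", [(0, 100)])]
        )
        assert [g.gene_id for g in genes] == ["g2"]

    def test_flattening_is_idempotent(self):
        genes = ac.flatten_transcripts(
            [("g1", "chr1", "+", [(100, 200), (400, 500)])]
        )
        again = ac.flatten_transcripts(
            [(g.gene_id, g.chrom, g.strand, tx) for g in genes for tx in g.transcripts]
        )
        assert (again[0].start, again[0].end) == (genes[0].start, genes[0].end)


class TestIntronLength:
    @pytest.mark.parametrize(
        "records, expected",
        [
            ([("g", "chr1", "+", [(0, 100), (200, 300)])], 100.0),
            ([("g", "chr1", "+", [(0, 100)])], 0.0),
            (
                [
                    ("g", "chr1", "+", [(0, 100), (200, 300)]),  # intron 100
                    ("g", "chr1", "+", [(0, 100), (400, 500)]),  # intron 300
                ],
                200.0,
            ),
        ],
    )
    def test_mean_total_intron(self, records, expected):
        assert ac.total_intron_length(records)["g"] == expected


class TestPairing:
    def test_tandem_pair_geometry(self):
        a = make_gene("A", 0, 6000, "+")
        b = make_gene("B", 6500, 12000, "+")
        (pair,) = ac.pair_adjacent_genes([a, b])
        assert pair.orientation == ac.TANDEM
        assert pair.gap_bp == 500
        assert pair.upstream.gene_id == "A"

    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            ("+", "+", ac.TANDEM),
            ("-", "-", ac.TANDEM),
            ("+", "-", ac.CONVERGENT),
            ("-", "+", ac.DIVERGENT),
        ],
    )
    def test_orientation_truth_table(self, s1, s2, expected):
        a = make_gene("A", 0, 6000, s1)
        b = make_gene("B", 6500, 12000, s2)
        (pair,) = ac.pair_adjacent_genes([a, b])
        assert pair.orientation == expected

    def test_length_bounds_filter(self):
        a = make_gene("A", 0, 3000)  # too short
        b = make_gene("B", 6500, 12000)
        assert ac.pair_adjacent_genes([a, b]) == []

    def test_duplicate_ids_error(self):
        a = make_gene("A", 0, 6000)
        b = make_gene("A", 6500, 12000)
        with pytest.raises(ValueError, match="duplicate"):
            ac.pair_adjacent_genes([a, b])

    def test_matches_bruteforce_nearest_neighbor_oracle(self, rng):
        genes = _random_nonoverlapping_genes(rng, n=50)
        pairs = ac.pair_adjacent_genes(genes, min_len=1, max_len=10**9)
        got = {(p.left_gene.gene_id, p.right_gene.gene_id) for p in pairs}
        assert got == _oracle_pairs(genes)

    def test_gap_symmetric_and_nonnegative(self, rng):
        genes = _random_nonoverlapping_genes(rng, n=30)
        for p in ac.pair_adjacent_genes(genes, min_len=1, max_len=10**9):
            assert p.gap_bp >= 0
            assert p.gap_bp == p.right_gene.start - p.left_gene.end


def _random_nonoverlapping_genes(rng, n):
    genes, cursor = [], 0
    for i in range(n):
        cursor += int(rng.integers(1, 3000))
        length = int(rng.integers(500, 8000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(make_gene(f"g{i:03d}", cursor, cursor + length, strand))
        cursor += length
    return genes


def _oracle_pairs(genes):
    """Exhaustive all-pairs nearest-non-overlapping-neighbor oracle."""
    chosen = set()
    for g in genes:
        right = [h for h in genes if h.chrom == g.chrom and h.start >= g.end]
        left = [h for h in genes if h.chrom == g.chrom and h.end <= g.start]
        if right:
            nn = min(right, key=lambda h: (h.start - g.end, h.gene_id))
            chosen.add(tuple(sorted((g.gene_id, nn.gene_id))))
        if left:
            nn = min(left, key=lambda h: (g.start - h.end, h.gene_id))
            chosen.add(tuple(sorted((g.gene_id, nn.gene_id))))
    return chosen


class TestDistanceBins:
    def _pairs_with_gaps(self, gaps):
        pairs = []
        cursor = 0
        for i, gap in enumerate(gaps):
            a = make_gene(f"a{i}", cursor, cursor + 6000)
            b = make_gene(f"b{i}", cursor + 6000 + gap, cursor + 12000 + gap)
            pairs.append(
                ac.GenePair(a, b, ac.TANDEM, gap, abs(a.tss - b.tss))
            )
            cursor += 200_000
        return pairs

    def test_default_edges_binning(self):
        counts = ac.bin_pairs_by_distance(
            self._pairs_with_gaps([500, 1999, 2000, 4999, 60000])
        )
        t = counts[ac.TANDEM]
        assert t["[0,2000)"] == 2
        assert t["[2000,5000)"] == 2
        assert t["[5000,50000)"] == 0
        assert t["[50000,inf)"] == 1

    def test_zero_gaps_in_first_bin(self):
        counts = ac.bin_pairs_by_distance(self._pairs_with_gaps([0, 0, 0]))
        assert counts[ac.TANDEM]["[0,2000)"] == 3

    def test_counts_partition_pairs(self, rng):
        gaps = [int(g) for g in rng.integers(0, 100_000, 40)]
        counts = ac.bin_pairs_by_distance(self._pairs_with_gaps(gaps))
        total = sum(v for d in counts.values() for v in d.values())
        assert total == len(gaps)

    def test_nonmonotone_edges_error(self):
        with pytest.raises(ValueError):
            ac.bin_pairs_by_distance([], bin_edges=[0, 5000, 2000])


class TestStirExtraction:
    def test_plus_strand_stir(self):
        a = make_gene("A", 0, 6000, "+")
        b = make_gene("B", 6500, 12000, "+")
        (pair,) = ac.pair_adjacent_genes([a, b])
        (stir,) = ac.extract_stirs([pair])
        assert (stir.start, stir.end, stir.strand) == (6000, 6500, "+")
        assert stir.anchor_gene_ids == ["A", "B"]  # upstream first

    def test_minus_strand_anchor_is_right_gene_cpa(self):
        b = make_gene("B", 0, 6000, "-")
        a = make_gene("A", 6500, 12000, "-")
        (pair,) = ac.pair_adjacent_genes([b, a])
        (stir,) = ac.extract_stirs([pair])
        assert (stir.start, stir.end) == (6000, 6500)
        # upstream gene is A (rightmost on minus strand); its CPA = 6500
        assert stir.anchor_gene_ids[0] == "A"
        assert pair.upstream.cpa == 6500

    def test_gap_above_cutoff_not_emitted(self):
        a = make_gene("A", 0, 6000, "+")
        b = make_gene("B", 8500, 15000, "+")
        (pair,) = ac.pair_adjacent_genes([a, b])
        assert ac.extract_stirs([pair], max_gap=2000) == []

    def test_recovers_planted_gaps(self, small_annotation):
        _, ann = small_annotation
        pairs = [
            p for p in ac.pair_adjacent_genes(ann.genes)
            if p.orientation == ac.TANDEM and 0 < p.gap_bp < 2000
        ]
        stirs = ac.extract_stirs(pairs)
        got = {(s.start, s.end) for s in stirs}
        expected = {(u.stir_start, u.stir_end) for u in ann.tandem_units}
        assert got == expected


class TestLongReads:
    def _pair_and_stir(self):
        a = make_gene("A", 0, 6000, "+", exons=[(0, 2000), (4000, 6000)])
        b = make_gene("B", 6500, 12500, "+", exons=[(6500, 8000), (10000, 12500)])
        (pair,) = ac.pair_adjacent_genes([a, b])
        stirs = ac.extract_stirs([pair])
        return pair, stirs

    def _read(self, name, start, end, strand="+", blocks=None):
        return LongRead(name, "chr1", start, end, strand, blocks or [(start, end)])

    def test_read_inside_gene_is_not_dual(self):
        pair, stirs = self._pair_and_stir()
        s = ac.classify_long_reads([self._read("r", 100, 1500)], [pair], stirs)
        assert s.dual_exon_read_fraction == 0.0

    def test_dual_fraction_matches_toy_construction(self):
        pair, stirs = self._pair_and_stir()
        reads = [self._read(f"r{i}", 100, 1500) for i in range(9)]
        reads.append(self._read("dual", 1500, 7000))  # spans exons of A and B
        s = ac.classify_long_reads(reads, [pair], stirs)
        assert s.dual_exon_read_fraction == pytest.approx(0.1)

    @pytest.mark.parametrize("extension, counted", [(60, 1.0), (49, 0.0)])
    def test_cpa_extension_threshold(self, extension, counted):
        pair, stirs = self._pair_and_stir()
        read = self._read("r", 5500, 6000 + extension)  # spans CPA at 6000
        s = ac.classify_long_reads([read], [pair], stirs)
        assert s.cpa_extension_fraction == counted

    def test_antisense_reads_ignored(self):
        pair, stirs = self._pair_and_stir()
        s = ac.classify_long_reads(
            [self._read("r", 100, 1500, strand="-")], [pair], stirs
        )
        assert s.n_reads == 0
        assert s.dual_exon_read_fraction is None

    def test_no_reads_gives_undefined_not_zero(self):
        pair, stirs = self._pair_and_stir()
        s = ac.classify_long_reads([], [pair], stirs)
        assert s.dual_exon_read_fraction is None
        assert s.cpa_extension_fraction is None

    def test_bruteforce_overlap_oracle_on_random_reads(self, rng):
        pair, stirs = self._pair_and_stir()
        reads = []
        for i in range(200):
            start = int(rng.integers(0, 12000))
            end = start + int(rng.integers(50, 4000))
            reads.append(self._read(f"r{i}", start, end))
        s = ac.classify_long_reads(reads, [pair], stirs)
        up, down = pair.upstream, pair.downstream

        def hits(read, gene):
            return any(
                min(read.end, e) - max(read.start, s0) > 0 for s0, e in gene.exons
            )

        assigned = [
            r for r in reads
            if min(r.end, up.end) > max(r.start, up.start)
            or min(r.end, down.end) > max(r.start, down.start)
        ]
        dual = [r for r in assigned if hits(r, up) and hits(r, down)]
        assert s.n_reads == len(assigned)
        assert s.dual_exon_read_fraction == pytest.approx(len(dual) / len(assigned))
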