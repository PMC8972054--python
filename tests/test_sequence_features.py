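"""Composition profiles, repeat occupancy, motif scanning/enrichment and
the dinucleotide-preserving shuffle."""

import itertools
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stirkit import sequence_features as sf
from stirkit._stats import paired_signed_rank

from conftest import make_region


class TestComposition:
    def test_pure_g_sequence(self):
        fr = sf.nucleotide_fractions({"s": "GGGG"})
        assert fr.loc["s", "G"] == 1.0

    def test_n_excluded_from_denominator(self):
        fr = sf.nucleotide_fractions({"s": "GGNN"})
        assert fr.loc["s", "G"] == 1.0

    def test_all_n_sequence_excluded(self):
        fr = sf.nucleotide_fractions({"s": "NNNN", "t": "ACGT"})
        assert list(fr.index) == ["t"]

    def test_fractions_match_counting_oracle(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=50))
            for i in range(20)
        }
        fr = sf.nucleotide_fractions(seqs)
        for sid, seq in seqs.items():
            for nt in "ACGT":
                assert fr.loc[sid, nt] == pytest.approx(seq.count(nt) / len(seq))

    def test_fractions_sum_to_one(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGTN"), size=60)) for i in range(10)}
        fr = sf.nucleotide_fractions(seqs)
        assert np.allclose(fr.sum(axis=1), 1.0)


class TestBinnedProfile:
    def test_acgt_repeats_uniform_quarter(self):
        ids, prof = sf.binned_composition_profile({"s": "ACGT" * 24}, n_bins=4)
        assert prof.shape == (1, 4, 4)
        assert np.allclose(prof, 0.25)

    def test_all_g_vs_all_g_controls_p_one(self):
        seqs = {f"s{i}": "G" * 80 for i in range(6)}
        ids, stir = sf.binned_composition_profile(seqs, n_bins=4)
        _, ctrl = sf.binned_composition_profile(seqs, n_bins=4)
        p = sf.per_bin_composition_tests(stir, ctrl)
        assert np.all(p == 1.0)

    def test_constant_shift_exact_signed_rank_p(self):
        # 6 paired profiles, all differences positive in every bin:
        # exact two-sided p = 2/2^6 = 0.03125 before correction
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.4, size=(6, 4, 4))
        stir = base + 0.05
        p = sf.per_bin_composition_tests(stir, base)
        assert np.allclose(p, np.minimum(0.03125 * 4, 1.0))

    def test_short_sequences_lower_bin_count(self):
        ids, prof = sf.binned_composition_profile({"s": "ACGTACGT"}, n_bins=70)
        assert prof.shape[1] == 8

    def test_bin_spans_are_partition(self, rng):
        for L in rng.integers(70, 2000, 20):
            spans = sf.bin_spans(int(L), 70)
            assert spans[0][0] == 0 and spans[-1][1] == L
            assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))


class TestRepeatOccupancy:
    def _repeats(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand", "class"])

    def test_region_inside_line_fully_covered(self):
        region = make_region(1000, 1200)
        reps = self._repeats([("chr1", 0, 5000, "L1", 0, "+", "LINE")])
        _, prof = sf.repeat_occupancy_profile([region], reps, n_bins=4)
        assert np.allclose(prof, 1.0)

    def test_half_covered_region(self):
        region = make_region(0, 1000)
        reps = self._repeats([("chr1", 0, 500, "L1", 0, "+", "LINE")])
        _, prof = sf.repeat_occupancy_profile([region], reps, n_bins=4)
        assert prof.mean() == pytest.approx(0.5)
        assert np.allclose(prof[0], [1, 1, 0, 0])

    def test_simple_repeats_excluded(self):
        region = make_region(0, 1000)
        reps = self._repeats([("chr1", 0, 1000, "sr", 0, "+", "Simple_repeat")])
        _, prof = sf.repeat_occupancy_profile([region], reps, n_bins=4)
        assert np.allclose(prof, 0.0)

    def test_minus_strand_profile_reversed(self):
        reps = self._repeats([("chr1", 0, 500, "L1", 0, "+", "LINE")])
        _, plus = sf.repeat_occupancy_profile([make_region(0, 1000, "+")], reps, 4)
        _, minus = sf.repeat_occupancy_profile([make_region(0, 1000, "-")], reps, 4)
        assert np.allclose(minus[0], plus[0][::-1])


IUPAC_ORACLE = {
    c: set(exp.strip("[]")) for c, exp in sf.IUPAC.items()
}


def naive_motif_count(seq, pattern):
    """Sliding-window IUPAC matcher, position by position."""
    n = 0
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + j] in IUPAC_ORACLE[c] for j, c in enumerate(pattern)):
            n += 1
    return n


class TestMotifScan:
    def test_exact_single_occurrence(self):
        counts = sf.scan_motif({"s": "GGGGCGGGG"}, sf.MotifSpec("GGGGCGGGG"))
        assert counts["s"] == 1

    def test_overlapping_matches_counted(self):
        counts = sf.scan_motif({"s": "GGGGAGGGGAGGGG"}, sf.MotifSpec("GGGGAGGGG"))
        assert counts["s"] == 2

    def test_strand_modes(self):
        seq = {"s": "CCCCTCCCC"}
        assert sf.scan_motif(seq, sf.MotifSpec("GGGGAGGGG", "RNA"))["s"] == 0
        assert sf.scan_motif(seq, sf.MotifSpec("GGGGAGGGG", "DNA"))["s"] == 1

    def test_pattern_longer_than_sequence(self):
        assert sf.scan_motif({"s": "GG"}, sf.MotifSpec("GGGG"))["s"] == 0

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            sf.MotifSpec("GGX")

    def test_iupac_degenerate_positions(self):
        counts = sf.scan_motif({"s": "GGGGCGGGGGC"}, sf.MotifSpec("GGGGCGGGGSC"))
        assert counts["s"] == 1

    def test_matches_naive_oracle_on_random_sequences(self, rng):
        for pattern in ("GGGGNGGGG", "GSG", "CCTTCCC"):
            spec = sf.MotifSpec(pattern, "DNA")
            for _ in range(100):
                seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 60))))
                expected = naive_motif_count(seq, pattern) + naive_motif_count(
                    seq, spec.reverse_complement
                )
                assert sf.scan_motif({"s": seq}, spec)["s"] == expected


class TestEnrichmentTable:
    def _counts(self, prevalences, n, rng, motif="M"):
        """Binary (0/1-occurrence) count tables at given per-group prevalence."""
        return {
            g: pd.DataFrame({motif: (rng.random(n) < p).astype(int)})
            for g, p in prevalences.items()
        }

    def test_planted_enrichment_passes_filter(self, rng):
        tabs = self._counts({"s": 0.5, "p": 0.1, "t": 0.1}, 400, rng)
        table = sf.motif_enrichment_table(tabs["s"], tabs["p"], tabs["t"])
        assert "M" in table.index
        # planted ratio 5 within binomial error
        assert table.loc["M", "min_ratio_prevalence"] == pytest.approx(5.0, rel=0.35)
        assert table.loc["M", "p_promoter"] < 0.05

    def test_absent_motif_dropped(self):
        zeros = pd.DataFrame({"M": [0] * 10})
        table = sf.motif_enrichment_table(zeros, zeros.copy(), zeros.copy())
        assert table.empty

    def test_one_sided_enrichment_dropped(self, rng):
        tabs = self._counts({"s": 0.5, "p": 0.8, "t": 0.1}, 200, rng)
        table = sf.motif_enrichment_table(tabs["s"], tabs["p"], tabs["t"])
        assert table.empty

    def test_rank_order_by_min_ratio_ranks(self, rng):
        s = pd.DataFrame({"strong": (rng.random(300) < 0.6).astype(int),
                          "weak": (rng.random(300) < 0.3).astype(int)})
        p = pd.DataFrame({"strong": (rng.random(300) < 0.1).astype(int),
                          "weak": (rng.random(300) < 0.2).astype(int)})
        t = p.copy()
        table = sf.motif_enrichment_table(s, p, t)
        assert list(table.index) == ["strong", "weak"]

    def test_empty_group_errors(self):
        df = pd.DataFrame({"M": [1]})
        with pytest.raises(ValueError):
            sf.motif_enrichment_table(df, pd.DataFrame(), df)


class TestDinucleotideShuffle:
    def test_homopolymer_fixed_point(self):
        assert sf.dinucleotide_shuffle("AAAA", 0) == "AAAA"

    def test_acgt_unique_arrangement(self):
        # brute force: ACGT is the only permutation with dinucleotides
        # {AC, CG, GT} and those endpoints
        valid = [
            "".join(p)
            for p in itertools.permutations("ACGT")
            if sf.dinucleotide_counts("".join(p)) == sf.dinucleotide_counts("ACGT")
            and p[0] == "A" and p[-1] == "T"
        ]
        assert valid == ["ACGT"]
        for seed in range(5):
            assert sf.dinucleotide_shuffle("ACGT", seed) == "ACGT"

    def test_endpoints_preserved(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=30))
            out = sf.dinucleotide_shuffle(seq, 1)
            assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_seeded_determinism(self):
        seq = "ACGTGCA" * 10
        assert sf.dinucleotide_shuffle(seq, 42) == sf.dinucleotide_shuffle(seq, 42)

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=2, max_size=60), st.integers(0, 2**20))
    def test_dinucleotide_counts_always_preserved(self, seq, seed):
        out = sf.dinucleotide_shuffle(seq, seed)
        assert sf.dinucleotide_counts(out) == sf.dinucleotide_counts(seq)


class TestShuffleNull:
    def test_absent_motif_p_one(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACT"), size=40)) for i in range(5)}
        p, null = sf.shuffle_motif_null(seqs, sf.MotifSpec("GGGG"), n_shuffles=20, seed=0)
        assert p == 1.0

    def test_single_nucleotide_motif_invariant_p_one(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=40)) for i in range(5)}
        p, null = sf.shuffle_motif_null(seqs, sf.MotifSpec("G"), n_shuffles=20, seed=0)
        assert p == 1.0
        assert np.all(null == null[0])

    def test_planted_motif_minimal_p(self, rng):
        # a long specific motif in every sequence over random background:
        # no shuffle retains it in all sequences
        motif = "GGGGCGGGG"
        seqs = {}
        for i in range(10):
            bg = "".join(rng.choice(list("ACGT"), size=100))
            seqs[f"s{i}"] = bg[:50] + motif + bg[50:]
        n = 1000
        p, _ = sf.shuffle_motif_null(seqs, sf.MotifSpec(motif), n_shuffles=n, seed=0)
        assert p == pytest.approx(1 / (n + 1))
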