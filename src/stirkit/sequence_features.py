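"""Sequence-level analysis of STIRs vs matched controls: nucleotide
composition (overall and binned along the region), repeat occupancy,
IUPAC motif scanning and prevalence statistics, and a
dinucleotide-preserving shuffle null.

All sequences are oriented 5'->3' on the transcribed strand; minus-strand
regions are reverse-complemented at extraction time (see
:func:`stirkit.io.extract_region_sequences`).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import bonferroni, paired_signed_rank, proportion_test

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
DEFAULT_N_BINS = 70

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

MODE_RNA = "RNA"  # transcribed strand only
MODE_DNA = "DNA"  # both strands


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC motif and the strand mode it is scanned in."""

    pattern: str
    mode: str = MODE_RNA

    def __post_init__(self) -> None:
        if not self.pattern or any(c not in IUPAC for c in self.pattern.upper()):
            raise ValueError(f"invalid IUPAC pattern {self.pattern!r}")
        if self.mode not in (MODE_RNA, MODE_DNA):
            raise ValueError(f"mode must be {MODE_RNA!r} or {MODE_DNA!r}")

    @property
    def reverse_complement(self) -> str:
        return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(self.pattern.upper()))


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def nucleotide_fractions(seqs: Mapping[str, str]) -> pd.DataFrame:
    """Per-sequence A/C/G/T fractions; Ns are excluded from the denominator.

    All-N sequences are excluded with a diagnostic.
    """
    rows, ids = [], []
    for sid, seq in seqs.items():
        s = seq.upper()
        counts = np.array([s.count(n) for n in NUCLEOTIDES], dtype=float)
        total = counts.sum()
        if total == 0:
            logger.warning("sequence %s has no unambiguous bases; excluded", sid)
            continue
        rows.append(counts / total)
        ids.append(sid)
    return pd.DataFrame(rows, index=ids, columns=list(NUCLEOTIDES))


def overall_composition(
    stir_fracs: pd.DataFrame,
    promoter_fracs: pd.DataFrame,
    three_prime_fracs: pd.DataFrame,
) -> pd.DataFrame:
    """Group mean/SD composition plus paired tests of STIRs vs each control.

    Controls must already be aggregated per focal region (quintet means) and
    row-aligned with the STIR table.  Bonferroni family: 4 nucleotides x 2
    controls.
    """
    out = {}
    for nt in NUCLEOTIDES:
        rec = {
            "stir_mean": stir_fracs[nt].mean(),
            "stir_sd": stir_fracs[nt].std(ddof=1),
            "promoter_mean": promoter_fracs[nt].mean(),
            "promoter_sd": promoter_fracs[nt].std(ddof=1),
            "three_prime_mean": three_prime_fracs[nt].mean(),
            "three_prime_sd": three_prime_fracs[nt].std(ddof=1),
        }
        for label, ctrl in (("promoter", promoter_fracs), ("three_prime", three_prime_fracs)):
            common = stir_fracs.index.intersection(ctrl.index)
            p = paired_signed_rank(stir_fracs.loc[common, nt], ctrl.loc[common, nt])
            rec[f"p_vs_{label}"] = float(bonferroni(p, 4 * 2))
        out[nt] = rec
    return pd.DataFrame(out).T


def bin_spans(length: int, n_bins: int) -> list[tuple[int, int]]:
    """Deterministic near-equal binning: bin b spans
    [floor(b*L/n), floor((b+1)*L/n))."""
    return [
        (length * b // n_bins, length * (b + 1) // n_bins) for b in range(n_bins)
    ]


def effective_n_bins(lengths: Sequence[int], n_bins: int = DEFAULT_N_BINS) -> int:
    """Lower the bin count to the minimal sequence length when needed."""
    m = min(lengths)
    if m < n_bins:
        logger.warning("shortest sequence (%d bp) < %d bins; using %d bins", m, n_bins, m)
        return m
    return n_bins


def binned_composition_profile(
    seqs: Mapping[str, str], n_bins: int = DEFAULT_N_BINS
) -> tuple[list[str], np.ndarray]:
    """Split each sequence into near-equal bins and compute per-bin
    nucleotide fractions.

    Returns (ids, array of shape (n_seqs, n_bins, 4)) with the nucleotide
    axis ordered A, C, G, T.  ``n_bins`` is reduced to the minimal sequence
    length if any sequence is shorter than the requested bin count.
    """
    ids = list(seqs)
    n_bins = effective_n_bins([len(seqs[i]) for i in ids], n_bins)
    out = np.zeros((len(ids), n_bins, 4))
    for i, sid in enumerate(ids):
        s = seqs[sid].upper()
        for b, (lo, hi) in enumerate(bin_spans(len(s), n_bins)):
            chunk = s[lo:hi]
            counts = np.array([chunk.count(n) for n in NUCLEOTIDES], dtype=float)
            tot = counts.sum()
            out[i, b] = counts / tot if tot else np.nan
    return ids, out


def per_bin_composition_tests(
    stir_profile: np.ndarray, control_profile: np.ndarray
) -> np.ndarray:
    """Per-bin, per-nucleotide Bonferroni-corrected paired signed-rank
    p-values (family = number of bins) for row-aligned profiles."""
    if stir_profile.shape != control_profile.shape:
        raise ValueError("profiles must be row-aligned and equally binned")
    _, n_bins, n_nt = stir_profile.shape
    p = np.ones((n_bins, n_nt))
    for b in range(n_bins):
        for k in range(n_nt):
            p[b, k] = paired_signed_rank(stir_profile[:, b, k], control_profile[:, b, k])
    return bonferroni(p, n_bins)


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

EXCLUDED_REPEAT_CLASSES = frozenset({"Simple_repeat", "Low_complexity"})


def repeat_occupancy_profile(
    regions,
    repeats: pd.DataFrame,
    n_bins: int = DEFAULT_N_BINS,
    excluded_classes: frozenset[str] = EXCLUDED_REPEAT_CLASSES,
) -> tuple[list[str], np.ndarray]:
    """Binned fraction of bases covered by >= 1 retained repeat per region.

    ``repeats`` needs chrom/start/end plus a ``class`` column; simple and
    low-complexity classes are excluded.  Rows are oriented 5'->3' on the
    region strand.
    """
    if "class" in repeats.columns:
        repeats = repeats[~repeats["class"].isin(excluded_classes)]
    by_chrom = {c: df for c, df in repeats.groupby("chrom")}
    ids, rows = [], []
    n_bins = effective_n_bins([r.length for r in regions], n_bins)
    for r in regions:
        cov = np.zeros(r.length, dtype=bool)
        for _, rep in by_chrom.get(r.chrom, pd.DataFrame()).iterrows():
            lo = max(int(rep["start"]), r.start)
            hi = min(int(rep["end"]), r.end)
            if hi > lo:
                cov[lo - r.start:hi - r.start] = True
        if r.strand == "-":
            cov = cov[::-1]
        rows.append([cov[lo:hi].mean() for lo, hi in bin_spans(r.length, n_bins)])
        ids.append(r.name)
    return ids, np.asarray(rows)


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("(?=(" + "".join(IUPAC[c] for c in pattern.upper()) + "))")


def scan_motif(seqs: Mapping[str, str], motif: MotifSpec) -> pd.Series:
    """Overlapping occurrence counts of the motif per sequence.

    DNA mode additionally counts reverse-complement matches on the same
    coordinates; RNA mode scans the transcribed strand only.
    """
    patterns = [_iupac_regex(motif.pattern)]
    if motif.mode == MODE_DNA and motif.reverse_complement != motif.pattern.upper():
        patterns.append(_iupac_regex(motif.reverse_complement))
    counts = {
        sid: sum(len(p.findall(seq.upper())) for p in patterns)
        for sid, seq in seqs.items()
    }
    return pd.Series(counts, dtype=int)


def motif_enrichment_table(
    stir_counts: pd.DataFrame,
    promoter_counts: pd.DataFrame,
    three_prime_counts: pd.DataFrame,
) -> pd.DataFrame:
    """Prevalence/occurrence statistics and ranking for a motif panel.

    Inputs are per-group count tables (rows sequences, columns motifs;
    control sequences pooled).  Motifs are kept only when the STIR group is
    higher than *both* controls in *both* measures (prevalence = fraction of
    sequences with >= 1 occurrence; mean occurrences per sequence).  Kept
    motifs get two-proportion tests vs each control (Bonferroni over the
    tests performed) and are ordered by the ascending sum of their two
    min-ratio ranks.
    """
    for df in (promoter_counts, three_prime_counts):
        if df.empty or stir_counts.empty:
            raise ValueError("empty count table")
    rows = {}
    for motif in stir_counts.columns:
        s = stir_counts[motif]
        p = promoter_counts[motif]
        t = three_prime_counts[motif]
        prev = {g: (c > 0).mean() for g, c in (("stir", s), ("prom", p), ("3p", t))}
        mean = {g: c.mean() for g, c in (("stir", s), ("prom", p), ("3p", t))}
        keep = (
            prev["stir"] > prev["prom"] and prev["stir"] > prev["3p"]
            and mean["stir"] > mean["prom"] and mean["stir"] > mean["3p"]
        )
        ratios_prev = [
            prev["stir"] / prev[g] for g in ("prom", "3p") if prev[g] > 0
        ]
        ratios_mean = [
            mean["stir"] / mean[g] for g in ("prom", "3p") if mean[g] > 0
        ]
        rows[motif] = {
            "prevalence_stir": prev["stir"],
            "prevalence_promoter": prev["prom"],
            "prevalence_three_prime": prev["3p"],
            "mean_occ_stir": mean["stir"],
            "mean_occ_promoter": mean["prom"],
            "mean_occ_three_prime": mean["3p"],
            "min_ratio_prevalence": min(ratios_prev) if ratios_prev else np.nan,
            "min_ratio_occurrence": min(ratios_mean) if ratios_mean else np.nan,
            "kept": keep,
            "raw_p_promoter": proportion_test(
                int((s > 0).sum()), len(s), int((p > 0).sum()), len(p)
            ),
            "raw_p_three_prime": proportion_test(
                int((s > 0).sum()), len(s), int((t > 0).sum()), len(t)
            ),
        }
    table = pd.DataFrame(rows).T
    kept = table[table["kept"].astype(bool)].copy()
    if not kept.empty:
        family = 2 * len(kept)
        kept["p_promoter"] = bonferroni(kept["raw_p_promoter"].astype(float), family)
        kept["p_three_prime"] = bonferroni(kept["raw_p_three_prime"].astype(float), family)
        r1 = kept["min_ratio_prevalence"].rank(ascending=False)
        r2 = kept["min_ratio_occurrence"].rank(ascending=False)
        kept["rank_sum"] = r1 + r2
        kept = kept.loc[
            sorted(kept.index, key=lambda m: (kept.loc[m, "rank_sum"], m))
        ]
    return kept.drop(columns=["kept", "raw_p_promoter", "raw_p_three_prime"],
                     errors="ignore")


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle
# ---------------------------------------------------------------------------

def dinucleotide_counts(seq: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out


def dinucleotide_shuffle(seq: str, rng: np.random.Generator | int) -> str:
    """Shuffle a sequence preserving its exact dinucleotide count vector
    (Altschul-Erickson Eulerian-path shuffle).

    The first and last characters are preserved; output is deterministic
    for a given seed/generator.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last_char = seq[-1]

    # pick a random "last edge" per vertex so that following last edges from
    # any vertex reaches the terminal character (guarantees an Eulerian path)
    sources = [u for u in edges if u != last_char]
    while True:
        last = {u: edges[u][rng.integers(len(edges[u]))] for u in sources}
        ok = True
        for u in sources:
            seen, v = set(), u
            while v != last_char:
                if v in seen or v not in last:
                    ok = False
                    break
                seen.add(v)
                v = last[v]
            if not ok:
                break
        if ok:
            break

    shuffled: dict[str, list[str]] = {}
    for u, targets in edges.items():
        pool = list(targets)
        if u in last:
            pool.remove(last[u])
        order = rng.permutation(len(pool))
        lst = [pool[i] for i in order]
        if u in last:
            lst.append(last[u])
        shuffled[u] = lst

    out = [seq[0]]
    pos = {u: 0 for u in shuffled}
    v = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[v][pos[v]]
        pos[v] += 1
        out.append(nxt)
        v = nxt
    return "".join(out)


def shuffle_motif_null(
    seqs: Mapping[str, str],
    motif: MotifSpec,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Empirical motif-prevalence p-value against dinucleotide-preserving
    shuffles of the same sequences.

    Returns (p, null prevalence distribution) with
    p = (1 + #{null >= observed}) / (n_shuffles + 1).
    """
    observed = float((scan_motif(seqs, motif) > 0).mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuffled = {sid: dinucleotide_shuffle(s, rng) for sid, s in seqs.items()}
        null[i] = (scan_motif(shuffled, motif) > 0).mean()
    p = (1 + int((null >= observed).sum())) / (n_shuffles + 1)
    return p, null
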