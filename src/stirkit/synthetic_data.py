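"""Synthetic inputs with planted statistical structure.

Every input the pipeline consumes can be generated here: annotations with
configurable pair orientations and gaps, a genome with class-specific base
composition and planted motifs, strand-aware signal tracks with a planted
STIR accumulation component, peak sets with per-class prevalences,
expression tables with coupled tandem expression, knockdown log2FC tables
with planted upstream/downstream effects, and long reads with a planted
CPA-readthrough rate.  Each generator draws from its own named substream of
a single integer seed, so adding a generator never perturbs the others.

Defaults mirror the study conditions: GC content 58% in STIRs vs 55%/46%
near control promoters / 3' ends; lead-motif prevalence ~33%/22%/3% across
the three region classes; 5 kb-isolated control genes; gaps below 2 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_core import GeneModel, LongRead, Region, ROLE_STIR
from .signal_metagene import SignalTrack

_STREAMS = {
    "annotation": 1,
    "sequence": 2,
    "track": 3,
    "peaks": 4,
    "kd": 5,
    "reads": 6,
    "expression": 7,
}


def substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[name]])


@dataclass
class SyntheticConfig:
    """Study-condition parameters for all generators."""

    seed: int = 0
    chrom: str = "chr1"
    # geometry
    n_tandem: int = 300
    n_divergent: int = 0
    n_convergent: int = 0
    n_isolated: int = 60
    gene_length_range: tuple[int, int] = (6_000, 9_000)
    gap_range: tuple[int, int] = (300, 1_900)
    unit_spacing: int = 6_000
    n_exons: int = 3
    #: gene starts/ends and gaps snap to this grid so signal-track steps
    #: never straddle a gene or STIR boundary
    coordinate_grid: int = 25
    # expression (TPM ~ lognormal; tandem partners coupled on log2 scale)
    tpm_log_mean: float = 2.5
    tpm_log_sd: float = 1.2
    expressed_fraction: float = 0.85
    coexpression_coupling_sd: float = 0.5
    # sequence composition and motif planting
    gc_background: float = 0.46
    gc_stir: float = 0.58
    gc_promoter: float = 0.55
    promoter_window: int = 2_000
    motif: str = "GGGGCGGGG"
    motif_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"stir": 0.33, "promoter": 0.22, "three_prime": 0.03}
    )
    motif_relative_position: float = 0.8
    # signal track (per-base Poisson rates)
    track_step: int = 25
    intergenic_rate: float = 0.2
    gene_body_rate: float = 1.0
    promoter_peak_rate: float = 5.0
    promoter_peak_width: int = 200
    stir_amplitude: float = 5.0
    antisense_rate: float = 0.05
    # ChIP peaks
    peak_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"stir": 0.5, "promoter": 0.25, "three_prime": 0.1}
    )
    peak_width: int = 100
    # knockdown model
    kd_noise_sd: float = 0.2
    kd_concordant_sd: float = 0.2
    kd_n_null_factors: int = 20
    kd_planted_m_up: float = 0.0
    kd_planted_m_down: float = 0.5
    # long reads
    reads_per_gene: int = 20
    cpa_overlap_fraction: float = 0.5
    readthrough_extension_prob: float = 0.9
    min_extension: int = 50
    dual_gene_rate: float = 0.0
    read_length: int = 1_500


@dataclass
class TandemUnit:
    upstream_id: str
    downstream_id: str
    stir_start: int
    stir_end: int
    strand: str
    chrom: str

    @property
    def stir_region(self) -> Region:
        return Region(
            chrom=self.chrom, start=self.stir_start, end=self.stir_end,
            strand=self.strand, role=ROLE_STIR,
            anchor_gene_ids=[self.upstream_id, self.downstream_id],
        )


@dataclass
class Annotation:
    """The generated gene layout plus bookkeeping of what was planted."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]
    tandem_units: list[TandemUnit]
    divergent_ids: list[tuple[str, str]]
    convergent_ids: list[tuple[str, str]]
    isolated_ids: list[str]

    @property
    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    @property
    def stirs(self) -> list[Region]:
        return [u.stir_region for u in self.tandem_units]

    @property
    def upstream_ids(self) -> list[str]:
        return [u.upstream_id for u in self.tandem_units]

    @property
    def downstream_ids(self) -> list[str]:
        return [u.downstream_id for u in self.tandem_units]


def _make_gene(
    gene_id: str, chrom: str, start: int, length: int, strand: str,
    n_exons: int, rng: np.random.Generator,
) -> GeneModel:
    exon_sizes = rng.integers(150, 400, size=n_exons)
    intronic = length - int(exon_sizes.sum())
    if intronic < n_exons - 1:
        exon_sizes = np.full(n_exons, max(50, length // (2 * n_exons)))
        intronic = length - int(exon_sizes.sum())
    cuts = np.sort(rng.integers(1, intronic, size=n_exons - 2)) if n_exons > 2 else np.array([], dtype=int)
    intron_sizes = np.diff(np.concatenate([[0], cuts, [intronic]]))
    exons, pos = [], start
    for i in range(n_exons):
        exons.append((pos, pos + int(exon_sizes[i])))
        pos += int(exon_sizes[i])
        if i < n_exons - 1:
            pos += int(intron_sizes[i])
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=start, end=start + length,
        strand=strand, transcripts=[exons],
        mean_total_intron_length=float(intronic),
    )


def generate_annotation(config: SyntheticConfig) -> Annotation:
    """Lay out tandem/divergent/convergent pair units and isolated genes
    along one chromosome, deterministically per seed.

    Units are separated by ``unit_spacing`` (> the 5 kb isolation cutoff),
    so the planted close pairs are exactly the pairs with gap below 2 kb and
    the isolated genes qualify for the control universe.
    """
    rng = substream(config.seed, "annotation")
    lo_len, hi_len = config.gene_length_range
    lo_gap, hi_gap = config.gap_range
    if lo_len < 1 or lo_gap < 1:
        raise ValueError("lengths and gaps must be positive")
    grid = config.coordinate_grid
    if config.unit_spacing % grid:
        raise ValueError("unit_spacing must sit on the coordinate grid")

    def snap(x: int) -> int:
        return max(grid, (int(x) // grid) * grid)
    genes: list[GeneModel] = []
    units: list[TandemUnit] = []
    divergent: list[tuple[str, str]] = []
    convergent: list[tuple[str, str]] = []
    isolated: list[str] = []
    cursor = config.unit_spacing
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"G{counter:05d}"

    specs = (
        [("tandem", None)] * config.n_tandem
        + [("divergent", ("-", "+"))] * config.n_divergent
        + [("convergent", ("+", "-"))] * config.n_convergent
    )
    for kind, strands in specs:
        l1 = snap(rng.integers(lo_len, hi_len + 1))
        l2 = snap(rng.integers(lo_len, hi_len + 1))
        gap = snap(rng.integers(lo_gap, hi_gap + 1))
        if strands is None:
            s = "+" if rng.random() < 0.5 else "-"
            strands = (s, s)
        a = _make_gene(next_id(), config.chrom, cursor, l1, strands[0], config.n_exons, rng)
        b = _make_gene(next_id(), config.chrom, cursor + l1 + gap, l2, strands[1], config.n_exons, rng)
        genes += [a, b]
        if kind == "tandem":
            up, down = (a, b) if strands[0] == "+" else (b, a)
            units.append(
                TandemUnit(
                    upstream_id=up.gene_id, downstream_id=down.gene_id,
                    stir_start=a.end, stir_end=b.start,
                    strand=strands[0], chrom=config.chrom,
                )
            )
        elif kind == "divergent":
            divergent.append((a.gene_id, b.gene_id))
        else:
            convergent.append((a.gene_id, b.gene_id))
        cursor = b.end + config.unit_spacing

    for _ in range(config.n_isolated):
        L = snap(rng.integers(lo_len, hi_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        g = _make_gene(next_id(), config.chrom, cursor, L, strand, config.n_exons, rng)
        genes.append(g)
        isolated.append(g.gene_id)
        cursor = g.end + config.unit_spacing

    return Annotation(
        genes=genes,
        chrom_sizes={config.chrom: cursor},
        tandem_units=units,
        divergent_ids=divergent,
        convergent_ids=convergent,
        isolated_ids=isolated,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(
    annotation: Annotation, config: SyntheticConfig, samples: Sequence[str] = ("S1",)
) -> pd.DataFrame:
    """Lognormal TPM table; tandem partners are coupled on the log2 scale
    (downstream = upstream * 2**N(0, coupling_sd)), a configured fraction of
    genes is left unexpressed (< 2 TPM)."""
    rng = substream(config.seed, "expression")
    gene_ids = [g.gene_id for g in annotation.genes]
    down_of_up = {u.upstream_id: u.downstream_id for u in annotation.tandem_units}
    out = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"), dtype=float)
    for sample in samples:
        tpm = pd.Series(
            np.exp(rng.normal(config.tpm_log_mean, config.tpm_log_sd, len(gene_ids))),
            index=gene_ids,
        )
        silent = rng.random(len(gene_ids)) > config.expressed_fraction
        tpm[silent] = rng.uniform(0, 2, int(silent.sum()))
        for up, down in down_of_up.items():
            if tpm[up] > 2:  # couple expressed pairs only
                tpm[down] = tpm[up] * 2 ** rng.normal(0, config.coexpression_coupling_sd)
        out[sample] = tpm
    return out


# ---------------------------------------------------------------------------
# genome sequence
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _composition_probs(gc: float) -> np.ndarray:
    at = (1 - gc) / 2
    return np.array([at, gc / 2, gc / 2, at])


def generate_sequences(
    annotation: Annotation, config: SyntheticConfig
) -> dict[str, str]:
    """Genome FASTA content with class-specific composition and motifs.

    Background (and hence 3'-control neighborhoods) at ``gc_background``,
    windows upstream of isolated-gene TSSs at ``gc_promoter``, STIRs at
    ``gc_stir``; the configured motif is planted per class at the configured
    prevalence, on the transcribed strand at ~``motif_relative_position``
    within STIRs and near the anchor for control windows.
    """
    rng = substream(config.seed, "sequence")
    genomes: dict[str, str] = {}
    motif = config.motif.upper()
    prev = config.motif_prevalence
    genes = annotation.genes_by_id
    for chrom, size in annotation.chrom_sizes.items():
        arr = rng.choice(_BASES, size=size, p=_composition_probs(config.gc_background))

        def paint(start: int, end: int, gc: float) -> None:
            start, end = max(0, start), min(size, end)
            if end > start:
                arr[start:end] = rng.choice(
                    _BASES, size=end - start, p=_composition_probs(gc)
                )

        def plant(pos: int, strand: str) -> None:
            m = motif if strand == "+" else motif.translate(_COMPLEMENT)[::-1]
            if 0 <= pos and pos + len(m) <= size:
                arr[pos:pos + len(m)] = np.frombuffer(m.encode(), dtype="S1")

        for gid in annotation.isolated_ids:
            g = genes[gid]
            if g.chrom != chrom:
                continue
            if g.strand == "+":
                paint(g.tss - config.promoter_window, g.tss, config.gc_promoter)
            else:
                paint(g.tss, g.tss + config.promoter_window, config.gc_promoter)
            # motif near the TSS (promoter-control class)
            if rng.random() < prev.get("promoter", 0):
                off = int(rng.integers(20, 250))
                pos = g.tss - off - len(motif) if g.strand == "+" else g.tss + off
                plant(pos, g.strand)
            # motif just past the CPA (3'-control class)
            if rng.random() < prev.get("three_prime", 0):
                off = int(rng.integers(20, 250))
                pos = g.cpa + off if g.strand == "+" else g.cpa - off - len(motif)
                plant(pos, g.strand)

        for unit in annotation.tandem_units:
            if unit.chrom != chrom:
                continue
            paint(unit.stir_start, unit.stir_end, config.gc_stir)
            if rng.random() < prev.get("stir", 0):
                L = unit.stir_end - unit.stir_start
                if L <= len(motif):
                    continue
                rel = config.motif_relative_position
                if unit.strand == "-":
                    rel = 1 - rel
                pos = unit.stir_start + int(rel * (L - len(motif)))
                plant(pos, unit.strand)
        genomes[chrom] = arr.tobytes().decode()
    return genomes


# ---------------------------------------------------------------------------
# signal tracks
# ---------------------------------------------------------------------------

def generate_signal_track(
    annotation: Annotation, config: SyntheticConfig
) -> tuple[SignalTrack, SignalTrack]:
    """Sense/antisense tracks: Poisson noise around a piecewise rate with a
    gene-body baseline, a promoter peak, and a STIR accumulation ramp that
    peaks at the downstream TSS (amplitude x gene-body baseline; control
    neighborhoods get no STIR component).

    Rates are realized in ``track_step``-bp steps; the emitted value is the
    Poisson count divided by the step, so the expected value equals the
    rate.  Both strands are emitted as unstranded-step tracks to be kept
    separate by the caller.
    """
    rng = substream(config.seed, "track")
    step = config.track_step
    sense: dict[str, list[tuple[int, int, float]]] = {}
    anti: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, size in annotation.chrom_sizes.items():
        # per-base rates, later averaged within each emission step so that
        # boundary steps are treated identically for STIRs and controls
        rate_plus = np.full(size, config.intergenic_rate, dtype=np.float32)
        rate_minus = np.full(size, config.intergenic_rate, dtype=np.float32)

        for g in annotation.genes:
            if g.chrom != chrom:
                continue
            rate = rate_plus if g.strand == "+" else rate_minus
            rate[g.start:g.end] = config.gene_body_rate
            if g.strand == "+":
                rate[g.start:g.start + config.promoter_peak_width] = (
                    config.promoter_peak_rate
                )
            else:
                rate[g.end - config.promoter_peak_width:g.end] = (
                    config.promoter_peak_rate
                )
        for unit in annotation.tandem_units:
            if unit.chrom != chrom:
                continue
            n = unit.stir_end - unit.stir_start
            if n <= 0:
                continue
            ramp = np.linspace(0, 1, n, dtype=np.float32)  # CPA -> TSS
            if unit.strand == "-":
                ramp = ramp[::-1]
            rate = rate_plus if unit.strand == "+" else rate_minus
            rate[unit.stir_start:unit.stir_end] = (
                config.intergenic_rate
                + config.stir_amplitude * config.gene_body_rate * ramp
            )
        # low uniform antisense floor inside transcribed units
        for g in annotation.genes:
            if g.chrom != chrom:
                continue
            o = rate_minus if g.strand == "+" else rate_plus
            o[g.start:g.end] = np.maximum(o[g.start:g.end], config.antisense_rate)

        n_steps = size // step
        lam_plus = rate_plus[:n_steps * step].reshape(n_steps, step).mean(axis=1)
        lam_minus = rate_minus[:n_steps * step].reshape(n_steps, step).mean(axis=1)
        counts_plus = rng.poisson(lam_plus * step) / step
        counts_minus = rng.poisson(lam_minus * step) / step
        sense[chrom] = [
            (i * step, (i + 1) * step, float(v)) for i, v in enumerate(counts_plus)
        ]
        anti[chrom] = [
            (i * step, (i + 1) * step, float(v)) for i, v in enumerate(counts_minus)
        ]
    return SignalTrack(sense), SignalTrack(anti)


# ---------------------------------------------------------------------------
# peaks, knockdown tables, long reads
# ---------------------------------------------------------------------------

def generate_peaks(
    annotation: Annotation, config: SyntheticConfig, factor_index: int = 0
) -> pd.DataFrame:
    """Bernoulli peak calls per region class for one factor.

    STIR peaks land inside the STIR; promoter/3'-class peaks land within
    ~250 bp of the isolated genes' TSS/CPA so any length-matched control
    region overlaps them.
    """
    rng = np.random.default_rng([int(config.seed), _STREAMS["peaks"], factor_index])
    prev = config.peak_prevalence
    w = config.peak_width
    genes = annotation.genes_by_id
    rows = []
    for unit in annotation.tandem_units:
        if rng.random() < prev.get("stir", 0):
            L = unit.stir_end - unit.stir_start
            start = unit.stir_start + int(rng.integers(0, max(1, L - w)))
            rows.append((unit.chrom, start, min(start + w, unit.stir_end)))
    for gid in annotation.isolated_ids:
        g = genes[gid]
        if rng.random() < prev.get("promoter", 0):
            off = int(rng.integers(0, 150))
            start = g.tss - off - w if g.strand == "+" else g.tss + off
            rows.append((g.chrom, max(0, start), max(0, start) + w))
        if rng.random() < prev.get("three_prime", 0):
            off = int(rng.integers(0, 150))
            start = g.cpa + off if g.strand == "+" else g.cpa - off - w
            rows.append((g.chrom, max(0, start), max(0, start) + w))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def generate_kd_table(
    annotation: Annotation,
    config: SyntheticConfig,
    factor: str,
    m_up: float = 0.0,
    m_down: float = 0.0,
    factor_index: int = 0,
) -> pd.Series:
    """Per-gene log2FC for one knockdown: Normal(0, sd) noise everywhere,
    plus the planted effect on upstream/downstream tandem genes (controls
    stay at 0 effect)."""
    rng = np.random.default_rng([int(config.seed), _STREAMS["kd"], factor_index])
    gene_ids = [g.gene_id for g in annotation.genes]
    lfc = pd.Series(
        rng.normal(0.0, config.kd_noise_sd, len(gene_ids)), index=gene_ids,
        name=factor,
    )
    lfc[annotation.upstream_ids] += m_up
    lfc[annotation.downstream_ids] += m_down
    return lfc


def generate_kd_panel(
    annotation: Annotation,
    config: SyntheticConfig,
    planted_factor: str = "PLANTED",
) -> dict[str, pd.Series]:
    """A knockdown panel: null factors with concordant effects plus one
    planted downstream-specific factor.

    Most knockdowns in real panels shift the upstream and downstream tandem
    genes together relative to controls, so each null factor draws one
    concordant effect c ~ N(0, kd_concordant_sd) applied to both genes of
    every pair; the planted factor applies (kd_planted_m_up,
    kd_planted_m_down) instead.
    """
    rng = np.random.default_rng([int(config.seed), _STREAMS["kd"], 0])
    panel: dict[str, pd.Series] = {}
    for j in range(config.kd_n_null_factors):
        c = float(rng.normal(0, config.kd_concordant_sd))
        panel[f"NULL{j:02d}"] = generate_kd_table(
            annotation, config, f"NULL{j:02d}", m_up=c, m_down=c,
            factor_index=j + 1,
        )
    panel[planted_factor] = generate_kd_table(
        annotation, config, planted_factor,
        m_up=config.kd_planted_m_up, m_down=config.kd_planted_m_down,
        factor_index=config.kd_n_null_factors + 1,
    )
    return panel


def generate_long_reads(
    annotation: Annotation, config: SyntheticConfig
) -> list[LongRead]:
    """Nascent-style long reads per tandem pair.

    Each gene of a pair gets ``reads_per_gene`` sense reads inside the gene
    body; a configured fraction of the upstream gene's reads span its CPA
    site, of which ``readthrough_extension_prob`` extend >= ``min_extension``
    nt into the STIR.  With probability ``dual_gene_rate`` a read spans from
    the upstream gene into the downstream gene's first exon.
    """
    rng = substream(config.seed, "reads")
    reads: list[LongRead] = []
    genes = annotation.genes_by_id
    n = 0

    def add(chrom: str, start: int, end: int, strand: str) -> None:
        nonlocal n
        n += 1
        reads.append(
            LongRead(
                name=f"read{n:06d}", chrom=chrom, start=start, end=end,
                strand=strand, blocks=[(start, end)],
            )
        )

    for unit in annotation.tandem_units:
        up, down = genes[unit.upstream_id], genes[unit.downstream_id]
        stir_len = unit.stir_end - unit.stir_start
        for g, is_up in ((up, True), (down, False)):
            for _ in range(config.reads_per_gene):
                if is_up and rng.random() < config.dual_gene_rate:
                    # spans the STIR and the first exonic bases of both genes
                    s = up.cpa - 200 if unit.strand == "+" else up.cpa + 200
                    e = down.tss + 200 if unit.strand == "+" else down.tss - 200
                    add(unit.chrom, min(s, e), max(s, e), unit.strand)
                    continue
                if is_up and rng.random() < config.cpa_overlap_fraction:
                    if rng.random() < config.readthrough_extension_prob:
                        ext = config.min_extension + int(rng.geometric(0.02))
                    else:
                        ext = int(rng.integers(1, config.min_extension))
                    ext = min(ext, stir_len)
                    length = min(config.read_length, g.length - 1)
                    if unit.strand == "+":
                        end = up.cpa + ext
                        start = max(g.start, end - length)
                    else:
                        start = up.cpa - ext
                        end = min(g.end, start + length)
                    add(unit.chrom, start, end, unit.strand)
                else:
                    length = min(config.read_length, g.length - 2)
                    start = g.start + int(rng.integers(0, g.length - length))
                    add(unit.chrom, start, min(start + length, g.end - 1), unit.strand)
    return reads
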