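"""Strand-aware metagene profiles of genomic signal over STIRs and matched
controls, outlier filtering, fold-enrichment summaries and the Pol2 pausing
index.

The metagene frame scales each region body to a fixed number of bins and
adds fixed-width flank bins (default 1 kb of flank in 50 bp bins) on both
sides; minus-strand rows are reversed so columns always run 5'->3' in
transcription direction, i.e. from the upstream gene's CPA site to the
downstream gene's TSS for a STIR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import bonferroni, paired_signed_rank
from .annotation_core import GeneModel, Region
from .sequence_features import bin_spans

logger = logging.getLogger(__name__)

DEFAULT_FLANK_BP = 1_000
DEFAULT_FLANK_BIN_BP = 50
DEFAULT_BODY_BINS = 70


class SignalTrack:
    """A sparse per-chromosome step function (bedGraph semantics).

    Intervals must be non-overlapping within a track; uncovered bases read
    as 0.  Sense and antisense signal live in separate tracks.
    """

    def __init__(self, intervals: Mapping[str, Sequence[tuple[int, int, float]]]):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in intervals.items():
            ivs = sorted(ivs)
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            values = np.array([v for _, _, v in ivs], dtype=float)
            if np.any(~np.isfinite(values)):
                raise ValueError("track values must be finite")
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping intervals on {chrom}")
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_bedgraph(cls, df_or_path) -> "SignalTrack":
        from .io import read_bedgraph

        df = df_or_path if isinstance(df_or_path, pd.DataFrame) else read_bedgraph(df_or_path)
        grouped = {
            chrom: list(zip(g["start"], g["end"], g["value"]))
            for chrom, g in df.groupby("chrom")
        }
        return cls(grouped)

    @property
    def chroms(self) -> set[str]:
        return set(self._data)

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); positions outside coverage
        (or off the chromosome start) read 0."""
        out = np.zeros(end - start, dtype=float)
        data = self._data.get(chrom)
        if data is None:
            return out
        starts, ends, values = data
        i = int(np.searchsorted(ends, start, side="right"))
        while i < len(starts) and starts[i] < end:
            lo = max(starts[i], start)
            hi = min(ends[i], end)
            if hi > lo:
                out[lo - start:hi - start] = values[i]
            i += 1
        return out

    def region_sum(self, chrom: str, start: int, end: int) -> float:
        return float(self.per_base(chrom, start, end).sum())

    def region_max(self, chrom: str, start: int, end: int) -> float:
        return float(self.per_base(chrom, start, end).max(initial=0.0))

    def to_bedgraph(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self._data):
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                rows.append((chrom, int(s), int(e), float(v)))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


@dataclass
class MetageneMatrix:
    """regions x (flank + body + flank) bins of mean per-base signal."""

    values: np.ndarray
    row_ids: list[str]
    body_bins: int
    flank_bins: int
    flank_bp: int = DEFAULT_FLANK_BP

    def __post_init__(self) -> None:
        if self.values.shape[1] != 2 * self.flank_bins + self.body_bins:
            raise ValueError("column count must be 2*flank_bins + body_bins")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def body(self) -> np.ndarray:
        return self.values[:, self.flank_bins:self.flank_bins + self.body_bins]

    def subset(self, row_ids: Sequence[str]) -> "MetageneMatrix":
        idx = [self.row_ids.index(r) for r in row_ids]
        return MetageneMatrix(
            self.values[idx], list(row_ids), self.body_bins, self.flank_bins,
            self.flank_bp,
        )


def build_metagene_matrix(
    regions: Sequence[Region],
    track: SignalTrack,
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bp: int = DEFAULT_FLANK_BP,
    flank_bin_bp: int = DEFAULT_FLANK_BIN_BP,
) -> MetageneMatrix:
    """Bin signal over each region body (scaled) and fixed-width flanks.

    Bin values are means of per-base signal.  Minus-strand rows are computed
    on the reversed per-base vector, so the first column is always the most
    5' flank bin in transcription direction.  Flanks running off the
    chromosome start are truncated (read as 0) with a diagnostic.
    """
    if flank_bp % flank_bin_bp:
        raise ValueError("flank_bp must be a multiple of flank_bin_bp")
    flank_bins = flank_bp // flank_bin_bp
    rows, ids = [], []
    for r in regions:
        lo = r.start - flank_bp
        if lo < 0:
            logger.warning("flank of %s truncated at chromosome start", r.name)
        base = track.per_base(r.chrom, lo, r.end + flank_bp)
        if r.strand == "-":
            base = base[::-1]
        left = base[:flank_bp].reshape(flank_bins, flank_bin_bp).mean(axis=1)
        right = base[-flank_bp:].reshape(flank_bins, flank_bin_bp).mean(axis=1)
        body_base = base[flank_bp:flank_bp + r.length]
        body = np.array(
            [body_base[a:b].mean() for a, b in bin_spans(r.length, body_bins)]
        )
        rows.append(np.concatenate([left, body, right]))
        ids.append(r.name)
    return MetageneMatrix(np.asarray(rows), ids, body_bins, flank_bins, flank_bp)


def build_stranded_metagene_matrix(
    regions: Sequence[Region],
    plus_track: SignalTrack,
    minus_track: SignalTrack,
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bp: int = DEFAULT_FLANK_BP,
    flank_bin_bp: int = DEFAULT_FLANK_BIN_BP,
) -> MetageneMatrix:
    """Sense-strand metagene from paired strand tracks: plus-strand regions
    read the plus track, minus-strand regions the minus track, and the rows
    are combined in input order."""
    rows, ids = [], []
    for r in regions:
        track = plus_track if r.strand == "+" else minus_track
        m = build_metagene_matrix([r], track, body_bins, flank_bp, flank_bin_bp)
        rows.append(m.values[0])
        ids.append(r.name)
    flank_bins = flank_bp // flank_bin_bp
    return MetageneMatrix(np.asarray(rows), ids, body_bins, flank_bins, flank_bp)


def aggregate_control_matrices(
    control_matrix: MetageneMatrix, focal_of_row: Sequence[str]
) -> MetageneMatrix:
    """Average each control quintet into one row per focal region.

    ``focal_of_row`` names the focal gene each control row belongs to; rows
    sharing a focal are averaged, preserving first-appearance order.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, focal in enumerate(focal_of_row):
        if focal not in groups:
            order.append(focal)
        groups.setdefault(focal, []).append(i)
    values = np.array(
        [control_matrix.values[groups[f]].mean(axis=0) for f in order]
    )
    return MetageneMatrix(
        values, order, control_matrix.body_bins, control_matrix.flank_bins,
        control_matrix.flank_bp,
    )


def summarize_profile(matrix: MetageneMatrix) -> pd.DataFrame:
    """Per-bin median and standard error (SD/sqrt(n)) across rows."""
    v = matrix.values
    n = v.shape[0]
    med = np.median(v, axis=0)
    se = np.zeros(v.shape[1]) if n == 1 else v.std(axis=0, ddof=1) / np.sqrt(n)
    return pd.DataFrame({"median": med, "se": se})


def per_bin_paired_test(
    tandem_matrix: MetageneMatrix, control_matrix: MetageneMatrix
) -> np.ndarray:
    """Bonferroni-corrected two-sided signed-rank p per bin.

    ``control_matrix`` must hold one (already quintet-averaged) row per
    tandem row, in the same order.
    """
    a, b = tandem_matrix.values, control_matrix.values
    if a.shape != b.shape:
        raise ValueError("matrices must be row-aligned")
    p = np.array([paired_signed_rank(a[:, j], b[:, j]) for j in range(a.shape[1])])
    return bonferroni(p, a.shape[1])


def filter_outlier_rows(
    combined: np.ndarray,
    lo_q: float = 0.0001,
    hi_q: float = 0.9999,
) -> np.ndarray:
    """Boolean keep-mask over rows: drop any row holding a value strictly
    outside the [lo_q, hi_q] quantiles of the whole matrix."""
    lo = np.nanquantile(combined, lo_q)
    hi = np.nanquantile(combined, hi_q)
    with np.errstate(invalid="ignore"):
        bad = (combined > hi) | (combined < lo)
    return ~np.any(bad, axis=1)


def stir_fold_enrichment(
    tandem_body: np.ndarray, control_quintet_bodies: np.ndarray
) -> float:
    """Fold = sum of per-STIR body signal over sum of per-focal
    quintet-mean body signal.

    ``control_quintet_bodies`` has shape (n_focal, n_controls, body_bins),
    aligned with ``tandem_body`` (n_focal, body_bins).
    """
    num = float(tandem_body.sum())
    den = float(control_quintet_bodies.mean(axis=1).sum())
    if den == 0:
        return float("nan")
    return num / den


@dataclass
class PausingIndexResult:
    gene_id: str
    pi: float | None


def pausing_index(
    track: SignalTrack,
    gene: GeneModel,
    window: int = 200,
    normalized: bool = False,
) -> PausingIndexResult:
    """Promoter-proximal pausing index.

    PI = (signal summed over the first ``window`` bases downstream of the
    TSS, in transcription direction) / (whole-gene signal / gene length).
    With ``normalized`` the numerator is divided by the window, making PI a
    pure density ratio.  Undefined (None) when the whole-gene signal is 0.
    """
    if gene.length <= window:
        raise ValueError("gene must be longer than the pausing window")
    if gene.strand == "+":
        prox = track.region_sum(gene.chrom, gene.start, gene.start + window)
    else:
        prox = track.region_sum(gene.chrom, gene.end - window, gene.end)
    total = track.region_sum(gene.chrom, gene.start, gene.end)
    if total == 0:
        return PausingIndexResult(gene.gene_id, None)
    pi = prox / (total / gene.length)
    if normalized:
        pi /= window
    return PausingIndexResult(gene.gene_id, float(pi))
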