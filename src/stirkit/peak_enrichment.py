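"""Binding prevalence of ChIP-seq peak sets in STIRs vs matched control
regions, minimal tandem-to-control enrichment ratios and factor ranking.

A region counts as bound when it overlaps at least one peak by >= 1 bp;
multiple peaks in one region count once.  Control prevalences are computed
over the pooled control regions (all quintets together).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._stats import bonferroni, proportion_test
from .annotation_core import Region


@dataclass
class PrevalenceRecord:
    factor: str
    n_stir: int
    n_prom: int
    n_3p: int
    bound_stir: int
    bound_prom: int
    bound_3p: int
    p_value_promoter: float = 1.0
    p_value_three_prime: float = 1.0

    @property
    def p_stir(self) -> float:
        return self.bound_stir / self.n_stir

    @property
    def p_prom(self) -> float:
        return self.bound_prom / self.n_prom

    @property
    def p_3p(self) -> float:
        return self.bound_3p / self.n_3p

    @property
    def min_ratio(self) -> float:
        """Minimal STIR-to-control prevalence ratio over the controls with
        non-zero prevalence; NaN when neither is defined."""
        ratios = [
            self.p_stir / p for p in (self.p_prom, self.p_3p) if p > 0
        ]
        return min(ratios) if ratios else float("nan")


def binding_indicator(
    regions: Sequence[Region], peaks: pd.DataFrame | Sequence[tuple]
) -> np.ndarray:
    """0/1 per region: overlaps >= 1 peak by >= 1 bp."""
    if isinstance(peaks, pd.DataFrame):
        rows = peaks[["chrom", "start", "end"]].itertuples(index=False)
    else:
        rows = peaks
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in rows:
        if end > start:
            trees.setdefault(chrom, IntervalTree())[int(start):int(end)] = True
    return np.array(
        [
            1 if r.chrom in trees and trees[r.chrom].overlaps(r.start, r.end) else 0
            for r in regions
        ],
        dtype=int,
    )


def prevalence_and_ratio(
    stir_ind: np.ndarray,
    prom_ind: np.ndarray,
    three_prime_ind: np.ndarray,
    factor: str = "",
    bonferroni_family: int = 1,
) -> PrevalenceRecord:
    """Prevalences, min ratio and per-control two-proportion tests for one
    factor.  ``bonferroni_family`` is the number of tests in the family
    (typically n_factors x 2 controls)."""
    for ind in (stir_ind, prom_ind, three_prime_ind):
        if len(ind) == 0:
            raise ValueError("empty region group")
    rec = PrevalenceRecord(
        factor=factor,
        n_stir=len(stir_ind), n_prom=len(prom_ind), n_3p=len(three_prime_ind),
        bound_stir=int(np.sum(stir_ind)),
        bound_prom=int(np.sum(prom_ind)),
        bound_3p=int(np.sum(three_prime_ind)),
    )
    rec.p_value_promoter = float(
        bonferroni(
            proportion_test(rec.bound_stir, rec.n_stir, rec.bound_prom, rec.n_prom),
            bonferroni_family,
        )
    )
    rec.p_value_three_prime = float(
        bonferroni(
            proportion_test(rec.bound_stir, rec.n_stir, rec.bound_3p, rec.n_3p),
            bonferroni_family,
        )
    )
    return rec


def rank_binders(records: Sequence[PrevalenceRecord]) -> list[PrevalenceRecord]:
    """STIR-enriched factors (prevalence above both controls), ordered by
    STIR prevalence then descending min ratio, ties by factor name."""
    if not records:
        raise ValueError("no records")
    kept = [r for r in records if r.p_stir > r.p_prom and r.p_stir > r.p_3p]
    return sorted(kept, key=lambda r: (-r.p_stir, -r.min_ratio, r.factor))


def prevalence_table(records: Sequence[PrevalenceRecord]) -> pd.DataFrame:
    rows = {
        r.factor: {
            "n_stir": r.n_stir, "bound_stir": r.bound_stir, "p_stir": r.p_stir,
            "n_prom": r.n_prom, "bound_prom": r.bound_prom, "p_prom": r.p_prom,
            "n_3p": r.n_3p, "bound_3p": r.bound_3p, "p_3p": r.p_3p,
            "min_ratio": r.min_ratio,
            "p_value_promoter": r.p_value_promoter,
            "p_value_three_prime": r.p_value_three_prime,
        }
        for r in records
    }
    return pd.DataFrame(rows).T
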