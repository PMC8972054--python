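"""Matched-control construction.

For every co-expressed tandem gene, five isolated ("non-tandem") genes with
the closest joint resemblance in expression level and total intron length
are selected, and regions of exactly the focal pair's STIR length are taken
upstream of each control's TSS (promoter controls, controlling for the
downstream tandem gene) or downstream of its CPA site (3' controls,
controlling for the upstream gene).

The matching distance is Euclidean over z-score-standardized log2(TPM + 1)
and log2(intron length + 1) with equal weights; ties break by gene_id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_core import (
    MAX_GENE_LEN,
    MIN_GENE_LEN,
    ROLE_PROMOTER_CONTROL,
    ROLE_THREE_PRIME_CONTROL,
    GeneModel,
    Region,
)

logger = logging.getLogger(__name__)

N_CONTROLS = 5
MIN_ISOLATION = 5_000

SIDE_PROMOTER = "promoter"
SIDE_THREE_PRIME = "three_prime"


@dataclass
class ControlSet:
    """The control quintet for one focal tandem gene."""

    focal_gene_id: str
    side: str  # promoter | three_prime
    control_gene_ids: list[str]
    control_regions: list[Region] = field(default_factory=list)


def build_nontandem_universe(
    genes: Sequence[GeneModel],
    min_isolation: int = MIN_ISOLATION,
    min_len: int = MIN_GENE_LEN,
    max_len: int = MAX_GENE_LEN,
) -> list[GeneModel]:
    """Genes within length bounds whose nearest neighbor on either side
    (any strand) is strictly farther than ``min_isolation``."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    universe: list[GeneModel] = []
    for chrom_genes in by_chrom.values():
        for g in chrom_genes:
            if not (min_len <= g.length <= max_len):
                continue
            isolated = True
            for h in chrom_genes:
                if h.gene_id == g.gene_id:
                    continue
                dist = max(h.start - g.end, g.start - h.end)
                # dist < 0 means overlap; bookended genes have dist 0
                if dist <= min_isolation:
                    isolated = False
                    break
            if isolated:
                universe.append(g)
    universe.sort(key=lambda g: g.gene_id)
    return universe


def _matching_features(
    genes: Sequence[GeneModel], expr: pd.DataFrame, sample: str
) -> pd.DataFrame:
    tpm = np.array(
        [
            float(expr.loc[g.gene_id, sample]) if g.gene_id in expr.index else 0.0
            for g in genes
        ]
    )
    intron = np.array([g.mean_total_intron_length for g in genes])
    return pd.DataFrame(
        {
            "log_tpm": np.log2(tpm + 1.0),
            "log_intron": np.log2(intron + 1.0),
        },
        index=[g.gene_id for g in genes],
    )


def match_controls(
    focal_gene: GeneModel,
    universe: Sequence[GeneModel],
    expr: pd.DataFrame,
    sample: str,
    side: str,
    k: int = N_CONTROLS,
) -> ControlSet:
    """The k universe genes nearest to the focal gene in standardized
    (log-expression, log-intron-length) space.

    Standardization uses the universe's mean and SD so the two criteria
    contribute on a common scale.  Deterministic: ties break by gene_id.
    """
    if len(universe) < k:
        raise ValueError(f"universe of {len(universe)} genes is smaller than k={k}")
    feats = _matching_features(list(universe), expr, sample)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = (feats - mu) / sd
    focal = (_matching_features([focal_gene], expr, sample).iloc[0] - mu) / sd
    dist = np.sqrt(((z - focal) ** 2).sum(axis=1))
    order = sorted(zip(dist.values, dist.index))
    chosen = [gid for _, gid in order if gid != focal_gene.gene_id][:k]
    return ControlSet(focal_gene_id=focal_gene.gene_id, side=side, control_gene_ids=chosen)


def match_control_map(
    focal_genes: Sequence[GeneModel],
    universe: Sequence[GeneModel],
    expr: pd.DataFrame,
    sample: str,
    k: int = N_CONTROLS,
) -> dict[str, list[str]]:
    """Vectorized quintet matching for many focal genes at once.

    Equivalent to calling :func:`match_controls` per gene (same
    standardization and tie-break) but standardizes the universe once.
    """
    if len(universe) < k:
        raise ValueError(f"universe of {len(universe)} genes is smaller than k={k}")
    feats = _matching_features(list(universe), expr, sample)
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0, ddof=0).replace(0.0, 1.0)
    z = ((feats - mu) / sd).values
    uids = np.array(feats.index)
    id_order = np.argsort(uids, kind="stable")
    out: dict[str, list[str]] = {}
    zf_all = ((_matching_features(list(focal_genes), expr, sample) - mu) / sd).values
    for gene, zf in zip(focal_genes, zf_all):
        d = np.sqrt(((z - zf) ** 2).sum(axis=1))
        # sort by (distance, gene_id): stable sort on pre-id-ordered arrays
        order = id_order[np.argsort(d[id_order], kind="stable")]
        chosen = [uids[i] for i in order if uids[i] != gene.gene_id][:k]
        out[gene.gene_id] = chosen
    return out


def extract_control_regions(
    control_set: ControlSet,
    genes_by_id: dict[str, GeneModel],
    stir_length: int,
    chrom_sizes: dict[str, int] | None = None,
) -> list[Region]:
    """Length-matched control regions adjacent to each control gene.

    Promoter controls sit immediately upstream of the control gene's TSS;
    3' controls immediately downstream of its CPA site, reflected for minus
    strand genes.  Regions running past a chromosome boundary are dropped
    with a diagnostic.
    """
    L = stir_length
    role = (
        ROLE_PROMOTER_CONTROL
        if control_set.side == SIDE_PROMOTER
        else ROLE_THREE_PRIME_CONTROL
    )
    regions: list[Region] = []
    for gid in control_set.control_gene_ids:
        g = genes_by_id[gid]
        if control_set.side == SIDE_PROMOTER:
            if g.strand == "+":
                start, end = g.tss - L, g.tss
            else:
                start, end = g.tss, g.tss + L
        elif control_set.side == SIDE_THREE_PRIME:
            if g.strand == "+":
                start, end = g.cpa, g.cpa + L
            else:
                start, end = g.cpa - L, g.cpa
        else:
            raise ValueError(f"unknown side {control_set.side!r}")
        size = None if chrom_sizes is None else chrom_sizes.get(g.chrom)
        if start < 0 or (size is not None and end > size):
            logger.warning(
                "control region for %s (%s) extends past chromosome bounds; dropped",
                gid, control_set.focal_gene_id,
            )
            continue
        regions.append(
            Region(
                chrom=g.chrom, start=start, end=end, strand=g.strand, role=role,
                anchor_gene_ids=[control_set.focal_gene_id, gid],
            )
        )
    control_set.control_regions = regions
    return regions


def aggregate_quintet(values: Sequence[float]) -> float:
    """Mean of the non-missing values of one control quintet; NaN if all
    are missing."""
    arr = np.asarray(values, dtype=float)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def build_control_sets(
    pairs,
    universe: Sequence[GeneModel],
    expr: pd.DataFrame,
    sample: str,
    stirs: Sequence[Region] | None = None,
    chrom_sizes: dict[str, int] | None = None,
    k: int = N_CONTROLS,
) -> tuple[dict[str, ControlSet], dict[str, ControlSet]]:
    """Promoter and 3' control sets for every tandem pair with a STIR.

    Returns (three_prime_sets keyed by upstream gene, promoter_sets keyed by
    downstream gene); when ``stirs`` is given, control regions of the focal
    STIR's length are attached.
    """
    genes_by_id = {g.gene_id: g for g in universe}
    stir_by_up = {r.anchor_gene_ids[0]: r for r in (stirs or [])}
    three_prime: dict[str, ControlSet] = {}
    promoter: dict[str, ControlSet] = {}
    for p in pairs:
        up, down = p.upstream, p.downstream
        cs3 = match_controls(up, universe, expr, sample, SIDE_THREE_PRIME, k=k)
        csp = match_controls(down, universe, expr, sample, SIDE_PROMOTER, k=k)
        stir = stir_by_up.get(up.gene_id)
        if stir is not None:
            extract_control_regions(cs3, genes_by_id, stir.length, chrom_sizes)
            extract_control_regions(csp, genes_by_id, stir.length, chrom_sizes)
        three_prime[up.gene_id] = cs3
        promoter[down.gene_id] = csp
    return three_prime, promoter
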