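"""Knockdown-effect quantification and downstream-specificity ranking.

For each knockdown (KD) experiment the per-gene effect is the log2 fold
change relative to the mean log2FC of the gene's five matched controls
(delta); m_up and m_down are the medians of these deltas over the upstream
and downstream tandem genes.  Experiments are ranked so that low ranks mark
factors that preferentially affect the downstream gene: ascending |m_up|,
descending downstream effect, descending |m_down - m_up|, summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._stats import paired_signed_rank


@dataclass
class KDEffectTable:
    factor: str
    deltas_up: pd.Series = field(default_factory=pd.Series)
    deltas_down: pd.Series = field(default_factory=pd.Series)

    @property
    def m_up(self) -> float:
        return float(self.deltas_up.median()) if len(self.deltas_up.dropna()) else float("nan")

    @property
    def m_down(self) -> float:
        return float(self.deltas_down.median()) if len(self.deltas_down.dropna()) else float("nan")


def _delta(
    lfc: pd.Series, gene_id: str, control_ids: Sequence[str]
) -> float:
    if gene_id not in lfc.index:
        return float("nan")
    ctrl = [lfc[c] for c in control_ids if c in lfc.index]
    if not ctrl:
        return float("nan")
    return float(lfc[gene_id] - np.mean(ctrl))


def effect_deltas(
    lfc: pd.Series,
    upstream_ids: Sequence[str],
    downstream_ids: Sequence[str],
    control_map: Mapping[str, Sequence[str]],
    factor: str = "",
) -> KDEffectTable:
    """Per-tandem-gene deltas vs quintet-mean controls, with group medians.

    Genes missing from the log2FC table (or with no scored controls) get a
    missing delta and are excluded from the medians.
    """
    up = pd.Series(
        {g: _delta(lfc, g, control_map.get(g, [])) for g in upstream_ids},
        dtype=float,
    )
    down = pd.Series(
        {g: _delta(lfc, g, control_map.get(g, [])) for g in downstream_ids},
        dtype=float,
    )
    return KDEffectTable(factor=factor, deltas_up=up, deltas_down=down)


def paired_effect_test(
    lfc: pd.Series,
    gene_ids: Sequence[str],
    control_map: Mapping[str, Sequence[str]],
) -> float:
    """Two-sided signed-rank p for gene log2FCs vs their quintet means."""
    gene_vals, ctrl_vals = [], []
    for g in gene_ids:
        if g not in lfc.index:
            continue
        ctrl = [lfc[c] for c in control_map.get(g, []) if c in lfc.index]
        if not ctrl:
            continue
        gene_vals.append(lfc[g])
        ctrl_vals.append(np.mean(ctrl))
    return paired_signed_rank(gene_vals, ctrl_vals)


def rank_kd_experiments(
    tables: Sequence[KDEffectTable], signed: bool = False
) -> pd.DataFrame:
    """Rank KD experiments by downstream-specificity.

    rank1: ascending |m_up| (least upstream effect first);
    rank2: descending |m_down| (or signed m_down with ``signed``);
    rank3: descending |m_down - m_up|.
    Final order is the ascending sum of the three ranks, ties broken by
    factor name; factors with undefined medians rank last.
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 experiments to rank")
    df = pd.DataFrame(
        {
            "factor": [t.factor for t in tables],
            "m_up": [t.m_up for t in tables],
            "m_down": [t.m_down for t in tables],
        }
    ).set_index("factor")
    defined = df.dropna()
    r1 = rankdata(np.abs(defined["m_up"]))
    key2 = defined["m_down"] if signed else np.abs(defined["m_down"])
    r2 = rankdata(-key2)
    r3 = rankdata(-np.abs(defined["m_down"] - defined["m_up"]))
    defined = defined.assign(rank1=r1, rank2=r2, rank3=r3, rank_sum=r1 + r2 + r3)
    undefined = df[df.isna().any(axis=1)].assign(
        rank1=np.nan, rank2=np.nan, rank3=np.nan, rank_sum=np.inf
    )
    out = pd.concat([defined, undefined])
    out = out.loc[sorted(out.index, key=lambda f: (out.loc[f, "rank_sum"], f))]
    out["final_rank"] = np.arange(1, len(out) + 1)
    return out
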