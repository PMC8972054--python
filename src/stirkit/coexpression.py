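"""Co-expressed tandem pair selection.

Pairs are first filtered for expression (both genes strictly above a TPM
cutoff, default 2), then the 75th percentile of the absolute TPM difference
across expressed pairs is taken as the maximal allowed difference, so that
roughly three quarters of the expressed pairs are retained as co-expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_core import GenePair

logger = logging.getLogger(__name__)

MIN_TPM = 2.0
COEXPRESSION_QUANTILE = 0.75


def _tpm(expr: pd.DataFrame, gene_id: str, sample: str) -> float:
    if sample not in expr.columns:
        raise KeyError(f"sample {sample!r} not in expression table")
    if gene_id not in expr.index:
        logger.warning("gene %s missing from expression table; TPM treated as 0", gene_id)
        return 0.0
    return float(expr.loc[gene_id, sample])


@dataclass
class CoexpressionResult:
    sample: str
    threshold_q75: float
    selected_pairs: list[GenePair]


def filter_expressed_pairs(
    pairs: list[GenePair],
    expr: pd.DataFrame,
    sample: str,
    min_tpm: float = MIN_TPM,
) -> list[GenePair]:
    """Pairs where both genes have TPM strictly above ``min_tpm``."""
    return [
        p
        for p in pairs
        if _tpm(expr, p.left_gene.gene_id, sample) > min_tpm
        and _tpm(expr, p.right_gene.gene_id, sample) > min_tpm
    ]


def pair_tpm_differences(
    pairs: list[GenePair], expr: pd.DataFrame, sample: str
) -> np.ndarray:
    return np.array(
        [
            abs(
                _tpm(expr, p.left_gene.gene_id, sample)
                - _tpm(expr, p.right_gene.gene_id, sample)
            )
            for p in pairs
        ]
    )


def coexpression_threshold(
    expressed_pairs: list[GenePair],
    expr: pd.DataFrame,
    sample: str,
    quantile: float = COEXPRESSION_QUANTILE,
) -> float:
    """Percentile (linear interpolation) of |TPM_left - TPM_right|."""
    if not expressed_pairs:
        raise ValueError("no expressed pairs")
    diffs = pair_tpm_differences(expressed_pairs, expr, sample)
    return float(np.quantile(diffs, quantile))


def select_coexpressed(
    expressed_pairs: list[GenePair],
    expr: pd.DataFrame,
    sample: str,
    threshold: float | None = None,
) -> CoexpressionResult:
    """Retain pairs whose absolute TPM difference is <= threshold.

    When ``threshold`` is None it is computed from the expressed pairs
    themselves (the default analysis flow).
    """
    if threshold is None:
        threshold = coexpression_threshold(expressed_pairs, expr, sample)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    diffs = pair_tpm_differences(expressed_pairs, expr, sample)
    selected = [p for p, d in zip(expressed_pairs, diffs) if d <= threshold]
    return CoexpressionResult(
        sample=sample, threshold_q75=float(threshold), selected_pairs=selected
    )
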