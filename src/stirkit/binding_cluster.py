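"""Gene x binding-experiment max-signal ratio matrix and its hierarchical
clustering.

Per gene and experiment, the maximum per-base signal over the STIR plus 1 kb
flanks is taken; the same is done for the gene's control quintet and
averaged.  The tandem/control ratio matrix is capped at 10, genes with too
many missing values are dropped, and the matrix is clustered with complete
linkage: columns by 1 - Pearson correlation (pairwise-complete), rows by
Euclidean distance rescaled for missing entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .annotation_core import Region
from .signal_metagene import SignalTrack

RATIO_CAP = 10.0
MAX_MISSING = 17
DEFAULT_FLANK_BP = 1_000


def max_signal_matrix(
    regions_of_gene: Mapping[str, Sequence[Region]],
    tracks: Mapping[str, SignalTrack],
    flank_bp: int = DEFAULT_FLANK_BP,
) -> pd.DataFrame:
    """genes x experiments matrix of maximal per-base signal over each
    gene's region(s) extended by ``flank_bp`` on both sides.

    Multiple regions per gene (a control quintet) are aggregated by the mean
    of their per-region maxima.  A gene on a chromosome absent from a track
    is missing for that experiment.
    """
    genes = list(regions_of_gene)
    out = pd.DataFrame(index=genes, columns=list(tracks), dtype=float)
    for exp, track in tracks.items():
        for gene in genes:
            maxima = []
            for r in regions_of_gene[gene]:
                if r.chrom not in track.chroms:
                    continue
                maxima.append(
                    track.region_max(r.chrom, max(0, r.start - flank_bp), r.end + flank_bp)
                )
            out.loc[gene, exp] = float(np.mean(maxima)) if maxima else np.nan
    return out


def normalize_ratio_matrix(
    tandem_max: pd.DataFrame,
    control_mean_max: pd.DataFrame,
    cap: float = RATIO_CAP,
    max_missing: int = MAX_MISSING,
) -> pd.DataFrame:
    """Elementwise tandem/control ratio, capped, with sparse rows removed.

    0/0 -> missing; x/0 (x > 0) -> cap; values above ``cap`` are set to
    ``cap``; rows with strictly more than ``max_missing`` missing values are
    dropped.
    """
    t = tandem_max.loc[:, control_mean_max.columns]
    c = control_mean_max.loc[t.index]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = t.values / c.values
    ratio[(t.values == 0) & (c.values == 0)] = np.nan
    ratio[(t.values > 0) & (c.values == 0)] = cap
    ratio = np.minimum(ratio, cap)
    df = pd.DataFrame(ratio, index=t.index, columns=t.columns)
    keep = df.isna().sum(axis=1) <= max_missing
    return df[keep]


def _pairwise_correlation_distance(m: np.ndarray) -> np.ndarray:
    """1 - Pearson r over pairwise-complete observations; undefined
    correlations (constant vectors, < 2 shared points) get the maximal
    in-range distance 1."""
    n = m.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(m[:, i]) | np.isnan(m[:, j]))
            x, y = m[mask, i], m[mask, j]
            if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
                dist = 1.0
            else:
                dist = 1.0 - float(np.corrcoef(x, y)[0, 1])
            d[i, j] = d[j, i] = dist
    return d


def _pairwise_euclidean_distance(m: np.ndarray) -> np.ndarray:
    """Euclidean distance over pairwise-complete entries, rescaled by
    sqrt(p / n_valid) so sparsity does not shrink distances."""
    n, p = m.shape
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~(np.isnan(m[i]) | np.isnan(m[j]))
            valid = int(mask.sum())
            if valid == 0:
                dist = 0.0
            else:
                diff = m[i, mask] - m[j, mask]
                dist = float(np.sqrt((diff ** 2).sum() * (p / valid)))
            d[i, j] = d[j, i] = dist
    return d


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    """Deterministic leaf order: at each merge the subtree containing the
    smaller minimum original index goes left."""

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        la, lb = leaves(a), leaves(b)
        return la + lb if min(la) < min(lb) else lb + la

    return leaves(2 * n - 2) if n > 1 else [0]


def _newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        a, b = int(Z[i - n, 0]), int(Z[i - n, 1])
        la = min(_collect(a))
        lb = min(_collect(b))
        left, right = (a, b) if la < lb else (b, a)
        return f"({node(left)},{node(right)})"

    def _collect(i: int) -> list[int]:
        if i < n:
            return [i]
        return _collect(int(Z[i - n, 0])) + _collect(int(Z[i - n, 1]))

    return (node(2 * n - 2) if n > 1 else labels[0]) + ";"


@dataclass
class ClusterResult:
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_newick: str
    col_newick: str


def cluster_matrix(ratio: pd.DataFrame) -> ClusterResult:
    """Complete-linkage clustering of the ratio matrix.

    Columns (experiments): distance = 1 - Pearson correlation computed over
    pairwise-complete values.  Rows (genes): pairwise-complete Euclidean
    distance.  Leaf ordering is deterministic (smaller minimum original
    index on the left at every merge).
    """
    if ratio.shape[0] < 2 or ratio.shape[1] < 2:
        raise ValueError("need >= 2 rows and columns to cluster")
    m = ratio.values.astype(float)
    col_d = _pairwise_correlation_distance(m)
    row_d = _pairwise_euclidean_distance(m)
    col_Z = linkage(squareform(col_d, checks=False), method="complete")
    row_Z = linkage(squareform(row_d, checks=False), method="complete")
    col_order = [ratio.columns[i] for i in _leaf_order(col_Z, m.shape[1])]
    row_order = [ratio.index[i] for i in _leaf_order(row_Z, m.shape[0])]
    return ClusterResult(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_Z,
        col_linkage=col_Z,
        row_newick=_newick(row_Z, list(ratio.index)),
        col_newick=_newick(col_Z, list(ratio.columns)),
    )
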