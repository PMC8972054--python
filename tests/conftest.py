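"""Shared fixtures: tiny hand-built gene layouts and a mid-size synthetic
dataset reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from stirkit.annotation_core import GeneModel, Region
from stirkit.synthetic_data import SyntheticConfig, generate_annotation


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    strand: str = "+",
    chrom: str = "chr1",
    exons: list[tuple[int, int]] | None = None,
    intron: float = 0.0,
) -> GeneModel:
    return GeneModel(
        gene_id=gene_id, chrom=chrom, start=start, end=end, strand=strand,
        transcripts=[exons] if exons else [[(start, end)]],
        mean_total_intron_length=intron,
    )


def make_region(start: int, end: int, strand: str = "+", role: str = "STIR",
                chrom: str = "chr1", anchors: list[str] | None = None) -> Region:
    return Region(chrom=chrom, start=start, end=end, strand=strand, role=role,
                  anchor_gene_ids=anchors or [f"r{start}"])


@pytest.fixture(scope="session")
def small_annotation():
    cfg = SyntheticConfig(seed=7, n_tandem=40, n_divergent=10, n_convergent=10,
                          n_isolated=30)
    return cfg, generate_annotation(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
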