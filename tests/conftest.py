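"""Shared fixtures: tiny hand-built references and simulated communities."""

from __future__ import annotations

import numpy as np
import pytest

from microdiv import simulate as msim
from microdiv.io import GeneModel, ReferenceSet


@pytest.fixture
def tiny_reference() -> ReferenceSet:
    # one contig, one + strand gene (ATG AAA TTT CCC TAA) at positions 3..17
    seq = "GGC" + "ATGAAATTTCCCTAA" + "GGCCA"
    return ReferenceSet({"c1": seq}, genome_id="tiny")


@pytest.fixture
def tiny_gene() -> GeneModel:
    return GeneModel(
        gene_id="g1", contig="c1", start=3, end=18, strand="+", frame_complete=True
    )


@pytest.fixture
def minus_reference() -> ReferenceSet:
    # gene on the - strand: CDS ATG GGG TAA appears reverse-complemented
    cds = "ATGGGGTAA"
    rc = "TTACCCCAT"
    seq = "AA" + rc + "CC"
    return ReferenceSet({"c1": seq}, genome_id="tiny-minus")


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel(
        gene_id="gm", contig="c1", start=2, end=11, strand="-", frame_complete=True
    )


def make_counts(length: int, fills: dict[int, dict[str, int]]) -> np.ndarray:
    """Build an (L, 4) count matrix from {position: {base: count}}."""
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((length, 4), dtype=np.int32)
    for pos, alleles in fills.items():
        for b, c in alleles.items():
            counts[pos, base_idx[b]] = c
    return counts


@pytest.fixture(scope="session")
def small_sim():
    """A small end-to-end simulation shared across read-level tests."""
    cfg = msim.SimulationConfig(
        seed=11,
        genome_length=20_000,
        n_genes=8,
        samples=(msim.SampleSpec("s01", "0-5", 50.0),),
    )
    return msim.run_simulation(cfg, "scratch/test_small_sim")
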