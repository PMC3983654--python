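"""Shared fixtures: the default synthetic cohort and small gene fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from zmel.annotate import GeneIndex
from zmel.cohort import CohortConfig, generate_cohort
from zmel.types import GeneInterval


@pytest.fixture(scope="session")
def default_bundle():
    """The default seeded synthetic study (generated once per session)."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def default_gene_index(default_bundle):
    return GeneIndex(default_bundle.genes)


@pytest.fixture()
def rng():
    return np.random.default_rng(20131023)


def make_gene(
    gene_id="g1",
    chrom="chr1",
    start=101,
    strand="+",
    exons=None,
    cds_start=None,
    cds_end=None,
) -> GeneInterval:
    if exons is None:
        exons = [(start, start + 99)]
    return GeneInterval(
        gene_id=gene_id,
        chrom=chrom,
        start=min(s for s, _ in exons),
        end=max(e for _, e in exons),
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=cds_end,
    )
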