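"""Shared fixtures: small simulated genotype tables and coding-gene sets."""

import numpy as np
import pytest

from divflow.coalescent import SimConfig, make_model
from divflow.synthetic import genotypes_from_model, make_coding_fixture
from divflow.variants import VariantTable


def build_table(gt, pos=None, chrom=None, pops=None, dp=30, gq=99,
                ref="A", alt="T"):
    """Construct a VariantTable from a (sites, samples, 2) genotype array."""
    gt = np.asarray(gt, dtype=np.int8)
    S, N, _ = gt.shape
    if pos is None:
        pos = np.arange(1, S + 1)
    if chrom is None:
        chrom = ["chr1"] * S
    if pops is None:
        pops = ["sp1"] * (N // 2) + ["sp2"] * (N - N // 2)
    return VariantTable(
        np.asarray(chrom, dtype=object),
        np.asarray(pos, dtype=np.int64),
        np.array([ref] * S, dtype=object),
        np.array([alt] * S, dtype=object),
        gt,
        np.full((S, N), dp, dtype=np.int32),
        np.full((S, N), gq, dtype=np.int32),
        [f"s{i}" for i in range(N)],
        np.asarray(pops, dtype=object),
    )


@pytest.fixture(scope="session")
def m5_table():
    """Two-species genotype table simulated under continuous gene flow."""
    model = make_model("M5", m=2e-5)
    cfg = SimConfig(12, 12, mu=1e-8, locus_length=1000, n_loci=100, seed=42)
    return genotypes_from_model(model, cfg, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def coding_fixture():
    """Four genes with planted MKT counts, on alternating strands."""
    return make_coding_fixture(
        [(20, 10, 5, 10), (0, 0, 0, 0), (3, 2, 1, 4), (5, 5, 5, 5)],
        rng=np.random.default_rng(5),
    )
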