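"""Shared fixtures: the toy locus, its three alleles and reference panels."""

import numpy as np
import pytest

import tgverify as tg


@pytest.fixture(scope="session")
def locus():
    return tg.make_toy_locus(seed=7)


@pytest.fixture(scope="session")
def allele_wt(locus):
    return tg.make_fixture_allele("wt", locus)


@pytest.fixture(scope="session")
def allele542(locus):
    return tg.make_fixture_allele("allele542", locus)


@pytest.fixture(scope="session")
def allele320(locus):
    return tg.make_fixture_allele("allele320", locus)


@pytest.fixture(scope="session")
def expected_mutant_panel(allele542):
    """Panel holding the expected single-insert mutant (the verification
    reference); entry name matches the construct interval's chrom."""
    return tg.ReferencePanel((("chrT", allele542.genome["chrT"]),))


@pytest.fixture(scope="session")
def mutant_index(expected_mutant_panel):
    return tg.build_unique_index(expected_mutant_panel, 20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
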