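import pytest

from coihap.seqio import MultipleAlignment, PopulationMap, collapse_haplotypes
from coihap.synthdata import ExpansionSimConfig, simulate_expansion_alignment


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study dataset: 140 individuals, 58 planted
    haplotypes, four canonical hotspot groups plus two variant key strings."""
    cfg = ExpansionSimConfig()
    aln, pops, truth = simulate_expansion_alignment(cfg)
    return cfg, aln, pops, truth


@pytest.fixture(scope="session")
def default_table(default_sim):
    _, aln, pops, _ = default_sim
    return collapse_haplotypes(aln, pops)


@pytest.fixture()
def tiny_alignment():
    """Four 20 bp sequences with exactly two segregating sites."""
    return MultipleAlignment(
        ("a", "b", "c", "d"),
        (
            "ACGTACGTACGTACGTACGT",
            "ACGTACGTACGTACGTACGT",
            "ACGTACTTACGTACGTACGT",   # site 7 G->T
            "ACGTACTTACGTACGAACGT",   # sites 7 and 16
        ),
    )


@pytest.fixture()
def two_pop_fixed():
    """Two populations fixed for different haplotypes (no within variance)."""
    aln = MultipleAlignment(
        ("a1", "a2", "a3", "b1", "b2", "b3"),
        ("AAAA",) * 3 + ("AGGA",) * 3,
    )
    pops = PopulationMap({s: s[0] for s in aln.ids})
    return aln, pops
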