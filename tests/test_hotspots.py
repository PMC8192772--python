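"""Site classification, hotspot groups, transition polarity, covariance
network and codon synonymy annotation."""

import itertools

import numpy as np
import pytest

from coihap.hotspots import (annotate_codon_synonymy, assign_groups,
                             classify_sites, covariance_network,
                             detect_reading_frame, infer_transition_order,
                             key_string, parsimony_informative_sites,
                             polymorphic_sites)
from coihap.seqio import MultipleAlignment, collapse_haplotypes


def _table(*seqs):
    aln = MultipleAlignment(
        tuple(f"s{i}" for i in range(len(seqs))), tuple(seqs)
    )
    return collapse_haplotypes(aln)


# --------------------------------------------------------------------------
# site classification
# --------------------------------------------------------------------------

def test_single_difference_is_polymorphic_not_informative():
    t = _table("AAAA", "AAGA")
    sites = classify_sites(t)
    assert polymorphic_sites(t) == [3]
    assert parsimony_informative_sites(t) == []
    assert sites[2].substitution_class == "transition"


def test_informative_transition_site():
    t = _table("AAAA", "AACA", "AGTA", "AGCA")
    sites = {c.position: c for c in classify_sites(t)}
    # site 2: A:2 G:2 -> informative transition
    assert sites[2].is_parsimony_informative
    assert sites[2].substitution_class == "transition"
    # site 3: A,C,T,C -> multi-state, informative (C twice, others once... no)
    assert sites[3].substitution_class == "multi-state"
    assert not sites[3].is_parsimony_informative


def test_individual_weighting_uses_member_counts():
    aln = MultipleAlignment(
        ("a", "b", "c"), ("AAAA", "AAAA", "AAGA")
    )
    t = collapse_haplotypes(aln)
    hap_counts = classify_sites(t, weighting="haplotype")[2].state_counts
    ind_counts = classify_sites(t, weighting="individual")[2].state_counts
    assert hap_counts == {"A": 1, "G": 1}
    assert ind_counts == {"A": 2, "G": 1}


def test_planted_site_counts_recovered(default_sim, default_table):
    cfg, _, _, truth = default_sim
    assert len(polymorphic_sites(default_table)) == cfg.n_polymorphic
    assert len(parsimony_informative_sites(default_table)) == cfg.n_informative
    planted = set(truth.shared_sites) | set(truth.singleton_sites) | set(
        truth.key_positions
    )
    assert set(polymorphic_sites(default_table)) == planted


# --------------------------------------------------------------------------
# group assignment and transition order
# --------------------------------------------------------------------------

def test_assign_groups_key_strings():
    t = _table(
        "A" * 10,
        "A" * 4 + "G" + "A" * 5,          # G at site 5
        "G" + "A" * 3 + "G" + "A" * 5,    # G at sites 1 and 5
    )
    ga = assign_groups(t, (1, 5))
    assert set(ga.groups) == {"A-A", "A-G", "G-G"}
    assert all(
        key_string(t[h].sequence, (1, 5)) == ks
        for ks, members in ga.groups.items()
        for h in members
    )


def test_group_sizes_recover_planted_frequencies(default_sim, default_table):
    cfg, _, _, _ = default_sim
    ga = assign_groups(default_table, cfg.key_positions)
    assert ga.sizes() == dict(cfg.group_frequencies)
    assert sum(ga.sizes().values()) == default_table.n_haplotypes


def test_transition_order_from_group_diversity(default_sim, default_table):
    cfg, _, _, truth = default_sim
    ga = assign_groups(default_table, cfg.key_positions)
    order = infer_transition_order(ga)
    anc = "-".join(["A"] * 4)
    assert order.ordered_groups[0] == anc
    assert order.ordered_groups[-1] == "G-G-G-G"
    # all four key sites polarised ancestral A -> derived G
    assert all(order.polarity[p] == ("A", "G") for p in cfg.key_positions)


def test_planted_stepwise_path_recovered():
    from coihap.synthdata import (ExpansionSimConfig,
                                  simulate_expansion_alignment)

    cfg = ExpansionSimConfig(
        group_frequencies={
            "A-A-A-A": 35, "A-A-G-A": 12, "G-A-G-A": 1, "G-G-G-G": 8
        },
        seed=2,
    )
    aln, _, truth = simulate_expansion_alignment(cfg)
    table = collapse_haplotypes(aln)
    ga = assign_groups(table, cfg.key_positions)
    order = infer_transition_order(ga)
    assert order.ordered_groups == truth.stepwise_path
    # the canonical chain ends with a two-site change (G-A-G-A -> G-G-G-G
    # flips both 282 and 420), so strict one-site stepwiseness is False
    assert not order.stepwise

    cfg2 = ExpansionSimConfig(
        n_individuals=80,
        group_frequencies={"A-A-A-A": 20, "A-A-G-A": 10, "G-A-G-A": 5},
        n_polymorphic=40,
        n_informative=14,
        seed=3,
    )
    aln2, _, truth2 = simulate_expansion_alignment(cfg2)
    ga2 = assign_groups(collapse_haplotypes(aln2), cfg2.key_positions)
    order2 = infer_transition_order(ga2)
    assert order2.ordered_groups == truth2.stepwise_path
    assert order2.stepwise


def test_non_stepwise_flagged():
    aln = MultipleAlignment(
        ("a", "b", "c", "d", "e"),
        ("AAAAAA", "AAAAAC", "AGGAAA", "AGGAAC", "AGGAAC"),
    )
    table = collapse_haplotypes(aln)
    ga = assign_groups(table, (2, 3))
    order = infer_transition_order(ga)
    assert not order.stepwise  # A-A -> G-G jumps two sites


def test_transition_order_invariant_to_group_input_order(default_sim,
                                                         default_table):
    cfg, _, _, _ = default_sim
    ga = assign_groups(default_table, cfg.key_positions)
    from coihap.hotspots import GroupAssignment

    shuffled = GroupAssignment(
        key_positions=ga.key_positions,
        groups=dict(reversed(list(ga.groups.items()))),
        group_order=tuple(reversed(ga.group_order)),
        per_group_h=ga.per_group_h,
        per_haplotype=ga.per_haplotype,
    )
    assert (
        infer_transition_order(ga).ordered_groups
        == infer_transition_order(shuffled).ordered_groups
    )


def test_diversity_tie_demands_override():
    aln = MultipleAlignment(
        ("a", "b", "c", "d"), ("AAAA", "AACA", "GAAA", "GACA")
    )
    table = collapse_haplotypes(aln)
    ga = assign_groups(table, (1,))
    with pytest.raises(ValueError, match="tie"):
        infer_transition_order(ga)
    order = infer_transition_order(ga, ancestral="A")
    assert order.ordered_groups == ("A", "G")


# --------------------------------------------------------------------------
# covariance network
# --------------------------------------------------------------------------

def test_perfect_linkage_counts_all_haplotypes():
    t = _table("AAAAC", "GGAAC", "AAAAT", "GGAAT")
    edges = covariance_network(t, sites=[1, 2])
    (e,) = edges
    assert e.covariate_count == t.n_haplotypes
    assert e.frequency_ratio == 1.0


def test_orthogonal_sites_half_covariate():
    # 20 haplotypes, sites 1 and 2 each 50/50 and mutually orthogonal
    seqs = []
    combos = [("A", "C"), ("A", "T"), ("G", "C"), ("G", "T")]
    for q, (a, b) in enumerate(combos):
        for r in range(5):
            tail = format(q * 5 + r, "05b").replace("0", "C").replace("1", "T")
            seqs.append(a + b + tail)
    t = _table(*seqs)
    assert t.n_haplotypes == 20
    (e,) = covariance_network(t, sites=[1, 2])
    assert e.covariate_count == 10


def test_covariance_matches_brute_force(default_sim, default_table):
    cfg, _, _, _ = default_sim
    sites = list(cfg.key_positions)
    edges = covariance_network(default_table, sites=sites)
    # independent brute-force tally with explicit major states
    for e in edges:
        counts_i, counts_j = {}, {}
        for h in default_table:
            counts_i[h.sequence[e.site_i - 1]] = (
                counts_i.get(h.sequence[e.site_i - 1], 0) + 1
            )
            counts_j[h.sequence[e.site_j - 1]] = (
                counts_j.get(h.sequence[e.site_j - 1], 0) + 1
            )
        maj_i = max(sorted(counts_i), key=counts_i.get)
        maj_j = max(sorted(counts_j), key=counts_j.get)
        expected = sum(
            1
            for h in default_table
            if (h.sequence[e.site_i - 1] == maj_i)
            == (h.sequence[e.site_j - 1] == maj_j)
        )
        assert e.covariate_count == expected


def test_covariance_symmetric_and_self_concordant(default_table, default_sim):
    cfg, _, _, _ = default_sim
    sites = list(cfg.key_positions)
    edges = {
        (e.site_i, e.site_j): e.covariate_count
        for e in covariance_network(default_table, sites=sites)
    }
    assert all(i < j for i, j in edges)
    assert len(edges) == 6  # all unordered pairs of 4 sites


def test_covariance_rejects_multiallelic_requested_site():
    t = _table("AAAA", "ACAA", "ATAA", "AGAA")
    with pytest.raises(ValueError, match="2"):
        covariance_network(t, sites=[2, 3])


# --------------------------------------------------------------------------
# codon annotation
# --------------------------------------------------------------------------

def test_key_sites_are_third_codon_positions(default_sim, default_table):
    cfg, aln, _, _ = default_sim
    ann = annotate_codon_synonymy(default_table.to_alignment(), frame=1)
    for p in cfg.key_positions:
        codon_pos, syn = ann[p - 1]
        assert codon_pos == 3
        assert syn is True  # planted in fourfold-degenerate codons


def test_frame_autodetection_on_synthetic_cds(default_sim):
    _, aln, _, _ = default_sim
    assert detect_reading_frame(aln) == 1


def test_synonymous_and_nonsynonymous_sites():
    # GGA/GGG both Gly (site 6 synonymous); GGA vs AGA = Gly vs Ser under
    # the invertebrate mitochondrial code (site 7 nonsynonymous)
    aln = MultipleAlignment(
        ("a", "b", "c"),
        ("ATGGGAGGATTC", "ATGGGGGGATTC", "ATGGGAAGATTC"),
    )
    ann = annotate_codon_synonymy(aln, frame=1)
    assert ann[5] == (3, True)
    assert ann[6] == (1, False)


def test_planted_nonsynonymous_snp_flagged():
    rng = np.random.default_rng(5)
    codons = ["GCT", "ACC", "GTT", "CCA", "GGA", "TCT", "CGA", "ATC"]
    base = "".join(codons)
    # first-position T->A in codon 3 (GTT Val -> ATT Ile): nonsynonymous
    mut = base[:6] + "A" + base[7:]
    aln = MultipleAlignment(("w", "m"), (base, mut))
    ann = annotate_codon_synonymy(aln, frame=1)
    assert ann[6] == (1, False)


def test_all_frames_stopped_raises():
    # TAA at offsets 0, 4 and 8 puts a stop codon in every frame
    aln = MultipleAlignment(("a", "b"), ("TAACTAACTAAC",) * 2)
    with pytest.raises(ValueError, match="strand"):
        detect_reading_frame(aln)
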