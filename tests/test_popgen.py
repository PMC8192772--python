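"""Unit and oracle tests for the diversity, neutrality, mismatch, AMOVA
and PCoA statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coihap.popgen import (amova, diversity_summary, equilibrium_mismatch,
                           ewens_log_pmf, expansion_mismatch, fus_fs,
                           fus_fs_from_counts, mismatch_distribution,
                           nei_haplotype_diversity, pairwise_phi_st, pcoa,
                           raggedness, segregating_sites, tajima_constants,
                           tajimas_d)
from coihap.seqio import MultipleAlignment, PopulationMap


def _aln(*seqs):
    return MultipleAlignment(
        tuple(f"s{i}" for i in range(len(seqs))), tuple(seqs)
    )


# --------------------------------------------------------------------------
# diversity
# --------------------------------------------------------------------------

def test_five_distinct_sequences_have_unit_haplotype_diversity():
    seqs = ["A" * 595 for _ in range(5)]
    for i in range(1, 5):
        seqs[i] = seqs[i][: i] + "G" + seqs[i][i + 1 :]
    rows = diversity_summary(_aln(*seqs))
    (row,) = rows
    assert row.N == 5 and row.N_h == 5
    assert row.h == pytest.approx(1.0, abs=1e-12)


def test_two_sequences_five_differences_K_and_pi():
    a = "A" * 595
    b = "G" * 5 + "A" * 590
    (row,) = diversity_summary(_aln(a, b))
    assert row.K == pytest.approx(5.0, abs=1e-12)
    assert row.S == 5
    assert row.pi_raw == pytest.approx(5 / 595, abs=1e-12)
    assert row.pi_jc > row.pi_raw


def test_identical_sequences_zero_diversity():
    rows = diversity_summary(_aln(*(["ACGTACGT"] * 6)))
    (row,) = rows
    assert row.h == 0 and row.S == 0 and row.K == 0 and row.pi_raw == 0


def test_singleton_population_reported_not_determined():
    aln = _aln("AAAA", "AAGA", "AAGA")
    pops = PopulationMap({"s0": "X", "s1": "Y", "s2": "Y"})
    rows = {r.population: r for r in diversity_summary(aln, pops)}
    assert math.isnan(rows["X"].h)
    assert rows["Y"].N == 2


def test_private_haplotype_counts():
    aln = _aln("AAAA", "AAAA", "AAGA", "AATA")
    pops = PopulationMap({"s0": "X", "s1": "Y", "s2": "Y", "s3": "Y"})
    rows = {r.population: r for r in diversity_summary(aln, pops)}
    # AAAA is shared; AAGA and AATA are private to Y
    assert rows["X"].N_p == 0
    assert rows["Y"].N_p == 2
    assert rows["Total"].N_p == 2


def test_pairwise_deletion_excludes_missing_sites():
    (row,) = diversity_summary(_aln("AANA", "AAGA"))
    assert row.K == 0  # the only differing column is masked by N


def test_jc_correction_always_at_least_raw(default_sim):
    _, aln, pops, _ = default_sim
    for r in diversity_summary(aln, pops):
        if not math.isnan(r.pi_raw):
            assert r.pi_jc >= r.pi_raw


# --------------------------------------------------------------------------
# Tajima's D
# --------------------------------------------------------------------------

def _tajima_oracle(aln):
    """Independent literal re-summation of the 1989 formulas."""
    n = aln.n
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    S = 0
    for j in range(aln.length):
        col = {s[j] for s in aln.seqs if s[j] in "ACGT"}
        if len(col) >= 2:
            S += 1
    diffs = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs.append(
                sum(
                    x != y
                    for x, y in zip(aln.seqs[i], aln.seqs[j])
                    if x in "ACGT" and y in "ACGT"
                )
            )
    K = sum(diffs) / len(diffs)
    return (K - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def test_tajimas_d_matches_literal_oracle(tiny_alignment):
    assert tajimas_d(tiny_alignment) == pytest.approx(
        _tajima_oracle(tiny_alignment), abs=1e-12
    )


def test_tajima_constants_literal_resummation():
    for n in (4, 30, 140):
        c = tajima_constants(n)
        assert c.a1 == pytest.approx(sum(1 / i for i in range(1, n)), rel=1e-12)
        assert c.e2 == pytest.approx(
            (2 * (n**2 + n + 3) / (9 * n * (n - 1))
             - (n + 2) / (c.a1 * n) + c.a2 / c.a1**2)
            / (c.a1**2 + c.a2),
            rel=1e-12,
        )


def test_tajimas_d_not_determined_without_segregation():
    assert math.isnan(tajimas_d(_aln(*["ACGT"] * 5)))
    assert math.isnan(tajimas_d(_aln("ACGT", "ACGA", "ACGT")))  # N < 4


def test_star_simulation_gives_negative_D():
    from coihap.synthdata import CoalescentSimConfig, simulate_coalescent

    aln = simulate_coalescent(
        CoalescentSimConfig(n=50, theta=5, growth_model="star", seed=7)
    )
    assert tajimas_d(aln) < 0


# --------------------------------------------------------------------------
# Fu's Fs
# --------------------------------------------------------------------------

def _exact_fs_oracle(n, k_obs, theta_frac):
    """Exact-rational Ewens tail via integer Stirling numbers."""
    s = {(1, 1): 1}
    for m in range(1, n):
        for k in range(1, m + 2):
            s[(m + 1, k)] = s.get((m, k - 1), 0) + m * s.get((m, k), 0)
    rising = Fraction(1)
    for i in range(n):
        rising *= theta_frac + i
    probs = [
        Fraction(s.get((n, k), 0)) * theta_frac**k / rising
        for k in range(1, n + 1)
    ]
    assert sum(probs) == 1
    s_prime = sum(probs[k_obs - 1 :])
    return math.log(float(s_prime / (1 - s_prime)))


@pytest.mark.parametrize("n,k,theta", [(4, 2, 1), (4, 4, 1), (10, 6, 3)])
def test_fus_fs_matches_exact_rational_oracle(n, k, theta):
    res = fus_fs_from_counts(n, k, float(theta))
    assert res.Fs == pytest.approx(
        _exact_fs_oracle(n, k, Fraction(theta)), rel=1e-10
    )


def test_fs_n4_k2_theta1_is_log3():
    # Stirling row |s(4,k)| = (6, 11, 6, 1); P(K>=2) = 18/24
    assert fus_fs_from_counts(4, 2, 1.0).Fs == pytest.approx(math.log(3))


def test_ewens_probabilities_sum_to_one():
    for n in (5, 30, 58, 100):
        total = np.exp(ewens_log_pmf(n, 5.0)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)


def test_fs_not_determined_for_monomorphic_sample():
    res = fus_fs(_aln(*["ACGT"] * 5))
    assert math.isnan(res.Fs)


def test_fs_strongly_negative_for_expansion_like_sample(default_sim):
    _, aln, _, _ = default_sim
    assert fus_fs(aln).Fs < -10


def test_fs_calibration_near_zero_under_constant_size():
    from coihap.synthdata import (CoalescentSimConfig, replicate_seeds,
                                  simulate_coalescent)

    vals = []
    for s in replicate_seeds(1234, 200):
        aln = simulate_coalescent(
            CoalescentSimConfig(n=30, theta=5, seed=int(s))
        )
        vals.append(fus_fs(aln).Fs)
    assert abs(np.nanmean(vals)) <= 0.5


# --------------------------------------------------------------------------
# mismatch distribution
# --------------------------------------------------------------------------

def test_mismatch_histogram_direct_count():
    # pairwise differences {1, 2, 3}
    aln = _aln("AAAAA", "GAAAA", "AGGAA")
    mm = mismatch_distribution(aln, fit=False)
    assert mm.histogram.tolist() == [0, 1, 1, 1]
    assert mm.n_pairs == 3


def test_mismatch_all_identical_mass_at_zero():
    mm = mismatch_distribution(_aln(*["ACGT"] * 4), fit=False)
    assert mm.histogram.tolist() == [6]
    assert mm.raggedness == pytest.approx(1.0)  # degenerate single-class curve


def test_mismatch_curves_share_total(default_sim):
    _, aln, _, _ = default_sim
    mm = mismatch_distribution(aln)
    assert mm.expected_constant.sum() == pytest.approx(mm.n_pairs, rel=1e-9)
    assert mm.expected_expansion.sum() == pytest.approx(mm.n_pairs, rel=1e-9)
    assert mm.histogram.sum() == aln.n * (aln.n - 1) / 2


def test_expansion_model_limits():
    # tau = 0 reduces to the theta0 equilibrium; large tau to theta1
    f0 = expansion_mismatch(20, theta0=3.0, theta1=50.0, tau=0.0)
    assert np.allclose(f0, equilibrium_mismatch(20, 3.0))
    finf = expansion_mismatch(20, theta0=3.0, theta1=50.0, tau=1e6)
    assert np.allclose(finf, equilibrium_mismatch(20, 50.0))


def test_expansion_model_is_a_probability_distribution():
    f = expansion_mismatch(400, theta0=1.0, theta1=100.0, tau=5.0)
    assert (f >= 0).all()
    assert f.sum() == pytest.approx(1.0, abs=1e-6)


def test_raggedness_flat_curve_is_smooth():
    assert raggedness(np.full(10, 0.1)) < raggedness(
        np.array([0, 0.5, 0, 0.3, 0, 0.2])
    )


# --------------------------------------------------------------------------
# AMOVA
# --------------------------------------------------------------------------

def test_amova_fixed_populations_phi_is_one(two_pop_fixed):
    aln, pops = two_pop_fixed
    res = amova(aln, pops, n_perm=99, seed=0)
    assert res.phi_st == pytest.approx(1.0)
    assert res.ssd_within == pytest.approx(0.0)
    assert res.p_value <= 0.2  # 6 sequences: limited permutation resolution


def test_amova_conservation(default_sim):
    _, aln, pops, _ = default_sim
    res = amova(aln, pops, n_perm=49, seed=1)
    assert res.percent_among + res.percent_within == pytest.approx(100, abs=1e-9)
    assert res.ssd_total == pytest.approx(
        res.ssd_among + res.ssd_within, rel=1e-12
    )
    assert 1 / 50 <= res.p_value <= 1


def test_amova_panmictic_phi_near_zero(default_sim):
    _, aln, pops, _ = default_sim
    res = amova(aln, pops, n_perm=199, seed=11)
    assert abs(res.phi_st) < 0.05
    assert res.p_value > 0.05


def test_pairwise_phi_st_shape_and_nd(default_sim):
    aln = _aln("AAAA", "AAGA", "AATA", "GAAA", "GAGA")
    pops = PopulationMap(
        {"s0": "X", "s1": "X", "s2": "Y", "s3": "Y", "s4": "Z"}
    )
    phi, pval = pairwise_phi_st(aln, pops, n_perm=19, seed=0)
    assert phi.shape == (3, 3)
    assert math.isnan(phi.loc["X", "Z"])  # Z has one sample
    assert not math.isnan(phi.loc["X", "Y"])


@given(
    st.integers(0, 2**31 - 1),
    st.integers(2, 4),
    st.integers(6, 14),
)
@settings(max_examples=25, deadline=None, derandomize=True)
def test_amova_conservation_fuzzed(seed, n_pops, n_seq):
    rng = np.random.default_rng(seed)
    seqs = tuple(
        "".join(rng.choice(list("ACGT"), size=12)) for _ in range(n_seq)
    )
    aln = _aln(*seqs)
    labels = [f"P{rng.integers(n_pops)}" for _ in range(n_seq)]
    while len(set(labels)) < 2:
        labels[rng.integers(n_seq)] = "P_extra"
    pops = PopulationMap(dict(zip(aln.ids, labels)))
    res = amova(aln, pops, n_perm=9, seed=0)
    assert res.percent_among + res.percent_within == pytest.approx(100, abs=1e-9)
    assert res.ssd_total == pytest.approx(
        res.ssd_among + res.ssd_within, abs=1e-9
    )
    assert 0.1 <= res.p_value <= 1.0


# --------------------------------------------------------------------------
# PCoA
# --------------------------------------------------------------------------

def test_pcoa_collinear_points_recover_spacing():
    D = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
    res = pcoa(D)
    assert res.coordinates.shape[1] == 1
    x = np.sort(res.coordinates[:, 0])
    assert np.allclose(np.diff(x), [1.0, 1.0])


def test_pcoa_recovers_planar_distances():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(12, 2))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    res = pcoa(D)
    rec = res.coordinates[:, :2]
    Dr = np.sqrt(((rec[:, None] - rec[None]) ** 2).sum(-1))
    assert np.allclose(D, Dr, atol=1e-9)
    assert res.explained_fraction.sum() == pytest.approx(1.0)


def test_pcoa_matches_scikit_bio():
    from skbio.stats.ordination import pcoa as skbio_pcoa

    rng = np.random.default_rng(3)
    pts = rng.normal(size=(10, 4))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    ours = pcoa(D)
    theirs = skbio_pcoa(D, number_of_dimensions=4)
    assert np.allclose(
        ours.explained_fraction[:4],
        theirs.proportion_explained.values[:4],
        atol=1e-8,
    )
    for ax in range(3):
        a = ours.coordinates[:, ax]
        b = theirs.samples.values[:, ax]
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-6)


def test_pcoa_rejects_asymmetric_input():
    D = np.array([[0.0, 1], [2, 0]])
    with pytest.raises(ValueError, match="symmetric"):
        pcoa(D)


def test_pcoa_groups_cluster(default_table, default_sim):
    from coihap.hotspots import assign_groups
    from coihap.popgen import pairwise_difference_matrix

    cfg, _, _, _ = default_sim
    ga = assign_groups(default_table, cfg.key_positions)
    diffs, _ = pairwise_difference_matrix(default_table.to_alignment())
    res = pcoa(diffs.astype(float))
    coords = res.coordinates[:, :2]
    idx = {h.hap_id: i for i, h in enumerate(default_table)}
    within, between = [], []
    haps = list(default_table)
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            d = np.linalg.norm(coords[i] - coords[j])
            same = (
                ga.per_haplotype[haps[i].hap_id]
                == ga.per_haplotype[haps[j].hap_id]
            )
            (within if same else between).append(d)
    assert np.mean(within) < np.mean(between)
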