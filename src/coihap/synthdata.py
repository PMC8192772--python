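"""Synthetic data generators with the statistical structure the analyses
assume, so every pipeline stage is testable without downloads.

Three generators are provided:

``simulate_expansion_alignment``
    An alignment emulating the study system's structure: 140 individuals
    collapsing to 58 haplotypes of a 595 bp coding fragment; four A/G
    hotspot key sites (207/282/354/420) partitioning haplotypes into
    groups planted along a stepwise A->G path (default sizes 35/12/1/8
    for the four canonical groups, plus two single-haplotype variant key
    strings so the totals close); 71 polymorphic / 31 parsimony-
    informative sites; a dominant haplotype carrying ~19% of individuals
    and many singletons (a star-like expansion profile); populations with
    no between-population structure at mixing = 1.

``simulate_coalescent``
    An infinite-sites coalescent for calibrating the neutrality tests:
    either the standard constant-size Kingman genealogy or a star
    genealogy (all lineages joined at one node, equal branch lengths
    scaled so the expected pairwise difference equals theta), which
    yields the excess of singletons characteristic of sudden expansion.

``make_motif_fixture``
    A G-free random background with G-quadruplex motifs planted at exact
    start-to-start spacings, for scanner round-trip tests.

All generators are deterministic functions of their seed (same seed,
byte-identical output) and return the planted truth for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .seqio import MultipleAlignment, PopulationMap

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _default_group_frequencies() -> dict[str, int]:
    # Four canonical key-string groups at the study's sizes, plus two
    # single-haplotype variant key strings so 58 haplotypes close exactly.
    return {
        "A-A-A-A": 35,
        "A-A-G-A": 12,
        "G-A-G-A": 1,
        "G-G-G-G": 8,
        "A-A-A-G": 1,
        "A-G-A-A": 1,
    }


@dataclass(frozen=True)
class ExpansionSimConfig:
    n_individuals: int = 140
    seq_length: int = 595
    key_positions: tuple[int, ...] = (207, 282, 354, 420)
    group_frequencies: Mapping[str, int] = field(
        default_factory=_default_group_frequencies
    )
    n_polymorphic: int = 71
    n_informative: int = 31
    dominant_fraction: float = 27.0 / 140.0   # the dominant haplotype's share
    singleton_fraction: float = 43.0 / 58.0   # fraction of haplotypes singleton
    third_position_bias: float = 0.9          # P(a planted site is 3rd codon pos)
    ancestral_state: str = "A"
    derived_state: str = "G"
    n_populations: int = 9
    population_mixing: float = 1.0            # 1 = panmictic
    seed: int = 1

    @property
    def n_haplotypes_target(self) -> int:
        return sum(self.group_frequencies.values())

    def __post_init__(self) -> None:
        if self.n_haplotypes_target > self.n_individuals:
            raise ValueError("more haplotypes than individuals")
        pos = list(self.key_positions)
        if pos != sorted(set(pos)):
            raise ValueError("key positions must be strictly increasing")
        if pos and pos[-1] > self.seq_length:
            raise ValueError("key position outside sequence")
        for ks in self.group_frequencies:
            if len(ks.split("-")) != len(pos):
                raise ValueError(f"key string {ks!r} does not match key sites")
        if not 0.0 <= self.population_mixing <= 1.0:
            raise ValueError("population_mixing must be in [0, 1]")


@dataclass(frozen=True)
class ExpansionTruth:
    """Planted ground truth returned alongside the simulated alignment."""

    haplotype_sequences: tuple[str, ...]
    haplotype_counts: tuple[int, ...]
    haplotype_groups: tuple[str, ...]          # key string per haplotype
    group_sizes: Mapping[str, int]             # haplotypes per key string
    key_positions: tuple[int, ...]
    shared_sites: tuple[int, ...]              # planted parsimony-informative
    singleton_sites: tuple[int, ...]
    stepwise_path: tuple[str, ...]             # ancestral -> most derived
    sample_to_haplotype: Mapping[str, int]


def _sense_codons(code: int = 5) -> list[str]:
    """Sense codons of the given table, excluding TA*-initial codons so a
    third-position transition can never create a stop."""
    table = CodonTable.unambiguous_dna_by_id[code]
    return [
        c
        for c in table.forward_table
        if not c.startswith("TA")
    ]


def _hamming_key(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a.split("-"), b.split("-")))


def _largest_remainder(weights: np.ndarray, total: int, minimum: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to weights, each part
    at least ``minimum``; deterministic largest-remainder rounding."""
    k = len(weights)
    if total < k * minimum:
        raise ValueError("allocation infeasible")
    spare = total - k * minimum
    raw = weights / weights.sum() * spare
    base = np.floor(raw).astype(int)
    rem = raw - base
    short = spare - base.sum()
    order = np.argsort(-rem, kind="stable")
    base[order[:short]] += 1
    return base + minimum


def simulate_expansion_alignment(
    cfg: ExpansionSimConfig,
) -> tuple[MultipleAlignment, PopulationMap, ExpansionTruth]:
    """Generate an alignment, population map and planted truth record.

    The ancestral sequence is a random in-frame coding sequence
    (translation table 5, frame 1, no internal stop codons, and no TA*-
    initial codons so planted third-position transitions stay stop-free).
    Key-site codons are chosen so the ancestral state occupies the key
    position and the derived state is tolerated; with third-position key
    sites both states are synonymous fourfold-family members.  Planted
    mutations are transitions, one site per codon, biased toward third
    codon positions.  Haplotype distinctness and the planted polymorphic/
    informative site counts hold by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.seq_length
    n_codons = L // 3
    code = CodonTable.unambiguous_dna_by_id[5]
    stops = set(code.stop_codons)
    pool = _sense_codons(5)

    # --- ancestral coding backbone -------------------------------------
    codons = [pool[i] for i in rng.integers(0, len(pool), size=n_codons)]
    tail = "".join("ACT"[i] for i in rng.integers(0, 3, size=L - 3 * n_codons))

    key_codon_idx = set()
    for p in cfg.key_positions:
        ci = (p - 1) // 3
        if ci >= n_codons:
            raise ValueError(f"key site {p} falls in an incomplete codon")
        off = (p - 1) % 3
        key_codon_idx.add(ci)
        ok = [
            c
            for c in pool
            if c[off] == cfg.ancestral_state
            and _mutate(c, off, cfg.derived_state) not in stops
            and not _mutate(c, off, cfg.derived_state).startswith("TA")
        ]
        if off == 2:
            fourfold = [
                c for c in ok
                if code.forward_table[c]
                == code.forward_table.get(_mutate(c, 2, cfg.derived_state))
            ]
            ok = fourfold or ok
        codons[ci] = ok[int(rng.integers(0, len(ok)))]
    ancestral = "".join(codons) + tail

    # --- roster of haplotypes ------------------------------------------
    anc_key = "-".join([cfg.ancestral_state] * len(cfg.key_positions))
    group_order = sorted(
        cfg.group_frequencies,
        key=lambda k: (_hamming_key(k, anc_key), k),
    )
    path = tuple(
        k for k in group_order if k in cfg.group_frequencies
    )
    hap_group: list[str] = []
    is_base: list[bool] = []
    for g in group_order:
        for i in range(cfg.group_frequencies[g]):
            hap_group.append(g)
            is_base.append(i == 0)
    n_hap = len(hap_group)

    # --- planted site budget -------------------------------------------
    # informativeness of key sites under haplotype weighting
    n_key_poly = n_key_inf = 0
    for i in range(len(cfg.key_positions)):
        counts: dict[str, int] = {}
        for g, size in cfg.group_frequencies.items():
            st = g.split("-")[i]
            counts[st] = counts.get(st, 0) + size
        if len(counts) >= 2:
            n_key_poly += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_key_inf += 1
    n_shared = cfg.n_informative - n_key_inf
    n_single_sites = cfg.n_polymorphic - n_key_poly - n_shared
    non_base = [i for i in range(n_hap) if not is_base[i]]
    if n_shared < 0 or n_single_sites < 0:
        raise ValueError("site budget infeasible for the requested counts")
    if len(non_base) > n_single_sites + n_shared:
        raise ValueError(
            "cannot make all haplotypes distinct: too few plantable sites"
        )
    if len(non_base) < n_single_sites:
        raise ValueError("more singleton sites than non-base haplotypes")

    # --- choose planted positions (one site per codon) -----------------
    free_codons = [i for i in range(n_codons) if i not in key_codon_idx]
    rng.shuffle(free_codons)
    site_positions: list[int] = []
    ci_iter = iter(free_codons)
    for _ in range(n_shared + n_single_sites):
        while True:
            try:
                ci = next(ci_iter)
            except StopIteration as exc:
                raise ValueError("sequence too short for site budget") from exc
            third = rng.random() < cfg.third_position_bias
            off = 2 if third else int(rng.integers(0, 2))
            pos = 3 * ci + off + 1
            base = ancestral[pos - 1]
            mut_codon = _mutate(codons[ci], off, _TRANSITION[base])
            if mut_codon in stops:
                continue  # skip this codon, try the next
            site_positions.append(pos)
            break
    shared_sites = sorted(site_positions[:n_shared])
    singleton_sites = sorted(site_positions[n_shared:])

    # --- distribute sites over haplotypes ------------------------------
    holders = list(non_base)
    rng.shuffle(holders)
    singleton_holders = holders[:n_single_sites]
    primary_holders = holders[n_single_sites:]  # distinguished by shared sites
    site_members: dict[int, set[int]] = {p: set() for p in shared_sites}
    for idx, hap in enumerate(primary_holders):
        site_members[shared_sites[idx]].add(hap)
    for p in shared_sites:
        want = int(rng.integers(2, 6))
        extras = [
            h for h in singleton_holders if h not in site_members[p]
        ]
        rng.shuffle(extras)
        need = max(2, want) - len(site_members[p])
        site_members[p].update(extras[:need])
        if len(site_members[p]) < 2:
            raise ValueError("cannot give a shared site two carriers")
    hap_sites: dict[int, set[int]] = {i: set() for i in range(n_hap)}
    for hap, pos in zip(singleton_holders, singleton_sites):
        hap_sites[hap].add(pos)
    for pos, members in site_members.items():
        for hap in members:
            hap_sites[hap].add(pos)

    # --- build haplotype sequences -------------------------------------
    key_off = {p: p - 1 for p in cfg.key_positions}
    hap_seqs: list[str] = []
    for i in range(n_hap):
        seq = list(ancestral)
        for kp, st in zip(cfg.key_positions, hap_group[i].split("-")):
            seq[key_off[kp]] = st
        for pos in hap_sites[i]:
            seq[pos - 1] = _TRANSITION[ancestral[pos - 1]]
        hap_seqs.append("".join(seq))
    if len(set(hap_seqs)) != n_hap:
        raise AssertionError("planted haplotypes are not distinct")

    # --- individual counts per haplotype -------------------------------
    counts = _allocate_counts(cfg, hap_group, is_base, path, rng)

    # --- emit individuals and populations ------------------------------
    ids, seqs, assignment = [], [], {}
    pops = [f"P{i + 1}" for i in range(cfg.n_populations)]
    home = rng.integers(0, cfg.n_populations, size=n_hap)
    width = max(3, len(str(cfg.n_individuals)))
    k = 0
    sample_to_hap: dict[str, int] = {}
    for i in range(n_hap):
        for _ in range(counts[i]):
            k += 1
            sid = f"S{k:0{width}d}"
            ids.append(sid)
            seqs.append(hap_seqs[i])
            if rng.random() < cfg.population_mixing:
                assignment[sid] = pops[int(rng.integers(0, cfg.n_populations))]
            else:
                assignment[sid] = pops[int(home[i])]
            sample_to_hap[sid] = i
    aln = MultipleAlignment(tuple(ids), tuple(seqs))
    truth = ExpansionTruth(
        haplotype_sequences=tuple(hap_seqs),
        haplotype_counts=tuple(int(c) for c in counts),
        haplotype_groups=tuple(hap_group),
        group_sizes=dict(cfg.group_frequencies),
        key_positions=cfg.key_positions,
        shared_sites=tuple(shared_sites),
        singleton_sites=tuple(singleton_sites),
        stepwise_path=path,
        sample_to_haplotype=sample_to_hap,
    )
    return aln, PopulationMap(assignment), truth


def _mutate(codon: str, offset: int, base: str) -> str:
    return codon[:offset] + base + codon[offset + 1 :]


def _allocate_counts(
    cfg: ExpansionSimConfig,
    hap_group: list[str],
    is_base: list[bool],
    path: tuple[str, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Individuals per haplotype: one dominant haplotype (~19% of the
    sample, planted in the most derived group), a singleton majority, and
    geometric-decay counts for the rest — concentrated in the earlier
    (more ancestral) groups so within-group diversity decreases along the
    planted path."""
    n_hap = len(hap_group)
    n_ind = cfg.n_individuals
    counts = np.ones(n_hap, dtype=int)
    n_extra = n_ind - n_hap
    derived = path[-1]
    dom = next(
        i for i in range(n_hap) if hap_group[i] == derived and is_base[i]
    )
    dom_extra = min(max(0, round(cfg.dominant_fraction * n_ind) - 1), n_extra)
    counts[dom] += dom_extra
    n_extra -= dom_extra
    if n_extra == 0:
        return counts
    n_singleton = round(cfg.singleton_fraction * n_hap)
    n_multi = max(1, n_hap - n_singleton - 1)
    group_sizes = {g: hap_group.count(g) for g in set(hap_group)}
    eligible = [
        g for g in path if g != derived and group_sizes[g] >= 2
    ]
    multi: list[int] = []
    if eligible:
        w = np.array([group_sizes[g] for g in eligible], dtype=float)
        per_group = dict(zip(eligible, _largest_remainder(
            w, min(n_multi, sum(group_sizes[g] for g in eligible)), 0)))
        # concentrate counts in the later (more derived) eligible groups so
        # haplotype diversity decreases along the path: the geometric decay
        # below gives the front of this list the largest counts
        for g in reversed(eligible):
            members = [i for i in range(n_hap) if hap_group[i] == g]
            multi.extend(members[: int(per_group[g])])
    if not multi:
        multi = [i for i in range(n_hap) if i != dom][: n_multi]
    if not multi:  # single-haplotype degenerate case
        counts[dom] += n_extra
        return counts
    weights = 0.75 ** np.arange(len(multi))
    extra = _largest_remainder(weights, n_extra, minimum=1 if
                               n_extra >= len(multi) else 0)
    for i, e in zip(multi, extra):
        counts[i] += int(e)
    assert counts.sum() == n_ind
    return counts


# --------------------------------------------------------------------------
# Coalescent simulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CoalescentSimConfig:
    n: int
    theta: float
    growth_model: str = "constant"   # constant | star
    seq_length: int = 595
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.growth_model not in ("constant", "star"):
            raise ValueError("growth_model must be 'constant' or 'star'")


def simulate_coalescent(cfg: CoalescentSimConfig) -> MultipleAlignment:
    """Infinite-sites coalescent alignment.

    constant: the n-sample Kingman coalescent; waiting time with k
    lineages is Exp(k(k-1)/2) in coalescent units, and each lineage
    accumulates Poisson(theta/2 * t) mutations per interval, shared by
    every sample below it.

    star: every lineage hangs from a single node with equal branch length
    1 (coalescent units), so each sample receives an independent
    Poisson(theta/2) mutation load and the expected pairwise difference
    equals theta, matching the constant model for direct comparison.

    Mutations map to distinct sites (ancestral A, derived G); if the
    realised number of segregating sites exceeds seq_length, an error
    advises a longer sequence (sites are never reused).
    """
    rng = np.random.default_rng(cfg.seed)
    n, theta = cfg.n, cfg.theta
    mutations: list[tuple[frozenset[int], int]] = []  # (carriers, count)
    if cfg.growth_model == "constant":
        lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
        while len(lineages) > 1:
            k = len(lineages)
            t = rng.exponential(2.0 / (k * (k - 1)))
            m_counts = rng.poisson(theta / 2.0 * t, size=k)
            for lin, m in zip(lineages, m_counts):
                if m > 0:
                    mutations.append((lin, int(m)))
            i, j = rng.choice(k, size=2, replace=False)
            merged = lineages[i] | lineages[j]
            lineages = [
                lin for idx, lin in enumerate(lineages) if idx not in (i, j)
            ]
            lineages.append(merged)
    else:
        m_counts = rng.poisson(theta / 2.0, size=n)
        for i, m in enumerate(m_counts):
            if m > 0:
                mutations.append((frozenset([i]), int(m)))
    total = sum(m for _, m in mutations)
    if total > cfg.seq_length:
        raise ValueError(
            f"{total} mutations exceed seq_length={cfg.seq_length}; "
            "use a longer sequence"
        )
    sites = rng.choice(cfg.seq_length, size=total, replace=False)
    seqs = np.full((n, cfg.seq_length), ord("A"), dtype=np.uint8)
    pos = 0
    for carriers, m in mutations:
        for _ in range(m):
            seqs[list(carriers), sites[pos]] = ord("G")
            pos += 1
    width = max(3, len(str(n)))
    return MultipleAlignment(
        tuple(f"S{i + 1:0{width}d}" for i in range(n)),
        tuple(bytes(row).decode("ascii") for row in seqs),
    )


def replicate_seeds(seed: int, n_reps: int) -> np.ndarray:
    """Child seeds (< 2^31) for replicate simulations from one seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_reps)


# --------------------------------------------------------------------------
# Motif fixture
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifFixture:
    sequence: str
    planted_spans: tuple[tuple[int, int], ...]   # 1-based inclusive
    planted_loops: tuple[tuple[int, int, int], ...]


def make_motif_fixture(
    motif_spec: Sequence[tuple[Sequence[int], Sequence[int]]],
    spacings: Sequence[int],
    seq_length: int,
    seed: int = 0,
    first_start: int = 1,
) -> MotifFixture:
    """Plant G-quadruplex motifs on a G-free random background.

    ``motif_spec`` lists (tract_lengths, loop_lengths) per motif;
    ``spacings`` are start-to-start distances between consecutive motifs.
    Loop fillers and the background are drawn from A/C/T only, so every
    planted G-run is maximal and the planted motifs are the only ones.
    """
    if motif_spec and len(spacings) != len(motif_spec) - 1:
        raise ValueError("need one spacing fewer than motifs")
    rng = np.random.default_rng(seed)
    bg = list("ACT"[i] for i in rng.integers(0, 3, size=seq_length))
    spans: list[tuple[int, int]] = []
    loops_out: list[tuple[int, int, int]] = []
    start = first_start
    for m, (tracts, loops) in enumerate(motif_spec):
        if len(tracts) != 4 or len(loops) != 3:
            raise ValueError("each motif needs 4 tracts and 3 loops")
        length = sum(tracts) + sum(loops)
        end = start + length - 1
        if end > seq_length:
            raise ValueError("motifs do not fit in seq_length")
        if spans and start <= spans[-1][1]:
            raise ValueError("planted motifs overlap")
        pos = start - 1
        for t, tract in enumerate(tracts):
            bg[pos : pos + tract] = ["G"] * tract
            pos += tract
            if t < 3:
                pos += loops[t]  # keep background (G-free) in the loop
        spans.append((start, end))
        loops_out.append(tuple(loops))
        if m < len(spacings):
            start = start + spacings[m]
    return MotifFixture("".join(bg), tuple(spans), tuple(loops_out))
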