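"""Site classification, hotspot-key haplotype groups, transition-order
inference and the positional covariance network.

The study system shows four purine "hotspot" columns in a COI alignment
(sites 207, 282, 354, 420; 1-based) whose A/G states change in a
concerted, apparently stepwise fashion.  Concatenating a haplotype's
states at those key sites yields a key string such as ``A-A-G-A``; key
strings partition the haplotypes into genetic groups.  The direction of
change (polarity) is inferred from within-group haplotype diversity: the
group with the highest diversity is taken as ancestral, mirroring the
standard argument that older alleles have accumulated more variation.

"Covariance" between two sites counts haplotypes whose states fall in the
same polarity class at both sites (both ancestral/major or both
derived/minor).  The definition is interpretive — the field usage it
implements is concerted-variation counting over an alignment, reported as
counts and frequency ratios on a network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio.Data import CodonTable

from .popgen import nei_haplotype_diversity
from .seqio import HaplotypeTable, MultipleAlignment

log = logging.getLogger(__name__)

_TRANSITIONS = ({"A", "G"}, {"C", "T"})
_BASES = "ACGT"


@dataclass(frozen=True)
class SiteClassification:
    position: int                      # 1-based
    state_counts: Mapping[str, int]    # A/C/G/T tallies (N and '-' ignored)
    is_polymorphic: bool
    is_parsimony_informative: bool
    substitution_class: str | None     # transition | transversion | multi-state
    codon_position: int | None = None
    is_synonymous: bool | None = None


def classify_sites(
    haps: HaplotypeTable,
    weighting: str = "haplotype",
    annotation: Sequence[tuple[int | None, bool | None]] | None = None,
) -> list[SiteClassification]:
    """Per-site state tallies and polymorphism/informativeness flags.

    weighting="haplotype" gives one vote per haplotype (the counting unit
    of the study's 71/31 site counts); "individual" weights each haplotype
    by its member count.  ``annotation`` optionally merges per-site
    (codon_position, is_synonymous) pairs from
    :func:`annotate_codon_synonymy`.
    """
    if haps.n_haplotypes < 2:
        raise ValueError("site classification needs >= 2 haplotypes")
    if weighting not in ("haplotype", "individual"):
        raise ValueError(f"unknown weighting {weighting!r}")
    seqs = [h.sequence for h in haps]
    weights = [
        1 if weighting == "haplotype" else h.count_total for h in haps
    ]
    length = len(seqs[0])
    out: list[SiteClassification] = []
    for j in range(length):
        counts: dict[str, int] = {}
        for seq, w in zip(seqs, weights):
            ch = seq[j]
            if ch in _BASES:
                counts[ch] = counts.get(ch, 0) + w
        states = sorted(counts)
        poly = len(states) >= 2
        informative = sum(1 for s in states if counts[s] >= 2) >= 2
        if not poly:
            sub = None
        elif len(states) > 2:
            sub = "multi-state"
        elif set(states) in _TRANSITIONS:
            sub = "transition"
        else:
            sub = "transversion"
        cp, syn = (None, None)
        if annotation is not None:
            cp, syn = annotation[j]
        out.append(
            SiteClassification(
                position=j + 1,
                state_counts=counts,
                is_polymorphic=poly,
                is_parsimony_informative=informative and poly,
                substitution_class=sub,
                codon_position=cp,
                is_synonymous=syn,
            )
        )
    return out


def polymorphic_sites(haps: HaplotypeTable) -> list[int]:
    return [c.position for c in classify_sites(haps) if c.is_polymorphic]


def parsimony_informative_sites(haps: HaplotypeTable) -> list[int]:
    return [
        c.position for c in classify_sites(haps) if c.is_parsimony_informative
    ]


# --------------------------------------------------------------------------
# Key-string groups
# --------------------------------------------------------------------------

def key_string(sequence: str, positions: Sequence[int]) -> str:
    return "-".join(sequence[p - 1] for p in positions)


@dataclass(frozen=True)
class GroupAssignment:
    key_positions: tuple[int, ...]
    groups: Mapping[str, tuple[str, ...]]       # key string -> hap ids
    group_order: tuple[str, ...]                # provisional or inferred
    per_group_h: Mapping[str, float]            # weighted by individuals
    per_haplotype: Mapping[str, str]            # hap id -> key string

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}


def assign_groups(
    haps: HaplotypeTable, key_positions: Sequence[int]
) -> GroupAssignment:
    """Partition haplotypes by their states at the key sites.

    Warns for key sites that are monomorphic or not biallelic among the
    haplotypes (the site is retained either way).  The provisional group
    order is by descending total individual count, ties by key string.
    Within-group haplotype diversity is Nei's h over haplotype frequencies
    weighted by individual counts.
    """
    length = len(haps.haplotypes[0].sequence)
    for p in key_positions:
        if not (1 <= p <= length):
            raise ValueError(f"key site {p} outside alignment (1..{length})")
        states = {h.sequence[p - 1] for h in haps}
        if len(states) == 1:
            log.warning("key site %d is monomorphic (%s)", p, states.pop())
        elif len(states) > 2:
            log.warning("key site %d is not biallelic: %s", p, sorted(states))
    groups: dict[str, list[str]] = {}
    per_hap: dict[str, str] = {}
    for h in haps:
        ks = key_string(h.sequence, key_positions)
        groups.setdefault(ks, []).append(h.hap_id)
        per_hap[h.hap_id] = ks
    per_group_h = {
        ks: nei_haplotype_diversity(
            [haps[hid].count_total for hid in members]
        )
        for ks, members in groups.items()
    }
    ind_counts = {
        ks: sum(haps[hid].count_total for hid in members)
        for ks, members in groups.items()
    }
    order = tuple(sorted(groups, key=lambda k: (-ind_counts[k], k)))
    return GroupAssignment(
        key_positions=tuple(key_positions),
        groups={k: tuple(v) for k, v in groups.items()},
        group_order=order,
        per_group_h=per_group_h,
        per_haplotype=per_hap,
    )


@dataclass(frozen=True)
class TransitionOrder:
    ordered_groups: tuple[str, ...]             # ancestral -> most derived
    polarity: Mapping[int, tuple[str, str]]     # site -> (ancestral, derived)
    stepwise: bool                              # consecutive keys differ at 1 site


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a.split("-"), b.split("-")))


def infer_transition_order(
    ga: GroupAssignment, ancestral: str | None = None
) -> TransitionOrder:
    """Order groups from ancestral to derived and polarise the key sites.

    The ancestral group is the one with maximal within-group haplotype
    diversity (a diversity tie raises an error demanding an explicit
    ``ancestral`` override, since the data cannot break it).  Remaining
    groups are ordered by Hamming distance of their key string from the
    ancestral key, ties broken by descending within-group diversity, then
    lexicographically for determinism.  A stepwise path is flagged only
    when every consecutive pair of key strings differs at exactly one
    site.
    """
    keys = list(ga.groups)
    if len(keys) < 2:
        raise ValueError("transition order needs >= 2 groups")
    if ancestral is None:
        hs = {k: ga.per_group_h.get(k, float("nan")) for k in keys}
        finite = {k: (0.0 if h != h else h) for k, h in hs.items()}
        best = max(finite.values())
        top = [k for k, h in finite.items() if h == best]
        if len(top) > 1:
            raise ValueError(
                f"within-group diversity tie for ancestral group {top}; "
                "pass ancestral= explicitly"
            )
        ancestral = top[0]
    elif ancestral not in ga.groups:
        raise ValueError(f"{ancestral!r} is not an observed group")
    rest = [k for k in keys if k != ancestral]
    rest.sort(
        key=lambda k: (
            _hamming(k, ancestral),
            -(ga.per_group_h.get(k) or 0.0)
            if ga.per_group_h.get(k) == ga.per_group_h.get(k)
            else 0.0,
            k,
        )
    )
    ordered = (ancestral, *rest)
    anc_states = ancestral.split("-")
    polarity: dict[int, tuple[str, str]] = {}
    for i, pos in enumerate(ga.key_positions):
        alts = sorted(
            {k.split("-")[i] for k in keys} - {anc_states[i]}
        )
        if alts:
            polarity[pos] = (anc_states[i], alts[0])
            if len(alts) > 1:
                log.warning(
                    "key site %d has several derived states %s", pos, alts
                )
        else:
            polarity[pos] = (anc_states[i], anc_states[i])
    stepwise = all(
        _hamming(a, b) == 1 for a, b in zip(ordered, ordered[1:])
    )
    if not stepwise:
        log.info("group chain is non-stepwise")
    return TransitionOrder(ordered, polarity, stepwise)


# --------------------------------------------------------------------------
# Covariance network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CovarianceEdge:
    site_i: int
    site_j: int
    covariate_count: int
    frequency_ratio: float


def _site_classes(
    haps: HaplotypeTable,
    site: int,
    polarity: Mapping[int, tuple[str, str]] | None,
) -> dict[str, int]:
    """Map observed states at a biallelic site to class 0/1.

    Class 0 is the ancestral state when polarity is supplied, else the
    major (most frequent over haplotypes) state, ties broken toward the
    alphabetically smaller base for determinism.
    """
    counts: dict[str, int] = {}
    for h in haps:
        ch = h.sequence[site - 1]
        if ch in _BASES:
            counts[ch] = counts.get(ch, 0) + 1
    states = sorted(counts)
    if len(states) > 2:
        raise ValueError(f"site {site} is multi-allelic: {states}")
    if polarity is not None and site in polarity:
        anc, der = polarity[site]
        return {anc: 0, der: 1}
    if len(states) == 1:
        return {states[0]: 0}
    major = max(states, key=lambda s: (counts[s], -ord(s)))
    minor = next(s for s in states if s != major)
    return {major: 0, minor: 1}


def covariance_network(
    haps: HaplotypeTable,
    sites: Sequence[int] | None = None,
    polarity: Mapping[int, tuple[str, str]] | None = None,
) -> list[CovarianceEdge]:
    """Pairwise same-class concordance counts over haplotypes.

    For each pair of (biallelic) sites, counts the haplotypes whose states
    at both sites fall in the same polarity class.  Haplotypes with a
    missing or out-of-class state at either site are not covariate.  The
    default site set is all polymorphic sites; multi-allelic sites in a
    user-requested set raise an error listing the sites.
    """
    if haps.n_haplotypes < 2:
        raise ValueError("covariance network needs >= 2 haplotypes")
    if sites is None:
        sites = [
            c.position
            for c in classify_sites(haps)
            if c.is_polymorphic and len(c.state_counts) == 2
        ]
    else:
        bad = []
        for s in sites:
            states = {
                h.sequence[s - 1] for h in haps if h.sequence[s - 1] in _BASES
            }
            if len(states) > 2:
                bad.append(s)
        if bad:
            raise ValueError(f"multi-allelic site(s) in requested set: {bad}")
    class_maps = {s: _site_classes(haps, s, polarity) for s in sites}
    n = haps.n_haplotypes
    edges: list[CovarianceEdge] = []
    for a, b in combinations(sorted(sites), 2):
        ca, cb = class_maps[a], class_maps[b]
        count = 0
        for h in haps:
            sa = ca.get(h.sequence[a - 1])
            sb = cb.get(h.sequence[b - 1])
            if sa is not None and sa == sb:
                count += 1
        edges.append(CovarianceEdge(a, b, count, count / n))
    return edges


def covariance_graph(edges: Iterable[CovarianceEdge]) -> nx.Graph:
    """Weighted undirected graph for GraphML export / network display."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(
            e.site_i, e.site_j, count=e.covariate_count, ratio=e.frequency_ratio
        )
    return g


# --------------------------------------------------------------------------
# Codon position and synonymy annotation
# --------------------------------------------------------------------------

def detect_reading_frame(
    aln: MultipleAlignment, code: int = 5, max_stop_fraction: float = 0.05
) -> int:
    """Pick the frame (1, 2 or 3) minimising internal stop codons.

    Counted over complete codons of every sequence under the given
    translation table (default 5, invertebrate mitochondrial, the standard
    table for this gene).  Raises if even the best frame has stops in more
    than ``max_stop_fraction`` of codons — a sign of a wrong strand or
    genetic code.
    """
    table = CodonTable.unambiguous_dna_by_id[code]
    stops = set(table.stop_codons)
    best_frame, best_count, totals = 1, None, {}
    for frame in (1, 2, 3):
        count = total = 0
        for seq in aln.seqs:
            body = seq[frame - 1 :]
            for k in range(0, len(body) - 2, 3):
                codon = body[k : k + 3]
                total += 1
                if codon in stops:
                    count += 1
        totals[frame] = (count, total)
        if best_count is None or count < best_count:
            best_frame, best_count = frame, count
    count, total = totals[best_frame]
    if total and count / total > max_stop_fraction:
        raise ValueError(
            f"all frames contain internal stops in >{max_stop_fraction:.0%} "
            "of codons; check strand or genetic code"
        )
    return best_frame


def annotate_codon_synonymy(
    aln: MultipleAlignment, code: int = 5, frame: int | str = "auto"
) -> list[tuple[int | None, bool | None]]:
    """Per-site (codon_position, is_synonymous) for a coding alignment.

    A polymorphic site is synonymous iff every observed state yields the
    same amino acid with each haplotype-specific codon context held fixed.
    Sites in incomplete terminal codons get codon_position but synonymy
    None; monomorphic sites get synonymy None.
    """
    if frame == "auto":
        frame = detect_reading_frame(aln, code=code)
    if frame not in (1, 2, 3):
        raise ValueError("frame must be 1, 2, 3 or 'auto'")
    table = CodonTable.unambiguous_dna_by_id[code].forward_table
    stops = set(CodonTable.unambiguous_dna_by_id[code].stop_codons)

    def aa(codon: str) -> str | None:
        if any(c not in _BASES for c in codon):
            return None
        return "*" if codon in stops else table[codon]

    L = aln.length
    out: list[tuple[int | None, bool | None]] = []
    for j in range(L):  # 0-based column
        offset = j - (frame - 1)
        if offset < 0:
            out.append((None, None))
            continue
        codon_pos = offset % 3 + 1
        codon_start = j - (codon_pos - 1)
        if codon_start + 3 > L:
            out.append((codon_pos, None))
            continue
        states = {
            seq[j] for seq in aln.seqs if seq[j] in _BASES
        }
        if len(states) < 2:
            out.append((codon_pos, None))
            continue
        synonymous = True
        for seq in aln.seqs:
            ctx = list(seq[codon_start : codon_start + 3])
            aas = set()
            for st in states:
                ctx[codon_pos - 1] = st
                a = aa("".join(ctx))
                if a is None:
                    continue
                aas.add(a)
            if len(aas) > 1:
                synonymous = False
                break
        out.append((codon_pos, synonymous))
    return out
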