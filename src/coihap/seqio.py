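"""Alignment and haplotype I/O.

The substrate of every analysis in this package is a multiple sequence
alignment of equal-length mtDNA fragments (the study system is a 595 bp
COI barcode fragment) together with a sample-to-population map.  This
module reads and validates those inputs, collapses identical sequences
into haplotypes, and writes haplotype tables.

Conventions
-----------
* Site coordinates are 1-based and inclusive everywhere in this package,
  so hotspot sites quoted as 207/282/354/420 refer to alignment columns
  207, 282, 354 and 420.
* A haplotype is defined by exact string identity.  ``N`` and ``-`` are
  ordinary characters for the purpose of identity (``N`` does not
  wildcard-match); downstream statistics treat them as missing data.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

VALID_CHARS = frozenset("ACGTN-")
_INVALID_RE = re.compile(r"[^ACGTN\-]")


class AlignmentError(ValueError):
    """Raised when an input violates alignment invariants."""


@dataclass(frozen=True)
class MultipleAlignment:
    """An ordered, validated set of equal-length sequence records."""

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs must have equal length")
        if not self.ids:
            raise AlignmentError("alignment is empty")
        length = len(self.seqs[0])
        if length < 1:
            raise AlignmentError(f"record {self.ids[0]!r} has an empty sequence")
        for sid, seq in zip(self.ids, self.seqs):
            if len(seq) != length:
                raise AlignmentError(
                    f"record {sid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"record {sid!r} contains invalid characters {sorted(bad)}"
                )
        dupes = [sid for sid, k in Counter(self.ids).items() if k > 1]
        if dupes:
            raise AlignmentError(f"duplicate sample ids: {dupes}")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str]]
    ) -> "MultipleAlignment":
        """Build from (id, sequence) pairs, uppercasing and mapping any
        character outside {A,C,G,T,N,-} to N with a logged warning."""
        ids, seqs = [], []
        for sid, seq in records:
            seq = seq.upper()
            if _INVALID_RE.search(seq):
                bad = sorted(set(_INVALID_RE.findall(seq)))
                log.warning(
                    "record %r: characters %s mapped to N", sid, bad
                )
                seq = _INVALID_RE.sub("N", seq)
            ids.append(str(sid))
            seqs.append(seq)
        return cls(tuple(ids), tuple(seqs))

    @property
    def length(self) -> int:
        """Alignment length in bp."""
        return len(self.seqs[0])

    @property
    def n(self) -> int:
        """Number of records."""
        return len(self.ids)

    @property
    def records(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(self.ids, self.seqs))

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "MultipleAlignment":
        """Sub-alignment restricted to ``ids`` (kept in the given order)."""
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [sid for sid in ids if sid not in index]
        if missing:
            raise KeyError(f"sample ids not in alignment: {missing}")
        return MultipleAlignment(
            tuple(ids), tuple(self.seqs[index[sid]] for sid in ids)
        )


@dataclass(frozen=True)
class PopulationMap:
    """Mapping from sample id to population label."""

    assignments: Mapping[str, str]

    def __getitem__(self, sample_id: str) -> str:
        return self.assignments[sample_id]

    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for label in self.assignments.values():
            seen.setdefault(label, None)
        return list(seen)

    def members(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def require_complete(self, aln: MultipleAlignment) -> None:
        missing = [sid for sid in aln.ids if sid not in self.assignments]
        if missing:
            raise AlignmentError(
                f"samples without a population label: {missing[:10]}"
            )


@dataclass(frozen=True)
class Haplotype:
    hap_id: str
    sequence: str
    member_ids: tuple[str, ...]
    count_total: int
    counts_by_population: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences with their members and per-population counts."""

    haplotypes: tuple[Haplotype, ...]
    n_sequences: int

    def __post_init__(self) -> None:
        if sum(h.count_total for h in self.haplotypes) != self.n_sequences:
            raise AlignmentError("haplotype counts do not sum to n_sequences")
        seqs = [h.sequence for h in self.haplotypes]
        if len(set(seqs)) != len(seqs):
            raise AlignmentError("two haplotypes share an identical sequence")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    def __getitem__(self, hap_id: str) -> Haplotype:
        for h in self.haplotypes:
            if h.hap_id == hap_id:
                return h
        raise KeyError(hap_id)

    def to_alignment(self) -> MultipleAlignment:
        """One record per haplotype (used for haplotype-level statistics)."""
        return MultipleAlignment(
            tuple(h.hap_id for h in self.haplotypes),
            tuple(h.sequence for h in self.haplotypes),
        )


def read_alignment(path: str | Path) -> MultipleAlignment:
    """Read a multi-record FASTA (wrapped or unwrapped) as an alignment."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return MultipleAlignment.from_records(records)


def write_alignment(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in aln.records:
            fh.write(f">{sid}\n{seq}\n")


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a 2-column TSV (sample_id TAB population)."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise AlignmentError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            sid, pop = parts
            if sid in assignments:
                raise AlignmentError(f"{path}:{lineno}: duplicate sample id {sid!r}")
            assignments[sid] = pop
    return PopulationMap(assignments)


def write_population_map(pops: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, pop in pops.assignments.items():
            fh.write(f"{sid}\t{pop}\n")


def collapse_haplotypes(
    aln: MultipleAlignment,
    pops: PopulationMap | None = None,
    name_map: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Collapse identical sequences into haplotypes.

    Haplotype ids are assigned in descending count order, ties broken by
    first occurrence in the alignment, as ``H001``, ``H002``, ...  A
    user-supplied ``name_map`` (default id -> preferred label) allows
    study-style labels such as ``ECH01``.
    """
    if pops is not None:
        pops.require_complete(aln)
    by_seq: dict[str, list[str]] = {}
    first_seen: dict[str, int] = {}
    for i, (sid, seq) in enumerate(aln.records):
        if seq not in by_seq:
            by_seq[seq] = []
            first_seen[seq] = i
        by_seq[seq].append(sid)
    order = sorted(by_seq, key=lambda s: (-len(by_seq[s]), first_seen[s]))
    width = max(3, len(str(len(order))))
    haps = []
    for rank, seq in enumerate(order, 1):
        members = tuple(by_seq[seq])
        hap_id = f"H{rank:0{width}d}"
        if name_map and hap_id in name_map:
            hap_id = name_map[hap_id]
        pop_counts: dict[str, int] = {}
        if pops is not None:
            for sid in members:
                p = pops[sid]
                pop_counts[p] = pop_counts.get(p, 0) + 1
        haps.append(
            Haplotype(hap_id, seq, members, len(members), pop_counts)
        )
    return HaplotypeTable(tuple(haps), aln.n)


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    """Write a TSV: hap_id, count, populations (label:count;...), sequence."""
    with open(path, "w") as fh:
        fh.write("hap_id\tcount\tpopulations\tsequence\n")
        for h in table:
            popstr = ";".join(
                f"{p}:{c}" for p, c in sorted(h.counts_by_population.items())
            )
            fh.write(f"{h.hap_id}\t{h.count_total}\t{popstr}\t{h.sequence}\n")
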