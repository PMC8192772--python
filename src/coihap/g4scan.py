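"""QGRS-style G-quadruplex motif discovery on DNA/mRNA coding sequence.

A candidate motif is four G-tracts (maximal runs of G of length >=
``g_min``) separated by three loops whose lengths fall within
``[loop_min, loop_max]``.  Enumeration is exhaustive over every ordered
choice of four such runs, so long-loop "new type" motifs (single-G tracts,
loops above the canonical 7 bp) are representable by relaxing the config.

Scoring is a documented surrogate for the published QGRS G-score, whose
formula the source tools do not disclose: longer minimum tracts raise the
score, longer and more uneven loops lower it,

    score = w_t * (min tract length - 1) - w_m * mean(loops)
            - w_r * (max(loops) - min(loops)),

defaults w_t=20, w_m=1, w_r=1.  Higher means a more stable quadruplex;
the weights are config-exposed so users can tune toward published QGRS
behaviour.

Non-overlapping selection mirrors the repeated-pass counting of
nonoverlapping motifs: each pass greedily extracts a maximal pairwise-
disjoint set (highest score first, ties leftmost then shortest) from the
candidates not selected in any earlier pass, for up to ``max_passes``
passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .seqio import HaplotypeTable

_DNA = set("ACGTU")


@dataclass(frozen=True)
class G4ScanConfig:
    g_min: int = 2          # minimum G-tract length; 1 admits "new type" tracts
    loop_min: int = 0
    loop_max: int = 20      # bp; raise to >= 21 for the longest reported loops
    max_passes: int = 10
    w_tract: float = 20.0
    w_mean_loop: float = 1.0
    w_loop_range: float = 1.0

    def __post_init__(self) -> None:
        if self.g_min < 1:
            raise ValueError("g_min must be >= 1")
        if not (0 <= self.loop_min <= self.loop_max):
            raise ValueError("need 0 <= loop_min <= loop_max")
        if self.max_passes < 1:
            raise ValueError("max_passes must be >= 1")


@dataclass(frozen=True)
class G4Candidate:
    start: int                      # 1-based inclusive
    end: int                        # 1-based inclusive
    tract_starts: tuple[int, int, int, int]
    tract_lengths: tuple[int, int, int, int]
    loops: tuple[int, int, int]
    score: float
    pass_index: int | None = None
    contains_sites: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "G4Candidate") -> bool:
        return self.start <= other.end and other.start <= self.end


def _g_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of G as (1-based start, length)."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "G":
            j = i
            while j < n and seq[j] == "G":
                j += 1
            runs.append((i + 1, j - i))
            i = j
        else:
            i += 1
    return runs


def score_candidate(c: G4Candidate, cfg: G4ScanConfig) -> float:
    loops = c.loops
    return (
        cfg.w_tract * (min(c.tract_lengths) - 1)
        - cfg.w_mean_loop * (sum(loops) / 3.0)
        - cfg.w_loop_range * (max(loops) - min(loops))
    )


def enumerate_candidates(seq: str, cfg: G4ScanConfig) -> list[G4Candidate]:
    """Every 4-tuple of maximal G-runs with loop lengths in bounds.

    Exhaustive and deterministic; the output is ordered by start position,
    then descending score.  Loops may themselves contain shorter G-runs;
    the tracts of a candidate are maximal runs, so the sum of tract and
    loop lengths always equals the candidate span.
    """
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN-")
    if bad:
        raise ValueError(f"sequence contains invalid characters {sorted(bad)}")
    runs = [r for r in _g_runs(seq) if r[1] >= cfg.g_min]
    out: list[G4Candidate] = []
    nr = len(runs)
    for i in range(nr):
        for j in range(i + 1, nr):
            gap1 = runs[j][0] - (runs[i][0] + runs[i][1])
            if gap1 > cfg.loop_max:
                break
            if gap1 < cfg.loop_min:
                continue
            for k in range(j + 1, nr):
                gap2 = runs[k][0] - (runs[j][0] + runs[j][1])
                if gap2 > cfg.loop_max:
                    break
                if gap2 < cfg.loop_min:
                    continue
                for m in range(k + 1, nr):
                    gap3 = runs[m][0] - (runs[k][0] + runs[k][1])
                    if gap3 > cfg.loop_max:
                        break
                    if gap3 < cfg.loop_min:
                        continue
                    tr = (runs[i], runs[j], runs[k], runs[m])
                    cand = G4Candidate(
                        start=runs[i][0],
                        end=runs[m][0] + runs[m][1] - 1,
                        tract_starts=tuple(t[0] for t in tr),
                        tract_lengths=tuple(t[1] for t in tr),
                        loops=(gap1, gap2, gap3),
                        score=0.0,
                    )
                    out.append(replace(cand, score=score_candidate(cand, cfg)))
    out.sort(key=lambda c: (c.start, -c.score, c.end))
    return out


def select_nonoverlapping(
    cands: Sequence[G4Candidate], cfg: G4ScanConfig
) -> list[G4Candidate]:
    """Iterated greedy selection of pairwise-disjoint candidate sets.

    Pass k picks the highest-scoring remaining candidate (ties: leftmost,
    then shortest), discards candidates overlapping it *within the pass*,
    and repeats until the pass can select nothing more; candidates chosen
    in earlier passes leave the pool.  Selected candidates carry their
    1-based pass index.  All intervals within a pass are pairwise
    disjoint, and the total selected count is non-decreasing in
    ``max_passes``.
    """
    pool = list(cands)
    selected: list[G4Candidate] = []
    for pass_idx in range(1, cfg.max_passes + 1):
        if not pool:
            break
        remaining = sorted(
            pool, key=lambda c: (-c.score, c.start, c.length)
        )
        chosen: list[G4Candidate] = []
        while remaining:
            best = remaining[0]
            chosen.append(best)
            remaining = [c for c in remaining[1:] if not c.overlaps(best)]
        chosen_ids = {id(c) for c in chosen}
        pool = [c for c in pool if id(c) not in chosen_ids]
        selected.extend(
            replace(c, pass_index=pass_idx)
            for c in sorted(chosen, key=lambda c: c.start)
        )
    return selected


def scan_sequence(seq: str, cfg: G4ScanConfig) -> list[G4Candidate]:
    """Enumerate then select non-overlapping motifs for one sequence."""
    return select_nonoverlapping(enumerate_candidates(seq, cfg), cfg)


def scan_alignment_hotspots(
    haps: HaplotypeTable,
    key_positions: Sequence[int],
    cfg: G4ScanConfig,
    polarity: Mapping[int, tuple[str, str]] | None = None,
) -> dict[str, list[G4Candidate]]:
    """Scan each haplotype and link motifs to the hotspot key sites.

    A motif is linked to a key site iff the site lies within its
    [start, end] span (alignment and sequence coordinates coincide for
    ungapped alignments).  Returns selected candidates per haplotype with
    ``contains_sites`` filled.
    """
    out: dict[str, list[G4Candidate]] = {}
    for h in haps:
        sel = scan_sequence(h.sequence, cfg)
        out[h.hap_id] = [
            replace(
                c,
                contains_sites=tuple(
                    p for p in key_positions if c.start <= p <= c.end
                ),
            )
            for c in sel
        ]
    return out


def hotspot_linkage_summary(
    haps: HaplotypeTable,
    scans: Mapping[str, Sequence[G4Candidate]],
    key_positions: Sequence[int],
    derived_state: str = "G",
):
    """Per haplotype and key site: state carried and linked-motif count.

    The ``derived_only`` column marks key sites whose linked motifs exist
    only when the haplotype carries the derived (G) state — the pattern
    expected if the derived hotspot guanine completes a quadruplex tract.
    Returns a pandas DataFrame.
    """
    import pandas as pd

    rows = []
    for h in haps:
        for p in key_positions:
            linked = sum(
                1 for c in scans.get(h.hap_id, ()) if p in c.contains_sites
            )
            rows.append(
                {
                    "hap_id": h.hap_id,
                    "site": p,
                    "state": h.sequence[p - 1],
                    "n_linked_motifs": linked,
                    "is_derived": h.sequence[p - 1] == derived_state,
                }
            )
    return pd.DataFrame(rows)


def write_motif_table(
    scans: Mapping[str, Sequence[G4Candidate]], path
) -> None:
    """BED-like TSV: sequence_id, start, end, score, tracts, loops, pass,
    linked sites (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write(
            "sequence_id\tstart\tend\tscore\ttract_lengths\tloops\t"
            "pass\tlinked_sites\n"
        )
        for sid, cands in scans.items():
            for c in cands:
                fh.write(
                    f"{sid}\t{c.start}\t{c.end}\t{c.score:.3f}\t"
                    f"{','.join(map(str, c.tract_lengths))}\t"
                    f"{','.join(map(str, c.loops))}\t"
                    f"{c.pass_index or ''}\t"
                    f"{','.join(map(str, c.contains_sites))}\n"
                )
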