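"""End-to-end orchestration: read -> collapse -> diversity/neutrality ->
mismatch -> AMOVA/Phi_ST -> PCoA -> hotspot groups -> covariance network
-> G-quadruplex scan, with reproducible seeds and a self-describing
report bundle.

Every output file starts with comment headers recording the package
version, the seed and a hash of the configuration, so a bundle can be
re-derived exactly; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .g4scan import (G4ScanConfig, scan_alignment_hotspots, write_motif_table)
from .hotspots import (assign_groups, classify_sites, covariance_graph,
                       covariance_network, infer_transition_order)
from .popgen import (amova, diversity_summary, mismatch_distribution,
                     neutrality_tests, pairwise_difference_matrix,
                     pairwise_phi_st, pcoa)
from .seqio import (MultipleAlignment, PopulationMap, collapse_haplotypes,
                    read_alignment, read_population_map, write_alignment,
                    write_haplotype_table, write_population_map)
from .synthdata import ExpansionSimConfig, simulate_expansion_alignment

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    alignment: str | None = None        # FASTA path; None -> simulate
    popmap: str | None = None           # TSV path
    key_positions: tuple[int, ...] = (207, 282, 354, 420)
    n_permutations: int = 1000
    seed: int = 1
    outdir: str = "results"
    g4: G4ScanConfig = field(default_factory=G4ScanConfig)
    ancestral_override: str | None = None

    def content_hash(self) -> str:
        # outdir does not affect results, so it is excluded from the hash
        d = dataclasses.asdict(self)
        d.pop("outdir")
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    outdir: Path
    files: dict[str, Path]
    skipped: dict[str, str]


def _header(cfg: PipelineConfig) -> str:
    return (
        f"# coihap {__version__}\n"
        f"# seed={cfg.seed} config_hash={cfg.content_hash()}\n"
    )


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run every stage and write the report bundle under ``cfg.outdir``.

    Stage failures abort with the failing stage named; stages whose
    preconditions the input cannot meet (e.g. AMOVA on one population)
    are skipped with a logged reason and recorded in the bundle.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    skipped: dict[str, str] = {}

    stage = "input"
    try:
        if cfg.alignment is None:
            sim_cfg = ExpansionSimConfig(
                key_positions=cfg.key_positions, seed=cfg.seed
            )
            aln, pops, _ = simulate_expansion_alignment(sim_cfg)
            write_alignment(aln, out / "alignment.fasta")
            write_population_map(pops, out / "populations.tsv")
            files["alignment"] = out / "alignment.fasta"
            files["populations"] = out / "populations.tsv"
        else:
            aln = read_alignment(cfg.alignment)
            pops = (
                read_population_map(cfg.popmap) if cfg.popmap else None
            )
        log.info("input: %d records x %d bp", aln.n, aln.length)

        stage = "haplotypes"
        table = collapse_haplotypes(aln, pops)
        write_haplotype_table(table, out / "haplotypes.tsv")
        files["haplotypes"] = out / "haplotypes.tsv"
        log.info("haplotypes: %d", table.n_haplotypes)

        stage = "diversity"
        rows = diversity_summary(aln, pops)
        div = pd.DataFrame([dataclasses.asdict(r) for r in rows])
        neut = []
        for r in rows:
            ids = (
                [s for s in aln.ids if pops[s] == r.population]
                if pops is not None and r.population != "Total"
                else list(aln.ids)
            )
            sub = aln.subset(ids)
            ns = neutrality_tests(sub)
            neut.append({"population": r.population,
                         "tajimas_D": ns.D, "fus_Fs": ns.Fs})
        div = div.merge(pd.DataFrame(neut), on="population")
        _write_tsv(div, out / "diversity.tsv", cfg)
        files["diversity"] = out / "diversity.tsv"

        stage = "mismatch"
        mm = mismatch_distribution(aln)
        mm_df = pd.DataFrame({
            "differences": np.arange(len(mm.histogram)),
            "observed": mm.histogram,
            "expected_constant": mm.expected_constant,
            "expected_expansion": mm.expected_expansion,
        })
        _write_tsv(mm_df, out / "mismatch.tsv", cfg)
        files["mismatch"] = out / "mismatch.tsv"

        stage = "amova"
        n_pops = len(pops.populations()) if pops is not None else 0
        if pops is None or n_pops < 2:
            skipped["amova"] = "needs >= 2 populations"
            log.info("amova skipped: %s", skipped["amova"])
        else:
            res = amova(aln, pops, n_perm=cfg.n_permutations, seed=cfg.seed)
            report = dataclasses.asdict(res)
            report["mismatch_raggedness"] = mm.raggedness
            report["mismatch_model_params"] = {
                "theta0": mm.model_params[0],
                "theta1": mm.model_params[1],
                "tau": mm.model_params[2],
            }
            with open(out / "amova.json", "w") as fh:
                fh.write(_header(cfg))
                json.dump(report, fh, indent=2, sort_keys=True)
                fh.write("\n")
            files["amova"] = out / "amova.json"
            phi, pval = pairwise_phi_st(
                aln, pops, n_perm=cfg.n_permutations, seed=cfg.seed
            )
            _write_tsv(phi, out / "pairwise_phi_st.tsv", cfg, index=True)
            files["pairwise_phi_st"] = out / "pairwise_phi_st.tsv"

        stage = "pcoa"
        hap_aln = table.to_alignment()
        diffs, _ = pairwise_difference_matrix(hap_aln)
        pc = pcoa(diffs.astype(float))
        pc_df = pd.DataFrame(
            pc.coordinates[:, : min(4, pc.coordinates.shape[1])],
            index=[h.hap_id for h in table],
        )
        pc_df.columns = [f"axis{i + 1}" for i in range(pc_df.shape[1])]
        pc_df.index.name = "hap_id"
        _write_tsv(pc_df, out / "pcoa.tsv", cfg, index=True)
        files["pcoa"] = out / "pcoa.tsv"

        stage = "sites"
        sites = classify_sites(table)
        site_df = pd.DataFrame([
            {
                "position": s.position,
                "states": "".join(sorted(s.state_counts)),
                "polymorphic": s.is_polymorphic,
                "parsimony_informative": s.is_parsimony_informative,
                "class": s.substitution_class or "",
            }
            for s in sites if s.is_polymorphic
        ])
        _write_tsv(site_df, out / "sites.tsv", cfg)
        files["sites"] = out / "sites.tsv"

        stage = "groups"
        ga = assign_groups(table, cfg.key_positions)
        try:
            order = infer_transition_order(ga, ancestral=cfg.ancestral_override)
            order_note = " -> ".join(order.ordered_groups) + (
                "" if order.stepwise else " [non-stepwise]"
            )
            polarity = order.polarity
        except ValueError as exc:
            skipped["transition_order"] = str(exc)
            order_note, polarity = "", None
        grp = pd.DataFrame([
            {
                "key_string": ks,
                "n_haplotypes": len(members),
                "haplotype_diversity": ga.per_group_h[ks],
                "haplotypes": ",".join(members),
            }
            for ks, members in ga.groups.items()
        ]).sort_values("n_haplotypes", ascending=False)
        with open(out / "groups.tsv", "w") as fh:
            fh.write(_header(cfg))
            if order_note:
                fh.write(f"# inferred order: {order_note}\n")
            grp.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        files["groups"] = out / "groups.tsv"

        stage = "covariance"
        edges = covariance_network(
            table, sites=list(cfg.key_positions), polarity=polarity
        )
        cov_df = pd.DataFrame([dataclasses.asdict(e) for e in edges])
        _write_tsv(cov_df, out / "covariance.tsv", cfg)
        nx.write_graphml(covariance_graph(edges), out / "covariance.graphml")
        files["covariance"] = out / "covariance.tsv"
        files["covariance_graphml"] = out / "covariance.graphml"

        stage = "g4scan"
        scans = scan_alignment_hotspots(table, cfg.key_positions, cfg.g4)
        write_motif_table(scans, out / "g4_motifs.tsv")
        files["g4_motifs"] = out / "g4_motifs.tsv"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "MANIFEST.json", "w") as fh:
        fh.write(_header(cfg))
        json.dump(
            {
                "files": {k: v.name for k, v in files.items()},
                "skipped": skipped,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    files["manifest"] = out / "MANIFEST.json"
    return ReportBundle(out, files, skipped)
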