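#!/usr/bin/env python
"""Hotspot-key haplotype groups, A->G transition polarity and the
site-covariance network.

Classifies alignment columns (polymorphic / parsimony-informative),
partitions haplotypes by their states at the four key sites, infers the
ancestral group from within-group haplotype diversity, and counts
same-polarity covariance between every pair of key sites.
"""

import argparse
from pathlib import Path

import networkx as nx
import pandas as pd

from coihap.hotspots import (annotate_codon_synonymy, assign_groups,
                             classify_sites, covariance_graph,
                             covariance_network, infer_transition_order)
from coihap.seqio import collapse_haplotypes, read_alignment

KEY = (207, 282, 354, 420)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    aln = read_alignment(args.indir / "alignment.fasta")
    table = collapse_haplotypes(aln)
    args.outdir.mkdir(parents=True, exist_ok=True)

    ann = annotate_codon_synonymy(table.to_alignment())
    sites = classify_sites(table, annotation=ann)
    poly = [s for s in sites if s.is_polymorphic]
    inf = [s for s in poly if s.is_parsimony_informative]
    print(
        f"{len(poly)} polymorphic sites, {len(inf)} parsimony-informative "
        f"among {table.n_haplotypes} haplotypes"
    )
    pd.DataFrame([
        {
            "position": s.position,
            "states": "/".join(sorted(s.state_counts)),
            "informative": s.is_parsimony_informative,
            "class": s.substitution_class,
            "codon_position": s.codon_position,
            "synonymous": s.is_synonymous,
        }
        for s in poly
    ]).to_csv(args.outdir / "sites.tsv", sep="\t", index=False)

    ga = assign_groups(table, KEY)
    order = infer_transition_order(ga)
    print("group sizes:", {k: v for k, v in sorted(ga.sizes().items())})
    arrow = " -> ".join(order.ordered_groups)
    step = "stepwise" if order.stepwise else "non-stepwise chain"
    print(f"inferred order ({step}): {arrow}")
    print("key-site polarity:",
          {p: f"{a}->{d}" for p, (a, d) in order.polarity.items()})
    pd.DataFrame([
        {"key_string": ks, "n_haplotypes": len(m),
         "h_within": ga.per_group_h[ks]}
        for ks, m in ga.groups.items()
    ]).sort_values("n_haplotypes", ascending=False).to_csv(
        args.outdir / "groups.tsv", sep="\t", index=False,
        float_format="%.4f")

    edges = covariance_network(table, sites=list(KEY),
                               polarity=order.polarity)
    for e in sorted(edges, key=lambda e: -e.covariate_count):
        print(
            f"covariance {e.site_i}-{e.site_j}: {e.covariate_count} of "
            f"{table.n_haplotypes} haplotypes ({100 * e.frequency_ratio:.0f}%)"
        )
    pd.DataFrame([e.__dict__ for e in edges]).to_csv(
        args.outdir / "covariance.tsv", sep="\t", index=False,
        float_format="%.4f")
    nx.write_graphml(covariance_graph(edges),
                     args.outdir / "covariance.graphml")


if __name__ == "__main__":
    main()
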