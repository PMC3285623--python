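"""Base composition, Perna-Kocher skews and clade summaries.

Loads the packaged 50-genome composition table, recomputes the AT/GC
strand skews from the proportions, and summarizes AT content per
superclade.  A strongly negative AT-skew with positive GC-skew (as in the
bryozoan row below) marks a genome whose coding strand is T- and G-rich.
"""

import mitocomp as mc

fx = mc.load_fixtures()

row = fx.genome_row("Flustra foliacea")
at_skew, gc_skew = mc.compute_skews(row.A, row.C, row.G, row["T"])
print(f"Flustra foliacea ({row.length_bp} bp): AT% {row.at_percent}, "
      f"AT-skew {at_skew:.3f}, GC-skew {gc_skew:.3f}")

grouping = {r.taxon: fx.superclades[r.phylum] for r in fx.table2.itertuples()}
summary = mc.group_summary(dict(zip(fx.table2.taxon, fx.table2.at_percent)),
                           grouping)
print(f"\nAT% across {summary['overall']['n']} mitogenomes: "
      f"mean {summary['overall']['mean']:.1f}, "
      f"range {summary['overall']['min']}-{summary['overall']['max']} "
      f"({summary['overall']['argmin']} to {summary['overall']['argmax']})")
for clade in ("Deuterostomia", "Lophotrochozoa", "Ecdysozoa"):
    c = summary["clades"][clade]
    print(f"  {clade:15s} n={c['n']:2d}  mean AT% {c['mean']:.1f}")
print("\nLower AT% in deuterostomes and higher in ecdysozoans means base "
      "composition varies by lineage - the bias the heterogeneity tests "
      "in example 03 are designed to detect.")
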