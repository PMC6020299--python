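"""Genome-reduction metrics: ortholog ANI, percent reduction, pathways.

Compares a genome with a 5%-diverged relative and scores amino-acid
synthesis pathway completeness before and after knocking out one enzyme.
"""
import numpy as np

from luxerode import simulate as sim
from luxerode.genome import AnnotatedGenome
from luxerode.reduction import (ani, ortholog_pairs, pathway_completeness,
                                read_pathways, reduction_stats)
from luxerode.resources import default_pathways

genome_a = sim.simulate_ancestor(n_genes=40, mean_gene_len=600, seed=13)
rng = np.random.default_rng(13)
seq = list(genome_a.contigs["chr1"])
for f in genome_a.features:
    for i in range(f.start - 1, f.end):
        if rng.random() < 0.05:
            seq[i] = "ACGT"[rng.integers(4)]
genome_b = AnnotatedGenome("relative", {"chr1": "".join(seq)},
                           list(genome_a.features)).validate()

pairs = ortholog_pairs(genome_a, genome_b)
print(f"reciprocal best hits: {len(pairs)}  "
      f"ANI = {ani(pairs):.1f}% (5% substitutions -> ~96%)")

print(f"functional-CDS reduction, 1662 vs mean 5200: "
      f"{reduction_stats(1662, 5200):.0f}%")

defs = read_pathways(default_pathways())
from luxerode.genome import Feature
enzymes = [e for d in defs for e in d.enzymes]
feats = [Feature(f"e{i}", "c1", 10 * i + 1, 10 * i + 9, "+", "CDS",
                 "functional", product=e) for i, e in enumerate(enzymes)]
full = AnnotatedGenome("full", {"c1": "A" * (10 * len(enzymes) + 10)}, feats)
out = pathway_completeness(full, defs)
print(f"complete pathways with every enzyme present: "
      f"{out['n_complete']}/{out['n_total']}")
broken = AnnotatedGenome("broken", full.contigs,
                         [f for f in feats if f.product != "trpB"])
out2 = pathway_completeness(broken, defs)
print(f"after losing trpB: {out2['n_complete']}/{out2['n_total']} "
      "(only tryptophan breaks)")
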