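"""Generate a synthetic ancestor/derived genome pair with ground truth.

Builds a 200-gene ancestral genome, then degrades it the way a
host-restricted symbiont genome erodes: gene deletion, truncation-based
pseudogenization, and a transposase burst with per-copy decay.
"""
from luxerode import simulate as sim

ancestor = sim.simulate_ancestor(n_genes=200, mean_gene_len=900,
                                 intergenic_len=150, gc_frac=0.40, seed=7)
params = sim.DegradationParams(
    deletion_frac=0.15, pseudo_frac=0.30, truncation_range=(0.1, 0.45),
    te_bursts=[sim.TEBurst("IS5", 40, decay_sub_rate=0.05,
                           decay_trunc_prob=0.4)],
    rng_seed=7)
derived, truth = sim.degrade_genome(ancestor, params)

print("ancestor:", ancestor.summary())
print("derived: ", derived.summary())
fates = [r["fate"] for r in truth.gene_fates.values()]
print("true fates:", {f: fates.count(f) for f in sorted(set(fates))})
print("planted TE copies:", len(truth.te_copies))
# The derived genome is smaller (deletions), carries truncated pseudogenes,
# and its CDS count is inflated by decayed transposase copies — the same
# signature the analyses downstream are built to detect.
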