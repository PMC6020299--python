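"""Local- vs global-clock likelihood-ratio test with rate recovery.

Simulates 6 kb of nucleotide data on a 10-taxon ultrametric tree where one
clade evolves 3.5x faster, then fits both clock models and reports the LRT.
"""
from luxerode import clock as ck
from luxerode import simulate as sim
from luxerode.pipeline import _pick_clade

tree = sim.random_ultrametric_tree(10, height=0.15, seed=5)
foreground = _pick_clade(tree)
model = ck.hky(2.0)
aln = sim.simulate_alignment(tree, model, foreground_clade=foreground,
                             rate_multiplier=3.5, n_sites=6000, seed=6)

null_fit, alt_fit = ck.fit_clock_pair(tree, aln, model, foreground)
res = ck.lrt(null_fit, alt_fit)
print(f"foreground clade: {sorted(foreground)}")
print(f"-lnL0 = {-null_fit.log_likelihood:.2f}   "
      f"-lnLA = {-alt_fit.log_likelihood:.2f}")
print(f"LR = {res.lr:.2f}  df = {res.df}  p = {res.p_value:.2e}  "
      f"r_hat = {res.rate_multiplier:.2f}")
# A large LR with df=1 rejects the single-rate clock; r_hat near 3.5 shows
# the clade's substitution-rate acceleration is recovered quantitatively.
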