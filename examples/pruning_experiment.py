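"""Effect of idealised pruning cuts on recovered allometric exponents.

Orchard management removes biomass in two characteristic ways:
branch-removing cuts (whole subtrees) and length-reducing cuts
(shortened tips).  This script prunes a synthetic tree both ways and
refits the segment mass ~ diameter exponent.
"""

from allomtree import metrics_table, prune, rma_fit, wbe_geometry


def md_slope(tree) -> tuple[float, int]:
    m = metrics_table(tree, levels=("segment",))
    f = rma_fit(m.diameter, m.mass)
    return f.a_hat, f.n


tree, truth = wbe_geometry(2, 8, noise_sigma=0.05, seed=7)
a0, n0 = md_slope(tree)
print(f"unpruned:        a = {a0:.3f} (n = {n0})")

removed_tree, frac = prune(tree, prune_fraction=0.08, seed=1)
a1, n1 = md_slope(removed_tree)
print(f"branch-removing: a = {a1:.3f} (n = {n1}), "
      f"{100 * frac:.1f}% of biomass removed")

trimmed_tree, frac = prune(tree, tip_trim=0.5, seed=1)
a2, n2 = md_slope(trimmed_tree)
print(f"length-reducing: a = {a2:.3f} (n = {n2}), "
      f"{100 * frac:.1f}% of biomass removed")
# Subtree removal mostly thins the sample; tip shortening perturbs the
# smallest branches' mass ~ diameter relation directly, so it moves the
# exponent further for the same removed biomass.
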