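"""Score a motif by hand: from per-residue p-values to Sig_motif.

Takes a hypothetical 3-residue motif whose defined positions have tail
probabilities 0.02, 0.01 and 0.03, combines them into p_motif (their
product), and corrects for motif size with the product-of-uniforms CDF to
get Sig_motif.  A Monte-Carlo simulation of products of three uniforms
verifies the closed form.
"""

import numpy as np

from slimprints import p_motif, sig_motif

p_values = [0.02, 0.01, 0.03]
pm = p_motif(p_values)
sig = sig_motif(pm, n=len(p_values))

print(f"p_RLC of defined residues : {p_values}")
print(f"p_motif (product)         : {pm:.2e}")
print(f"Sig_motif (n={len(p_values)})          : {sig:.3e}")

rng = np.random.default_rng(0)
draws = rng.random((1_000_000, 3)).prod(axis=1)
print(f"Monte-Carlo estimate      : {(draws <= pm).mean():.3e}  (10^6 products)")
print(
    "\nSig_motif is the probability that three independent uniform p-values "
    "would have a product at most p_motif: unlike p_motif itself it is "
    "comparable across motifs with different numbers of defined positions."
)
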