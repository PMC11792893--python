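"""Test whether the two surfaces of an amphistomatous leaf coordinate.

Compares a perfectly offset-coordinated pair (adaxial lattice shifted by
half a lattice vector) with an independent pair.  Coordination shows up as
a negative pixel-wise correlation between the two nearest-stomatal-
distance-squared rasters.
"""

from amphistoma import coordination, synthetic
from amphistoma.synthetic import PairSimConfig

for mode in ("offset_coordinated", "independent"):
    pair = synthetic.simulate_pair(PairSimConfig(n_ab=150, n_ad=150,
                                                 mode=mode, seed=3))
    res = coordination.coordination_test(pair, n_sim=999, resolution=64, seed=4)
    print(f"{mode:20s}  r = {res.r_observed:+.3f}   p = {res.p_raw:.4f}")

print()
print("The offset pair shows r < 0 (pixels far from a stomate on one side")
print("are near one on the other) and a small one-tailed p-value; the")
print("independent pair's correlation is indistinguishable from its null.")
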