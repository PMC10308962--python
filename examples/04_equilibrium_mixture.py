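"""The incomplete-equilibrium simulation.

Communities are not at metastable equilibrium; the chemical-adaptation
hypothesis is that they sit partway there.  Mixing the equilibrium Z_C
profile (weight 20%) with a zero-trend random taxon pool (80%) shows how
a strong theoretical slope shrinks to the size actually observed in field
data while its confidence interval widens.
"""

import numpy as np

from redoxzc import (
    EquilibriumMix, mix_and_fit, ols_fit, sample_equilibrium_profile,
    select_near_zero_pool, stability_grid, zc_vs_eh_profile,
)
from redoxzc.synth import make_gibbs_fixture, make_reference_db

db, _ = make_reference_db(5, seed=11)
gibbs = make_gibbs_fixture(db, seed=3)
names = [p.taxon_name for p in sorted(db, key=lambda p: p.zc)]
grid = stability_grid(names, gibbs, eh_range_mV=(-500.0, 200.0), shape=(64, 64))

eh7_V, zc_eq = sample_equilibrium_profile(zc_vs_eh_profile(grid, 7.0), 50)
zc_eq = zc_eq * (0.665 / ols_fit(eh7_V, zc_eq).m)   # scale to 0.665/V

pool = np.random.default_rng(0).normal(-0.2, 0.05, 400)
zc_rand, n_draws = select_near_zero_pool(pool, eh7_V, tolerance=0.001, seed=0)

m_eq = ols_fit(eh7_V, zc_eq)
m_rand = ols_fit(eh7_V, zc_rand)
mixed = mix_and_fit(EquilibriumMix(eh7_V, zc_eq, zc_rand, w_eq=0.20))

print(f"equilibrium slope : {m_eq.m:+.4f} 1/V  (moe95 {m_eq.moe95:.4f})")
print(f"random-pool slope : {m_rand.m:+.5f} 1/V  (accepted after "
      f"{n_draws} draws)")
print(f"20/80 mixture     : {mixed.m:+.4f} 1/V  (moe95 {mixed.moe95:.4f})")
print("\nThe mixture slope is exactly 0.2*m_eq + 0.8*m_rand (~0.133/V),")
print("comparable to the largest slopes seen in local-scale field data,")
print("and its confidence interval is much wider than the pure signal's.")
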