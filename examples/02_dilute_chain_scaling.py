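"""Flory scaling of dilute 2D chains in good (athermal) solvent.

Runs small dilute ensembles (phi = 1/32) for N = 16, 32, 64 and fits
<Rg^2> ~ N^(2 nu).  In two dimensions the excluded-volume exponent is
nu = 3/4, so the fitted slope should be close to 1.5 — strong swelling
compared with the ideal-chain value of 1.
"""

from cmapoly.scaling import estimate_2nu
from cmapoly.study import dilute_study

results = dilute_study(seed=11, n_replicas=8, run_time=800)

print("N    <Rg^2>   +-SEM    chains x configs")
for N, res in sorted(results.items()):
    print(f"{N:<4d} {res.rg2_mean:7.2f}  {res.rg2_sem:6.2f}   "
          f"{res.n_chains} x {res.n_configs}")

fit = estimate_2nu(sorted(results), [results[N].rg2_mean for N in sorted(results)])
print(f"\nfitted 2 nu = {fit.exponent:.3f} +- {fit.stderr:.3f} "
      "(2D good-solvent prediction: 1.5)")
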