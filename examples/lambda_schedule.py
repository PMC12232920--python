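"""Optimize a production lambda schedule from a dense burn-in.

The burn-in simulates 21 states of an alchemical transformation whose
well position moves like lambda^3 — slow at first, fast near lambda = 1 —
so a uniform schedule wastes states at small lambda and starves the end.
The optimizer equalizes the predicted replica-exchange acceptance.
"""

import numpy as np

from fenet import schedule, synthgen

burnin = synthgen.gen_burnin(
    synthgen.GaussianAlchemy(kappa=1.0, d=4.0), n_dense=21,
    n_per_state=150, seed=8, position_fn=lambda lam: 4.0 * lam**3,
)

uniform = np.linspace(0, 1, 8)
pv_uni = [schedule.pair_property(burnin, uniform[i], uniform[i + 1],
                                 "exchange") for i in range(7)]
res = schedule.optimize_schedule(burnin, 8, kind="exchange")

print("uniform schedule acceptances:",
      " ".join(f"{p:.3f}" for p in pv_uni))
print("optimized schedule: ",
      " ".join(f"{l:.3f}" for l in res.lambdas_opt))
print("optimized acceptances:",
      " ".join(f"{p:.3f}" for p in res.property_values))
print(f"variance of acceptance: uniform {np.var(pv_uni):.2e}, "
      f"optimized {res.objective:.2e}")
print("\nSpacing shrinks toward lambda = 1 where the states decorrelate "
      "fastest; equalized acceptance removes the exchange bottleneck.")
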