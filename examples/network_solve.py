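"""Solve a thermodynamic graph of ligand transformations.

Generates a dense 6-ligand graph with known free energies and noisy edge
estimates, solves for the ligand free energies by the closed-form
weighted least-squares minimizer, and prints per-edge residuals and
cycle-closure errors.  The solved differences close every cycle exactly;
the raw per-edge estimates do not.
"""

import numpy as np

from fenet import network, synthgen

true_c = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
tg, truth = synthgen.gen_graph(6, "dense", true_c, noise_sem=0.4, seed=11)

sol = network.solve_network(tg)
print(f"reference ligand: {sol.ref_ligand}\n")
print(f"{'ligand':>8s} {'solved':>8s} {'true':>6s} {'sigma':>7s}")
for i, name in enumerate(sol.ligands):
    print(f"{name:>8s} {sol.c[i]:8.3f} {truth['c'][i]:6.1f} "
          f"{sol.sigma[i]:7.3f}")

worst_raw = max(abs(err) for _, err in sol.cycles)
cmap = dict(zip(sol.ligands, sol.c))
worst_solved = max(
    abs(sum(cmap[ns[(i + 1) % len(ns)]] - cmap[ns[i]]
            for i in range(len(ns))))
    for ns, _ in sol.cycles
)
print(f"\n{len(sol.cycles)} cycles: worst raw closure "
      f"{worst_raw:.3f} kcal/mol, worst solved closure "
      f"{worst_solved:.1e} (exact by construction)")
print("Residuals (solved difference minus raw g) show how the network "
      "redistributes the inconsistency:")
for (a, b, g, k, s), r in zip(tg.edges[:5], sol.edge_residuals[:5]):
    print(f"  {a}~{b}: g = {g:7.3f}, residual = {r:7.3f}")
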