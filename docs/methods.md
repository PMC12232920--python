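# Methods

This note records the models, conventions, numerical choices, and known
limitations of the package, in enough detail to reproduce or audit any
result it computes.

## Units and conventions

All public free energies are kcal/mol; reduced energies βU are unitless
(β = 1/k_BT with k_B = 0.0019872041 kcal/mol/K). Energy tables store βU.
MBAR free energies are anchored at G[0] = 0; edge and network layers
re-reference as needed. The CLI's kJ option converts at I/O boundaries
only.

The umbrella bias convention is U = Σ_d fc_d (x_d − c_d)² — the Amber
restraint-energy convention, with no ½ prefactor — switchable to the
½-convention (`half_k` / `--halfk`). The metafile dialect is
`ham_idx dumpave_path center_1 fc_1 [center_2 fc_2 …] temperature` with
`#` comments; a Grossfield-WHAM-ordered reader (`path centers… springs…
[T]`, ham_idx 0, default 300 K when the temperature column is absent) is
provided for interoperability. Neither dialect claims byte compatibility
with other tools; the format is documented here precisely because column
order is the usual source of silent errors.

## Time-series preprocessing

The statistical inefficiency is g = 1 + 2 Σ_τ (1 − τ/n) ρ(τ) with the
biased (1/n) autocovariance estimator, summing lags until the first
non-positive ρ; this truncation curbs noise accumulation and is standard.
g is clamped to ≥ 1; a numerically constant series is legal input with
g = 1, because harmonic-bias energy series can be flat in stiff windows.

Equilibration detection scans candidate truncation points at every 2% of
the series (50 candidates regardless of length, bounding cost) and keeps
the t0 that maximizes the effective sample count (n − t0)/g of the
retained tail, ties to the smallest t0. The algorithm behind the original
tool's equilibration checker is not published; the max-n_eff scan is this
package's choice and is what the tests characterize: on a 10⁴-point series
with an abrupt level shift at the midpoint it localizes t0 within the 2%
scan resolution. Gradual drifts, oscillatory equilibration, and
multivariate criteria are out of scope.

Decorrelated subsampling takes every ⌈g⌉-th frame from t0 and requires at
least 2 survivors.

## MBAR solver

The objective and its analytic gradient are evaluated with per-sample
log-sum-exp stabilization. Zero-count states are legal (they are pure
reweighting targets, e.g. the unbiased Hamiltonian of an umbrella run):
their b-term weight N_i/N vanishes and they drop out of the mixture
denominator; their free energies are recovered from the converged mixture
weights afterwards.

Solution strategy: self-consistent iteration on the standard fixed-point
equations to a gradient infinity-norm of 1e-2, then Newton steps with the
analytic Hessian (restricted to the anchored subspace, with backtracking
on the objective) to the final tolerance of 1e-9. The objective is convex,
so this converges quadratically in practice; non-convergence raises an
error carrying the last iterate and residual.

The overlap matrix is the standard MBAR construction O_ij = Σ_k N_j W_ik
W_jk with W_ik = exp(βG_i − u_ik)/D_k; its rows sum to 1 identically and,
for identical states, O_ij = N_j/N.

Uncertainties are bootstrap: resampling with replacement within each
originating state (counts preserved), re-solving per replicate, σ over
replicates, σ[0] = 0 by gauge. Bootstrap assumes decorrelated columns, so
the time-series layer must run first on correlated data. The bootstrap
was preferred over the analytic asymptotic covariance because it transfers
unchanged to nonlinear downstream quantities (per-bin surface values,
ΔΔG); the analytic covariance is future work. Default replicate count in
the pipelines is 16 — enough for a ~20%-accurate σ, which is what a
3σ acceptance band needs.

## Umbrella-sampling surfaces

One biased state per window plus one zero-count unbiased state; the
common unbiased part of the potential cancels in the reduced bias
energies, so only bias energies enter the table. All windows must share
one temperature and one Hamiltonian index (multi-temperature reweighting
is future work). Optional equilibration trimming operates on each
window's bias-energy series — the quantity that actually drives the
reweighting.

Binning is half-open, [min + iw, min + (i+1)w); out-of-grid samples are
dropped and counted in a log summary. Periodic dimensions (period p)
wrap samples into the grid and use minimum-image displacements in the
bias. Per occupied bin b: F_b = −k_BT ln Σ_{k∈b} w_k with the unbiased
weights w, referenced so min_b F = 0 exactly; n_b is the raw count; the
reweighting entropy is S_b = −Σ ŵ ln ŵ / ln n_b with ŵ normalized within
the bin and S = 1 for a single sample — a normalized measure of how many
samples effectively support the bin (the cited reference does not print
its formula, so this construction is the package's own and is documented
as such). dF is a window-stratified bootstrap as above.

The XML schema (`<ndfes dims>`, per-dimension `<axis min width nbins
[period]>`, per-bin `<bin idx F dF n S>`) serializes floats at 17
significant digits, which round-trips IEEE doubles bitwise; read(write(g))
== g exactly, and unknown attributes are ignored with a warning so newer
files still load.

Averaging surfaces takes the unweighted per-bin mean over the grids
containing the bin, with σ/√m as the error (0 for m = 1) and summed
counts; grids must be identical.

## Alchemical edges

The edge XML organizes environments (exactly `ref` and `target`) →
stages → trials → states; `efep_<tlam>_<elam>.dat` files carry the
potential energy (kcal/mol) of every sample of tlam evaluated at elam.
The filename λ format written by the generator is fixed 8-decimal; the
reader accepts any parseable float pair and matches values to 1e-9.
Row counts must agree across elam for fixed tlam (same samples).
Temperature is an attribute of `<edge>` (default 298 K).

The whole-edge objective is block diagonal in trials, so the
unconstrained optimum factorizes into independent per-trial solves.
Trial free energies assume a common λ = 0/λ = 1 referencing within a
stage; trials couple only through the 1/N_trial averaging. The stage
standard error is the sample σ/√N over trial ΔG values (0 for a single
trial), combined in quadrature across stages and environments.

Constrained pretabulation minimizes the edge objective subject to the
single linear constraint ΔΔG(G) = x by Newton on the KKT system with the
analytic block-diagonal Hessian, warm-started from the unconstrained
optimum, to a residual of 1e-10. Each trial's λ = 0 free energy is
anchored to remove the per-trial gauge freedom (a uniform shift of one
trial's block changes neither the objective nor ΔΔG); this makes the
KKT system nonsingular without affecting the minimum value. A
penalty-method minimizer is retained in the tests as the independent
oracle.

The surrogate fit is closed-form least squares over the four displaced
residuals: with z_i = ½(x_i − g)² and y_i = F̃_i − F̃_center,
k = Σ y_i z_i / Σ z_i². Whether the original tool fits all five points or
four, and with what weighting, is not published; four displaced residuals
with the center pinned is this package's choice. y_i < −1e-9 ("center is
not the minimum") and k ≤ 0 are errors.

Note on normalization: because the per-trial objective is per-sample
normalized and trials are averaged, k is the curvature of a per-sample
objective. The Fisher-information reading of the surrogate is therefore
var(ΔΔG) ≈ 1/(k · N_trial · N_s); the tests verify this to within a
factor of 2 on Gaussian edges. Relative k across edges — what the network
solve consumes — is unaffected by the common scale.

Diagnostics per adjacent λ pair: overlap matrix entries, forward/backward
energy-gap means and variances (adjacent-state ΔU stands in for dU/dλ,
which tabulated input cannot provide), and the predicted exchange
acceptance ⟨min(1, e^(−βΔΔ))⟩ from paired samples.

## Network solve

Ligand free energies solve Mc = XᵀKg with the reference column removed;
the reference ligand defaults to the lexicographically smallest name for
determinism. Parallel edges stay distinct (equivalent to summing k).
The ligand covariance is M⁻¹XᵀKΣKXM⁻¹ with Σ = diag(trial_sem²): k
encodes objective curvature (information), trial scatter encodes
reproducibility, and both are reported rather than conflated. Cycle
closure of solved differences is exact by telescoping; the report lists
the raw-g closure errors over a minimum-weight cycle basis plus all
triangles (exhaustive simple-cycle enumeration is exponential, and basis
closure implies all-cycle closure for solved differences). Disconnected
graphs are an error naming the components (each needs its own
reference).

Experimental values are hard equality constraints via a KKT block
system; constrained pairs must be graph edges. Constraints that close a
cycle are checked for consistency by potential assignment (tolerance
1e-8 kcal/mol); inconsistent or redundant constraint sets are errors.
Soft (weighted) priors are a noted extension, not implemented.

Outlier trials: stages with ≥ 4 trials use the modified z-score
0.6745(x − median)/MAD with |z| > 3.5 flagged; smaller stages use a
leave-one-out rule (mean shift > 5 standard errors of the remainder).

## λ-schedule optimization

Properties between arbitrary λ are estimated by MBAR reweighting of the
dense burn-in, with per-sample reduced energies at intermediate λ
linearly interpolated between the bracketing dense states — exact for
Hamiltonians that mix linearly in λ, approximate otherwise; for softcore
forms use `grid_only` schedules restricted to the dense grid. Fewer than
11 burn-in states triggers a warning.

The exchange property is the exact double-ensemble average
⟨min(1, e^(−Δ))⟩ computed in O(N log N) by sorting and prefix
log-sum-exps (no subsampling); overlap is Σ_k min(w_i, w_j); KL is the
symmetrized divergence of the weight vectors.

Placement: per-interval resistance r = −ln(property) (the divergence
itself for KL) is accumulated into a cumulative curve, interpolated
monotonically (PCHIP), and inverted by bisection to 1e-10 at equal
resistance increments; the placement is then refined by a self-consistent
equalization loop (re-evaluating the resistances of the current schedule
and re-placing, to 1e-11 in λ), which corrects the small non-additivity
of finite-interval resistances and converges to equal adjacent
properties — the zero of the variance objective when an equalizer exists.
The variance of the post-hoc property is reported as the objective.
A property that underflows to 0 on a dense interval is a hard error
("burn-in overlap gap") — no schedule can bridge a gap the burn-in
itself could not. The symmetric option averages the schedule with its
mirror about λ = ½.

## Minimum free energy paths

The surface is interpolated multilinearly over bin centers with analytic
gradients; unoccupied bins take the nearest occupied value plus a
penalty offset (default 25 kcal/mol), repelling the string from
unsampled territory. Queries outside the grid's bounding box raise;
within the half-bin margin outside the outermost centers the interpolant
continues constantly.

The string starts as the straight line between the fixed endpoints
(`free_ends` lets them slide within their own bins), takes
gradient-descent steps on interior nodes, and is resampled to equal
arclength each iteration; convergence requires the maximum node
displacement below tol for 3 consecutive iterations. Because the
multilinear gradient is discontinuous at bin centers, a fixed step can
orbit a kink indefinitely; the step is halved whenever the displacement
stalls for 5 iterations, which restores convergence. No randomness is
involved anywhere. This gradient-descent string with reparameterization
converges to the same curve as a projected minimum-energy-path force on
a fixed interpolated surface and is simpler; the outer loop of the
surface-accelerated string method — re-sampling and re-estimating the
surface between string iterations — belongs to the caller.

## Synthetic data

The generators draw independent samples from closed-form distributions —
deliberately not MD-like — so estimator output can be compared to exact
truths: a quadratic landscape under a harmonic bias has a Gaussian biased
density with mean 2k·x₀/(a + 2k) and variance k_BT/(a + 2k); the quartic
double well h(x² − 1)² is sampled by rejection against a uniform
envelope (acceptance reported); the Gaussian alchemy U(x; λ) =
½κ(x − λd)² + λε has G(λ) = λε + const, hence exact ΔG = ε per leg and
ΔΔG = ε_target − ε_ref per edge; random graphs have known ligand free
energies with g = Δc + N(0, σ) and k = 1/σ². Options add AR(1)
correlation (stationary marginal preserved; quadratic landscape only)
and a drifted burn-in head to exercise the time-series layer.

What passing these tests does and does not show: the synthetic data have
exactly harmonic biases, Gaussian or quartic targets, independent or
AR(1) samples, and no anharmonic coupling, hysteresis, or slow orthogonal
degrees of freedom. Agreement demonstrates the estimators are correct
implementations of their definitions with calibrated uncertainties under
clean sampling; it does not certify convergence of any particular real
simulation.

Default problem sizes in tests and the acceptance script (e.g. 11–15
windows × 1500 samples, 5–6 λ states × 150–250 samples × 2–6 trials,
100-replicate solver cross-checks, 16 bootstrap replicates) are desk
scale: they keep the statistical error a few times smaller than each
acceptance band while running in seconds.

## Known limitations

Single temperature per surface; no vFEP splines or target-potential
(wTP/gwTP) reweighting; no generic-bias (non-harmonic) metafiles; hard
constraints only in the network solve; linear-mixing assumption for
off-grid schedule properties; no analytic MBAR covariance; no HTML
reports (JSON + plain text instead).
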