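# Methods

## Scope and model

`poremsm` analyzes equilibrium dynamics of a two-chain potassium channel
as three coupled layers: a slow whole-molecule conformational process
(macrostates such as stretched "Up" and compressed "Down" plus
intermediates), a faster selectivity-filter (SF) conformational state
(open vs pinched), and fast ion-occupancy dynamics over the four SF
binding sites S1–S4. The statistical machinery is the standard MSM stack —
tICA for kinetic coordinates, k-means discretization, reversible
maximum-likelihood transition matrices, PCCA+ lumping — plus WHAM for
free-energy profiles along the ion-transition coordinate Δz (projection of
the SF-center-of-mass-to-ion vector onto the pore axis).

Because the multi-hundred-microsecond MD datasets this kind of analysis
targets are not redistributable, the package ships synthetic generators
whose ground truth is analytic. Everything the estimators are tested on is
generated at run time.

## Conventions and units

Lengths nm (Å only at the pore-diameter probe, where constriction is
conventionally quoted in Å); energies kcal/mol; kT = 0.596 kcal/mol at
300 K; times in ns with frame spacing carried by the trajectory container.
Occupancy strings are ordered S1→S4 with X = occupied; the integer code
takes S1 as the most significant bit, so `OXXO` ↔ 6. The pore axis points
extracellular; site boundaries default to the five carbonyl-layer centroid
planes (the layers sandwiching each site), configurable as explicit
z-planes since real structures do not dictate a unique choice. Cross-chain
"corresponding residue" distances pair residue i on chain A with residue i
on chain B (alpha carbons by default) — one feature per residue, 129 for
the default pore-region ranges 1–24, 112–189, 230–256.

## Estimators

**tICA.** Mean-free covariances pooled over trajectories with pair-count
weights; pairs never straddle trajectory ends; C₀ is the symmetric average
of head and tail covariances (guaranteeing PSD) and C_τ is symmetrized,
which forces a real spectrum and matches classical practice. The
generalized eigenproblem uses a scale-free default ridge
1e-10·tr(C₀)/d. At lag 0 the two covariances are returned as the same
matrix by construction. Defaults mirror the reference protocol: lag 1 ns,
3 components.

**Clustering.** scikit-learn MiniBatchKMeans (seeded) followed by full-data
Lloyd iterations to a fixed point — the mini-batch pass alone leaves
stochastic-update residue that breaks exact contracts (zero inertia when
k equals the number of distinct points; duplication invariance). Clusters
emptied during polishing are reseeded from the farthest frame. Final
assignment is an exact nearest-center pass, ties to the lower index.
Default k = 500.

**Reversible MLE.** Sliding-window counts at the stated lag (default
20 ns), trimmed to the largest strongly connected component (trimmed
states are recorded, never silently dropped), then the standard
self-consistent iteration on x_ij = π_i T_ij:

    x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j).

Convergence requires both the log-likelihood change and the parameter
update to fall below tol (default 1e-12): the likelihood flattens
quadratically near the optimum, so a likelihood-only criterion can stop
orders of magnitude short in parameter space. Since x stays symmetric, the
returned π (row sums of x) satisfies stationarity and detailed balance
identically up to rounding; the model constructor asserts row sums (1e-12),
stationarity (1e-10) and detailed balance (1e-8) after every fit. Spectra
are computed in the π-symmetrized basis.

**PCCA+.** Memberships from the top-m right eigenvectors via the
inner-simplex vertex search (farthest-row Gram–Schmidt deflation),
inverted at the vertices and projected to feasibility by clipping to
[0, 1] and row renormalization. Crisp labels by argmax, ties to the lower
macrostate index. Macrostate names (Up/Down/I1/I2) are presentation-layer
configuration, not inferred. Representative conformations per macrostate:
dihedrals embedded as (sin, cos) to avoid angular wrap, PCA, and the
conformation nearest the mean in the top-2 PC subspace (our rule; recorded
in output metadata).

**Ion kinetics.** A transition pair (t, t+lag) conditions on macrostate m
only if every frame in [t, t+lag] is labeled m; pairs spanning
conformational changes are discarded and counted, never attributed to
either side. The ion-model lag defaults to the conformational MSM lag
(20 ns). Network arrows are weighted by stationary flux π_i T_ij —
comparable across macrostates with different frame counts — and the edge
list also carries probabilities and rates since conventions differ.

**WHAM.** Binned self-consistent solution in log space with bias energies
evaluated at bin centers. The automatic grid spans the pooled samples with
a 25 % margin and bin width half the narrowest window's thermal width
√(kT/k): fine enough that within-bin bias variation is small, coarse
enough that overlap-region bins keep usable counts (with the stiff
reference protocol, more bins demonstrably inflate a positive barrier
bias from starved tail bins; with expected counts the solver is exact to
< 0.02 kcal/mol at these widths). Plain iteration converges linearly and
very slowly when adjacent windows barely overlap, so sweeps are
accelerated by component-wise Aitken extrapolation, accepted only when it
reduces the sweep residual — the fixed point and the stopping rule
(max |ΔF_i| < tol, default side 1e-8 kcal/mol in the reference protocol)
are unchanged. Bins never visited stay NaN; profiles are anchored to
min 0; window sets whose histograms share no occupied bins are returned
unconverged with a diagnostic rather than an arbitrary stitching.
Equilibration discard follows the 1-of-6 convention (first sixth of each
window) when callers pass time-series data; the i.i.d. rejection sampler
needs none. Replicate aggregation re-anchors each profile before
computing per-bin means/sds and barrier means ± sd; the overlap
convergence flag uses a default threshold of 0.05 on the adjacent-pair
overlap coefficient (the criterion is standard, the number is ours).

## Synthetic generators: what they emulate, and what not

**Langevin features.** Overdamped (not inertial) Euler–Maruyama on
potentials built as −kT·log of a Gaussian mixture, so stationary basin
weights are exactly the mixture weights — metastability and timescale
separation with analytic ground truth. Depth enters as the mixture weight
exp(depth/kT); a single well of width w is exactly harmonic with stiffness
kT/w². kT = 0 degenerates to gradient descent (the landscape is then
shaped with the 300 K reference kT). The generator reproduces
metastable-basin kinetics but none of the geometric structure of real MD
features (no solvent noise spectrum, no anharmonic cross-correlations), so
passing tests demonstrate estimator correctness, not force-field realism.

**Coupled chain.** Three aligned categorical layers sampled per step in
the order macro → SF | macro → ion | (macro, SF). Study conditions
(`default_coupled_chain_spec`): four macrostates with mean dwell ≈ 33 000
steps (stay probability 0.99997) and an SF layer relaxing in ~2 steps
(total flip rate 0.6/step), so the conditional SF distribution inside a
macrostate equals the flip-ratio design a/b up to a carry-over correction
of order the timescale ratio (~10⁻⁴); the exact conditional odds,
computable from the 128-state joint kernel, are 74.9 against the 75:1
design. Down's flip ratio favors pinched 75:1; Up and I2 mirror it toward
open; I1 never enters the pinched state. Ion tables are Metropolis chains
over single-ion moves (entry/exit at S1/S4, hops between adjacent sites)
with Gibbs stationary distributions; OXXO is the global energy minimum
everywhere, the Down tables span all 16 codes while Up is confined to a
7-state conduction-cycle neighborhood and the intermediates to 9 — the
support ordering mirrors the more diffuse ion dynamics of the compressed
conformation. The pinched-filter variant adds +1.2 kT to every
non-resting state. These energies are design choices to realize the
qualitative structure, not fitted quantities.

**Umbrella sampler.** Exact i.i.d. samples per window by rejection from
the bias-only Gaussian N(z_i, kT/k) — WHAM's estimator does not care about
time ordering, and i.i.d. input makes convergence analysis clean. An
optional Metropolis mode with stated stride exists for
autocorrelation-sensitive tests. The window layout follows the five-point
protocol (both wells, the transition state, both midpoints, ≈ 0.05 nm
spacing) with an 8000 kcal mol⁻¹ nm⁻² spring; the spring constant's length
unit is a convention choice recorded in window metadata (nm⁻² assumed).
The tilted double well a((z/w)²−1)² + b(z/w) is solved for (a, b) so the
forward/reverse barriers take prescribed values exactly.

**Toy frames.** One ion at each occupied site's midpoint (uniform jitter
refused at and beyond half the smallest site height, preserving the
round-trip guarantee), four carbonyl oxygens per layer on a 0.25 nm ring,
0.3 nm site spacing, marker atoms for the pore probe, optional cavity
waters; exportable to PDB.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: 10⁵–10⁶-step
chains, 1.5×10⁵-step Langevin runs, 5 windows × 5000 samples × 8
replicates for free-energy profiles. Every stochastic routine takes one
integer seed into `numpy.random.default_rng`; identical (spec, seed) give
bit-identical output, and derived seeds are produced by hashing
(seed, stage-name) below 2³¹.

## Known limitations

- tICA offers no kinetic-map/commute scaling and no feature selection.
- No Bayesian MSM uncertainty, hidden Markov models, or
  Chapman–Kolmogorov tests beyond implied timescales.
- PCCA+ uses the clip-and-renormalize feasibility projection without the
  subsequent objective optimization; adequate for the well-separated
  spectra it is applied to here, and the partition-of-unity and purity
  invariants are asserted directly.
- WHAM only (no MBAR), 1-D profiles only, replicate spread as the only
  uncertainty estimate (no autocorrelation correction).
- Periodic-boundary imaging is out of scope beyond an optional
  pre-centering of input coordinates.
- With the stiff five-window protocol, adjacent-window histogram overlap
  is intrinsically small (coefficients ~10⁻³–10⁻²); single-profile
  barrier estimates carry ~0.2 kcal/mol of linking noise, which is why
  barrier reporting averages ≥ 8 replicates, mirroring the
  multiple-conformation convention.
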