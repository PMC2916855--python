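# Methods

## Model and assumptions

The package analyses the linear (density-independent) dynamics of `n`
age-structured patch populations coupled by juvenile dispersal. The state is
the stacked vector of per-patch age distributions, projected yearly by the
block matrix

```
M = I_n ⊗ S + C ⊗ F        (identical patches)
```

where `S` is the `m×m` subdiagonal survival matrix, `F` the first-row
fertility matrix, and `C` the `n×n` connectivity matrix of recruitment
proportions (`C[i,j]`: share of patch-`j` juveniles recruiting to patch `i`;
row = destination, column = origin). For nonidentical patches the block form
is `S_i + C[i,i] F_i` on the diagonal and `C[i,j] F_j` off it — fertility is
produced by the origin patch.

This is the linearization of any density-dependent metapopulation model
about its extinction state, so every statement here is a statement about
*invasion from rarity*: whether the extinction state is unstable. Nothing in
the package describes dynamics away from low density, demographic
stochasticity, or environmental forcing.

Key reductions implemented and cross-validated against each other:

* `χ = R·ρ(C)` with `R = Σ f_k l_k` (survivorship `l_1 = 1`,
  `l_k = Π_{j≤k} p_j`): the extinction state is unstable iff `χ > 1`.
* the `m×m` stability matrix `S + ρ(C)F` has dominant eigenvalue crossing 1
  exactly when χ does;
* under the uniform scheme `C = σI + εA`, `ρ(C) = σ + ε·ρ(A)` identically.

Juvenile-to-recruit survival is absorbed into the retention/transport
proportions (`σ`, `ε`, the entries of `C`): only the fertility row is
discounted, and no separate first-year survival parameter exists. `l_k`
therefore starts at `l_1 = 1`.

Thresholds are strict: `χ > 1` persists; `|χ − 1| ≤ 1e−12` is labelled
`critical` and classified non-persisting.

## Cycle calculus

"Cyclic component" is operationalized as a nontrivial strongly connected
component (size ≥ 2; the adjacency has zero diagonal, self-recruitment lives
only in `C`). An edge lies on a directed cycle iff its endpoints share an
SCC, so SCC-internal edges are exactly the cycle-participating links and
everything else is a lonely link. `ρ(A)` equals the maximum of the component
radii; a component is *simple* (a single directed cycle, radius exactly 1)
iff every internal in- and out-degree is 1. Undirected input is treated as
bidirectional — each symmetric pair is a 2-cycle.

Dominant-component ties (equal radii) are broken by patch count, then by
lowest patch id; persistence is unaffected. Critical-link ranking recomputes
`ρ` exactly per removal (dense eigensolve) rather than by perturbation
approximations — conservation networks are small, and exactness is worth
more than speed here. Lonely links are reported with `delta_rho = 0` without
recomputation, which is exact.

## Numerical choices

* **Spectral radius.** Up to `n = 500` the matrix is first reduced to
  Frobenius normal form (strong components of its pattern, via
  `scipy.sparse.csgraph`) and a dense eigensolve runs per irreducible block.
  This is mathematically exact and avoids the classical failure of dense
  eigensolvers on nilpotent blocks, which otherwise report spurious
  eigenvalues of magnitude ~`eps^(1/n)`; it is what makes `ρ(A) = 0` exact
  on acyclic networks and `χ = σR` exact in their analysis. Above 500 a
  seeded power iteration runs with a two-step magnitude estimate (damping
  period-2 oscillation on bipartite-like structures), tolerance `1e−10`,
  at most `1e5` matrix products, a residual acceptance check, and a dense
  fallback — plain power iteration need not converge on periodic or
  reducible matrices (a simple cycle has a full ring of equal-modulus
  eigenvalues).
* **Simulation.** The state is renormalized to unit total (L1 — natural for
  population totals) every step with the log of the true total accumulated
  separately, so `χ ≫ 1` cannot overflow and `χ ≪ 1` cannot underflow. The
  growth factor is fitted from the two snapshots `T/2` and `T`:
  `(‖N_T‖/‖N_{T/2}‖)^{1/(T−T/2)}`. It converges to `λmax` when the dominant
  behaviour is primitive; imprimitive systems (pure cycles) oscillate and
  the estimate then carries an `O(1/T)` periodic remainder. Tests therefore
  check sign agreement with `λmax` in general and closeness only in the
  presence of a spectral gap.
* **Determinism.** Every stochastic generator takes a mandatory seed; JSON
  reports round floats to 12 significant digits so identical invocations are
  byte-identical.
* **Characteristic polynomials** are report-oriented (`n ≤ 64`), computed by
  `numpy.poly`; they exist for inspecting small components, not for
  computing radii.

## Parameters and defaults

* Fixture demography: `m = 2`, `f = (0, 4)`, `p_2 = 0.5` (so `R = 2`),
  `σ = 0.3` — a biennial invertebrate-like life cycle with strong fecundity
  and modest retention, chosen so that single patches are sinks
  (`σR = 0.6`) and network effects are visible.
* `bootstrap_sinks`: the ring of 10 such patches with `ε = 0.3` gives
  `χ = 2(0.3 + 0.3·2) = 1.8` — every patch a sink, metapopulation growing.
  Solved from the uniform-scheme closed form given `σ`, `R`, and the ring
  radius `q = 2`.
* `fig2_*` networks use `n = 24` and mean degree 2 (regular ring; ER with
  `p = 2/(n−1)`; configuration model with a right-skewed graphical sequence
  of mean 2) — large enough for degree statistics to be meaningful, small
  enough to print.
* `fig4_two_components` is a *reconstruction*: the published example's exact
  6-patch/9-link wiring is not recoverable, so the fixture realizes the
  stated constraints (one simple 3-patch/3-link component; one strongly
  connected 6-patch/9-link component of intersecting cycles, here an outer
  6-cycle with three chords giving `ρ ≈ 1.442`; nine appendage patches on
  lonely links only; a critical link whose removal leaves only
  non-intersecting simple cycles, `ρ = 1`). Tests assert the structural
  counts, never a specific radius for the complex component.
* `fig5_all_to_all`: four nonidentical patches on a complete graph with
  elementwise-ordered demographies (`R_0 > R_1 > R_2 > R_3`), so the upper
  and lower envelopes coincide with actual patches.
* Coherency cutoff: a network is called coherent when the largest connected
  component exceeds half the patches (the standard giant-component
  convention; configurable).

## Synthetic data: what it does and does not emulate

Test inputs are seeded random demographies (uniform `p_k ∈ [0.05, 1]`,
`f_k ∈ [0, 4]`, `σ ∈ [0, 1]`, `m ≤ 5`) and random directed/undirected/acyclic
networks of up to ~13 patches, plus the named fixtures. These probe the
*mathematical* claims — threshold equivalences, exactness of the cycle
calculus, envelope bounds — across a broad parameter box. They do not
emulate real larval-dispersal data: no distance-kernel or asymmetric
advection-weighted connectivity, no temporal variability, no correlation
between demography and network position. Passing tests therefore validate
the theory and its implementation, not any claim about a particular marine
system.

## Heterogeneous patches: envelope generalization

The dominating/subordinate-patch construction assumes an actual patch
dominates (or is dominated by) all others elementwise. The package
generalizes to elementwise envelopes — upper: max over patches of every
`f_k`, `p_k`, `σ`; lower: minima — which preserves the proof mechanism
(Perron-root monotonicity in matrix entries: the heterogeneous block matrix
is entrywise sandwiched by the two homogeneous envelope systems) and always
yields valid bounds; when a dominating patch exists the envelope *is* that
patch. Both hypothetical systems retain the original network; the envelope σ
replaces the diagonal of `C`. `χ_upper < 1` ⇒ extinct, `χ_lower > 1` ⇒
persisting, otherwise indeterminate (including the boundary `χ_upper = 1`,
where strictness is not guaranteed), with the exact dominant eigenvalue of
the full system reported as tie-breaker whenever `nm ≤ 2000`.

Heterogeneous patch fates extend the homogeneous reachability argument
operationally (component-restricted eigensolves plus directed reachability);
this is a design choice of the package, documented as such.

## Closed-form estimates: validity regimes

`ρ(A) ≈ p(n−1)` (ER) is a dense-regime estimate; in sparse ER networks the
largest-hub term `√d_max` can dominate and the estimate degrades, so the
package checks it only densely (`n = 300`, `p = 0.1`, within 5%) and
`degree_stats` warns when asked about directed networks, where both
estimates are uncalibrated. `⟨d⟩(1+CV²) = ⟨d²⟩/⟨d⟩` is checked on
configuration-model networks (`n = 2000`, geometric-like degrees of mean ~3,
three seeds) to within 15% — it is an approximation, not an identity.

## Problem sizes

Randomized suites use 100–200 instances per property with `n ≤ 12`, `m ≤ 5`
(full systems ≤ 60×60), simulations of 600–2000 steps, and spectral checks
up to `n = 2000` for the heterogeneity estimate; the whole suite runs in
well under a minute.

## Known limitations

* Linear dynamics only; no density dependence, stochasticity, or spatial
  synchronization effects.
* Dispersal is age-blind: juveniles of every patch follow the same network;
  age-class-specific inter-patch migration is out of scope.
* Unweighted adjacency (0/1 routes) with uniform `ε`, or a fully explicit
  `C`; no distance-kernel parameterization.
* Enumerating all simple cycles is deliberately avoided (exponential); the
  SCC decomposition carries all persistence-relevant information.
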