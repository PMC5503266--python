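# Methods

This note records how each quantity in the package is computed and why the
results are exact where exactness is claimed.

## The full-state chain

For a connected undirected graph on `N` vertices the invader set `S ⊆ V` is a
Markov state. With invader fitness `r`, replacement weights `w_ij = 1/d_i` for
each edge, and total reproductive weight `w_S = r|S| + (N − |S|)`, the one-step
kernel moves mass only between sets differing in one vertex:

- gain of `j ∉ S`: probability `(r/w_S) · Σ_{i∈S} w_ij`,
- loss of `i ∈ S`: probability `(1/w_S) · Σ_{j∉S} w_ji`,

with the remainder a self-loop. Fixation probabilities satisfy the absorbing
linear system `Φ_S = Σ_T P(S,T) Φ_T` with `Φ_∅ = 0`, `Φ_V = 1`. The package
assembles the `2^N − 2` transient equations as sparse rows over exact
rationals, ordered by invader count so that elimination fill-in stays local,
and solves them exactly (`moran_exact`, orders ≤ 14).

### Exact linear solving

Small systems are solved by sparse fraction-free Gaussian elimination over
`ℚ`. Larger systems (the order-10 complete graph has 1022 transient states)
use Dixon's p-adic method: the system is cleared to integers, an LU
factorisation is computed modulo a prime `p < 2^20` using machine integers, a
p-adic digit expansion of the solution is lifted digit by digit, and the
rational solution is recovered by lattice-free extended-Euclidean rational
reconstruction, then verified exactly against the original system. This
replaces minutes of big-rational elimination with seconds of modular
arithmetic while keeping the result certified exact.

## Symmetry lumping of the ℓ-graph chain

The balanced ℓ-graph on `N = 2n + 2` vertices (clique halves `A`, `B`,
path vertices `u`–`v` with `u ∼ A`, `v ∼ B`) has an automorphism group
containing all permutations within `A` and within `B` and the swap
`(A, u) ↔ (B, v)`. A state is determined up to automorphism by the orbit label
`(e, k, k′, e′)`: whether `u` is an invader, how many invaders sit in `A`, how
many in `B`, and whether `v` is an invader, canonicalised by the swap so that
`(k, e) ≥ (k′, e′)` lexicographically. Counting these labels gives
`N(N+1)/2` orbit states — 21, 36 and 55 for `N = 6, 8, 10`.

The partition is *strongly lumpable*: the total transition rate from any state
into a target orbit depends only on the source orbit, which the test suite
verifies directly by summing the full kernel over orbits. Consequently the
lumped chain's fixation probabilities are exactly those of the full chain,
and the average over a uniform start is the orbit average weighted by orbit
sizes (`2n` clique starts, two path starts). Unbalanced variants
`(p, q)` with `p ≠ q` lack the swap symmetry; their reduction keeps all
`4(p+1)(q+1)` labels and is validated against the full chain for small cases.

## Reconstructing Φ(r) as a rational function

For fixed `N` the average fixation probability is a rational function of `r`
of degree at most `d = N(N+1)/2 − 2` over the same denominator degree, with
`Φ → 1` as `r → ∞` forcing equal leading coefficients. Writing
`Φ = a(r)/b(r)` with `a_d = b_d = 1`, each exact lumped solve at a rational
node `r_k` gives one linear equation in the `2d` unknown coefficients. The
package evaluates at `2d` nodes (`1..d+1` and `1/2..1/d`), solves the system
with the Dixon solver, and validates the candidate against *all* nodes plus
held-out nodes not used in the fit.

The generic degree bound can be degenerate — the six-vertex ℓ-graph has true
degree 17 rather than 19, making the order-19 interpolation matrix singular.
On singularity or validation failure the degree is decreased and the fit
retried; the final function is accepted only when it reproduces every exact
evaluation, so a wrong degree cannot survive.

## Sign certification by Sturm sequences

With `Φ₀(r) = r^{N−1}(r−1)/(r^N − 1)`, the difference `Δ(r) = Φ(r) − Φ₀(r)`
is a ratio of integer polynomials whose denominator is positive for `r > 0`,
so the sign of `Δ` on an interval is the sign of its numerator. Root counting
uses Sturm sequences over exact integers: the numerator is replaced by its
squarefree part, the sequence is built with content-normalised pseudo-
remainders, and the number of roots in an open interval is the difference of
sign-variation counts at the endpoints, with endpoint roots handled
explicitly. A polynomial with no roots in `(1, ∞)` has constant sign there,
determined by one rational evaluation; `certify_sign` returns `always+`,
`always-`, `mixed`, or `zero`. The implementation is cross-checked in the
test suite against sympy's independent real-root isolation.

`Δ` always vanishes at `r = 1` (both curves equal `1/N` there). The symbolic
classifier divides the numerator of `Δ′` by its `(r − 1)`-factor, recording
the multiplicity `m`; the sign of the quotient on `(1, ∞)` gives the sign of
`Δ` there, and the same sign analysis on `(0, 1)` — with a parity flip when
`m` is odd — gives the sign below 1. A graph is certified a *suppressor* when
`Δ < 0` on all of `(1, ∞)` and `Δ > 0` on all of `(0, 1)`, an *amplifier*
for the reversed signs. For arbitrary graphs a grid-based classifier compares
exact values of `Φ` and `Φ₀` on a rational grid instead.

## Exhaustive order-6 scan

Connected isomorphism classes up to order 7 come from the networkx graph
atlas (112 classes at order 6; the enumeration is re-derived by brute force
for small orders in the tests). Each class is solved exactly on the grid
`r = 1/4, 2/4, …, 10` and labelled; exactly one order-6 class is a
suppressor, and it is isomorphic (by canonical adjacency form) to the
balanced ℓ-graph with `n = 2`.

## Monte-Carlo simulation

The simulator follows the *embedded* chain: self-loop steps are skipped by
sampling directly among the `O(E)` state-changing events, each directed edge
`(i, j)` with `i` and `j` in different camps contributing weight
`f_i · w_ij`. Trials start from a uniformly random vertex and run to
absorption. The inner loop is numba-compiled; determinism comes from seeding
the generator inside the kernel, with per-point seeds spawned from a numpy
`SeedSequence` for curves. Estimates carry Wilson score confidence intervals
(statsmodels), whose nominal coverage is checked empirically in the
acceptance suite. Million-trial runs resolve the `~10^-3` suppression of the
six- and ten-vertex ℓ-graphs and the `~3×10^-4` amplification of the
unbalanced `(1, 3)` variant at `r = 8` to within four standard errors of the
exact values.
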