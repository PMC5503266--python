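# moranfix

Exact and Monte-Carlo computation of fixation probabilities for the Moran
birth–death process on undirected graphs, with symbolic certification of
whether a graph **suppresses** or **amplifies** natural selection.

## Background

In the Moran birth–death process a population of constant size `N` lives on
the vertices of a graph. One vertex starts as an invading mutant with relative
fitness `r`; residents have fitness 1. At each step an individual is chosen to
reproduce with probability proportional to fitness, and its offspring replaces
a uniformly chosen neighbour (weight `1/d` for a vertex of degree `d`).
Eventually the mutant lineage either takes over every vertex (*fixation*) or
dies out (*extinction*). The quantity of interest is the fixation probability
`Φ(r)`, averaged over a uniformly random starting vertex.

On the complete graph — and, by the circulation property, on every
*isothermal* graph, where the sum of incoming replacement weights is the same
at every vertex — the fixation probability equals the well-mixed closed form

```
Φ₀(r) = (1 − 1/r) / (1 − 1/r^N).
```

A graph is an **amplifier of selection** if `Φ(r) > Φ₀(r)` for all `r > 1`
(advantageous mutants fix more often, deleterious ones less often) and a
**suppressor of selection** if the inequalities are reversed. Suppressors are
rare: among all 112 connected graphs on six vertices exactly one is a
suppressor. It is the smallest member of a family we call **ℓ-graphs**: take
the complete graph on `2n` vertices, split it into halves `A` and `B`, and
attach a path `u–v` where `u` is adjacent to all of `A` and `v` to all of `B`.
This package constructs these graphs, computes their fixation probabilities
exactly as rational functions of `r`, and certifies their suppressor character
symbolically for `N = 6, 8, 10`, with unbalanced variants that instead become
amplifiers for large `r`.

## What the package does

- **`moranfix.graph_models`** — constructors (complete, star, complete
  bipartite, balanced and unbalanced ℓ-graphs), vertex temperatures and the
  isothermal test, canonical forms, exhaustive enumeration of connected
  isomorphism classes up to order 7, edge-list I/O.
- **`moranfix.moran_exact`** — the full `2^N`-state absorbing chain solved
  over exact rationals (orders up to 14); transition kernel available
  directly.
- **`moranfix.lumped_chain`** — strong lumping of the ℓ-graph chain by its
  automorphisms down to `N(N+1)/2` orbit states (21/36/55 for `N = 6/8/10`),
  plus the unbalanced-family reduction; agrees with the full chain exactly.
- **`moranfix.rational_fixation`** — reconstruction of `Φ(r)` as an exact
  rational function from lumped solves at rational nodes, the difference
  `Δ(r) = Φ(r) − Φ₀(r)`, and Sturm-sequence sign certification of `Δ` on
  `(0, 1)` and `(1, ∞)`; also a grid-based classifier for arbitrary graphs.
- **`moranfix.monte_carlo`** — a numba-compiled simulator of the embedded
  chain (self-loop steps skipped) with Wilson score confidence intervals;
  fully reproducible given a seed.
- **`moranfix.cli`** — a `moranfix` command with subcommands `generate`,
  `exact`, `lumped`, `reconstruct`, `classify`, `mc`, `mc-curve`, `scan`, and
  `run` (YAML-driven).

## Worked example

Exact average fixation probability of the six-vertex ℓ-graph at `r = 2`:

```console
$ moranfix exact --graph ell:2 --r 2
{
  "graph": "ell:2",
  "order": 6,
  "r": "2",
  "average": {
    "exact": "290563457033894472128/573017130923792511951",
    "decimal": "0.507076388040024"
  }
}
```

This is strictly below the well-mixed value `Φ₀(2) = 32/63 ≈ 0.507937`, and
the symbolic classifier certifies that the difference is negative for *every*
`r > 1` and positive for every `r` in `(0, 1)`:

```console
$ moranfix classify --n 2 --mode symbolic
{
  "mode": "symbolic",
  "n": 2,
  "label": "suppressor",
  "certificate": "Δ'' always+ on (0,∞); Δ' = (r−1)^1·q(r) with q always- on (1,∞) and always- on (0,1); hence Δ always- on (1,∞) and always+ on (0,1)"
}
```

A million-trial Monte-Carlo run brackets the exact value:

```console
$ moranfix mc --graph ell:2 --r 2 --trials 1000000 --seed 1
{
  "graph": "ell:2",
  "r": 2.0,
  "trials": 1000000,
  "seed": 1,
  "level": 0.99,
  "fixations": 506564,
  "p_hat": 0.506564,
  "ci_low": 0.5052761570557285,
  "ci_high": 0.5078517558419269
}
```

The 99% interval contains the exact value 0.507076… and excludes `Φ₀(2)`.

The same functionality is available from Python:

```python
from fractions import Fraction
from moranfix import reduced_fixation, reconstruct_ell, classify_symbolic

phi = reconstruct_ell(2)            # exact rational function of r
assert phi(1) == Fraction(1, 6)     # neutral mutants fix with probability 1/N
assert phi(Fraction(9, 4)) == reduced_fixation(2, Fraction(9, 4))
print(classify_symbolic(phi, 6).label)   # "suppressor"
```

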