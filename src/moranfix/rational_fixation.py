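"""Fixation probability as an exact rational function of the fitness.

The average fixation probability Φ(r) of any finite graph is a quotient
Φ'(r)/Φ''(r) of polynomials with rational coefficients.  Generically the
degree is bounded by 2^N − 2, but the lumped chain of an ℓ-graph caps it
at d = N(N+1)/2 − 2.  Since Φ(r) → 1 as r → ∞, the leading coefficients
can be normalised to a_d = b_d = 1, leaving 2d unknown coefficients that
are pinned down by evaluating Φ exactly at the 2d low-complexity rational
fitness values {1, …, d+1, 1/2, …, 1/d} and solving the resulting linear
system.

Once Φ is reconstructed, the difference Δ(r) = Φ(r) − Φ₀(r) against the
well-mixed baseline Φ₀(r) = r^{N−1}(r−1)/(r^N − 1) is put over a common
denominator and its numerator's sign on (1, ∞) and (0, 1) is certified by
Sturm-sequence real-root isolation over exact rationals.  A graph is a
suppressor of selection if Δ < 0 for all r > 1 (and then Δ > 0 for
r < 1), an amplifier if the inequalities are reversed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import sympy
from sympy.polys.domains import QQ

from ._ratsolve import SingularMatrixError, solve_dixon
from . import lumped_chain
from .moran_exact import average_fixation

__all__ = [
    "RationalFunc",
    "ClassificationVerdict",
    "phi0",
    "phi2",
    "degree_bound",
    "evaluation_points",
    "reconstruct_rational",
    "reconstruct_ell",
    "delta_function",
    "certify_sign",
    "classify",
    "classify_symbolic",
    "classify_grid",
    "default_grid",
]

log = logging.getLogger(__name__)

_r = sympy.Symbol("r")


def _frac(x) -> Fraction:
    if isinstance(x, tuple):
        return Fraction(*x)
    return Fraction(x)


def phi0(r, N: int) -> Fraction:
    """Well-mixed (complete-graph) fixation probability of a single invader.

    Φ₀(r) = r^{N−1}(r−1)/(r^N − 1) for r ≠ 1, with the continuity value
    1/N at neutral drift r = 1.
    """
    if N < 2:
        raise ValueError(f"need N >= 2, got {N}")
    rq = _frac(r)
    if rq <= 0:
        raise ValueError(f"fitness must be positive, got {rq}")
    if rq == 1:
        return Fraction(1, N)
    return rq ** (N - 1) * (rq - 1) / (rq**N - 1)


def phi2(r, N: int) -> Fraction:
    """Reference bound Φ₂(r) = Φ₀(r²): the well-mixed process at fitness r².

    Star and complete bipartite fixation probabilities converge to this
    amplified limit as the large part grows.
    """
    return phi0(_frac(r) ** 2, N)


def degree_bound(N: int) -> int:
    """Degree bound d = N(N+1)/2 − 2 for ℓ-graph numerator/denominator.

    Follows from the lumped chain having N(N+1)/2 states, compared to the
    generic full-state bound 2^N − 2.
    """
    if N < 6 or N % 2:
        raise ValueError(f"ℓ-graph orders are even and >= 6, got {N}")
    return N * (N + 1) // 2 - 2


def evaluation_points(d: int) -> list[Fraction]:
    """The 2d interpolation nodes {1, …, d+1} ∪ {1/2, …, 1/d}.

    These are the least complex rationals: coefficient bit-size of the
    interpolation system, and hence of its solution, stays manageable.
    """
    if d < 2:
        raise ValueError(f"need degree d >= 2, got {d}")
    return [Fraction(i) for i in range(1, d + 2)] + [Fraction(1, i) for i in range(2, d + 1)]


@dataclass(frozen=True)
class RationalFunc:
    """Exact quotient Φ'(r)/Φ''(r); coefficients ascending, monic at degree d."""

    numer: tuple[Fraction, ...]
    denom: tuple[Fraction, ...]

    @property
    def degree(self) -> int:
        return max(len(self.numer), len(self.denom)) - 1

    def __call__(self, r) -> Fraction:
        rq = _frac(r)
        num = den = Fraction(0)
        for c in reversed(self.numer):
            num = num * rq + c
        for c in reversed(self.denom):
            den = den * rq + c
        if den == 0:
            raise ZeroDivisionError(f"denominator vanishes at r = {rq}")
        return num / den

    def as_sympy(self):
        num = sympy.Poly(list(reversed([sympy.Rational(c) for c in self.numer])), _r)
        den = sympy.Poly(list(reversed([sympy.Rational(c) for c in self.denom])), _r)
        return num, den


def _solve_interpolation(evals, d: int) -> RationalFunc:
    """Set up and solve the 2d x 2d linear system for the coefficients.

    Unknowns x = (a_0..a_{d-1}, b_0..b_{d-1}); for each node r with value
    f = Φ(r):  Σ a_i r^i − f Σ b_i r^i = (f − 1) r^d.
    """
    nodes = evals[: 2 * d]
    rows, rhs = [], []
    for rv, fv in nodes:
        rq = QQ(rv.numerator, rv.denominator)
        fq = QQ(fv.numerator, fv.denominator)
        powers = [QQ(1)]
        for _ in range(d):
            powers.append(powers[-1] * rq)
        row = {}
        for i in range(d):
            row[i] = powers[i]
            row[d + i] = -fq * powers[i]
        rows.append(row)
        rhs.append((fq - QQ(1)) * powers[d])
    x = solve_dixon(rows, rhs)
    a = [Fraction(int(v.numerator), int(v.denominator)) for v in x[:d]] + [Fraction(1)]
    b = [Fraction(int(v.numerator), int(v.denominator)) for v in x[d:]] + [Fraction(1)]
    return RationalFunc(tuple(a), tuple(b))


def _reduce_common_factor(f: RationalFunc) -> RationalFunc:
    """Divide out the polynomial GCD of numerator and denominator."""
    num, den = f.as_sympy()
    g = num.gcd(den)
    if g.degree() > 0:
        num = num.exquo(g)
        den = den.exquo(g)
        # keep the monic-leading normalisation
        lc = den.LC()
        num = num.quo_ground(lc)
        den = den.quo_ground(lc)
    return RationalFunc(
        tuple(Fraction(c.p, c.q) for c in reversed(num.all_coeffs())),
        tuple(Fraction(c.p, c.q) for c in reversed(den.all_coeffs())),
    )


def reconstruct_rational(
    evals: Sequence[tuple[Fraction, Fraction]],
    d: int,
    holdout: Sequence[tuple[Fraction, Fraction]] = (),
) -> RationalFunc:
    """Recover Φ'(r)/Φ''(r) of degree <= d from >= 2d exact evaluations.

    If the 2d x 2d system is singular the true degrees are below d; the
    degree is lowered until the system becomes nonsingular.  The result
    must reproduce *every* supplied evaluation pair and every held-out
    pair exactly, else a certification error is raised.
    """
    evals = [(_frac(r), _frac(v)) for r, v in evals]
    if len({r for r, _ in evals}) != len(evals):
        raise ValueError("evaluation nodes must be distinct")
    f = None
    for dd in range(d, 1, -1):
        if len(evals) < 2 * dd:
            continue
        try:
            f = _solve_interpolation(evals, dd)
            break
        except SingularMatrixError:
            log.info("interpolation system singular at degree %d; retrying at %d", dd, dd - 1)
    if f is None:
        raise SingularMatrixError(f"no nonsingular system found at any degree <= {d}")
    f = _reduce_common_factor(f)
    for rv, fv in list(evals) + [(_frac(r), _frac(v)) for r, v in holdout]:
        if f(rv) != fv:
            raise ArithmeticError(
                f"reconstructed function fails exact validation at r = {rv}"
            )
    return f


def reconstruct_ell(n: int, extra_validation: int = 3) -> RationalFunc:
    """Reconstruct Φ(r) of the balanced ℓ-graph of order N = 2n+2.

    Evaluates the lumped chain exactly at the 2d standard nodes, solves
    the coefficient system, and validates at ``extra_validation``
    held-out non-node rationals (7/3, 5/7, d+3/2, ...).
    """
    N = 2 * n + 2
    d = degree_bound(N)
    nodes = evaluation_points(d)
    log.info("reconstructing ℓ_%d: degree bound %d, %d evaluations", N, d, len(nodes))
    evals = [(rv, lumped_chain.reduced_fixation(n, rv)) for rv in nodes]
    held = []
    candidates = [Fraction(7, 3), Fraction(5, 7), Fraction(2 * d + 3, 2), Fraction(13, 5)]
    for rv in candidates[:extra_validation]:
        held.append((rv, lumped_chain.reduced_fixation(n, rv)))
    return reconstruct_rational(evals, d, holdout=held)


def delta_function(phi: RationalFunc, N: int) -> RationalFunc:
    """Δ(r) = Φ(r) − Φ₀(r) as a single reduced quotient Δ'(r)/Δ''(r).

    Over the common denominator Φ''(r)·(r^N − 1); the removable
    singularity at r = 1 cancels in the polynomial GCD reduction.
    """
    num, den = phi.as_sympy()
    rn = sympy.Poly([1] + [0] * (N - 1) + [-1], _r)       # r^N - 1
    phi0_num = sympy.Poly([1, -1] + [0] * (N - 1), _r)    # r^{N-1}(r - 1)
    dnum = num * rn - phi0_num * den
    dden = den * rn
    g = dnum.gcd(dden)
    if g.degree() > 0:
        dnum = dnum.exquo(g)
        dden = dden.exquo(g)
    return RationalFunc(
        tuple(Fraction(c.p, c.q) for c in reversed(dnum.all_coeffs())),
        tuple(Fraction(c.p, c.q) for c in reversed(dden.all_coeffs())),
    )


# ---------------------------------------------------------------------------
# Sturm-sequence sign certification
# ---------------------------------------------------------------------------

Sign = Literal["always+", "always-", "mixed", "zero"]


def _primitive(coeffs: list[int]) -> list[int]:
    """Integer content removal (sign-preserving)."""
    import math

    g = 0
    for c in coeffs:
        g = math.gcd(g, abs(c))
        if g == 1:
            return coeffs
    return [c // g for c in coeffs] if g else coeffs


def _to_int_coeffs(coeffs: Sequence[Fraction]) -> list[int]:
    import math

    lcm = 1
    for c in coeffs:
        lcm = lcm * c.denominator // math.gcd(lcm, c.denominator)
    return _primitive([int(c * lcm) for c in coeffs])


def _poly_rem(a: list[int], b: list[int]) -> list[Fraction]:
    """Remainder of a / b over Q (coefficients ascending)."""
    a = [Fraction(c) for c in a]
    db, lb = len(b) - 1, b[-1]
    while len(a) - 1 >= db and any(a):
        while a and a[-1] == 0:
            a.pop()
        if len(a) - 1 < db:
            break
        f = a[-1] / lb
        shift = len(a) - 1 - db
        for i, c in enumerate(b):
            a[shift + i] -= f * c
        a.pop()
    while a and a[-1] == 0:
        a.pop()
    return a


def _sturm_sequence(coeffs: Sequence[Fraction]) -> list[list[int]]:
    """Sturm chain of the squarefree part, content-normalised at each step.

    Working with the squarefree part keeps the chain proper (it ends in a
    nonzero constant), so endpoint evaluations behave even at multiple
    roots of the original polynomial; content removal after every
    remainder step controls integer coefficient growth.
    """
    p = _to_int_coeffs(coeffs)
    if len(p) > 2:
        sqf = sympy.Poly(list(reversed(p)), _r).sqf_part()
        p = _primitive([int(c) for c in reversed(sqf.all_coeffs())])
    dp = _primitive([i * c for i, c in enumerate(p)][1:])
    chain = [p, dp]
    while len(chain[-1]) > 1:
        rem = _poly_rem(chain[-2], chain[-1])
        if not rem:
            break
        chain.append(_primitive([-c for c in _to_int_coeffs(rem)]))
    return chain


def _eval_int_poly(coeffs: list[int], x: Fraction) -> Fraction:
    acc = Fraction(0)
    for c in reversed(coeffs):
        acc = acc * x + c
    return acc


def _sign_changes(values) -> int:
    signs = [v for v in ((1 if v > 0 else -1 if v < 0 else 0) for v in values) if v]
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def _count_roots_open(coeffs: Sequence[Fraction], lo: Fraction | None, hi: Fraction | None) -> int:
    """Distinct real roots in the open interval (lo, hi); None = ±∞.

    Sturm's theorem on the squarefree part.  Endpoint roots are excluded
    by nudging the bound past them (the chain counts roots in (lo, hi]).
    """
    chain = _sturm_sequence(coeffs)
    if len(chain[0]) <= 1:
        return 0

    def sigma(x: Fraction | None, at_pos_inf: bool = False) -> int:
        if x is None:
            vals = [(c[-1] if at_pos_inf or (len(c) % 2) else -c[-1]) for c in chain]
            return _sign_changes(vals)
        return _sign_changes([_eval_int_poly(c, x) for c in chain])

    # With zero values dropped from the sign-change count, sigma(x) equals
    # the right limit sigma(x+): sigma(lo) - sigma(hi) counts the distinct
    # roots in (lo, hi], so a root at lo is already excluded and a root at
    # hi must be subtracted off.
    total = sigma(lo) - (sigma(None, at_pos_inf=True) if hi is None else sigma(hi))
    if hi is not None and _eval_int_poly(chain[0], hi) == 0:
        total -= 1
    return total


def certify_sign(coeffs: Sequence[Fraction], interval: tuple = (1, None)) -> Sign:
    """Certified sign of a rational-coefficient polynomial on an open interval.

    Exact real-root isolation via Sturm sequences: the sign is constant
    iff there is no root strictly inside the interval, and is then read
    off one rational sample point.  ``interval`` endpoints are rationals
    or None for ±∞ (default: (1, ∞)).
    """
    coeffs = [_frac(c) for c in coeffs]
    while coeffs and coeffs[-1] == 0:
        coeffs = coeffs[:-1]
    if not coeffs:
        return "zero"
    lo = None if interval[0] is None else _frac(interval[0])
    hi = None if interval[1] is None else _frac(interval[1])
    if _count_roots_open(coeffs, lo, hi) > 0:
        return "mixed"
    # no roots strictly inside: one interior sample fixes the sign
    sample = _sample_point(coeffs, lo, hi)
    val = _eval_int_poly(_to_int_coeffs(coeffs), sample)
    if val == 0:  # sample landed on an endpoint-adjacent root: perturb inward
        step = Fraction(1, 7)
        while val == 0:
            sample += step if hi is None else (hi - sample) / 7
            val = _eval_int_poly(_to_int_coeffs(coeffs), sample)
    return "always+" if val > 0 else "always-"


def _sample_point(coeffs, lo, hi) -> Fraction:
    if lo is not None and hi is not None:
        return (lo + hi) / 2
    if lo is not None:
        # beyond the Cauchy root bound the sign equals the leading term's
        ints = _to_int_coeffs(coeffs)
        bound = 1 + max(abs(c) for c in ints[:-1]) // abs(ints[-1]) + 1 if len(ints) > 1 else 2
        return max(lo + 1, Fraction(bound))
    if hi is not None:
        ints = _to_int_coeffs(coeffs)
        bound = 1 + max(abs(c) for c in ints[:-1]) // abs(ints[-1]) + 1 if len(ints) > 1 else 2
        return min(hi - 1, Fraction(-bound))
    return Fraction(0)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassificationVerdict:
    """Suppressor/amplifier verdict with the evidence that backs it."""

    label: Literal["suppressor", "amplifier", "isothermal-neutral", "mixed"]
    mode: Literal["symbolic", "grid"]
    certificate: str
    evidence: tuple = ()  # grid mode: (r, Φ, Φ₀, Δ) rows


def _divide_out_root_one(coeffs: list[Fraction]) -> tuple[list[Fraction], int]:
    """Remove all (r − 1) factors (Δ(1) = 0 forces at least one).

    Returns the quotient and the multiplicity m; the parity of m decides
    how the quotient's sign on (0, 1) translates back to Δ's sign there.
    """
    m = 0
    while len(coeffs) > 1 and sum(coeffs) == 0:
        # synthetic division by (r - 1), ascending coefficients
        out = [Fraction(0)] * (len(coeffs) - 1)
        acc = Fraction(0)
        for i in range(len(coeffs) - 1, 0, -1):
            acc += coeffs[i]
            out[i - 1] = acc
        coeffs = out
        m += 1
    return coeffs, m


def classify_symbolic(phi: RationalFunc, N: int) -> ClassificationVerdict:
    """Certify suppressor/amplifier status of Φ on all of (1, ∞) and (0, 1).

    Builds Δ = Φ − Φ₀ as Δ'/Δ'', certifies Δ'' > 0 on (0, ∞), divides the
    forced (r−1) root out of Δ', and Sturm-certifies the sign of the
    quotient on both open intervals.
    """
    delta = delta_function(phi, N)
    if all(c == 0 for c in delta.numer):
        return ClassificationVerdict(
            "isothermal-neutral", "symbolic", "Δ ≡ 0: fixation equals the well-mixed baseline"
        )
    den_sign = certify_sign(delta.denom, (0, None))
    if den_sign not in ("always+", "always-"):
        raise ArithmeticError("Δ'' changes sign on (0, ∞); cannot certify")
    core, mult = _divide_out_root_one(list(delta.numer))
    core_above = certify_sign(core, (1, None))
    core_below = certify_sign(core, (0, 1))
    swap = {"always+": "always-", "always-": "always+"}
    # Δ sign = sign(core) · sign((r−1)^mult) / sign(Δ''):
    above = core_above
    below = swap.get(core_below, core_below) if mult % 2 else core_below
    if den_sign == "always-":
        above = swap.get(above, above)
        below = swap.get(below, below)
    cert = (
        f"Δ'' {den_sign} on (0,∞); Δ' = (r−1)^{mult}·q(r) with q {core_above} on (1,∞) "
        f"and {core_below} on (0,1); hence Δ {above} on (1,∞) and {below} on (0,1)"
    )
    if above == "always-" and below == "always+":
        return ClassificationVerdict("suppressor", "symbolic", cert)
    if above == "always+" and below == "always-":
        return ClassificationVerdict("amplifier", "symbolic", cert)
    return ClassificationVerdict("mixed", "symbolic", cert)


def default_grid() -> list[Fraction]:
    """The standard classification grid: r = 0.25 to 10 in steps of 0.25."""
    return [Fraction(i, 4) for i in range(1, 41)]


def classify_grid(
    g,
    grid: Sequence[Fraction] | None = None,
    evaluator=None,
) -> ClassificationVerdict:
    """Grid-mode classification from exact Φ evaluations.

    Suppressor iff Δ < 0 strictly at every grid point r > 1 and Δ > 0 at
    every grid point r < 1 (exact rational comparisons); amplifier is the
    mirror image; isothermal-neutral iff Δ = 0 everywhere on the grid.
    """
    if grid is None:
        grid = default_grid()
    grid = [_frac(r) for r in grid]
    N = g.number_of_nodes()
    if evaluator is None:
        evaluator = average_fixation
    rows = []
    all_zero, sup_ok, amp_ok = True, True, True
    for rv in grid:
        if rv <= 0:
            raise ValueError("grid-mode fitness values must be positive")
        ph = _frac(evaluator(g, rv))
        p0 = phi0(rv, N)
        dl = ph - p0
        rows.append((rv, ph, p0, dl))
        if dl != 0:
            all_zero = False
        if rv > 1:
            sup_ok &= dl < 0
            amp_ok &= dl > 0
        elif rv < 1:
            sup_ok &= dl > 0
            amp_ok &= dl < 0
    ev = tuple(rows)
    if all_zero:
        return ClassificationVerdict(
            "isothermal-neutral", "grid", f"Δ = 0 at all {len(grid)} grid points", ev
        )
    if sup_ok:
        return ClassificationVerdict(
            "suppressor", "grid", "Δ < 0 at every grid r > 1 and Δ > 0 at every grid r < 1", ev
        )
    if amp_ok:
        return ClassificationVerdict(
            "amplifier", "grid", "Δ > 0 at every grid r > 1 and Δ < 0 at every grid r < 1", ev
        )
    return ClassificationVerdict("mixed", "grid", "Δ changes sign across the grid", ev)


def classify(target, mode: str = "grid", grid=None, N: int | None = None) -> ClassificationVerdict:
    """Classify a graph (grid mode) or a reconstructed Φ (symbolic mode)."""
    if mode == "symbolic":
        if not isinstance(target, RationalFunc):
            raise TypeError("symbolic mode requires a RationalFunc")
        if N is None:
            raise ValueError("symbolic mode requires the population size N")
        return classify_symbolic(target, N)
    if mode == "grid":
        return classify_grid(target, grid)
    raise ValueError(f"unknown mode {mode!r}")
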