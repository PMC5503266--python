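"""Closed forms, rational reconstruction and Sturm sign certification."""

from fractions import Fraction

import pytest
import sympy
from hypothesis import given, settings, strategies as st

from moranfix import lumped_chain as lc
from moranfix import rational_fixation as rf


class TestClosedForms:
    def test_phi0_values(self):
        assert rf.phi0(1, 10) == Fraction(1, 10)
        assert rf.phi0(2, 3) == Fraction(4, 7)
        assert rf.phi0(Fraction(1, 2), 2) == Fraction(1, 3)

    def test_phi0_tends_to_one(self):
        assert 1 - rf.phi0(10**6, 5) < Fraction(1, 10**5)

    def test_phi2_is_phi0_of_r_squared(self):
        assert rf.phi2(2, 2) == rf.phi0(4, 2) == Fraction(4, 5)
        assert rf.phi2(1, 7) == Fraction(1, 7)
        assert all(rf.phi2(r, 6) > rf.phi0(r, 6) for r in (2, 3, Fraction(7, 2)))

    @pytest.mark.parametrize("N,d", [(6, 19), (8, 34), (10, 53)])
    def test_degree_bound(self, N, d):
        assert rf.degree_bound(N) == d

    def test_evaluation_points(self):
        assert set(rf.evaluation_points(2)) == {1, 2, 3, Fraction(1, 2)}
        pts = rf.evaluation_points(19)
        assert len(pts) == 38 == len(set(pts))
        assert all(p > 0 for p in pts)


class TestReconstruction:
    def planted(self):
        # (r^2 + 1) / (r^2 + r + 1)
        return rf.RationalFunc(
            (Fraction(1), Fraction(0), Fraction(1)),
            (Fraction(1), Fraction(1), Fraction(1)),
        )

    def test_round_trip_exact_degree(self):
        f = self.planted()
        evals = [(r, f(r)) for r in rf.evaluation_points(2)]
        g = rf.reconstruct_rational(evals, 2)
        assert g.numer == f.numer and g.denom == f.denom

    def test_degree_degeneracy_retries_downward(self):
        f = self.planted()
        evals = [(r, f(r)) for r in rf.evaluation_points(4)]
        g = rf.reconstruct_rational(evals, 4)
        for r in (Fraction(11, 7), 9, Fraction(1, 13)):
            assert g(r) == f(r)

    def test_inconsistent_data_raises(self):
        f = self.planted()
        evals = [(r, f(r)) for r in rf.evaluation_points(3)]
        corrupted = [(r, v + Fraction(1, 1000) if r == 2 else v) for r, v in evals]
        with pytest.raises((ArithmeticError, ValueError)):
            rf.reconstruct_rational(corrupted, 3)

    def test_ell6_reconstruction_properties(self):
        phi = rf.reconstruct_ell(2)
        assert phi(1) == Fraction(1, 6)
        # held-out agreement with the lumped solve at a non-node rational
        assert phi(Fraction(9, 4)) == lc.reduced_fixation(2, Fraction(9, 4))
        # monotone on a sampled grid, approaching 1 from below
        samples = [phi(Fraction(k, 3)) for k in range(1, 31)]
        assert samples == sorted(samples)
        assert phi.numer[-1] == phi.denom[-1]  # leading coefficients match: Φ → 1


class TestCertifySign:
    @pytest.mark.parametrize(
        "coeffs,interval,expected",
        [
            ([-1, 1], (1, None), "always+"),          # r - 1
            ([-15, 8, -1], (1, None), "mixed"),       # -(r-3)(r-5)
            ([1, 0, 1], (1, None), "always+"),        # r^2 + 1
            ([2, -3, 1], (1, None), "mixed"),         # (r-1)(r-2), root at 2
            ([2, -3, 1], (2, None), "always+"),       # endpoint root excluded
            ([0, 1], (0, 1), "always+"),              # r on (0,1)
            ([4, -4, 1], (1, None), "mixed"),         # (r-2)^2 touches zero
            ([0, 0], (0, None), "zero"),
            ([-3], (None, None), "always-"),
        ],
    )
    def test_examples(self, coeffs, interval, expected):
        assert rf.certify_sign(coeffs, interval) == expected

    @given(st.lists(st.integers(-6, 6), min_size=1, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_agrees_with_sympy_root_isolation(self, coeffs):
        verdict = rf.certify_sign(coeffs, (1, None))
        r = sympy.Symbol("r")
        poly = sum(c * r**i for i, c in enumerate(coeffs))
        if poly == 0:
            assert verdict == "zero"
            return
        roots = [rt for rt in sympy.real_roots(sympy.Poly(poly, r)) if rt > 1]
        if roots:
            assert verdict == "mixed"
        else:
            sample = poly.subs(r, sympy.Rational(10**9))
            assert verdict == ("always+" if sample > 0 else "always-")


class TestDelta:
    def _phi0_func(self, N):
        numer = [Fraction(0)] * (N - 1) + [Fraction(-1), Fraction(1)]
        denom = [Fraction(-1)] + [Fraction(0)] * (N - 1) + [Fraction(1)]
        return rf.RationalFunc(tuple(numer), tuple(denom))

    def test_well_mixed_gives_zero_delta(self):
        delta = rf.delta_function(self._phi0_func(5), 5)
        assert all(c == 0 for c in delta.numer)

    def test_ell6_delta_signs(self):
        phi = rf.reconstruct_ell(2)
        delta = rf.delta_function(phi, 6)
        assert delta(1) == 0
        assert delta(2) < 0
        assert delta(Fraction(1, 2)) > 0


class TestClassification:
    def test_symbolic_suppressor(self):
        verdict = rf.classify_symbolic(rf.reconstruct_ell(2), 6)
        assert verdict.label == "suppressor"
        assert "Δ''" in verdict.certificate

    def test_symbolic_neutral_for_well_mixed(self):
        phi = TestDelta()._phi0_func(6)
        assert rf.classify_symbolic(phi, 6).label == "isothermal-neutral"

    def test_grid_star_is_amplifier(self, star3):
        grid = [Fraction(i, 4) for i in range(1, 25)]
        assert rf.classify_grid(star3, grid).label == "amplifier"

    def test_grid_isothermal_neutral(self):
        from moranfix.graph_models import make_complete_bipartite

        grid = [Fraction(1, 2), Fraction(2), Fraction(4)]
        v = rf.classify_grid(make_complete_bipartite(2, 2), grid)
        assert v.label == "isothermal-neutral"

    def test_grid_ell6_is_suppressor(self, ell6):
        v = rf.classify_grid(ell6, rf.default_grid())
        assert v.label == "suppressor"
        assert len(v.evidence) == 40

    def test_classify_dispatch_errors(self):
        with pytest.raises(TypeError):
            rf.classify("not a function", mode="symbolic", N=6)
        with pytest.raises(ValueError):
            rf.classify(None, mode="nonsense")
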