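"""Closed-form hybrid-model arithmetic: solving, reproduction, ranges."""

import math

import pytest
from hypothesis import given, strategies as st
from scipy.optimize import bisect

from epiherit import (DisorderSummary, InfeasibleModelError,
                      InsufficientDataError, TransmissionModel,
                      explained_range, measured_genetics, reproduce_hybrid,
                      residual_share, round_half_away, solve_hybrid,
                      total_environment)


class TestTotalEnvironment:
    def test_component_sum(self):
        d = DisorderSummary("d", 0.5, E_P=0.2, E_F=0.0, E_S=0.05, E_U=0.1)
        assert total_environment(d) == pytest.approx(0.35)

    def test_passthrough(self):
        d = DisorderSummary("d", 0.5, E_total=0.4)
        assert total_environment(d) == pytest.approx(0.4)

    def test_familial_component_defaults_to_zero(self):
        d = DisorderSummary("d", 0.5, E_P=0.2, E_S=0.05, E_U=0.1)
        assert total_environment(d) == pytest.approx(0.35)

    def test_couple_share_of_total(self):
        # a couple component of 0.27 that is 63% of E implies E ~ 0.4286
        E = 0.27 / 0.63
        d = DisorderSummary("d", 0.5, E_P=0.27, E_S=0.0, E_U=E - 0.27)
        tot = total_environment(d)
        assert tot == pytest.approx(E)
        assert d.E_P / tot == pytest.approx(0.63)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError, match="insufficient environmental"):
            total_environment(DisorderSummary("d", 0.5, E_S=0.1))


class TestSolveHybrid:
    def test_worked_example(self):
        dec = solve_hybrid(0.6, E=0.4, E_P=0.3, x=0.5)
        assert dec.G_A == pytest.approx(0.225, abs=1e-12)
        assert dec.G == pytest.approx(0.375, abs=1e-12)
        assert dec.mode == "solved"
        # back-substitution into the defining ratio
        assert (dec.G_A + 0.5 * 0.3) / (dec.G_A + 0.4) == pytest.approx(0.6, abs=1e-12)

    def test_no_couple_environment_identity(self):
        # with E_P = 0 and E = 1 - H2 the model collapses to G = H2
        dec = solve_hybrid(0.924, E=1 - 0.924, E_P=0.0, x=0.5)
        assert dec.G_A == pytest.approx(0.924, abs=1e-12)
        assert dec.G == pytest.approx(0.924, abs=1e-12)

    def test_feasibility_boundary(self):
        # x*E_P == H2*E exactly -> all heritability is transmitted environment
        H2, E_P, x = 0.3, 0.24, 0.5
        E = x * E_P / H2
        dec = solve_hybrid(H2, E=E, E_P=E_P, x=x)
        assert dec.G_A == pytest.approx(0.0, abs=1e-12)
        assert dec.G == pytest.approx(x * E_P, abs=1e-12)

    def test_infeasible_raises(self):
        with pytest.raises(InfeasibleModelError, match="exceeds heritability budget"):
            solve_hybrid(0.1, E=0.3, E_P=0.3, x=0.9)

    def test_heritability_at_one_rejected(self):
        with pytest.raises(ValueError, match="below 1"):
            solve_hybrid(1.0, E=0.3, E_P=0.1, x=0.5)

    def test_accepts_transmission_model_object(self):
        a = solve_hybrid(0.6, 0.4, 0.3, TransmissionModel(0.5))
        b = solve_hybrid(0.6, 0.4, 0.3, 0.5)
        assert a == b

    @given(st.floats(0.05, 0.9), st.floats(0.0, 0.5), st.floats(0.0, 1.0),
           st.floats(0.01, 0.99))
    def test_backsubstitution_and_bisection(self, H2, E_P, extra, x):
        E = E_P + extra
        if H2 * E < x * E_P or E == 0.0:
            return
        dec = solve_hybrid(H2, E, E_P, x)
        assert abs((dec.G_A + x * E_P) / (dec.G_A + E) - H2) < 1e-10
        f = lambda ga: (ga + x * E_P) / (ga + E) - H2
        if f(0.0) < 0 < f(10.0):
            assert abs(bisect(f, 0.0, 10.0, xtol=1e-12) - dec.G_A) < 1e-8

    @given(st.floats(0.05, 0.9), st.floats(0.01, 0.5), st.floats(0.0, 0.5),
           st.floats(0.05, 0.9), st.floats(0.01, 0.04))
    def test_additive_variance_decreases_in_x(self, H2, E_P, extra, x, dx):
        """dG_A/dx = -E_P/(1-H2) < 0 exactly, for any feasible pair of x values."""
        E = E_P + extra
        x2 = x + dx
        if H2 * E < x2 * E_P:
            return
        g1 = solve_hybrid(H2, E, E_P, x).G_A
        g2 = solve_hybrid(H2, E, E_P, x2).G_A
        assert (g2 - g1) / dx == pytest.approx(-E_P / (1 - H2), rel=1e-6, abs=1e-9)

    def test_vanishing_transmission_limit(self):
        # x -> 0 approaches the pure-genetic solution G_A = H2*E/(1-H2)
        H2, E, E_P = 0.6, 0.4, 0.3
        dec = solve_hybrid(H2, E, E_P, x=1e-12)
        assert dec.G_A == pytest.approx(H2 * E / (1 - H2), rel=1e-9)
        assert dec.G == pytest.approx(dec.G_A, rel=1e-9)

    @given(st.floats(0.05, 0.9), st.floats(0.0, 0.5), st.floats(0.0, 0.5),
           st.floats(0.01, 0.99))
    def test_percentage_conservation(self, H2, E_P, extra, x):
        E = E_P + extra
        if H2 * E < x * E_P:
            return
        dec = solve_hybrid(H2, E, E_P, x)
        assert dec.pct_G_of_H2 + dec.pct_residual_of_H2 == pytest.approx(100.0, abs=1e-9)


class TestReproduceHybrid:
    @pytest.mark.parametrize("H2, G_A, E_P, G, residual, pct", [
        (0.763, 0.468, 0.2, 0.568, 0.195, 74.4),
        (0.676, 0.333, 0.27, 0.468, 0.208, 69.2),
        (0.924, 0.924, 0.0, 0.924, 0.0, 100.0),
    ])
    def test_published_decompositions(self, H2, G_A, E_P, G, residual, pct):
        dec = reproduce_hybrid(H2, G_A, E_P, x=0.5)
        assert dec.G == pytest.approx(G, abs=1e-12)
        assert dec.residual == pytest.approx(residual, abs=1e-12)
        assert round_half_away(dec.pct_G_of_H2, 1) == pytest.approx(pct)
        assert dec.mode == "reproduced"

    def test_negative_residual_flagged_not_raised(self):
        dec = reproduce_hybrid(0.5, 0.45, 0.2, x=0.5)
        assert dec.residual < 0
        assert "negative_residual" in dec.flags


class TestMeasuredGenetics:
    @pytest.mark.parametrize("snp, cnv, expected", [
        (0.28, 0.02, 0.30), (0.17, 0.2, 0.37), (0.21, None, 0.21)])
    def test_sum(self, snp, cnv, expected):
        assert measured_genetics(snp, cnv) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            measured_genetics(-0.1)


class TestResidualShare:
    @pytest.mark.parametrize("H2, G, residual, pct", [
        (0.763, 0.30, 0.463, 60.7),
        (0.924, 0.924, 0.0, 0.0),
        (0.562, 0.435, 0.127, 22.6),
    ])
    def test_examples(self, H2, G, residual, pct):
        res, p = residual_share(H2, G)
        assert res == pytest.approx(residual, abs=1e-12)
        assert round_half_away(p, 1) == pytest.approx(pct)

    def test_zero_heritability_undefined(self):
        with pytest.raises(ValueError, match="undefined share"):
            residual_share(0.0, 0.1)


class TestExplainedRange:
    def test_measured_range_across_five(self, five_disorders):
        items = [(d.name, d.H2, measured_genetics(d.G_SNP, d.G_CNV))
                 for d in five_disorders]
        rng = explained_range(items)
        assert (rng.pct_min_int, rng.pct_max_int) == (36, 48)

    def test_hybrid_residual_range_excluding_outlier(self, five_disorders):
        items = [(d.name, d.H2, reproduce_hybrid(d.H2, d.G_A_reported, d.E_P, 0.5).G)
                 for d in five_disorders]
        rng = explained_range(items, exclude=["ASD"])
        assert rng.residual_min == pytest.approx(0.127, abs=5e-4)
        assert rng.residual_max == pytest.approx(0.208, abs=5e-4)

    def test_single_disorder_degenerate(self):
        rng = explained_range([("a", 0.5, 0.25)])
        assert rng.pct_min == rng.pct_max == pytest.approx(50.0)

    def test_empty_after_exclusion(self):
        with pytest.raises(ValueError, match="no disorders left"):
            explained_range([("a", 0.5, 0.25)], exclude=["a"])


class TestValidationAndRounding:
    def test_inconsistent_total_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            DisorderSummary("d", 0.5, E_P=0.2, E_F=0.0, E_S=0.1, E_U=0.1,
                            E_total=0.5)

    def test_transmission_fraction_bounds(self):
        with pytest.raises(ValueError):
            TransmissionModel(1.0)
        with pytest.raises(ValueError):
            TransmissionModel(0.0)

    @pytest.mark.parametrize("value, nd, expected", [
        (2.5, 0, 3.0), (-2.5, 0, -3.0), (0.375, 2, 0.38),
        (36.269, 0, 36.0), (48.0427, 0, 48.0), (60.68, 1, 60.7)])
    def test_ties_round_half_away_from_zero(self, value, nd, expected):
        assert round_half_away(value, nd) == pytest.approx(expected)
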