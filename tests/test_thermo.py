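"""Single-site ITC model: equilibrium solver, forward heats, fitting and
thermodynamic bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cwbind import thermo
from conftest import PRINTED_SYSTEMS, mx_bisection, noise_free_isotherm

# frozen regression fixture: 22 injection heats (uJ) for the canonical
# design with Kd = 1.3 uM, dH = -89 kJ/mol, n = 1, computed once with the
# bisection oracle per injection
Q22_WT_ME1 = (
    -139.82863768786808, -139.09073670859954, -138.01555507190503,
    -136.3617194804072, -133.65321600495017, -128.89170061452955,
    -119.94235404287079, -102.93418751412231, -75.50940720346634,
    -46.00891115792659, -25.820444093137777, -14.999188383248553,
    -9.36278499920113, -6.248908740775308, -4.399045665066055,
    -3.226152806580979, -2.440837031579232, -1.890731140490015,
    -1.4905549228036108, -1.1899627363324843, -0.957842684457237,
    -0.7742016778678504,
)


class TestBoundConcentration:
    def test_no_partner_gives_zero(self):
        assert thermo.solve_bound_concentration(0.0, 1e-4, 1e-6) == 0.0
        assert thermo.solve_bound_concentration(1e-4, 0.0, 1e-6) == 0.0

    def test_no_binding_limit(self):
        # Kd far above any concentration: essentially nothing bound
        mx = thermo.solve_bound_concentration(1e-4, 1e-4, 1e6)
        assert mx == pytest.approx(1e-14, abs=1e-13)

    def test_matches_bisection_oracle_at_reference_point(self):
        mx = thermo.solve_bound_concentration(8e-5, 8e-5, 1.3e-6)
        assert mx == pytest.approx(mx_bisection(8e-5, 8e-5, 1.3e-6), rel=1e-10)

    @given(
        logKd=st.floats(-9, -3),
        logM=st.floats(-6, -3),
        logX=st.floats(-6, -3),
        n=st.floats(0.5, 2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_bisection_across_grid(self, logKd, logM, logX, n):
        Kd, Mt, Xt = 10.0**logKd, 10.0**logM, 10.0**logX
        mx = thermo.solve_bound_concentration(Mt, Xt, Kd, n)
        ref = mx_bisection(Mt, Xt, Kd, n)
        # abs floor = the oracle's own xtol; rel 1e-10 elsewhere
        assert mx == pytest.approx(ref, rel=1e-10, abs=2e-18)
        assert 0.0 <= mx <= min(n * Mt, Xt)

    def test_rejects_nonpositive_kd(self):
        with pytest.raises(ValueError):
            thermo.solve_bound_concentration(1e-4, 1e-4, 0.0)


class TestPredictHeats:
    def test_zero_enthalpy_means_zero_heat(self, design):
        p = thermo.ThermodynamicParameters(Kd=1e-6, dH=0.0, n=1.0)
        assert np.allclose(thermo.predict_injection_heats(p, design), 0.0)

    def test_stoichiometric_limit(self, design):
        # very tight binding: every early injection binds completely, so the
        # heat per mole of injectant equals dH
        p = thermo.ThermodynamicParameters(Kd=1e-12, dH=-89.0, n=1.0)
        q = thermo.predict_injection_heats(p, design)
        moles = np.asarray(design.inj_volumes) * design.X0
        per_mole = q[:3] * 1e-9 / moles[:3]  # kJ/mol
        assert per_mole == pytest.approx(-89.0, rel=0.02)

    def test_frozen_oracle_vector(self, design, wt_me1_truth):
        q = thermo.predict_injection_heats(wt_me1_truth, design)
        assert np.allclose(q, Q22_WT_ME1, rtol=1e-9)

    def test_temperature_mismatch_rejected(self, design):
        p = thermo.ThermodynamicParameters(Kd=1e-6, dH=-50.0, T=310.0)
        with pytest.raises(ValueError, match="temperature"):
            thermo.predict_injection_heats(p, design)

    def test_heat_conservation(self, design, wt_me1_truth):
        # without the displacement term, injection heats telescope to Q_N;
        # with it the discrepancy is bounded by (sum v / V0) * max|Q|
        q = thermo.predict_injection_heats(wt_me1_truth, design)
        Mt, Xt = design.totals()
        mx = np.array([
            thermo.solve_bound_concentration(m, x, wt_me1_truth.Kd) for m, x in zip(Mt, Xt)
        ])
        Q = wt_me1_truth.dH * design.V0 * mx * 1e9
        bound = (sum(design.inj_volumes) / design.V0) * np.max(np.abs(Q))
        assert abs(q.sum() - Q[-1]) <= bound

    @pytest.mark.parametrize("Kd", [2e-6, 1e-7])  # c = 50 and 1000
    def test_saturation_approaches_n_dH(self, Kd):
        # cumulative binding heat per mole of macromolecule -> n*dH once the
        # molar ratio is well past equivalence
        design = thermo.standard_design(M0=1e-4, X0=2e-3, n_inj=30)
        p = thermo.ThermodynamicParameters(Kd=Kd, dH=-80.0, n=1.0)
        ratio = design.molar_ratio
        i = int(np.searchsorted(ratio, 5.0))
        Mt, Xt = design.totals()
        mx = thermo.solve_bound_concentration(Mt[i], Xt[i], Kd, p.n)
        Q_per_mole = p.dH * mx / Mt[i]  # kJ per mole of M in the cell
        assert Q_per_mole == pytest.approx(p.n * p.dH, rel=0.02)


class TestBlankSubtraction:
    def test_zero_blank_is_identity(self, design, wt_me1_truth):
        iso = noise_free_isotherm(1.3e-6, -89.0, 1.0, design)
        blank = thermo.Isotherm(design=design, heats=(0.0,) * design.n_injections)
        assert thermo.subtract_blank(iso, blank).heats == iso.heats

    def test_constant_blank_shifts_linearly(self, design):
        iso = noise_free_isotherm(1.3e-6, -89.0, 1.0, design)
        out = thermo.subtract_blank(iso, -3.5)
        assert np.allclose(np.asarray(out.heats), np.asarray(iso.heats) + 3.5)

    def test_sample_equals_blank_gives_zero(self, design):
        iso = noise_free_isotherm(1.3e-6, -89.0, 1.0, design)
        assert np.allclose(thermo.subtract_blank(iso, iso).heats, 0.0)

    def test_mismatched_counts_rejected(self, design):
        iso = noise_free_isotherm(1.3e-6, -89.0, 1.0, design)
        short = thermo.standard_design(n_inj=10)
        blank = noise_free_isotherm(1.3e-6, -89.0, 1.0, short)
        with pytest.raises(ValueError, match="injection counts"):
            thermo.subtract_blank(iso, blank)


class TestIndependentFit:
    @pytest.mark.parametrize("system", sorted(PRINTED_SYSTEMS))
    def test_noise_free_round_trip(self, system):
        Kd, dH, n, _ = PRINTED_SYSTEMS[system]
        iso = noise_free_isotherm(Kd, dH, n)
        fit = thermo.fit_independent_model(iso, free_n=True)
        assert fit.converged
        assert fit.params.Kd == pytest.approx(Kd, rel=5e-3)
        assert fit.params.dH == pytest.approx(dH, rel=5e-3)
        assert fit.params.n == pytest.approx(n, rel=5e-3)

    def test_fixed_n_round_trip(self):
        iso = noise_free_isotherm(1.3e-6, -89.0, 1.0)
        fit = thermo.fit_independent_model(iso, free_n=False)
        assert fit.params.n == pytest.approx(1.0, abs=1e-9)
        assert fit.params.Kd == pytest.approx(1.3e-6, rel=1e-3)

    @given(
        logKd=st.floats(math.log10(1e-7), math.log10(1.2e-5)),
        dH=st.floats(-120.0, -30.0),
        n=st.floats(0.85, 1.2),
    )
    @settings(max_examples=15, deadline=None)
    def test_round_trip_within_c_window(self, logKd, dH, n):
        # c = n*M0/Kd between ~5 and 1000: parameters identifiable to 0.5%
        Kd = 10.0**logKd
        iso = noise_free_isotherm(Kd, dH, n)
        fit = thermo.fit_independent_model(iso, free_n=True)
        assert fit.params.Kd == pytest.approx(Kd, rel=5e-3)
        assert fit.params.dH == pytest.approx(dH, rel=5e-3)
        assert fit.params.n == pytest.approx(n, rel=5e-3)

    def test_all_zero_heats_flagged(self, design):
        iso = thermo.Isotherm(design=design, heats=(0.0,) * design.n_injections)
        fit = thermo.fit_independent_model(iso)
        assert not fit.converged or abs(fit.params.dH) < 1e-6

    def test_weak_binding_flagged(self):
        # Kd far above cell concentration: c < 1, unreliable by construction
        iso = noise_free_isotherm(5e-3, -50.0, 1.0)
        fit = thermo.fit_independent_model(iso)
        assert fit.weak_binding
        assert "weak-binding" in fit.message


class TestStateFunctions:
    def test_unit_kd_gives_zero_dG(self):
        dG, TdS, dS = thermo.derive_state_functions(1.0, -50.0, 298.15)
        assert dG == 0.0
        assert TdS == -50.0

    @pytest.mark.parametrize(
        "Kd,dH,expected_dS",
        [(12.2e-6, -77.0, -164.0), (1.4e-6, -79.0, -153.0)],
    )
    def test_reported_entropies_reproduced(self, Kd, dH, expected_dS):
        _, _, dS = thermo.derive_state_functions(Kd, dH, 298.15)
        assert dS == pytest.approx(expected_dS, abs=1.0)

    def test_parameter_invariants_hold_exactly(self):
        p = thermo.ThermodynamicParameters(Kd=4.6e-6, dH=-84.0, n=1.0)
        assert p.dG == pytest.approx(8.314 * 298.15 * math.log(4.6e-6) / 1000, abs=1e-12)
        assert p.TdS == pytest.approx(p.dH - p.dG, abs=1e-9)
        assert p.dS == pytest.approx(1000 * p.TdS / p.T, abs=1e-9)
        assert p.dG < 0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            thermo.derive_state_functions(-1e-6, -50.0)
        with pytest.raises(ValueError):
            thermo.derive_state_functions(1e-6, -50.0, T=0.0)


class TestTTest:
    def test_identical_groups(self):
        t, p = thermo.compare_groups_ttest([1.3, 1.3, 1.3], [1.3, 1.3, 1.3])
        assert p == 1.0

    def test_zero_variance_unequal_means(self):
        _, p = thermo.compare_groups_ttest([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0

    def test_wt_me1_vs_me2_summary_stats(self):
        # replicates synthesized to match mean/SD exactly (m-s, m, m+s)
        a = [1.3 - 0.32, 1.3, 1.3 + 0.32]
        b = [4.6 - 0.28, 4.6, 4.6 + 0.28]
        t, p = thermo.compare_groups_ttest(a, b)
        # hand computation: t = dmean / (s_p sqrt(2/3)), s_p^2 = (0.32^2+0.28^2)/2
        sp = math.sqrt((0.32**2 + 0.28**2) / 2)
        assert t == pytest.approx((1.3 - 4.6) / (sp * math.sqrt(2 / 3)), rel=1e-12)
        assert abs(t) == pytest.approx(13.44, abs=0.01)
        assert p < 0.01

    def test_matches_scipy_on_regular_data(self):
        a, b = [1.1, 1.5, 0.9, 1.3], [2.0, 2.4, 1.9]
        t, p = thermo.compare_groups_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_requires_replicates(self):
        with pytest.raises(ValueError):
            thermo.compare_groups_ttest([1.0], [2.0, 3.0])
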