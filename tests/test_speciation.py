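import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from equichel import (ChemicalSystem, ConvergenceError, Species,
                      alpha_coefficient, solve_free_concentrations,
                      species_distribution)

from .oracle import as_tuples, oracle_speciate


def residual_ok(state, tol=1e-10):
    return all(abs(r) <= tol for r in state.residuals.values())


class TestSolveBasics:
    def test_no_reactions_free_equals_totals(self):
        empty = ChemicalSystem(species=())
        st_ = solve_free_concentrations(empty, {"M": 1e-9, "L": 1e-4}, 7.0)
        assert st_.free["M"] == pytest.approx(1e-9, rel=1e-12)
        assert st_.free["L"] == pytest.approx(1e-4, rel=1e-12)

    def test_half_equivalence_monoprotic(self, monoprotic_ligand):
        st_ = solve_free_concentrations(monoprotic_ligand, {"L": 1e-4}, 4.58)
        assert st_.free["L"] == pytest.approx(5.0e-5, rel=1e-9)
        assert st_.species_conc["LH"] == pytest.approx(5.0e-5, rel=1e-9)

    def test_negative_totals_rejected(self, fe_6a):
        with pytest.raises(ValueError):
            solve_free_concentrations(fe_6a, {"Fe": -1e-9, "L": 1e-4}, 7.4)

    def test_nonfinite_ph_rejected(self, fe_6a):
        with pytest.raises(ValueError):
            solve_free_concentrations(fe_6a, {"Fe": 1e-9, "L": 1e-4},
                                      float("nan"))

    def test_concentrations_floored_positive(self, fe_6a):
        st_ = solve_free_concentrations(fe_6a, {"Fe": 1e-9, "L": 1e-4}, 7.4)
        assert all(v > 0 for v in st_.free.values())
        assert all(v > 0 for v in st_.species_conc.values())


class TestOracleAgreement:
    """The Newton solver against the independent nested-bracketing oracle."""

    @pytest.mark.parametrize("pH", [2.0, 4.0, 7.4, 10.0])
    def test_full_6a_model(self, fe_6a, pH):
        st_ = solve_free_concentrations(fe_6a, {"Fe": 1e-9, "L": 1e-4}, pH)
        oM, oL, oc = oracle_speciate(as_tuples(fe_6a), 1e-9, 1e-4, pH)
        assert st_.free["Fe"] == pytest.approx(oM, rel=1e-6)
        assert st_.free["L"] == pytest.approx(oL, rel=1e-6)
        for name, conc in oc.items():
            if conc > 1e-25:
                assert st_.species_conc[name] == pytest.approx(conc, rel=1e-6)

    def test_dominant_iron_species_matches_oracle(self, fe_6a):
        st_ = solve_free_concentrations(fe_6a, {"Fe": 1e-9, "L": 1e-4}, 7.4)
        _, _, oc = oracle_speciate(as_tuples(fe_6a), 1e-9, 1e-4, 7.4)
        fe_species = [sp.name for sp in fe_6a.species if sp.n_metal > 0]
        ours = max(fe_species, key=lambda n: st_.species_conc[n])
        oracles = max(fe_species, key=lambda n: oc[n])
        assert ours == oracles

    def test_titration_ratio_conditions(self, fe_11a):
        # 0.3 equiv metal, the complexation-titration stoichiometry
        st_ = solve_free_concentrations(
            fe_11a, {"Fe": 7.5e-5, "L": 2.5e-4}, 3.0)
        oM, oL, _ = oracle_speciate(as_tuples(fe_11a), 7.5e-5, 2.5e-4, 3.0)
        assert st_.free["Fe"] == pytest.approx(oM, rel=1e-6)
        assert st_.free["L"] == pytest.approx(oL, rel=1e-6)


class TestSolverInvariants:
    @given(
        log_tM=st.floats(-9, -3),
        log_tL=st.floats(-6, -2),
        pH=st.floats(1.0, 11.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_mass_balance_property(self, fe_6a, log_tM, log_tL, pH):
        st_ = solve_free_concentrations(
            fe_6a, {"Fe": 10 ** log_tM, "L": 10 ** log_tL}, pH)
        assert residual_ok(st_)

    def test_start_point_independence(self, fe_6a):
        rng = np.random.default_rng(42)
        ref = solve_free_concentrations(fe_6a, {"Fe": 1e-9, "L": 1e-4}, 7.4)
        for _ in range(10):
            init = {"Fe": 10.0 ** rng.uniform(-25, -3),
                    "L": 10.0 ** rng.uniform(-12, -2)}
            st_ = solve_free_concentrations(
                fe_6a, {"Fe": 1e-9, "L": 1e-4}, 7.4, initial_free=init)
            assert st_.free["Fe"] == pytest.approx(ref.free["Fe"], rel=1e-8)
            assert st_.free["L"] == pytest.approx(ref.free["L"], rel=1e-8)

    def test_closed_form_diprotic(self):
        sys_ = ChemicalSystem(species=(Species("LH", 0, 1, 1, 6.0),
                                       Species("LH2", 0, 1, 2, 10.0)))
        tL, pH = 1e-3, 5.0
        st_ = solve_free_concentrations(sys_, {"L": tL}, pH)
        denom = 1 + 10 ** (6.0 - pH) + 10 ** (10.0 - 2 * pH)
        assert st_.free["L"] == pytest.approx(tL / denom, rel=1e-9)

    def test_closed_form_1to1_complex(self, ml_only):
        tM = tL = 1e-6
        pH = 7.0
        st_ = solve_free_concentrations(ml_only, {"M": tM, "L": tL}, pH)
        # symmetric quadratic: b*x^2 + x - tM = 0 with x = [M] = [L]
        b = 10.0 ** 20
        x = (-1 + math.sqrt(1 + 4 * b * tM)) / (2 * b)
        assert st_.free["M"] == pytest.approx(x, rel=1e-9)
        assert st_.species_conc["ML"] == pytest.approx(tM - x, rel=1e-9)


class TestAlphaCoefficient:
    def test_no_side_species_gives_unity(self, ml_only):
        assert alpha_coefficient(ml_only, "M", 7.0) == 1.0

    def test_iron_hydrolysis_alpha_at_physiological_ph(self, fe_6a):
        expected = 1 + 10 ** (-2.56 + 7.4) + 10 ** (-6.20 + 14.8) \
            + 10 ** (-11.41 + 22.2) + 10 ** (-21.88 + 29.6)
        a = alpha_coefficient(fe_6a, "Fe", 7.4)
        assert a == pytest.approx(expected, rel=1e-12)
        assert math.log10(a) == pytest.approx(10.79, abs=0.01)

    def test_ligand_protonation_alpha(self, fe_6a):
        expected = 1 + 10 ** (4.58 - 7.4) + 10 ** (4.62 - 14.8)
        assert alpha_coefficient(fe_6a, "L", 7.4) == pytest.approx(
            expected, rel=1e-12)
        assert alpha_coefficient(fe_6a, "L", 7.4) == pytest.approx(1.0015, abs=1e-4)

    def test_unknown_component_rejected(self, fe_6a):
        with pytest.raises(KeyError):
            alpha_coefficient(fe_6a, "Cu", 7.4)

    def test_solver_matches_alpha_closed_form_mononuclear(self):
        # mononuclear-only system: fraction complexed from the full solver
        # must equal the side-reaction-coefficient closed form
        sys_ = ChemicalSystem(species=(
            Species("LH", 0, 1, 1, 4.58),
            Species("ML", 1, 1, 0, 12.0),
            Species("M(OH)", 1, 0, -1, -2.56),
        ))
        c_M, pH = 1e-9, 6.0
        for c_L in (1e-6, 1e-4, 1e-2):
            st_ = solve_free_concentrations(sys_, {"M": c_M, "L": c_L}, pH)
            chi_solver = st_.species_conc["ML"] / c_M
            aM = alpha_coefficient(sys_, "M", pH)
            aL = alpha_coefficient(sys_, "L", pH)
            # conditional constant; uncomplexed ligand pool corrected for
            # the (small) metal-bound fraction
            beta_cond = 10.0 ** 12.0 / (aM * aL)
            l_eff = c_L - chi_solver * c_M
            chi_alpha = beta_cond * l_eff / (1 + beta_cond * l_eff)
            assert abs(chi_solver - chi_alpha) <= 1e-6


class TestDistribution:
    def test_fractions_sum_to_one(self, fe_6a):
        df = species_distribution(fe_6a, {"Fe": 1e-9, "L": 1.54e-4},
                                  np.arange(2.0, 12.0, 0.25))
        sums = df.drop(columns="pH").sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_monoprotic_crossing_and_plateau(self, monoprotic_ligand):
        grid = np.arange(3.0, 9.0 + 1e-9, 0.02)
        df = species_distribution(monoprotic_ligand, {"L": 1e-4}, grid)
        # LH and L cross at the pKa
        i = int(np.argmin(np.abs(grid - 4.58)))
        assert df["L"].iloc[i] == pytest.approx(0.5, abs=0.01)
        assert df["LH"].iloc[i] == pytest.approx(0.5, abs=0.01)
        # deprotonated at physiological pH
        j = int(np.argmin(np.abs(grid - 7.4)))
        assert df["L"].iloc[j] == pytest.approx(
            1 / (1 + 10 ** (4.58 - 7.4)), abs=1e-4)

    def test_phenolic_ligand_stays_protonated_at_ph74(self, fe_6d):
        df = species_distribution(fe_6d, {"Fe": 0.0, "L": 1e-4},
                                  [7.3, 7.4, 7.5])
        row = df.iloc[1].drop("pH")
        assert row.idxmax() == "LH"

    def test_continuity_on_fine_grid(self, fe_6a):
        grid = np.arange(2.0, 12.0 + 1e-9, 0.05)
        df = species_distribution(fe_6a, {"Fe": 1e-9, "L": 1.54e-4}, grid,
                                  reference="Fe")
        jumps = df.drop(columns="pH").diff().abs().max().max()
        assert jumps <= 0.2

    def test_decreasing_grid_rejected(self, fe_6a):
        with pytest.raises(ValueError):
            species_distribution(fe_6a, {"Fe": 0, "L": 1e-4}, [3.0, 2.0])

    def test_zero_reference_total_rejected(self, fe_6a):
        with pytest.raises(ValueError):
            species_distribution(fe_6a, {"Fe": 0.0, "L": 0.0}, [7.4])
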