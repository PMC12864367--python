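"""Fast-variable closures and slow dynamics of the reduced model."""

import numpy as np
import pytest

from pembrosim.fullmodel import FULL_INDEX, FULL_VARS, rhs_full
from pembrosim.reduced import (
    FAST_VARS,
    REDUCED_INDEX,
    REDUCED_VARS,
    embed_reduced,
    fast_observables,
    reduced_initials,
    rhs_reduced,
)
from pembrosim.simulate import compare_trajectories, integrate


def reduced_vec(init, p):
    return reduced_initials(init, p)


class TestFastObservables:
    def test_linear_closures_vanish_with_drivers(self, toy_params, toy_init):
        y = reduced_vec(toy_init.replace(T_8=0.0, A_1=0.0), toy_params)
        f = fast_observables(y, toy_params)
        assert f.I_2 == 0.0
        assert f.QA_T8 == 0.0 and f.QA_K == 0.0 and f.QA_8LN == 0.0

    def test_macrophage_closure_without_cytokine_drive(self, toy_params, toy_init):
        quiet = toy_init.replace(C=0.0, M_2=0.0, T_8=0.0, K=0.0, D=0.0)
        y = reduced_vec(quiet, toy_params)
        f = fast_observables(y, toy_params)
        assert f.M_0 == pytest.approx(toy_params.A_M0 / toy_params.d_M0)

    def test_non_negative_on_random_slow_states(self, toy_params, rng):
        for _ in range(200):
            y = rng.uniform(0.0, 10.0, len(REDUCED_VARS))
            f = fast_observables(y, toy_params)
            for name in FAST_VARS:
                assert getattr(f, name) >= 0.0


class TestFastEquilibriumConsistency:
    def _gross_fast_flux(self, full, p):
        """Scale for each fast balance: the magnitude of its production."""
        f = {}
        ix = FULL_INDEX
        f["I_2"] = p.lambda_I2T8 * full[ix["T_8"]]
        f["I_gamma"] = p.lambda_IgK * full[ix["K"]]
        f["I_alpha"] = p.lambda_IaT8 * full[ix["T_8"]] + p.lambda_IaK * full[ix["K"]]
        f["I_beta"] = p.lambda_IbC * full[ix["C"]] + p.lambda_IbM2 * full[ix["M_2"]]
        f["I_10"] = p.lambda_I10C * full[ix["C"]]
        f["I_12"] = p.lambda_I12D * full[ix["D"]]
        f["M_0"] = p.A_M0
        f["TA_8"] = (p.lambda_TA8T8 + p.d_T8) * full[ix["TA_8"]]
        f["TA_r"] = (p.lambda_TArTr + p.d_Tr) * full[ix["TA_r"]]
        f["QA_T8"] = (p.lambda_QA + p.d_QA) * full[ix["QA_T8"]]
        f["QA_K"] = (p.lambda_QA + p.d_QA) * full[ix["QA_K"]]
        f["QA_8LN"] = (p.lambda_QA + p.d_QA) * full[ix["QA_8LN"]]
        return f

    def test_embedded_states_annihilate_fast_balances(self, toy_params, rng):
        # substituting the closed forms into the full vector field leaves a
        # residual below 1e-10 relative to each balance's gross flux
        for _ in range(50):
            y = rng.uniform(0.1, 10.0, len(REDUCED_VARS))
            full = embed_reduced(y, toy_params)
            dy = rhs_full(0.0, full, toy_params)
            gross = self._gross_fast_flux(full, toy_params)
            for name in FAST_VARS:
                scale = max(gross[name], 1e-300)
                assert abs(dy[FULL_INDEX[name]]) / scale < 1e-10, name

    def test_slow_components_match_reduced_rhs(self, toy_params, rng):
        for _ in range(50):
            y = rng.uniform(0.1, 10.0, len(REDUCED_VARS))
            full = embed_reduced(y, toy_params)
            df = rhs_full(0.0, full, toy_params)
            dr = rhs_reduced(0.0, y, toy_params)
            for name in REDUCED_VARS:
                a, b = df[FULL_INDEX[name]], dr[REDUCED_INDEX[name]]
                assert a == pytest.approx(b, rel=1e-9, abs=1e-12), name


class TestReducedInitials:
    def test_slow_entries_copied_verbatim(self, defaults, default_init):
        y = reduced_initials(default_init, defaults)
        assert y[REDUCED_INDEX["C"]] == 1.79e7
        assert y[REDUCED_INDEX["D_LN"]] == 1.05e7
        assert y[REDUCED_INDEX["PD_8LN"]] == 1.56e9

    def test_fast_initials_come_from_closures_not_tables(
        self, defaults, default_init
    ):
        # the closed-form IL-2 value is what the reduced model reports at
        # t = 0, not the tabulated cytokine initial condition
        y = reduced_initials(default_init, defaults)
        f = fast_observables(y, defaults)
        closed = defaults.lambda_I2T8 * default_init["T_8"] / defaults.d_I2
        assert f.I_2 == pytest.approx(closed, rel=1e-12)

    def test_idempotent(self, defaults, default_init):
        y1 = reduced_initials(default_init, defaults)
        y2 = reduced_initials(default_init, defaults)
        assert np.array_equal(y1, y2)


class TestReducedDynamics:
    def test_drug_decays_linearly_without_receptor(self, toy_params, toy_init):
        y = reduced_initials(
            toy_init.replace(A_1=2.0, PD_T8=0.0, PD_K=0.0), toy_params
        )
        dy = rhs_reduced(0.0, y, toy_params)
        assert dy[REDUCED_INDEX["A_1"]] == pytest.approx(
            -toy_params.d_A1 * 2.0
        )

    def test_essential_non_negativity(self, toy_params, rng):
        for _ in range(200):
            base = rng.uniform(0.0, 5.0, len(REDUCED_VARS))
            for name in REDUCED_VARS:
                y = base.copy()
                y[REDUCED_INDEX[name]] = 0.0
                dy = rhs_reduced(0.0, y, toy_params)
                assert dy[REDUCED_INDEX[name]] >= -1e-12, name

    def test_trajectories_track_full_model_when_timescales_separate(
        self, toy_params, toy_init
    ):
        # with fast rates >= 100x slow ones, slow variables of the reduced
        # model stay within 2% sup-relative of the full model after a
        # transient of 5 / min(fast rates)
        t_final = 5.0
        transient = 5.0 / 50.0
        grid = np.linspace(0.0, t_final, 401)
        # start the full model with fast species on the slow manifold:
        # otherwise the relaxation of off-manifold fast stocks injects an
        # O(fast-initial/fast-rate) offset into the slow variables that no
        # transient window removes
        from pembrosim.params import InitialState

        y0 = reduced_initials(toy_init, toy_params)
        full0 = embed_reduced(y0, toy_params)
        init_full = InitialState.from_mapping(
            {name: full0[FULL_INDEX[name]] for name in FULL_VARS}
        )
        full = integrate("full", init_full, toy_params, None,
                         t_final=t_final, save_grid=grid, rtol=1e-8, atol=1e-12)
        red = integrate("reduced", toy_init, toy_params, None,
                        t_final=t_final, save_grid=grid, rtol=1e-8, atol=1e-12)
        scores = compare_trajectories(
            full, red, variables=REDUCED_VARS, t_min=transient
        )
        worst = max(scores, key=scores.get)
        assert scores[worst] < 0.02, (worst, scores[worst])
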