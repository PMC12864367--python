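"""Stochastic engine: primitives, single steps, and mean-field limits."""

import dataclasses
import math

import numpy as np
import pytest

from pembrosim.abm import (
    AgentEnsemble,
    abm_step,
    event_probability,
    expected_step_increment,
    integer_spawn,
    run_abm,
)
from pembrosim.params import InitialState, build_schedule
from pembrosim.reduced import REDUCED_INDEX, REDUCED_VARS, rhs_reduced
from pembrosim.scaling import ScalingSet, make_scalings

from .conftest import TOY_INIT, make_toy_params


def pure_death_params(**overrides):
    """Toy set where exhausted CD8s are a pure linear death process and, with
    C << C_0, viable cancer cells are a linear birth process."""
    zeros = dict(
        lambda_CT8=0.0, lambda_CK=0.0, lambda_CIa=0.0,
        A_D0=0.0, lambda_DNc=0.0, lambda_D0K=0.0, lambda_DDLN=0.0,
        A_T08=0.0, lambda_T08TA8=0.0, lambda_TA8T8=0.0,
        lambda_T8I2=0.0, lambda_T8C=0.0, lambda_TexA1=0.0,
        A_T0r=0.0, lambda_T0rTAr=0.0, lambda_TArTr=0.0,
        A_M0=0.0, lambda_M2Ib=0.0, lambda_M2I10=0.0,
        A_K0=0.0, lambda_KI2=0.0, lambda_KI12=0.0,
        lambda_I2T8=0.0, lambda_IgK=0.0, lambda_IaT8=0.0, lambda_IaK=0.0,
        lambda_IbC=0.0, lambda_IbM2=0.0, lambda_I10C=0.0, lambda_I12D=0.0,
        lambda_PDT8=0.0, lambda_PDK=0.0, lambda_PD8LN=0.0,
        lambda_PDA1=0.0, lambda_PLC=0.0, lambda_PLM2=0.0, lambda_PLLNDLN=0.0,
        f_pembro=0.0,
    )
    zeros.update(overrides)
    return make_toy_params(**zeros)


def toy_ensemble(counts: dict[str, int]) -> AgentEnsemble:
    c = np.zeros(len(REDUCED_VARS), dtype=np.int64)
    for name, n in counts.items():
        c[REDUCED_INDEX[name]] = n
    return AgentEnsemble(counts=c, gamma=np.ones(len(REDUCED_VARS)))


class TestPrimitives:
    def test_event_probability_values(self):
        assert event_probability(0.0, 0.1) == 0.0
        assert event_probability(math.log(2), 1.0) == pytest.approx(0.5)

    def test_event_probability_bounded_by_rate_times_step(self, rng):
        for lam in rng.uniform(0.01, 50.0, size=100):
            dt = rng.uniform(1e-3, 0.1)
            p = event_probability(lam, dt)
            assert 0.0 <= p < 1.0
            assert p <= lam * dt

    def test_event_probability_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            event_probability(-1.0, 0.1)

    def test_integer_spawn_exact_on_integers(self, rng):
        assert all(integer_spawn(3.0, rng) == 3 for _ in range(20))

    def test_integer_spawn_fractional_distribution(self, rng):
        draws = np.array([integer_spawn(2.3, rng) for _ in range(100_000)])
        assert set(np.unique(draws)) == {2, 3}
        # empirical mean within 3 binomial standard errors of 2.3
        se = math.sqrt(0.3 * 0.7 / len(draws))
        assert abs(draws.mean() - 2.3) < 3 * se

    def test_integer_spawn_rejects_negative(self, rng):
        with pytest.raises(ValueError):
            integer_spawn(-0.1, rng)


class TestSingleStep:
    def test_all_rates_zero_leaves_ensemble_unchanged(self, rng):
        p = pure_death_params(
            lambda_C=0.0, d_Nc=0.0, d_D0=0.0, d_D=0.0, d_T08=0.0,
            d_T8=0.0, d_Tex=0.0, d_T0r=0.0, d_Tr=0.0, d_M2=0.0,
            d_K0=0.0, d_K=0.0, d_PD=0.0, d_PL=0.0, d_A1=0.0,
        )
        ens = toy_ensemble({n: 50 for n in REDUCED_VARS})
        out = abm_step(ens, p, 0.01, rng)
        assert np.array_equal(out.counts, ens.counts)
        assert out.t == pytest.approx(0.01)

    def test_pure_death_survivors_match_binomial_mean(self, rng):
        # ensemble mean over replicates of a one-step pure-death update is
        # within 3 standard errors of N * exp(-d dt)
        p = pure_death_params(d_Tex=0.5)
        n0, dt, reps = 300, 0.2, 4000
        surv_p = math.exp(-0.5 * dt)
        finals = np.empty(reps)
        for r in range(reps):
            ens = toy_ensemble({"T_ex": n0})
            finals[r] = abm_step(ens, p, dt, rng).counts[REDUCED_INDEX["T_ex"]]
        se = math.sqrt(n0 * surv_p * (1 - surv_p) / reps)
        assert abs(finals.mean() - n0 * surv_p) < 3 * se

    def test_necrosis_spawns_group_ratio_agents(self, rng):
        # one cancer-agent necrosis event spawns floor(g_C/g_Nc) or that + 1
        # necrotic agents
        p = pure_death_params(lambda_C=0.0, lambda_CIa=5.0, d_Nc=0.0,
                              lambda_IaT8=1.0, d_Ia=1.0)
        ens = toy_ensemble({"C": 1, "T_8": 1})
        # give C a large group size relative to N_c: ratio 7/2 = 3.5
        ens.gamma[REDUCED_INDEX["C"]] = 7.0
        ens.gamma[REDUCED_INDEX["N_c"]] = 2.0
        spawned = []
        for _ in range(400):
            out = abm_step(ens, p, 5.0, rng)
            if out.counts[REDUCED_INDEX["C"]] == 0:
                spawned.append(int(out.counts[REDUCED_INDEX["N_c"]]))
        assert spawned, "no necrosis events sampled"
        assert set(spawned) <= {3, 4}
        frac = np.mean([s == 4 for s in spawned])
        assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / len(spawned))

    def test_counts_never_negative(self, rng):
        p = make_toy_params()
        ens = toy_ensemble({n: 20 for n in REDUCED_VARS})
        for _ in range(200):
            ens = abm_step(ens, p, 0.05, rng)
            assert np.all(ens.counts >= 0)


class TestMeanField:
    def test_one_step_expectation_matches_euler_to_second_order(
        self, defaults, default_init
    ):
        # |E[increment] - Euler increment| must shrink like dt^2
        s = make_scalings(default_init, defaults)
        ens = AgentEnsemble.from_initial(default_init, defaults, s)
        y = ens.dimensional()
        euler_rate = rhs_reduced(0.0, y, defaults) / ens.gamma

        def err(dt):
            e = expected_step_increment(ens, defaults, dt)
            return np.linalg.norm(e - dt * euler_rate, ord=1)

        e1, e2 = err(0.02), err(0.01)
        assert e1 > 0
        assert e2 <= 0.3 * e1

    def test_linear_birth_death_tracks_closed_form(self):
        # T_ex decays at rate d; C grows at rate lambda_C (C << C_0); the
        # ensemble mean must stay within 3 SE of the ODE closed forms
        p = pure_death_params(d_Tex=0.4, lambda_C=0.3, C_0=1e9)
        init = InitialState.from_mapping(
            {**TOY_INIT, "T_ex": 400.0, "C": 400.0}
        )
        scal = ScalingSet.identity()
        t_final, dt, reps = 2.0, 0.02, 300
        trajs = run_abm(init, p, None, t_final=t_final, dt=dt,
                        n_reps=reps, seed=7, save_dt=0.5, scalings=scal)
        times = trajs[0].times
        tex = np.array([tr["T_ex"] for tr in trajs])
        c = np.array([tr["C"] for tr in trajs])
        for j, t in enumerate(times):
            mean_tex = 400.0 * math.exp(-0.4 * t)
            se = max(np.std(tex[:, j], ddof=1) / math.sqrt(reps), 1e-9)
            assert abs(tex[:, j].mean() - mean_tex) < 3 * se + 1e-9
            # discrete births lag e^{bt} by O(dt); allow that bias explicitly
            mean_c = 400.0 * math.exp(0.3 * t)
            bias = mean_c * 0.5 * 0.3**2 * dt * t
            se_c = max(np.std(c[:, j], ddof=1) / math.sqrt(reps), 1e-9)
            assert abs(c[:, j].mean() - mean_c) < 3 * se_c + bias + 1e-9

    def test_step_refinement_stable_on_linear_model(self):
        # halving dt changes the ensemble mean by no more than Monte-Carlo
        # error on the pure-death toy
        p = pure_death_params(d_Tex=0.5, lambda_C=0.0)
        init = InitialState.from_mapping({**TOY_INIT, "T_ex": 500.0})
        scal = ScalingSet.identity()
        means, ses = [], []
        for dt in (0.04, 0.02):
            trajs = run_abm(init, p, None, t_final=1.0, dt=dt, n_reps=400,
                            seed=11, save_dt=1.0, scalings=scal)
            finals = np.array([tr.final("T_ex") for tr in trajs])
            means.append(finals.mean())
            ses.append(finals.std(ddof=1) / math.sqrt(len(finals)))
        assert abs(means[0] - means[1]) < 3 * math.hypot(*ses)


class TestRunAbm:
    def test_same_seed_bit_identical(self, defaults, default_init):
        a = run_abm(default_init, defaults, None, t_final=1.0, dt=0.01,
                    n_reps=2, seed=5)
        b = run_abm(default_init, defaults, None, t_final=1.0, dt=0.01,
                    n_reps=2, seed=5)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.data, tb.data)

    def test_different_seed_differs(self, defaults, default_init):
        a = run_abm(default_init, defaults, None, t_final=1.0, dt=0.01,
                    n_reps=1, seed=5)
        b = run_abm(default_init, defaults, None, t_final=1.0, dt=0.01,
                    n_reps=1, seed=6)
        assert not np.array_equal(a[0].data, b[0].data)

    def test_initial_counts_follow_recipe(self, defaults, default_init):
        s = make_scalings(default_init, defaults)
        ens = AgentEnsemble.from_initial(default_init, defaults, s)
        assert ens.counts[REDUCED_INDEX["C"]] == 5000
        assert ens.counts[REDUCED_INDEX["N_c"]] == 2000
        assert ens.counts[REDUCED_INDEX["T_8"]] == 2000
        assert ens.counts[REDUCED_INDEX["P_L"]] == 1000
        assert ens.counts[REDUCED_INDEX["D_LN"]] == 1000
        assert ens.counts[REDUCED_INDEX["T0_8"]] == 2000

    def test_dose_raises_drug_counts(self, defaults, default_init):
        sched = build_schedule(200.0, 21.0, 1)
        trajs = run_abm(default_init, defaults, sched, t_final=0.1, dt=0.01,
                        n_reps=1, seed=3, save_dt=0.05)
        a1 = trajs[0]["A_1"]
        assert a1[0] == 0.0
        # one bolus lands near the drug reference concentration scale
        assert a1[-1] == pytest.approx(200.0 * defaults.f_pembro, rel=0.05)
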