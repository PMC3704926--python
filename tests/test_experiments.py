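"""Unit tests for experiment drivers and invasion statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from fadsim import (
    DispersalParams,
    GeneticParams,
    InvasionResult,
    ModifierAllele,
    SteadyStateConfig,
    Strategy,
    classify_invasion_outcomes,
    exact_binomial_test,
    run_invasion,
    run_parameter_sweep,
    run_steady_state,
    takeover_time,
)

TINY_SS = SteadyStateConfig(min_gens=60, max_gens=200, window=50, check_every=20)


def tiny_steady_state(seed=5, n=60, strategy=Strategy.UNI, c=0.0, alpha=0.1):
    gp = GeneticParams(L=64, s=0.1, h=0.2, U=0.5, R=2.0)
    dp = DispersalParams(alpha_U=alpha, alpha_F=alpha, c=c)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_steady_state(
            n_total=n,
            capacity=10,
            gparams=gp,
            dparams=dp,
            strategy=strategy,
            rng=np.random.default_rng(seed),
            ss=TINY_SS,
        )


class TestTakeoverTime:
    def test_forced_by_definition(self):
        assert takeover_time([0.01, 0.3, 0.85]) == 2

    def test_undefined_when_high_unreached(self):
        assert takeover_time([0.01, 0.3, 0.5, 0.2]) is None

    def test_trajectory_starting_above_low(self):
        assert takeover_time([0.05, 0.4, 0.9]) == 2

    def test_counts_from_first_low_crossing(self):
        assert takeover_time([0.001, 0.005, 0.02, 0.3, 0.81]) == 2


class TestExactBinomialTest:
    def test_zero_successes_gives_one(self):
        assert exact_binomial_test(0, 50, 0.05) == 1.0

    def test_all_successes_closed_form(self):
        assert exact_binomial_test(100, 100, 0.05) == pytest.approx(
            0.05**100, rel=1e-9
        )

    def test_matches_direct_tail_summation(self):
        k, n, p0 = 20, 50, 0.05
        direct = sum(
            math.comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1)
        )
        assert exact_binomial_test(k, n, p0) == pytest.approx(direct, rel=1e-9)

    @pytest.mark.parametrize(
        "k,n,p0", [(-1, 10, 0.5), (11, 10, 0.5), (5, 0, 0.5), (5, 10, 0.0), (5, 10, 1.0)]
    )
    def test_invalid_inputs_rejected(self, k, n, p0):
        with pytest.raises((ValueError, TypeError)):
            exact_binomial_test(k, n, p0)


def _fake_results(n, fixed, timeout_at=None):
    out = []
    for i in range(n):
        if i < fixed:
            out.append(InvasionResult("fixed", 100, 500, 1.0, pd.DataFrame()))
        elif timeout_at is not None:
            out.append(
                InvasionResult("timeout", None, 30_000, timeout_at, pd.DataFrame())
            )
        else:
            out.append(InvasionResult("extinct", None, 50, 0.0, pd.DataFrame()))
    return out


class TestClassification:
    def test_only_fad(self):
        fad = _fake_results(100, fixed=80)
        uni = _fake_results(100, fixed=1)
        assert classify_invasion_outcomes(fad, uni, 0.01) == "only_FAD"

    def test_none(self):
        fad = _fake_results(100, fixed=0)
        uni = _fake_results(100, fixed=0)
        assert classify_invasion_outcomes(fad, uni, 0.01) == "none"

    def test_both(self):
        fad = _fake_results(100, fixed=60)
        uni = _fake_results(100, fixed=40)
        assert classify_invasion_outcomes(fad, uni, 0.01) == "both_succeed"

    def test_polymorphism(self):
        fad = _fake_results(100, fixed=0, timeout_at=0.5)
        uni = _fake_results(100, fixed=0)
        assert classify_invasion_outcomes(fad, uni, 0.01) == "FAD_polymorphism"

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ValueError):
            classify_invasion_outcomes(_fake_results(10, 1), _fake_results(5, 1), 0.01)


class TestSteadyState:
    def test_initial_state_and_record_count(self):
        res = tiny_steady_state()
        assert res.records[0].mean_fitness == 1.0
        assert len(res.records) == res.n_generations + 1
        assert 0.0 < res.plateau_mean_fitness <= 1.0

    def test_fixed_seed_reproducible(self):
        a = tiny_steady_state(seed=21)
        b = tiny_steady_state(seed=21)
        assert a.plateau_mean_fitness == b.plateau_mean_fitness
        assert a.plateau_het == b.plateau_het
        assert a.n_generations == b.n_generations

    def test_nonconvergence_is_reported(self):
        gp = GeneticParams(L=64, s=0.1, h=0.2, U=0.5, R=2.0)
        dp = DispersalParams()
        # max_gens too small for the fitness decline to flatten out
        ss = SteadyStateConfig(min_gens=20, max_gens=25, window=20, check_every=5)
        with pytest.warns(RuntimeWarning):
            res = run_steady_state(
                n_total=60,
                capacity=10,
                gparams=gp,
                dparams=dp,
                rng=np.random.default_rng(3),
                ss=ss,
            )
        assert not res.converged


class TestInvasion:
    def test_exact_initial_frequency_and_outcome_set(self):
        res = tiny_steady_state()
        out = run_invasion(
            res.population,
            ModifierAllele(Strategy.FAD, 0.1),
            0.05,
            np.random.default_rng(8),
            g_max=300,
        )
        assert out.trajectory["invader_freq"].iloc[0] == pytest.approx(0.05)
        assert out.outcome in ("fixed", "extinct", "timeout")
        assert 0.0 <= out.final_freq <= 1.0

    def test_absorbing_states_consistent(self):
        res = tiny_steady_state()
        for i in range(5):
            out = run_invasion(
                res.population,
                ModifierAllele(Strategy.UNI, 0.1),
                0.05,
                np.random.default_rng(50 + i),
                g_max=400,
            )
            if out.outcome == "extinct":
                assert out.final_freq == 0.0
            elif out.outcome == "fixed":
                assert out.final_freq == 1.0
            else:
                assert 0.0 < out.final_freq < 1.0

    def test_requires_homogeneous_resident(self):
        res = tiny_steady_state()
        pop = res.population.copy()
        pop.alleles = pop.alleles + (ModifierAllele(Strategy.FAD, 0.1),)
        with pytest.raises(ValueError):
            run_invasion(pop, ModifierAllele(Strategy.FAD, 0.1), 0.05, np.random.default_rng(0))

    def test_invalid_frequency_rejected(self):
        res = tiny_steady_state()
        with pytest.raises(ValueError):
            run_invasion(
                res.population, ModifierAllele(Strategy.FAD, 0.1), 0.0, np.random.default_rng(0)
            )


class TestSweep:
    def test_tiny_sweep_shape_and_determinism(self):
        kwargs = dict(
            alphas=[0.1],
            costs=[0.1],
            hs=[0.2],
            n_total=60,
            capacity=10,
            L=64,
            R=2.0,
            invader_strategies=(Strategy.FAD, Strategy.UNI),
            f0=0.05,
            g_max=150,
            replicates=2,
            base_seed=17,
            ss=TINY_SS,
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rows1, cells1 = run_parameter_sweep(**kwargs)
            rows2, cells2 = run_parameter_sweep(**kwargs)
        assert len(rows1) == 4  # 2 strategies x 2 replicates
        assert len(cells1) == 1
        assert rows1.equals(rows2)
        assert cells1.equals(cells2)
        for col in (
            "run_id", "seed", "alpha_res", "alpha_inv", "c", "h", "s",
            "strategy_res", "strategy_inv", "f0", "outcome", "takeover_gens",
            "final_freq", "mean_fitness_end", "het_fraction_end",
        ):
            assert col in rows1.columns
        assert cells1["classification"].iloc[0] in (
            "both_succeed", "only_FAD", "FAD_polymorphism", "none",
        )
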