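import math

import numpy as np
import pytest
from scipy import optimize, stats

from genetoxbmd import (
    ContractError,
    dose_vs_control_contrast,
    generate_preset,
    overall_trend_test,
    significance_tier,
)


def brute_force_lr(doses, counts, denoms, constrain_dose=None):
    """Independent oracle: numerically maximise the Poisson log-likelihood of
    the categorical-dose model with log-denominator offset, full vs reduced.

    Reduced model: intercept-only when ``constrain_dose`` is None, otherwise
    the full model with the named group's rate tied to the control group's.
    """
    doses = np.asarray(doses, float)
    counts = np.asarray(counts, float)
    denoms = np.asarray(denoms, float)
    levels = np.unique(doses)

    def group_ll(log_rate, mask):
        lam = math.exp(log_rate) * denoms[mask]
        return float(np.sum(counts[mask] * np.log(lam) - lam))

    def maximise(groups):
        # the likelihood separates over rate groups: one scalar search each
        total = 0.0
        for grp in groups:
            mask = np.isin(doses, grp)
            centre = math.log(max(counts[mask].sum() / denoms[mask].sum(), 1e-12))
            res = optimize.minimize_scalar(
                lambda lr: -group_ll(lr, mask),
                bounds=(centre - 5.0, centre + 5.0),
                method="bounded",
                options={"xatol": 1e-12},
            )
            total += -res.fun
        return total

    full = maximise([[g] for g in levels])
    if constrain_dose is None:
        reduced = maximise([list(levels)])
    else:
        ctrl = levels.min()
        groups = [[ctrl, constrain_dose]] + [
            [g] for g in levels if g not in (ctrl, constrain_dose)
        ]
        reduced = maximise(groups)
    return 2.0 * (full - reduced)


class TestOverallTrend:
    def test_null_identity(self):
        doses = np.repeat([0.0, 1.0, 2.0], 3)
        res = overall_trend_test((doses, np.full(9, 7.0), np.full(9, 100.0)))
        assert res.overall_stat == pytest.approx(0.0, abs=1e-12)
        assert res.overall_p == pytest.approx(1.0)

    def test_two_group_worked_value(self):
        """LR = 2*[5 ln(5/12.5) + 20 ln(20/12.5)] for counts 5 vs 20 on equal
        denominators."""
        res = overall_trend_test(([0.0, 1.0], [5.0, 20.0], [100.0, 100.0]))
        expected = 2.0 * (5 * math.log(5 / 12.5) + 20 * math.log(20 / 12.5))
        assert res.overall_stat == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(9.6372, abs=5e-4)
        assert res.overall_df == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_groups = int(rng.integers(3, 6))
        doses = np.repeat(np.arange(n_groups, dtype=float), 4)
        denoms = rng.uniform(50, 200, doses.size)
        counts = rng.poisson(rng.uniform(0.05, 0.5) * denoms)
        res = overall_trend_test((doses, counts.astype(float), denoms))
        oracle = brute_force_lr(doses, counts, denoms)
        assert res.overall_stat == pytest.approx(oracle, abs=1e-6)

    def test_matches_statsmodels_glm(self):
        """Cross-check against a Poisson GLM with categorical dose and
        log-denominator offset."""
        sm = pytest.importorskip("statsmodels.api")
        import pandas as pd

        rng = np.random.default_rng(42)
        doses = np.repeat([0.0, 1.0, 5.0, 10.0], 6)
        denoms = rng.uniform(100, 300, doses.size)
        counts = rng.poisson((0.1 + 0.02 * doses) * denoms)
        df = pd.DataFrame({"dose": doses, "count": counts, "denom": denoms})
        full = sm.GLM.from_formula(
            "count ~ C(dose)", df, family=sm.families.Poisson(),
            offset=np.log(df["denom"]),
        ).fit()
        null = sm.GLM.from_formula(
            "count ~ 1", df, family=sm.families.Poisson(),
            offset=np.log(df["denom"]),
        ).fit()
        res = overall_trend_test((doses, counts.astype(float), denoms))
        assert res.overall_stat == pytest.approx(2 * (full.llf - null.llf), abs=1e-6)

    def test_denominator_scaling_invariance(self):
        rng = np.random.default_rng(1)
        doses = np.repeat([0.0, 1.0, 2.0, 4.0], 5)
        denoms = rng.uniform(100, 400, doses.size)
        counts = rng.poisson(0.1 * denoms).astype(float)
        r1 = overall_trend_test((doses, counts, denoms))
        r2 = overall_trend_test((doses, counts, denoms * 37.5))
        assert r1.overall_stat == pytest.approx(r2.overall_stat, rel=1e-12)
        for c1, c2 in zip(r1.contrasts, r2.contrasts):
            assert c1.lr_stat == pytest.approx(c2.lr_stat, rel=1e-12)

    def test_overall_dominates_every_contrast(self):
        rng = np.random.default_rng(9)
        doses = np.repeat([0.0, 1.0, 2.0, 4.0, 8.0], 4)
        denoms = rng.uniform(100, 300, doses.size)
        counts = rng.poisson((0.05 + 0.01 * doses) * denoms).astype(float)
        res = overall_trend_test((doses, counts, denoms))
        assert all(res.overall_stat >= c.lr_stat - 1e-9 for c in res.contrasts)

    def test_null_p_uniform_and_contrast_type_I(self):
        """Simulated common-rate null: overall p ~ U(0,1) (KS < 0.08) and the
        per-dose contrasts reject at the d tier at ~5%."""
        rng = np.random.default_rng(2024)
        doses = np.repeat([0.0, 1.0, 2.0, 4.0], 7)
        pvals = []
        rejects = total = 0
        for _ in range(500):
            denoms = rng.uniform(1e4, 3e4, doses.size)
            counts = rng.poisson(5e-3 * denoms).astype(float)
            res = overall_trend_test((doses, counts, denoms))
            pvals.append(res.overall_p)
            for c in res.contrasts:
                total += 1
                rejects += c.tier != "ns"
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.08
        rate = rejects / total
        assert 0.032 <= rate <= 0.072


class TestContrasts:
    def test_identical_rates_give_ns(self):
        doses = np.repeat([0.0, 1.0, 2.0], 4)
        res = dose_vs_control_contrast((doses, np.full(12, 5.0), np.full(12, 100.0)), 1.0)
        assert res.lr_stat == pytest.approx(0.0, abs=1e-12)
        assert res.tier == "ns"

    @pytest.mark.parametrize("seed", range(8))
    def test_contrast_matches_numeric_maximisation(self, seed):
        rng = np.random.default_rng(100 + seed)
        doses = np.repeat([0.0, 1.0, 2.0, 4.0], 5)
        denoms = rng.uniform(50, 150, doses.size)
        counts = rng.poisson(rng.uniform(0.05, 0.3) * denoms)
        target = float(rng.choice([1.0, 2.0, 4.0]))
        res = dose_vs_control_contrast((doses, counts.astype(float), denoms), target)
        oracle = brute_force_lr(doses, counts, denoms, constrain_dose=target)
        assert res.lr_stat == pytest.approx(oracle, abs=1e-6)

    def test_absent_dose_is_contract_error(self):
        doses = np.repeat([0.0, 1.0, 2.0], 3)
        with pytest.raises(ContractError):
            dose_vs_control_contrast((doses, np.ones(9), np.full(9, 10.0)), 3.0)

    def test_tier_mapping_consistent_with_cutoffs(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @settings(max_examples=300, derandomize=True, deadline=None)
        @given(p=st.floats(0.0, 1.0, allow_nan=False))
        def check(p):
            tier = significance_tier(p)
            cutoffs = {"a": 1e-4, "b": 1e-3, "c": 1e-2, "d": 5e-2}
            if tier == "ns":
                assert p >= 0.05
            else:
                assert p < cutoffs[tier]
                # and it is the tightest tier that applies
                tighter = {"a": None, "b": 1e-4, "c": 1e-3, "d": 1e-2}[tier]
                if tighter is not None:
                    assert p >= tighter

        check()

    def test_tier_mapping(self):
        assert significance_tier(0.00005) == "a"
        assert significance_tier(0.0003) == "b"
        assert significance_tier(0.005) == "c"
        assert significance_tier(0.03) == "d"
        assert significance_tier(0.2) == "ns"

    def test_continuous_endpoint_converts_to_counts(self):
        ds = generate_preset("adducts_liver", seed=1)
        res = overall_trend_test(ds)
        assert res.overall_df == 10
        assert res.overall_p < 0.001  # strong dose effect in this preset
        assert len(res.contrasts) == 10
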