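import math

import numpy as np
import pytest
from scipy import optimize

from genetoxbmd import (
    BmrSpec,
    ContractError,
    compare_endpoints,
    ki67_correlation,
    proportionality,
    rank_tissues,
)
from genetoxbmd.profile_ci import BmdEstimate


def mk(tissue, bmdl, bmdu, endpoint="lacz_mf", bmd=None, model_id="m4", c=None,
       unbounded=False):
    bmd = bmd if bmd is not None else math.sqrt(bmdl * bmdu)
    return BmdEstimate(
        tissue=tissue, endpoint=endpoint, bmd=bmd, bmdl=bmdl, bmdu=bmdu,
        ces=BmrSpec(1.0), model_id=model_id, max_response_c=c,
        bmdu_unbounded=unbounded,
    )


class TestRankTissues:
    def test_disjoint_cis_are_distinguishable(self):
        rk = rank_tissues([mk("a", 1, 2), mk("b", 3, 4)])
        assert rk.order_labels() == ("a", "b")
        assert rk.distinguishable[0, 1]
        assert rk.groups == (("a",), ("b",))

    def test_overlapping_cis_share_a_group(self):
        rk = rank_tissues([mk("a", 1, 3), mk("b", 2, 4)])
        assert not rk.distinguishable[0, 1]
        assert rk.groups == (("a", "b"),)

    def test_three_group_fixture(self):
        """Seven estimates in disjoint CI blocks {SI} < {BM, Sp} < {Kd, Lv,
        Lg, GS} produce exactly three ordered groups."""
        ests = [
            mk("SI", 1.0, 1.5),
            mk("BM", 2.0, 3.0),
            mk("Sp", 2.5, 3.5),
            mk("Kd", 5.0, 7.0),
            mk("Lv", 6.0, 8.0),
            mk("Lg", 6.5, 8.5),
            mk("GS", 7.0, 9.0),
        ]
        rk = rank_tissues(ests)
        assert [sorted(g) for g in rk.groups] == [
            ["SI"], ["BM", "Sp"], ["GS", "Kd", "Lg", "Lv"]
        ]

    def test_permutation_invariance(self):
        ests = [mk("a", 1, 2), mk("b", 3, 4), mk("c", 2.5, 5)]
        rk1 = rank_tissues(ests)
        rk2 = rank_tissues(ests[::-1])
        assert rk1.order_labels() == rk2.order_labels()
        assert rk1.groups == rk2.groups

    def test_coincident_midpoints_never_distinguishable(self):
        rk = rank_tissues([mk("a", 1.0, 4.0), mk("b", 1.9, 2.105263157894737)])
        assert not rk.distinguishable[0, 1]

    def test_unbounded_bmdu_ranks_last(self):
        rk = rank_tissues(
            [mk("a", 5, 5000, unbounded=True), mk("b", 1, 2), mk("c", 3, 4)]
        )
        assert rk.order_labels()[-1] == "a"

    def test_mixed_endpoints_rejected(self):
        with pytest.raises(ContractError):
            rank_tissues([mk("a", 1, 2), mk("b", 3, 4, endpoint="mn_ret")])


class TestCompareEndpoints:
    def test_sorted_by_midpoint(self):
        summary = compare_endpoints(
            {
                "mn_ret": mk("bm", 200, 450, endpoint="mn_ret", c=8.0),
                "dna_adducts": mk("bm", 0.08, 0.125, endpoint="dna_adducts", c=200.0),
                "lacz_mf": mk("bm", 2, 4.5, endpoint="lacz_mf", c=100.0),
            }
        )
        assert [s.endpoint for s in summary] == ["dna_adducts", "lacz_mf", "mn_ret"]

    def test_model_without_asymptote_has_absent_c(self):
        summary = compare_endpoints(
            {"lacz_mf": mk("bm", 2, 4, model_id="m2", c=None)}
        )
        assert summary[0].max_response_c is None

    def test_c_ordering_recovered_from_fits(self):
        """Fits to saturating synthetic data with very different dynamic
        ranges report c in the generating order (adduct-like >> MN-like)."""
        from genetoxbmd import ExpModelParams, StudyDesign, fit_model

        from conftest import simulate_xy

        design = StudyDesign()
        x, y = simulate_xy("m4", ExpModelParams(a=1.0, b=0.5, c=200.0), design, 0.2, 3)
        c_adduct = fit_model("m4", (x, y), seed=0).params.c
        x, y = simulate_xy("m4", ExpModelParams(a=1.0, b=0.5, c=8.0), design, 0.2, 3)
        c_mn = fit_model("m4", (x, y), seed=0).params.c
        assert c_adduct > c_mn


class TestProportionality:
    def _pairs(self, ratio=3.0, slope=1.0, noise=0.0, n=7, seed=0):
        rng = np.random.default_rng(seed)
        xs = np.geomspace(0.05, 5.0, n)
        ys = ratio * xs ** slope * np.exp(rng.normal(0, noise, n))
        ex = [mk(f"t{i}", x * 0.8, x * 1.25, bmd=x, endpoint="dna_adducts")
              for i, x in enumerate(xs)]
        ey = [mk(f"t{i}", y * 0.8, y * 1.25, bmd=y) for i, y in enumerate(ys)]
        return ex, ey

    def test_exact_proportionality(self):
        ex, ey = self._pairs(ratio=3.0)
        res = proportionality(ex, ey)
        assert res.proportionality_constant == pytest.approx(3.0, abs=1e-9)
        assert res.slope_free == pytest.approx(1.0, abs=1e-9)
        assert res.unity_adequate

    def test_slope_two_rejected(self):
        ex, ey = self._pairs(slope=2.0, noise=0.02)
        res = proportionality(ex, ey)
        assert not res.unity_adequate

    def test_scale_equivariance(self):
        ex, ey = self._pairs(ratio=3.0, noise=0.05)
        res1 = proportionality(ex, ey)
        k = 4.0
        ex_k = [mk(e.tissue, e.bmdl * k, e.bmdu * k, bmd=e.bmd * k,
                   endpoint="dna_adducts") for e in ex]
        res2 = proportionality(ex_k, ey)
        assert res2.proportionality_constant == pytest.approx(
            res1.proportionality_constant / k, rel=1e-9
        )
        assert res2.slope_free == pytest.approx(res1.slope_free, rel=1e-9)

    def test_offset_matches_brute_force_least_squares(self):
        """The slope-1 offset equals the 1-parameter LS minimiser (oracle)."""
        ex, ey = self._pairs(ratio=2.0, noise=0.3, seed=5)
        res = proportionality(ex, ey)
        lx = np.log10([e.bmd for e in ex])
        ly = np.log10([e.bmd for e in ey])
        oracle = optimize.minimize_scalar(
            lambda o: float(np.sum((ly - lx - o) ** 2)),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-13},
        ).x
        assert res.log10_offset == pytest.approx(float(oracle), abs=1e-10)

    def test_unmatched_tissues_rejected(self):
        ex, ey = self._pairs()
        with pytest.raises(ContractError, match="mismatch"):
            proportionality(ex[:-1], ey)


class TestKi67:
    def test_perfectly_proportional_ratio(self):
        ki67 = {"liver": 1.0, "lung": 2.0, "si": 4.0}
        ex = [mk(t, v * 0.9, v * 1.1, bmd=v, endpoint="dna_adducts")
              for t, v in [("liver", 1.0), ("lung", 2.0), ("si", 4.0)]]
        ey = [mk(t, 0.9, 1.1, bmd=1.0) for t in ("liver", "lung", "si")]
        res = ki67_correlation(ki67, ex, ey)
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert not res.degenerate

    def test_constant_ratio_flagged_degenerate(self):
        ki67 = {"liver": 1.0, "lung": 2.0, "si": 4.0}
        ex = [mk(t, 1.8, 2.2, bmd=2.0, endpoint="dna_adducts")
              for t in ("liver", "lung", "si")]
        ey = [mk(t, 0.9, 1.1, bmd=1.0) for t in ("liver", "lung", "si")]
        res = ki67_correlation(ki67, ex, ey)
        assert res.degenerate

    def test_label_permutation_destroys_alignment(self):
        rng = np.random.default_rng(0)
        tissues = [f"t{i}" for i in range(6)]
        vals = np.geomspace(1, 30, 6)
        ki67 = dict(zip(tissues, vals))
        ex = [mk(t, v * 0.9, v * 1.1, bmd=v, endpoint="dna_adducts")
              for t, v in zip(tissues, vals)]
        ey = [mk(t, 0.9, 1.1, bmd=1.0) for t in tissues]
        aligned = ki67_correlation(ki67, ex, ey).r
        shuffled = []
        for _ in range(100):
            perm = rng.permutation(list(vals))
            shuffled.append(ki67_correlation(dict(zip(tissues, perm)), ex, ey).r)
        assert abs(aligned) > np.mean(np.abs(shuffled)) + 0.2

    def test_too_few_tissues_rejected(self):
        with pytest.raises(ContractError):
            ki67_correlation(
                {"liver": 1.0, "lung": 2.0},
                [mk("liver", 1, 2, endpoint="dna_adducts"), mk("lung", 1, 2, endpoint="dna_adducts")],
                [mk("liver", 1, 2), mk("lung", 1, 2)],
            )
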