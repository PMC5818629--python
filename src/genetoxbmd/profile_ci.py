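"""BMD point estimate and two-sided profile-likelihood confidence interval.

The selected model is reparameterised so the benchmark dose T is an explicit
parameter: its rate b is eliminated through the closed-form inversion
(e.g. for m4, b = ln((c-1)/(c-1-ces)) / T).  At each fixed T the remaining
nuisance parameters are maximised (background a and residual sigma have
closed-form profiles; c and/or d are optimised numerically), giving the
profile log-likelihood LL_p(T).  The two-sided CI at level L collects the T
where

    2 * (LL_max - LL_p(T)) <= chi2_{1, L}

(2.7055 at L = 0.90, i.e. a drop of 1.3528), with the endpoints located by
bracket expansion plus Brent root-finding on each side.  An upper bound that
never crosses within 100x the top dose is flagged unbounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize, stats

from .datamodel import DoseResponseDataset, ZeroRule
from .errors import ContractError
from .exp_family import BmrSpec, D_MAX, D_MIN, ExpModelParams, bmd_closed_form
from .fit_select import (
    SelectionResult,
    _as_xy,
    _concentrated_ll,
    _ll_from_rss,
    _rss_for_d,
    select_model,
)

#: the profile search for the upper bound stops at this multiple of the top dose
UPPER_CAP_FACTOR = 100.0
#: and the lower bound at this fraction of the point estimate
LOWER_CAP_FACTOR = 1e-9


@dataclass(frozen=True)
class BmdEstimate:
    """BMD with BMDL/BMDU at a stated benchmark response."""

    tissue: str
    endpoint: str
    bmd: float
    bmdl: float
    bmdu: float
    ces: BmrSpec
    model_id: str
    bmdu_unbounded: bool = False
    bmdl_unbounded: bool = False
    max_response_c: float | None = None  # model parameter c where the model has one

    def __post_init__(self):
        if not (0 < self.bmdl <= self.bmd * (1 + 1e-9) and self.bmd <= self.bmdu * (1 + 1e-9)):
            raise ContractError(
                f"interval ordering violated: bmdl={self.bmdl}, bmd={self.bmd}, "
                f"bmdu={self.bmdu}"
            )

    @property
    def precision_ratio(self) -> float:
        return self.bmdu / self.bmdl

    @property
    def midpoint(self) -> float:
        """Geometric midpoint of the BMDL-BMDU interval (forest-plot ordering)."""
        return math.sqrt(self.bmdl * self.bmdu)

    def overlaps(self, other: "BmdEstimate") -> bool:
        return not (self.bmdu < other.bmdl or other.bmdu < self.bmdl)

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "endpoint": self.endpoint,
            "bmd": self.bmd,
            "bmdl": self.bmdl,
            "bmdu": self.bmdu,
            "ces": self.ces.ces,
            "model_id": self.model_id,
            "precision_ratio": self.precision_ratio,
            "midpoint": self.midpoint,
            "bmdu_unbounded": self.bmdu_unbounded,
            "max_response_c": self.max_response_c,
        }


@dataclass(frozen=True)
class NoBmdResult:
    """Returned when the selected model shows no significant dose-response."""

    tissue: str
    endpoint: str
    reason: str
    model_id: str = "m1"

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "endpoint": self.endpoint,
            "reason": self.reason,
            "model_id": self.model_id,
            "bmd": None,
        }


# ---------------------------------------------------------------------------
# Profile log-likelihood with BMD as an explicit parameter
# ---------------------------------------------------------------------------

def _profile_ll_factory(
    model_id: str,
    params: ExpModelParams,
    x: np.ndarray,
    z: np.ndarray,
    ces: float,
) -> Callable[[float], float]:
    """Return LL_p(T): nuisance-maximised log-likelihood at fixed BMD = T.

    a and sigma are profiled in closed form throughout; m3 optimises d,
    m4 optimises c, m5 optimises (c, d).  Warm starts come from the MLE.
    """
    k = math.log1p(ces)  # ln(1+ces)

    if model_id == "m2":

        def ll(T: float) -> float:
            b = k / T
            r = z - b * x
            rss = float(np.sum((r - np.mean(r)) ** 2))
            return _ll_from_rss(rss, z)

        return ll

    if model_id == "m3":

        def rss_at(T: float, d: float) -> float:
            b = k / T ** d
            r = z - b * x ** d
            return float(np.sum((r - np.mean(r)) ** 2))

        def ll(T: float) -> float:
            res = optimize.minimize_scalar(
                lambda d: rss_at(T, d),
                bounds=(D_MIN, D_MAX),
                method="bounded",
                options={"xatol": 1e-9},
            )
            # the bounded search can miss a boundary optimum; check both ends
            best = min(res.fun, rss_at(T, D_MIN), rss_at(T, D_MAX))
            return _ll_from_rss(best, z)

        return ll

    if model_id in ("m4", "m5"):
        c_hat = params.c
        d_hat = params.d if model_id == "m5" else 1.0

        def lng_at(T: float, c: float, d: float) -> np.ndarray:
            b = math.log((c - 1.0) / (c - 1.0 - ces)) / T ** d
            return np.log(c - (c - 1.0) * np.exp(-b * x ** d))

        def rss_at(T: float, u: float, d: float) -> float:
            # u parameterises c = 1 + ces + exp(u), keeping the BMR reachable
            c = 1.0 + ces + math.exp(u)
            r = z - lng_at(T, c, d)
            return float(np.sum((r - np.mean(r)) ** 2))

        u_hat = math.log(max(c_hat - 1.0 - ces, 1e-12))
        U_LO, U_HI = -30.0, 30.0

        if model_id == "m4":
            # warm-started 1-D search over u; the optimal c moves smoothly
            # with T during bracketing, so the previous optimum is an
            # excellent start; widen the window if the optimum hits its edge
            state = {"u": u_hat}

            def ll(T: float) -> float:
                u0 = state["u"]
                for width in (6.0, 16.0, 60.0):
                    lo = max(u0 - width, U_LO)
                    hi = min(u0 + width, U_HI)
                    res = optimize.minimize_scalar(
                        lambda u: rss_at(T, u, 1.0),
                        bounds=(lo, hi),
                        method="bounded",
                        options={"xatol": 1e-7},
                    )
                    at_edge = (res.x - lo < 1e-3 and lo > U_LO) or (
                        hi - res.x < 1e-3 and hi < U_HI
                    )
                    if not at_edge:
                        break
                state["u"] = float(res.x)
                return _ll_from_rss(float(res.fun), z)

            return ll

        state = {"v": np.array([u_hat, d_hat])}

        def ll(T: float) -> float:
            best = None
            for v0 in (state["v"], np.array([u_hat, d_hat])):
                res = optimize.minimize(
                    lambda v: rss_at(T, v[0], v[1]),
                    v0,
                    method="L-BFGS-B",
                    bounds=[(U_LO, U_HI), (D_MIN, D_MAX)],
                    options={"ftol": 1e-14, "gtol": 1e-10},
                )
                if best is None or res.fun < best.fun:
                    best = res
                if np.allclose(v0, state["v"]) and np.allclose(v0, [u_hat, d_hat]):
                    break  # identical starts: skip the duplicate
            state["v"] = np.asarray(best.x, dtype=float)
            return _ll_from_rss(float(best.fun), z)

        return ll

    raise ContractError(f"no profile reparameterisation for model {model_id!r}")


def profile_curve(
    selection: SelectionResult,
    ds,
    bmd_grid,
    ces: float = 1.0,
    zero_rule: ZeroRule = "half-minimum",
) -> np.ndarray:
    """Profile log-likelihood LL_p(T) at each grid dose (diagnostic)."""
    x, y = _as_xy(ds, zero_rule)
    grid = np.asarray(bmd_grid, dtype=float)
    cap = UPPER_CAP_FACTOR * float(np.max(x))
    if np.any(grid <= 0) or np.any(grid > cap):
        raise ContractError(f"grid must lie in (0, {cap:g}]")
    fit = selection.selected_fit
    ll = _profile_ll_factory(fit.model_id, fit.params, x, np.log(y), ces)
    return np.array([ll(T) for T in grid])


def estimate_bmd(
    selection: SelectionResult,
    ds,
    ces: float = 1.0,
    level: float = 0.90,
    tissue: str | None = None,
    endpoint: str | None = None,
    zero_rule: ZeroRule = "half-minimum",
) -> BmdEstimate | NoBmdResult:
    """BMD at the MLE plus a two-sided ``level`` profile-likelihood CI."""
    if not (0 < level < 1):
        raise ContractError(f"level must lie in (0, 1), got {level}")
    if isinstance(ds, DoseResponseDataset):
        tissue = tissue if tissue is not None else ds.tissue
        endpoint = endpoint if endpoint is not None else ds.endpoint
    tissue = tissue or ""
    endpoint = endpoint or ""

    fit = selection.selected_fit
    if fit.model_id == "m1":
        return NoBmdResult(
            tissue=tissue,
            endpoint=endpoint,
            reason="no significant dose-response (flat model selected)",
        )
    if fit.params.b is not None and fit.params.b <= 0:
        return NoBmdResult(
            tissue=tissue,
            endpoint=endpoint,
            reason="fitted response is non-increasing; BMD undefined",
            model_id=fit.model_id,
        )

    bmr = BmrSpec(ces)
    bmd = bmd_closed_form(fit.model_id, fit.params, bmr)

    x, y = _as_xy(ds, zero_rule)
    z = np.log(y)
    prof = _profile_ll_factory(fit.model_id, fit.params, x, z, ces)
    # the profile maximum; >= the selected fit's loglik by construction, use
    # whichever is larger to guard against inner-optimiser slack
    ll_max = max(fit.loglik, prof(bmd))
    half_crit = float(stats.chi2.ppf(level, 1)) / 2.0

    def drop(T: float) -> float:
        return ll_max - prof(T) - half_crit

    cap_hi = UPPER_CAP_FACTOR * float(np.max(x))
    cap_lo = LOWER_CAP_FACTOR * bmd

    bmdl, lo_unbounded = _find_bound(drop, bmd, cap_lo, side="lower")
    bmdu, hi_unbounded = _find_bound(drop, bmd, cap_hi, side="upper")

    return BmdEstimate(
        tissue=tissue,
        endpoint=endpoint,
        bmd=bmd,
        bmdl=min(bmdl, bmd),
        bmdu=max(bmdu, bmd),
        ces=bmr,
        model_id=fit.model_id,
        bmdu_unbounded=hi_unbounded,
        bmdl_unbounded=lo_unbounded,
        max_response_c=fit.params.c,
    )


def _find_bound(
    drop: Callable[[float], float], bmd: float, cap: float, side: str
) -> tuple[float, bool]:
    """Geometric bracket expansion from the MLE, then Brent on ``drop``."""
    factor = 0.5 if side == "lower" else 2.0
    t_in = bmd
    t_out = bmd * factor
    for _ in range(200):
        past_cap = t_out < cap if side == "lower" else t_out > cap
        if past_cap:
            d_cap = drop(cap)
            if d_cap <= 0:  # profile never drops below the cutoff before the cap
                return cap, True
            t_out = cap
            break
        if drop(t_out) > 0:
            break
        t_in = t_out
        t_out *= factor
    else:
        return cap, True
    lo, hi = (t_out, t_in) if side == "lower" else (t_in, t_out)
    root = optimize.brentq(drop, lo, hi, xtol=1e-12, rtol=1e-9, maxiter=200)
    return float(root), False
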