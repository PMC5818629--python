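"""ML fitting of each exponential family member and the LRT selection ladder.

Fitting exploits the log-normal error structure: on the log scale every model
is ``ln y = ln a + ln g(x; theta) + eps`` with ``g = f/a``, so the background
``a`` and the residual SD ``sigma`` have closed-form profile MLEs for any
value of the nonlinear parameters ``theta``.  The optimiser therefore works
in at most three dimensions:

- m1: closed form (geometric mean);
- m2: closed form (OLS of ln y on x);
- m3: 1-D search over the shape d (OLS of ln y on x^d at fixed d);
- m4: 2-D over (ln b, ln(c-1));
- m5: 3-D over (ln b, ln(c-1), d).

Each saturating fit is warm-started from its nested submodel's optimum
(m4 from near-m1, m5 from m4 at d=1) plus Latin-hypercube multi-starts, so
the true nesting chains m1 < m2 < m3 and m1 < m4 < m5 hold monotonically in
log-likelihood up to optimiser tolerance.

Model selection follows the nested-ladder convention for this family:
m2 is accepted over m1 at a df=1 likelihood-ratio test (p < alpha); the
3-parameter extensions m3 and m4 are each tested against m2 (df=1) and the
better accepted one is carried; m5 is tested against the carried model
(df=1).  The selected model is the most complex accepted one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

from .datamodel import DoseResponseDataset, ZeroRule, to_modelling_response
from .errors import ContractError, FitError
from .exp_family import (
    D_MAX,
    D_MIN,
    ExpModelParams,
    ExpModelSpec,
    N_PARAMS,
    evaluate,
    loglik,
)

#: floor on the profiled residual SD; keeps the likelihood finite on
#: noiseless (e.g. synthetic zero-noise) data
SIGMA_FLOOR = 1e-6

#: refit is triggered if a nested submodel beats its extension by more than this
LL_TOL = 1e-6

N_MULTISTART = 10


@dataclass(frozen=True)
class ExpModelFit:
    """One fitted family member on one dataset."""

    spec: ExpModelSpec
    params: ExpModelParams
    loglik: float
    converged: bool
    n_obs: int

    @property
    def model_id(self) -> str:
        return self.spec.model_id

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


@dataclass(frozen=True)
class LadderStep:
    """One comparison in the selection ladder."""

    comparison: str  # e.g. "m2 vs m1"
    stat: float  # 2 * delta log-likelihood
    df: int
    accepted: bool

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "stat": self.stat,
            "df": self.df,
            "accepted": self.accepted,
        }


@dataclass(frozen=True)
class SelectionResult:
    fits: dict[str, ExpModelFit]
    selected: str
    ladder_trace: tuple[LadderStep, ...]

    @property
    def selected_fit(self) -> ExpModelFit:
        return self.fits[self.selected]

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
            "ladder_trace": [s.to_dict() for s in self.ladder_trace],
        }


# ---------------------------------------------------------------------------
# Concentrated likelihood machinery
# ---------------------------------------------------------------------------

def _concentrated_ll(z: np.ndarray, lng: np.ndarray) -> tuple[float, float, float]:
    """Profile (ln a, sigma) analytically; return (loglik, ln_a_hat, sigma_hat).

    ``z`` are log responses, ``lng`` the log mean curve with a = 1.
    """
    r = z - lng
    ln_a = float(np.mean(r))
    rss = float(np.sum((r - ln_a) ** 2))
    n = z.size
    s2 = max(rss / n, SIGMA_FLOOR ** 2)
    ll = -0.5 * n * (math.log(2.0 * math.pi * s2) + rss / (n * s2)) - float(np.sum(z))
    return ll, ln_a, math.sqrt(s2)


def _rss_for_d(z: np.ndarray, x: np.ndarray, d: float) -> tuple[float, float, float]:
    """Exact OLS of z on x**d: returns (rss, intercept, slope)."""
    t = x ** d
    tbar = float(np.mean(t))
    zbar = float(np.mean(z))
    stt = float(np.sum((t - tbar) ** 2))
    if stt <= 0:
        return float(np.sum((z - zbar) ** 2)), zbar, 0.0
    b = float(np.sum((t - tbar) * (z - zbar))) / stt
    resid = z - zbar - b * (t - tbar)
    return float(np.sum(resid ** 2)), zbar - b * tbar, b


def _ll_from_rss(rss: float, z: np.ndarray) -> float:
    n = z.size
    s2 = max(rss / n, SIGMA_FLOOR ** 2)
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + rss / (n * s2)) - float(np.sum(z))


def _lng_m4(x: np.ndarray, b: float, c: float) -> np.ndarray:
    return np.log(c - (c - 1.0) * np.exp(-b * x))


def _fit_m1(x: np.ndarray, z: np.ndarray) -> tuple[ExpModelParams, float]:
    ll, ln_a, sig = _concentrated_ll(z, np.zeros_like(z))
    return ExpModelParams(a=math.exp(ln_a), sigma=sig), ll


def _fit_m2(x: np.ndarray, z: np.ndarray) -> tuple[ExpModelParams, float]:
    rss, ln_a, b = _rss_for_d(z, x, 1.0)
    ll = _ll_from_rss(rss, z)
    sig = max(math.sqrt(rss / z.size), SIGMA_FLOOR)
    return ExpModelParams(a=math.exp(ln_a), b=b, sigma=sig), ll


def _fit_m3(x: np.ndarray, z: np.ndarray) -> tuple[ExpModelParams, float]:
    # 1-D profile over d: dense grid then local refinement
    grid = np.linspace(D_MIN, D_MAX, 31)
    rss_grid = [_rss_for_d(z, x, d)[0] for d in grid]
    i = int(np.argmin(rss_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda d: _rss_for_d(z, x, d)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    d = float(res.x) if res.fun <= rss_grid[i] else float(grid[i])
    d = min(max(d, D_MIN), D_MAX)
    rss, ln_a, b = _rss_for_d(z, x, d)
    ll = _ll_from_rss(rss, z)
    sig = max(math.sqrt(rss / z.size), SIGMA_FLOOR)
    return ExpModelParams(a=math.exp(ln_a), b=b, d=d, sigma=sig), ll


# bounds in transformed coordinates (ln b, ln(c-1), d)
_LB_LNB, _UB_LNB = -14.0, 6.0
_LB_LNC1, _UB_LNC1 = -9.0, 16.0


def _m45_objective(x: np.ndarray, z: np.ndarray, with_d: bool) -> Callable:
    def obj(theta: np.ndarray) -> float:
        b = math.exp(theta[0])
        c = 1.0 + math.exp(theta[1])
        xe = x ** theta[2] if with_d else x
        lng = np.log(c - (c - 1.0) * np.exp(-b * xe))
        r = z - lng
        return float(np.sum((r - np.mean(r)) ** 2))

    return obj


def _starts_m45(
    x: np.ndarray, z: np.ndarray, with_d: bool, seed: int
) -> list[np.ndarray]:
    xpos = x[x > 0]
    xmax = float(np.max(xpos))
    # heuristic: c from the top-group vs control geometric means
    top = z[x == np.max(x)]
    ctrl = z[x == np.min(x)]
    c0 = max(math.exp(float(np.mean(top)) - float(np.mean(ctrl))), 1.5)
    heur = []
    for bscale in (0.5 / xmax, 2.0 / xmax, 8.0 / xmax):
        p = [math.log(bscale), math.log(c0 - 1.0 + 1e-9)]
        if with_d:
            p.append(1.0)
        heur.append(np.array(p))
    # near-m1 start (c -> 1) so the fit never falls below the flat model
    p = [math.log(1.0 / xmax), -8.0]
    if with_d:
        p.append(1.0)
    heur.append(np.array(p))
    # seeded Latin-hypercube over the transformed box
    ndim = 3 if with_d else 2
    sampler = stats.qmc.LatinHypercube(d=ndim, seed=seed)
    lo = np.array([_LB_LNB + 4, _LB_LNC1 + 4] + ([D_MIN] if with_d else []))
    hi = np.array([_UB_LNB - 2, _UB_LNC1 - 4] + ([D_MAX] if with_d else []))
    draws = stats.qmc.scale(sampler.random(N_MULTISTART - len(heur)), lo, hi)
    return heur + [row for row in draws]


def _fit_m4(
    x: np.ndarray, z: np.ndarray, seed: int
) -> tuple[ExpModelParams, float, bool]:
    obj = _m45_objective(x, z, with_d=False)
    bounds = [(_LB_LNB, _UB_LNB), (_LB_LNC1, _UB_LNC1)]
    best, ok = _multistart(obj, _starts_m45(x, z, False, seed), bounds)
    b = math.exp(best.x[0])
    c = 1.0 + math.exp(best.x[1])
    lng = _lng_m4(x, b, c)
    ll, ln_a, sig = _concentrated_ll(z, lng)
    return ExpModelParams(a=math.exp(ln_a), b=b, c=c, sigma=sig), ll, ok


def _fit_m5(
    x: np.ndarray, z: np.ndarray, seed: int, m4_params: ExpModelParams | None
) -> tuple[ExpModelParams, float, bool]:
    obj = _m45_objective(x, z, with_d=True)
    bounds = [(_LB_LNB, _UB_LNB), (_LB_LNC1, _UB_LNC1), (D_MIN, D_MAX)]
    starts = _starts_m45(x, z, True, seed)
    if m4_params is not None:
        # warm start at the m4 optimum (d = 1) guarantees ll(m5) >= ll(m4)
        starts.insert(
            0,
            np.array(
                [
                    math.log(m4_params.b),
                    math.log(max(m4_params.c - 1.0, 1e-9)),
                    1.0,
                ]
            ),
        )
        starts.insert(
            1,
            np.array(
                [
                    math.log(m4_params.b),
                    math.log(max(m4_params.c - 1.0, 1e-9)),
                    2.0,
                ]
            ),
        )
    best, ok = _multistart(obj, starts, bounds)
    b = math.exp(best.x[0])
    c = 1.0 + math.exp(best.x[1])
    d = float(np.clip(best.x[2], D_MIN, D_MAX))
    lng = np.log(c - (c - 1.0) * np.exp(-b * x ** d))
    ll, ln_a, sig = _concentrated_ll(z, lng)
    return ExpModelParams(a=math.exp(ln_a), b=b, c=c, d=d, sigma=sig), ll, ok


def _multistart(obj, starts, bounds):
    best = None
    ok = False
    for s0 in starts:
        s0 = np.clip(s0, [b[0] for b in bounds], [b[1] for b in bounds])
        try:
            res = optimize.minimize(
                obj,
                s0,
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.fun < best.fun:
            best = res
            ok = bool(res.success) or ok
        elif res.success:
            ok = True
    if best is None:
        raise FitError("all optimisation starts failed")
    return best, ok


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------

def _as_xy(
    ds, zero_rule: ZeroRule = "half-minimum"
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(ds, DoseResponseDataset):
        return to_modelling_response(ds, zero_rule=zero_rule)
    x, y = ds
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ContractError("responses must be strictly positive")
    return x, y


def fit_model(
    model_id: str,
    ds,
    seed: int = 0,
    zero_rule: ZeroRule = "half-minimum",
) -> ExpModelFit:
    """Maximum-likelihood fit of one family member.

    ``ds`` is a :class:`DoseResponseDataset` or an ``(doses, responses)``
    pair.  Deterministic given ``seed`` (which seeds the multi-start draws).
    """
    spec = ExpModelSpec(model_id)
    x, y = _as_xy(ds, zero_rule)
    # stable order: fits must be invariant to row permutation
    order = np.lexsort((y, x))
    x, y = x[order], y[order]
    z = np.log(y)
    converged = True
    if model_id == "m1":
        params, ll = _fit_m1(x, z)
    elif model_id == "m2":
        params, ll = _fit_m2(x, z)
    elif model_id == "m3":
        params, ll = _fit_m3(x, z)
    elif model_id == "m4":
        params, ll, converged = _fit_m4(x, z, seed)
    elif model_id == "m5":
        m4p, _, _ = _fit_m4(x, z, seed)
        params, ll, converged = _fit_m5(x, z, seed, m4p)
    else:
        raise ContractError(f"unknown model id {model_id!r}")
    return ExpModelFit(
        spec=spec, params=params, loglik=ll, converged=converged, n_obs=x.size
    )


def _carry(candidates: list[ExpModelFit]) -> ExpModelFit:
    """Higher-loglik accepted 3-parameter model; exact ties prefer m4."""
    return max(candidates, key=lambda f: (f.loglik, f.model_id == "m4"))


def select_model(
    ds,
    alpha: float = 0.05,
    seed: int = 0,
    zero_rule: ZeroRule = "half-minimum",
) -> SelectionResult:
    """Run the nested LRT ladder and return the selected model with its trace.

    A step accepts the more complex model when 2*delta(loglik) exceeds the
    chi-square critical value at ``alpha`` with df = 1 (3.841 at 0.05).
    Fits that fail to converge are pruned from the ladder.
    """
    if not (0 < alpha < 1):
        raise ContractError(f"alpha must lie in (0, 1), got {alpha}")
    crit = float(stats.chi2.ppf(1.0 - alpha, 1))
    xy = _as_xy(ds, zero_rule)

    fits: dict[str, ExpModelFit] = {}

    def fit(mid: str) -> ExpModelFit:
        f = fit_model(mid, xy, seed=seed)
        fits[mid] = f
        return f

    trace: list[LadderStep] = []
    m1 = fit("m1")
    m2 = fit("m2")
    stat21 = 2.0 * (m2.loglik - m1.loglik)
    acc21 = stat21 > crit
    trace.append(LadderStep("m2 vs m1", stat21, 1, acc21))
    if not acc21:
        return SelectionResult(fits=fits, selected="m1", ladder_trace=tuple(trace))

    candidates = []
    for mid in ("m3", "m4"):
        f = fit(mid)
        stat = 2.0 * (f.loglik - m2.loglik)
        usable = f.converged
        acc = usable and stat > crit
        trace.append(LadderStep(f"{mid} vs m2", stat, 1, acc))
        if acc:
            candidates.append(f)
    if not candidates:
        return SelectionResult(fits=fits, selected="m2", ladder_trace=tuple(trace))
    carried = _carry(candidates)

    m5 = fit("m5")
    stat5 = 2.0 * (m5.loglik - carried.loglik)
    acc5 = m5.converged and stat5 > crit
    trace.append(LadderStep(f"m5 vs {carried.model_id}", stat5, 1, acc5))
    selected = "m5" if acc5 else carried.model_id
    return SelectionResult(fits=fits, selected=selected, ladder_trace=tuple(trace))
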