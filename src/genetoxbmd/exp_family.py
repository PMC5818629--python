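"""The nested exponential dose-response family, BMD inversion, log-normal likelihood.

Five members, indexed by increasing flexibility (number of free mean
parameters in brackets):

=====  ==============================  ===========================
model  mean function f(x)              free parameters
=====  ==============================  ===========================
m1     a                               a                       [1]
m2     a * exp(b*x)                    a, b                    [2]
m3     a * exp(b*x^d)                  a, b, d                 [3]
m4     a * (c - (c-1)*exp(-b*x))       a, b, c                 [3]
m5     a * (c - (c-1)*exp(-b*x^d))     a, b, c, d              [4]
=====  ==============================  ===========================

All members satisfy f(0) = a (the background response).  m4/m5 saturate at
a*c, so c is the model-determined maximum response as a multiple of
background.  Residuals are log-normal: ln y ~ Normal(ln f(x), sigma^2) with a
single sigma shared across dose groups.

Exact algebraic nestings: m2(b=0) = m1, m3(d=1) = m2, m4(c=1) = m1,
m5(d=1) = m4.  Note m2/m3 (convex growth) are not nested in m4/m5
(concave saturation); the two chains meet only at m1.

The benchmark dose at a continuous effect size ``ces`` (fractional increase
over background; ces = 1.0 is a two-fold increase) solves
f(BMD) = a*(1 + ces), which is available in closed form for m2-m5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import BmrUnreachableError, ContractError, NoDoseDependenceError

MODEL_IDS = ("m1", "m2", "m3", "m4", "m5")

#: number of free mean-function parameters per model (sigma excluded)
N_PARAMS = {"m1": 1, "m2": 2, "m3": 3, "m4": 3, "m5": 4}

#: which of (a, b, c, d) each model uses
PARAM_NAMES = {
    "m1": ("a",),
    "m2": ("a", "b"),
    "m3": ("a", "b", "d"),
    "m4": ("a", "b", "c"),
    "m5": ("a", "b", "c", "d"),
}

#: bounds on the shape exponent d (m3/m5); the lower bound keeps the slope at
#: dose 0 finite, the upper is the conventional cap for this family
D_MIN, D_MAX = 1.0, 4.0


@dataclass(frozen=True)
class ExpModelSpec:
    """Identifier + parameter count for one family member."""

    model_id: str

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ContractError(f"unknown model id {self.model_id!r}")

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.model_id]

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.model_id]


@dataclass(frozen=True)
class ExpModelParams:
    """Parameter set for one family member.

    a  background response (> 0)
    b  rate; must be > 0 for m4/m5, may be any sign for m2/m3 (the fitted
       sign records whether the response increases; BMD inversion requires
       b > 0)
    c  maximum response as a multiple of background (> 1), m4/m5 only
    d  shape exponent in [1, 4], m3/m5 only
    sigma  residual SD on the natural-log scale (> 0), optional until fitted
    """

    a: float
    b: float | None = None
    c: float | None = None
    d: float | None = None
    sigma: float | None = None

    def __post_init__(self):
        if not (self.a > 0):
            raise ContractError(f"background a must be > 0, got {self.a}")
        if self.c is not None and not (self.c > 1):
            raise ContractError(f"maximum-response multiple c must be > 1, got {self.c}")
        if self.c is not None and not (self.b is not None and self.b > 0):
            raise ContractError("saturating models (c set) require rate b > 0")
        if self.d is not None and not (D_MIN <= self.d <= D_MAX):
            raise ContractError(f"shape d must lie in [{D_MIN}, {D_MAX}], got {self.d}")
        if self.sigma is not None and not (self.sigma > 0):
            raise ContractError(f"sigma must be > 0, got {self.sigma}")

    def for_model(self, model_id: str) -> None:
        """Raise unless exactly the parameters this model needs are present."""
        need = set(PARAM_NAMES[model_id])
        have = {n for n in ("a", "b", "c", "d") if getattr(self, n) is not None}
        if need != have:
            raise ContractError(
                f"{model_id} needs parameters {sorted(need)}, got {sorted(have)}"
            )

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("a", "b", "c", "d", "sigma")
            if getattr(self, k) is not None
        }


def evaluate(model_id: str, params: ExpModelParams, x) -> np.ndarray | float:
    """Expected response f(x) of ``model_id`` at dose(s) ``x >= 0``."""
    params.for_model(model_id)
    xa = np.asarray(x, dtype=float)
    if np.any(xa < 0):
        raise ContractError("doses must be nonnegative")
    a = params.a
    with np.errstate(over="ignore"):  # exp overflow at extreme doses -> inf
        if model_id == "m1":
            out = np.full_like(xa, a)
        elif model_id == "m2":
            out = a * np.exp(params.b * xa)
        elif model_id == "m3":
            out = a * np.exp(params.b * xa ** params.d)
        elif model_id == "m4":
            out = a * (params.c - (params.c - 1.0) * np.exp(-params.b * xa))
        else:  # m5
            out = a * (params.c - (params.c - 1.0) * np.exp(-params.b * xa ** params.d))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BmrSpec:
    """Benchmark response: fractional increase over background.

    ``ces = 1.0`` means a 100% (two-fold) increase relative to control.
    """

    ces: float = 1.0

    def __post_init__(self):
        if not (self.ces > 0):
            raise ContractError(f"ces must be > 0, got {self.ces}")

    @property
    def target_multiple(self) -> float:
        return 1.0 + self.ces


def bmd_closed_form(model_id: str, params: ExpModelParams, bmr: BmrSpec) -> float:
    """Dose at which f(dose) = a*(1+ces), in closed form.

    m2: ln(1+ces)/b;  m3: (ln(1+ces)/b)^(1/d)
    m4: -(1/b)*ln((c-1-ces)/(c-1));  m5: same^(1/d)
    """
    params.for_model(model_id)
    ces = bmr.ces
    if model_id == "m1":
        raise NoDoseDependenceError("m1 has no dose dependence; no BMD exists")
    if params.b is None or params.b <= 0:
        raise NoDoseDependenceError(
            f"BMD requires an increasing response (b > 0); got b={params.b}"
        )
    if model_id in ("m2", "m3"):
        base = math.log1p(ces) / params.b
    else:  # m4 / m5
        c = params.c
        if c <= 1.0 + ces:
            raise BmrUnreachableError(
                f"benchmark response 1+ces={1 + ces:g} is not reachable: the "
                f"model's asymptote is c={c:g} times background",
                asymptote=c,
            )
        base = -math.log((c - 1.0 - ces) / (c - 1.0)) / params.b
    if model_id in ("m3", "m5"):
        return base ** (1.0 / params.d)
    return base


def loglik(model_id: str, params: ExpModelParams, doses, responses) -> float:
    """Exact log-normal log-likelihood: ln y_i ~ N(ln f(x_i), sigma^2).

    Includes the -sum(ln y_i) Jacobian of the log transform, so this is the
    density of y itself; the term is constant across models on the same data
    and cancels in every likelihood ratio.
    """
    if params.sigma is None:
        raise ContractError("loglik requires params.sigma")
    y = np.asarray(responses, dtype=float)
    if np.any(y <= 0):
        raise ContractError("responses must be strictly positive")
    x = np.asarray(doses, dtype=float)
    mu = np.log(evaluate(model_id, params, x))
    r = np.log(y) - mu
    n = y.size
    s2 = params.sigma ** 2
    return float(
        -0.5 * n * math.log(2.0 * math.pi * s2)
        - 0.5 * np.sum(r ** 2) / s2
        - np.sum(np.log(y))
    )
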