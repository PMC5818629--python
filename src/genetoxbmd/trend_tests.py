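"""Overall dose-effect testing and per-dose-vs-control contrasts.

Counts are modelled as Poisson with a log link and the log denominator as
offset; dose enters as a categorical factor.  For that saturated-by-group
design the MLE is available in closed form (each group's rate is its total
count over its total denominator), so the likelihood-ratio statistics below
are exact:

- overall: full categorical model vs intercept-only,
  LR = 2 * sum_g C_g * ln(rate_g / rate_pooled), df = (#groups - 1);
- contrast of dose g vs control: full model vs the model constraining
  group g's rate to equal the control rate (their totals pool), df = 1.

Continuous endpoints (DNA adduct frequencies) are converted to integer
per-animal counts by rounding the response on its reporting denominator
(one unit of 10^8 nucleotides per animal), then tested the same way.

Significance tiers follow the reporting convention
a: p < 0.0001, b: p < 0.001, c: p < 0.01, d: p < 0.05, ns otherwise.
No multiplicity adjustment is applied across contrasts (raw tiered
p-values are reported per dose).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datamodel import DoseResponseDataset
from .errors import ContractError, ValidationError

TIERS = (("a", 1e-4), ("b", 1e-3), ("c", 1e-2), ("d", 5e-2))


def significance_tier(p: float) -> str:
    for tier, cutoff in TIERS:
        if p < cutoff:
            return tier
    return "ns"


@dataclass(frozen=True)
class DoseContrast:
    dose: float
    lr_stat: float
    p: float
    tier: str

    def to_dict(self) -> dict:
        return {"dose": self.dose, "lr_stat": self.lr_stat, "p": self.p, "tier": self.tier}


@dataclass(frozen=True)
class TrendTestResult:
    tissue: str
    endpoint: str
    overall_stat: float
    overall_df: int
    overall_p: float
    contrasts: tuple[DoseContrast, ...]

    def to_dict(self) -> dict:
        return {
            "tissue": self.tissue,
            "endpoint": self.endpoint,
            "overall_stat": self.overall_stat,
            "overall_df": self.overall_df,
            "overall_p": self.overall_p,
            "contrasts": [c.to_dict() for c in self.contrasts],
        }


# ---------------------------------------------------------------------------
# Count extraction
# ---------------------------------------------------------------------------

def _counts_and_denoms(ds) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-animal (dose, count, denominator) arrays for Poisson testing."""
    if isinstance(ds, DoseResponseDataset):
        doses = ds.doses()
        if ds.is_count:
            counts = np.array([r.count for r in ds.records], dtype=float)
            denoms = np.array([r.denominator for r in ds.records], dtype=float)
        else:
            # continuous responses are frequencies per one reporting unit of
            # denominator; reconstruct integer counts on that unit
            counts = np.array(
                [round(r.response) for r in ds.records], dtype=float
            )
            denoms = np.ones_like(counts)
        return doses, counts, denoms
    doses, counts, denoms = ds
    return (
        np.asarray(doses, dtype=float),
        np.asarray(counts, dtype=float),
        np.asarray(denoms, dtype=float),
    )


def _group_totals(
    doses: np.ndarray, counts: np.ndarray, denoms: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    levels = np.unique(doses)
    C = np.array([counts[doses == g].sum() for g in levels])
    D = np.array([denoms[doses == g].sum() for g in levels])
    if np.any(D <= 0):
        bad = levels[D <= 0]
        raise ValidationError(f"dose group(s) {bad.tolist()} have zero total denominator")
    return levels, C, D


def _xlogy(c: np.ndarray, ratio: np.ndarray) -> float:
    # c * ln(ratio) with the 0*ln(0) = 0 convention
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(c > 0, c * np.log(np.where(c > 0, ratio, 1.0)), 0.0)
    return float(np.sum(terms))


def overall_trend_test(ds) -> TrendTestResult:
    """Type-3-style LR chi-square for any dose effect, plus all contrasts.

    ``ds`` is a :class:`DoseResponseDataset` or a ``(doses, counts,
    denominators)`` triple.
    """
    doses, counts, denoms = _counts_and_denoms(ds)
    levels, C, D = _group_totals(doses, counts, denoms)
    if levels.size < 2:
        raise ContractError("need at least two dose groups")
    pooled = C.sum() / D.sum()
    rates = C / D
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(C > 0, rates / pooled, 1.0)
    stat = 2.0 * _xlogy(C, ratio)
    df = levels.size - 1
    p = float(stats.chi2.sf(stat, df))
    contrasts = tuple(
        _contrast(levels, C, D, g) for g in levels if g != levels.min()
    )
    tissue = ds.tissue if isinstance(ds, DoseResponseDataset) else ""
    endpoint = ds.endpoint if isinstance(ds, DoseResponseDataset) else ""
    return TrendTestResult(
        tissue=tissue,
        endpoint=endpoint,
        overall_stat=max(stat, 0.0),
        overall_df=df,
        overall_p=p,
        contrasts=contrasts,
    )


def _contrast(
    levels: np.ndarray, C: np.ndarray, D: np.ndarray, dose: float
) -> DoseContrast:
    i0 = int(np.argmin(levels))
    ig = int(np.nonzero(levels == dose)[0][0])
    c0, d0 = C[i0], D[i0]
    cg, dg = C[ig], D[ig]
    pooled = (c0 + cg) / (d0 + dg)
    stat = 2.0 * (
        _xlogy(np.array([c0]), np.array([(c0 / d0) / pooled if c0 > 0 else 1.0]))
        + _xlogy(np.array([cg]), np.array([(cg / dg) / pooled if cg > 0 else 1.0]))
    )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, 1))
    return DoseContrast(dose=float(dose), lr_stat=stat, p=p, tier=significance_tier(p))


def dose_vs_control_contrast(ds, dose: float) -> DoseContrast:
    """LR contrast of one nonzero dose group against the control group (df=1)."""
    doses, counts, denoms = _counts_and_denoms(ds)
    levels, C, D = _group_totals(doses, counts, denoms)
    if dose == levels.min():
        raise ContractError("contrast dose must be a nonzero level, not the control")
    if dose not in levels:
        raise ContractError(f"dose {dose} not present in dataset (levels: {levels.tolist()})")
    return _contrast(levels, C, D, dose)
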