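"""Sensitivity ranking and cross-endpoint comparisons built on BMD CIs.

The comparative logic follows the confidence-interval convention for potency
ranking: two BMDs are *distinguishable* exactly when their BMDL-BMDU
intervals do not overlap; estimates are ordered by the geometric midpoint
sqrt(BMDL * BMDU); and adjacent estimates whose intervals overlap are chained
into a common sensitivity group (transitive closure in midpoint order).

The proportionality analysis quantifies the double-log unity-slope
construction: tissue-matched BMDs for two endpoints are proportional when a
slope-1 line fits the (log10 x, log10 y) scatter as well as an unconstrained
line; the offset of the slope-1 line is the mean paired log10 difference and
10^offset the proportionality constant.  Adequacy of the unity slope is an
F-test on the extra residual sum of squares of the constrained fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import ContractError
from .profile_ci import BmdEstimate


@dataclass(frozen=True)
class RankingResult:
    """Tissues ordered by CI geometric midpoint, with pairwise separability."""

    ordered: tuple[BmdEstimate, ...]
    distinguishable: np.ndarray  # boolean, aligned with `ordered`
    groups: tuple[tuple[str, ...], ...]  # ordered partition of tissue labels

    def order_labels(self) -> tuple[str, ...]:
        return tuple(e.tissue for e in self.ordered)

    def to_dict(self) -> dict:
        return {
            "order": list(self.order_labels()),
            "midpoints": [e.midpoint for e in self.ordered],
            "groups": [list(g) for g in self.groups],
            "distinguishable": self.distinguishable.tolist(),
        }


def rank_tissues(estimates: Sequence[BmdEstimate]) -> RankingResult:
    """Rank >= 2 same-endpoint estimates by geometric CI midpoint.

    Estimates flagged with an unbounded BMDU sort after all bounded ones.
    """
    if len(estimates) < 2:
        raise ContractError("ranking needs at least two estimates")
    endpoints = {e.endpoint for e in estimates}
    if len(endpoints) > 1:
        raise ContractError(
            f"rank_tissues requires a single endpoint, got {sorted(endpoints)}"
        )
    ordered = tuple(
        sorted(estimates, key=lambda e: (e.bmdu_unbounded, e.midpoint, e.tissue))
    )
    n = len(ordered)
    dist = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = not ordered[i].overlaps(ordered[j])
    groups: list[list[str]] = [[ordered[0].tissue]]
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.overlaps(prev):
            groups[-1].append(cur.tissue)
        else:
            groups.append([cur.tissue])
    return RankingResult(
        ordered=ordered,
        distinguishable=dist,
        groups=tuple(tuple(g) for g in groups),
    )


@dataclass(frozen=True)
class EndpointComparison:
    """Per-endpoint summary sorted by midpoint (lowest-BMD endpoint first)."""

    endpoint: str
    bmd: float
    bmdl: float
    bmdu: float
    midpoint: float
    max_response_c: float | None  # absent for models without an asymptote

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "bmd": self.bmd,
            "bmdl": self.bmdl,
            "bmdu": self.bmdu,
            "midpoint": self.midpoint,
            "max_response_c": self.max_response_c,
        }


def compare_endpoints(
    estimates_by_endpoint: Mapping[str, BmdEstimate]
) -> tuple[EndpointComparison, ...]:
    """Cross-endpoint ordering of BMDs sharing a tissue/compartment.

    Reports each endpoint's CI range and, where the selected model saturates,
    the maximum-response multiple c.
    """
    if not estimates_by_endpoint:
        raise ContractError("no estimates supplied")
    out = [
        EndpointComparison(
            endpoint=ep,
            bmd=e.bmd,
            bmdl=e.bmdl,
            bmdu=e.bmdu,
            midpoint=e.midpoint,
            max_response_c=e.max_response_c,
        )
        for ep, e in estimates_by_endpoint.items()
    ]
    return tuple(sorted(out, key=lambda s: s.midpoint))


@dataclass(frozen=True)
class ProportionalityResult:
    pairs: tuple[tuple[str, BmdEstimate, BmdEstimate], ...]
    log10_offset: float
    proportionality_constant: float
    slope_free: float
    intercept_free: float
    rss_unity: float
    rss_free: float
    f_stat: float
    f_p: float
    unity_adequate: bool

    def to_dict(self) -> dict:
        return {
            "tissues": [t for t, _, _ in self.pairs],
            "log10_offset": self.log10_offset,
            "proportionality_constant": self.proportionality_constant,
            "slope_free": self.slope_free,
            "f_stat": self.f_stat,
            "f_p": self.f_p,
            "unity_adequate": self.unity_adequate,
        }


def proportionality(
    estimates_x: Sequence[BmdEstimate],
    estimates_y: Sequence[BmdEstimate],
    alpha: float = 0.05,
    weighted: bool = False,
) -> ProportionalityResult:
    """Unity-slope analysis of tissue-matched BMDs on double-log axes.

    The offset of the slope-1 line is the (optionally precision-weighted)
    mean of log10(bmd_y) - log10(bmd_x); the free-slope line is ordinary
    least squares; the unity slope is adequate when its extra residual sum
    of squares is not significant at ``alpha`` by an F(1, n-2) test.
    ``weighted`` uses 1/log10(BMDU/BMDL)^2 pair weights for the offset
    (CI widths are displayed, not used, in the unweighted default).
    """
    by_x = {e.tissue: e for e in estimates_x}
    by_y = {e.tissue: e for e in estimates_y}
    if set(by_x) != set(by_y):
        raise ContractError(
            "tissue mismatch between endpoints: "
            f"only-x={sorted(set(by_x) - set(by_y))}, "
            f"only-y={sorted(set(by_y) - set(by_x))}"
        )
    tissues = sorted(by_x)
    if len(tissues) < 3:
        raise ContractError("proportionality needs >= 3 matched tissues")
    pairs = tuple((t, by_x[t], by_y[t]) for t in tissues)
    lx = np.array([math.log10(by_x[t].bmd) for t in tissues])
    ly = np.array([math.log10(by_y[t].bmd) for t in tissues])

    diffs = ly - lx
    if weighted:
        w = np.array(
            [
                1.0
                / max(
                    math.log10(by_x[t].precision_ratio) ** 2
                    + math.log10(by_y[t].precision_ratio) ** 2,
                    1e-12,
                )
                for t in tissues
            ]
        )
        offset = float(np.sum(w * diffs) / np.sum(w))
    else:
        offset = float(np.mean(diffs))

    # free fit: OLS of log10 y on log10 x
    slope, intercept = np.polyfit(lx, ly, 1)
    rss_free = float(np.sum((ly - (slope * lx + intercept)) ** 2))
    # unity fit: slope fixed at 1, LS intercept = unweighted mean difference
    unity_intercept = float(np.mean(diffs))
    rss_unity = float(np.sum((ly - (lx + unity_intercept)) ** 2))

    n = len(tissues)
    dof = n - 2
    if rss_free <= 1e-14 * max(rss_unity, 1.0):
        # degenerate exact fit: unity adequate iff it is (numerically) as exact
        f_stat = math.inf if rss_unity > 1e-12 else 0.0
        f_p = 0.0 if rss_unity > 1e-12 else 1.0
    else:
        f_stat = max(rss_unity - rss_free, 0.0) / (rss_free / dof)
        f_p = float(stats.f.sf(f_stat, 1, dof))
    return ProportionalityResult(
        pairs=pairs,
        log10_offset=offset,
        proportionality_constant=10.0 ** offset,
        slope_free=float(slope),
        intercept_free=float(intercept),
        rss_unity=rss_unity,
        rss_free=rss_free,
        f_stat=float(f_stat),
        f_p=f_p,
        unity_adequate=bool(f_p >= alpha),
    )


@dataclass(frozen=True)
class Ki67Correlation:
    tissues: tuple[str, ...]
    r: float
    p: float
    n: int
    log_scale: bool
    degenerate: bool
    caveat: str = (
        "correlation based on very few tissues (n >= 3 but small); "
        "interpret as supporting evidence only"
    )

    def to_dict(self) -> dict:
        return {
            "tissues": list(self.tissues),
            "r": None if self.degenerate else self.r,
            "p": None if self.degenerate else self.p,
            "n": self.n,
            "log_scale": self.log_scale,
            "degenerate": self.degenerate,
            "caveat": self.caveat,
        }


def ki67_correlation(
    ki67: Mapping[str, float],
    estimates_x: Sequence[BmdEstimate],
    estimates_y: Sequence[BmdEstimate],
    log_scale: bool = False,
) -> Ki67Correlation:
    """Pearson correlation of the Ki-67 proliferation index against the
    per-tissue BMD ratio bmd_x / bmd_y (e.g. adduct BMD over mutation BMD).

    ``log_scale`` correlates against log10 of the ratio.  A zero-variance
    ratio (or index) yields a flagged degenerate result rather than NaN
    propagation.
    """
    by_x = {e.tissue: e for e in estimates_x}
    by_y = {e.tissue: e for e in estimates_y}
    tissues = sorted(set(ki67) & set(by_x) & set(by_y))
    if len(tissues) < 3:
        raise ContractError(
            f"ki67_correlation needs >= 3 matched tissues, got {len(tissues)}"
        )
    ratio = np.array([by_x[t].bmd / by_y[t].bmd for t in tissues])
    if log_scale:
        ratio = np.log10(ratio)
    idx = np.array([ki67[t] for t in tissues], dtype=float)
    if np.ptp(ratio) == 0 or np.ptp(idx) == 0:
        return Ki67Correlation(
            tissues=tuple(tissues), r=math.nan, p=math.nan, n=len(tissues),
            log_scale=log_scale, degenerate=True,
        )
    r, p = stats.pearsonr(idx, ratio)
    return Ki67Correlation(
        tissues=tuple(tissues), r=float(r), p=float(p), n=len(tissues),
        log_scale=log_scale, degenerate=False,
    )
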