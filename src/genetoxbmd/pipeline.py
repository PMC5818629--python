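"""End-to-end orchestration: fit -> select -> BMD+CI -> trend -> rank -> compare.

``run_pipeline`` takes any number of tissue x endpoint datasets, runs the
whole analysis with one configuration, and (optionally) writes the report
bundle — CSV/JSON tables, plots and a run log — to an output directory.
Datasets that fail validation are skipped with a logged reason; the run
fails only if nothing remains.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .compare_rank import (
    EndpointComparison,
    ProportionalityResult,
    RankingResult,
    compare_endpoints,
    proportionality,
    rank_tissues,
)
from .datamodel import DoseResponseDataset, ZeroRule
from .errors import ContractError, GenetoxBmdError
from .exp_family import BmrSpec
from .fit_select import SelectionResult, select_model
from .profile_ci import BmdEstimate, NoBmdResult, estimate_bmd
from .trend_tests import TrendTestResult, overall_trend_test


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration (defaults follow the study conventions:
    CES 1.0 i.e. a two-fold benchmark response, two-sided 90% CI,
    LRT acceptance at p < 0.05)."""

    ces: float = 1.0
    ci_level: float = 0.90
    lrt_alpha: float = 0.05
    zero_rule: ZeroRule = "half-minimum"
    seed: int = 0
    proportionality_pairs: tuple[tuple[str, str], ...] = (("dna_adducts", "lacz_mf"),)
    weighted_proportionality: bool = False
    make_plots: bool = False

    def __post_init__(self):
        if not self.ces > 0:
            raise ContractError("ces must be > 0")
        if not 0 < self.ci_level < 1:
            raise ContractError("ci_level must lie in (0, 1)")
        if not 0 < self.lrt_alpha < 1:
            raise ContractError("lrt_alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "ces": self.ces,
            "ci_level": self.ci_level,
            "lrt_alpha": self.lrt_alpha,
            "zero_rule": self.zero_rule,
            "seed": self.seed,
            "proportionality_pairs": [list(p) for p in self.proportionality_pairs],
            "weighted_proportionality": self.weighted_proportionality,
        }


@dataclass
class ReportBundle:
    config: RunConfig
    selections: dict[str, SelectionResult]
    estimates: dict[str, BmdEstimate | NoBmdResult]
    trend_results: dict[str, TrendTestResult]
    rankings: dict[str, RankingResult]
    comparisons: dict[str, tuple[EndpointComparison, ...]]
    proportionality: dict[str, ProportionalityResult]
    skipped: dict[str, str]

    def bmd_table(self) -> pd.DataFrame:
        """Supplementary-table layout: tissue, endpoint, BMD, BMDL, BMDU, ratio."""
        rows = []
        for key in sorted(self.estimates):
            e = self.estimates[key]
            if isinstance(e, NoBmdResult):
                rows.append(
                    {
                        "tissue": e.tissue,
                        "endpoint": e.endpoint,
                        "model": e.model_id,
                        "bmd": math.nan,
                        "bmdl": math.nan,
                        "bmdu": math.nan,
                        "bmdu_bmdl_ratio": math.nan,
                        "note": e.reason,
                    }
                )
            else:
                rows.append(
                    {
                        "tissue": e.tissue,
                        "endpoint": e.endpoint,
                        "model": e.model_id,
                        "bmd": e.bmd,
                        "bmdl": e.bmdl,
                        "bmdu": e.bmdu,
                        "bmdu_bmdl_ratio": e.precision_ratio,
                        "note": "bmdu_unbounded" if e.bmdu_unbounded else "",
                    }
                )
        return pd.DataFrame(rows)

    def trend_table(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.trend_results):
            t = self.trend_results[key]
            for c in t.contrasts:
                rows.append(
                    {
                        "tissue": t.tissue,
                        "endpoint": t.endpoint,
                        "overall_stat": t.overall_stat,
                        "overall_df": t.overall_df,
                        "overall_p": t.overall_p,
                        "dose": c.dose,
                        "lr_stat": c.lr_stat,
                        "p": c.p,
                        "tier": c.tier,
                    }
                )
        return pd.DataFrame(rows)


def run_pipeline(
    datasets: Sequence[DoseResponseDataset],
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> ReportBundle:
    selections: dict[str, SelectionResult] = {}
    estimates: dict[str, BmdEstimate | NoBmdResult] = {}
    trends: dict[str, TrendTestResult] = {}
    skipped: dict[str, str] = {}

    for ds in datasets:
        key = ds.key()
        try:
            sel = select_model(
                ds, alpha=config.lrt_alpha, seed=config.seed, zero_rule=config.zero_rule
            )
            est = estimate_bmd(
                sel,
                ds,
                ces=config.ces,
                level=config.ci_level,
                zero_rule=config.zero_rule,
            )
            trd = overall_trend_test(ds)
        except GenetoxBmdError as exc:
            skipped[key] = str(exc)
            continue
        selections[key] = sel
        estimates[key] = est
        trends[key] = trd

    if not estimates:
        raise ContractError(
            "all datasets failed; reasons: " + json.dumps(skipped, indent=2)
        )

    ok = {k: e for k, e in estimates.items() if isinstance(e, BmdEstimate)}

    rankings: dict[str, RankingResult] = {}
    by_endpoint: dict[str, list[BmdEstimate]] = {}
    for e in ok.values():
        by_endpoint.setdefault(e.endpoint, []).append(e)
    for ep, ests in sorted(by_endpoint.items()):
        if len(ests) >= 2:
            rankings[ep] = rank_tissues(ests)

    comparisons: dict[str, tuple[EndpointComparison, ...]] = {}
    by_tissue: dict[str, dict[str, BmdEstimate]] = {}
    for e in ok.values():
        by_tissue.setdefault(e.tissue, {})[e.endpoint] = e
    for tis, eps in sorted(by_tissue.items()):
        if len(eps) >= 2:
            comparisons[tis] = compare_endpoints(eps)

    props: dict[str, ProportionalityResult] = {}
    for ep_x, ep_y in config.proportionality_pairs:
        ex = by_endpoint.get(ep_x, [])
        ey = by_endpoint.get(ep_y, [])
        shared = {e.tissue for e in ex} & {e.tissue for e in ey}
        if len(shared) >= 3:
            props[f"{ep_x}_vs_{ep_y}"] = proportionality(
                [e for e in ex if e.tissue in shared],
                [e for e in ey if e.tissue in shared],
                weighted=config.weighted_proportionality,
            )

    bundle = ReportBundle(
        config=config,
        selections=selections,
        estimates=estimates,
        trend_results=trends,
        rankings=rankings,
        comparisons=comparisons,
        proportionality=props,
        skipped=skipped,
    )
    if outdir is not None:
        write_report(bundle, outdir)
    return bundle


def write_report(bundle: ReportBundle, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.bmd_table().to_csv(out / "bmd_table.csv", index=False)
    bundle.trend_table().to_csv(out / "trend_tests.csv", index=False)
    for ep, rk in bundle.rankings.items():
        (out / f"ranking_{ep}.json").write_text(json.dumps(rk.to_dict(), indent=2))
    for tis, cmp_ in bundle.comparisons.items():
        (out / f"comparison_{tis}.json").write_text(
            json.dumps([c.to_dict() for c in cmp_], indent=2)
        )
    for name, pr in bundle.proportionality.items():
        (out / f"proportionality_{name}.json").write_text(
            json.dumps(pr.to_dict(), indent=2)
        )
    log = {
        "package_version": __version__,
        "config": bundle.config.to_dict(),
        "datasets": sorted(bundle.estimates),
        "skipped": bundle.skipped,
        "selected_models": {
            k: s.selected for k, s in sorted(bundle.selections.items())
        },
        "ladder_traces": {
            k: [st.to_dict() for st in s.ladder_trace]
            for k, s in sorted(bundle.selections.items())
        },
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    if bundle.config.make_plots:
        plot_report(bundle, out)


# ---------------------------------------------------------------------------
# Plots (forest-style CI plot; double-log proportionality scatter)
# ---------------------------------------------------------------------------

def plot_forest(ranking: RankingResult, ax=None, title: str = ""):
    """BMD 90% CIs on a log10 axis, ordered by geometric midpoint."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(ranking.ordered) + 1.5))
    for i, e in enumerate(reversed(ranking.ordered)):
        ax.plot([e.bmdl, e.bmdu], [i, i], "-", color="tab:blue", lw=2)
        ax.plot([e.bmd], [i], "o", color="tab:blue")
    ax.set_yticks(range(len(ranking.ordered)))
    ax.set_yticklabels([e.tissue for e in reversed(ranking.ordered)])
    ax.set_xscale("log")
    ax.set_xlabel("BMD (mg/kg BW/day), 90% CI")
    if title:
        ax.set_title(title)
    return ax


def plot_proportionality(result: ProportionalityResult, ax=None, title: str = ""):
    """Double-log scatter of paired BMDs with the fitted unity-slope line."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import numpy as np

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for tissue, ex, ey in result.pairs:
        ax.plot(
            [ex.bmdl, ex.bmdu], [ey.bmd, ey.bmd], "-", color="0.7", lw=1
        )
        ax.plot(
            [ex.bmd, ex.bmd], [ey.bmdl, ey.bmdu], "-", color="0.7", lw=1
        )
        ax.plot([ex.bmd], [ey.bmd], "o", color="tab:red")
        ax.annotate(tissue, (ex.bmd, ey.bmd), fontsize=7)
    xs = np.array([ex.bmd for _, ex, _ in result.pairs])
    grid = np.geomspace(xs.min() / 3, xs.max() * 3, 50)
    ax.plot(grid, grid * result.proportionality_constant, "k--", lw=1,
            label=f"unity slope (x {result.proportionality_constant:.2g})")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.legend(fontsize=8)
    if title:
        ax.set_title(title)
    return ax


def plot_report(bundle: ReportBundle, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    for ep, rk in bundle.rankings.items():
        ax = plot_forest(rk, title=ep)
        ax.figure.tight_layout()
        ax.figure.savefig(outdir / f"forest_{ep}.svg")
        plt.close(ax.figure)
    for name, pr in bundle.proportionality.items():
        ax = plot_proportionality(pr, title=name)
        ax.figure.tight_layout()
        ax.figure.savefig(outdir / f"proportionality_{name}.svg")
        plt.close(ax.figure)
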