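"""Seeded generator of study-like dose-response datasets.

Emulates a 28-day oral gavage design: 11 dose levels from 0 to 50 mg/kg
BW/day on a doubling grid, 7 animals per treated group and 14 vehicle
controls (84 animals).  Each animal's expected response follows a saturating
exponential mean curve times a log-normal between-animal biological factor;
the measurement layer is endpoint-appropriate:

- ``continuous_lognormal`` (DNA adduct frequency): multiplicative log-normal
  measurement noise on the mean;
- ``poisson_count`` (lacZ and Pig-a mutant frequencies): mutant count ~
  Poisson(frequency * denominator), denominator = total pfu / cells
  interrogated, drawn per animal;
- ``binomial_count`` (micronuclei): count ~ Binomial(cells scored, fraction).

Presets anchor the maximum-response multiple c to the fold-change scale each
endpoint showed (e.g. spleen adducts ~506-fold, small-intestine lacZ
~208-fold, MN-RET ~4.5-fold) and place the true benchmark doses so that the
qualitative structure of the study is reproducible: the lacZ three-group
tissue ranking (SI < {BM, Sp} < {Kd, Lv, Lg, GS}) and the hematopoietic
progression BMD(adducts) < BMD(mutation) < BMD(MN).  Assay denominators are
plausible conventions (total pfu 2-5e5, Pig-a RET ~3e5 / RBC ~3e6 cells,
MN 2e4 cells scored), not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .datamodel import ENDPOINTS, AnimalRecord, DoseResponseDataset
from .errors import ContractError, ValidationError
from .exp_family import BmrSpec, ExpModelParams, bmd_closed_form, evaluate

STUDY_DOSES = (0.0, 0.10, 0.20, 0.39, 0.78, 1.56, 3.13, 6.25, 12.50, 25.00, 50.00)


@dataclass(frozen=True)
class StudyDesign:
    """Dose grid and group sizes (defaults: the 11-dose, 84-animal design)."""

    doses: tuple[float, ...] = STUDY_DOSES
    n_per_dose: int = 7
    n_control: int = 14

    def __post_init__(self):
        d = self.doses
        if not d or d[0] != 0.0:
            raise ValidationError("dose grid must start at 0 (vehicle control)")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValidationError("doses must be strictly increasing")
        if self.n_per_dose < 1 or self.n_control < 1:
            raise ValidationError("group sizes must be positive")

    def group_sizes(self) -> list[tuple[float, int]]:
        return [
            (x, self.n_control if x == 0.0 else self.n_per_dose) for x in self.doses
        ]

    @property
    def n_animals(self) -> int:
        return self.n_control + self.n_per_dose * (len(self.doses) - 1)


@dataclass(frozen=True)
class DenominatorSampler:
    """Per-animal assay denominator, uniform on [low, high] (low = high: fixed)."""

    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low <= self.high):
            raise ValidationError("denominator bounds must satisfy 0 < low <= high")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.low == self.high:
            return np.full(n, float(self.low))
        return np.round(rng.uniform(self.low, self.high, size=n))


EndpointKind = Literal["continuous_lognormal", "poisson_count", "binomial_count"]


@dataclass(frozen=True)
class EndpointModel:
    """True data-generating process for one tissue x endpoint."""

    endpoint: str
    tissue: str
    kind: EndpointKind
    model_id: str  # family member of the true mean curve
    true_params: ExpModelParams  # a on the natural measurement scale
    biological_cv: float = 0.2  # extra log-normal between-animal SD (ln scale)
    denominator_sampler: DenominatorSampler | None = None

    def __post_init__(self):
        if self.kind not in ("continuous_lognormal", "poisson_count", "binomial_count"):
            raise ContractError(f"unknown endpoint kind {self.kind!r}")
        if self.kind != "continuous_lognormal" and self.denominator_sampler is None:
            raise ContractError("count endpoints need a denominator_sampler")
        if self.kind == "continuous_lognormal" and self.true_params.sigma is None:
            raise ContractError("continuous endpoints need true_params.sigma")
        if self.biological_cv < 0:
            raise ContractError("biological_cv must be >= 0")

    def mean_curve(self, x) -> np.ndarray:
        return np.asarray(evaluate(self.model_id, self.true_params, x))

    def true_bmd(self, ces: float = 1.0) -> float:
        return bmd_closed_form(self.model_id, self.true_params, BmrSpec(ces))


def generate(
    design: StudyDesign, endpoint: EndpointModel, seed: int
) -> DoseResponseDataset:
    """Simulate one dataset; byte-identical for identical seeds."""
    rng = np.random.default_rng(seed)
    records: list[AnimalRecord] = []
    k = 0
    for dose, n in design.group_sizes():
        mu = float(endpoint.mean_curve(dose))
        bio = np.exp(rng.normal(0.0, endpoint.biological_cv, size=n)) \
            if endpoint.biological_cv > 0 else np.ones(n)
        if endpoint.kind == "continuous_lognormal":
            sig = endpoint.true_params.sigma
            noise = np.exp(rng.normal(0.0, sig, size=n)) if sig > 0 else np.ones(n)
            vals = mu * bio * noise
            for v in vals:
                k += 1
                records.append(
                    AnimalRecord(animal_id=f"a{k:03d}", dose=dose, response=float(v))
                )
        else:
            denoms = endpoint.denominator_sampler.draw(rng, n)
            freq = mu * bio
            if endpoint.kind == "binomial_count":
                if np.any(freq > 1.0):
                    raise ContractError(
                        "binomial endpoint produced per-cell fraction > 1; "
                        "check the mean curve scale"
                    )
                counts = rng.binomial(denoms.astype(np.int64), freq)
            else:
                counts = rng.poisson(freq * denoms)
                counts = np.minimum(counts, denoms.astype(np.int64))
            for cnt, den in zip(counts, denoms):
                k += 1
                records.append(
                    AnimalRecord(
                        animal_id=f"a{k:03d}",
                        dose=dose,
                        count=int(cnt),
                        denominator=float(den),
                    )
                )
    return DoseResponseDataset(
        tissue=endpoint.tissue, endpoint=endpoint.endpoint, records=tuple(records)
    )


# ---------------------------------------------------------------------------
# Preset registry: one generator configuration per tissue x endpoint studied
# ---------------------------------------------------------------------------

def _rate_for_bmd(c: float, bmd: float, ces: float = 1.0) -> float:
    """Solve b so the saturating curve a*(c-(c-1)exp(-b x)) has the given BMD."""
    if c <= 1.0 + ces:
        raise ContractError("asymptote c must exceed 1+ces")
    return math.log((c - 1.0) / (c - 1.0 - ces)) / bmd


def _continuous(tissue: str, a: float, c: float, bmd: float, sigma: float = 0.25,
                bio_cv: float = 0.2) -> EndpointModel:
    return EndpointModel(
        endpoint="dna_adducts",
        tissue=tissue,
        kind="continuous_lognormal",
        model_id="m4",
        true_params=ExpModelParams(a=a, b=_rate_for_bmd(c, bmd), c=c, sigma=sigma),
        biological_cv=bio_cv,
    )


def _poisson(endpoint: str, tissue: str, a: float, c: float, bmd: float,
             denom: DenominatorSampler, bio_cv: float = 0.2) -> EndpointModel:
    return EndpointModel(
        endpoint=endpoint,
        tissue=tissue,
        kind="poisson_count",
        model_id="m4",
        true_params=ExpModelParams(a=a, b=_rate_for_bmd(c, bmd), c=c),
        biological_cv=bio_cv,
        denominator_sampler=denom,
    )


def _binomial(endpoint: str, tissue: str, a: float, c: float, bmd: float,
              denom: DenominatorSampler, bio_cv: float = 0.15) -> EndpointModel:
    return EndpointModel(
        endpoint=endpoint,
        tissue=tissue,
        kind="binomial_count",
        model_id="m4",
        true_params=ExpModelParams(a=a, b=_rate_for_bmd(c, bmd), c=c),
        biological_cv=bio_cv,
        denominator_sampler=denom,
    )


_PFU = DenominatorSampler(2e5, 5e5)  # total pfu per animal
_RET = DenominatorSampler(2e5, 4e5)  # Pig-a RETs interrogated
_RBC = DenominatorSampler(2.5e6, 3.5e6)  # Pig-a RBCs interrogated
_MN = DenominatorSampler(2e4, 2e4)  # cells scored for micronuclei


def _build_presets() -> dict[str, EndpointModel]:
    presets: dict[str, EndpointModel] = {}
    # DNA adducts (per 10^8 nt); c anchored to top fold-changes per tissue,
    # true BMDs well below the mutation endpoints'
    for tissue, a, c, bmd in [
        ("spleen", 0.20, 506.0, 0.04),
        ("lung", 0.15, 433.0, 0.06),
        ("bladder", 0.25, 139.0, 0.08),
        ("liver", 0.40, 219.0, 0.09),
        ("bone_marrow", 0.50, 19.6, 0.10),
        ("kidney", 0.30, 187.0, 0.11),
        ("small_intestine", 0.60, 27.4, 0.18),
        ("glandular_stomach", 0.35, 46.3, 0.35),
    ]:
        presets[f"adducts_{tissue}"] = _continuous(tissue, a, c, bmd)
    # lacZ mutant frequency (background ~5e-5 per pfu); true BMDs chosen so
    # tissues fall in the three CI-separated sensitivity groups
    for tissue, c, bmd in [
        ("small_intestine", 208.0, 3.0),
        ("bone_marrow", 120.0, 7.0),
        ("spleen", 81.0, 7.2),
        ("glandular_stomach", 28.6, 23.0),
        ("lung", 14.1, 23.5),
        ("kidney", 5.0, 24.5),
        ("liver", 14.6, 25.5),
    ]:
        presets[f"lacz_{tissue}"] = _poisson("lacz_mf", tissue, 5e-5, c, bmd, _PFU)
    # Pig-a mutant phenotype (few mutants per 10^6 cells at background ->
    # low counts and wide CIs, as in the blood-cell endpoints)
    presets["piga_ret"] = _poisson(
        "piga_mf_ret", "blood_ret", 3e-6, 385.5, 8.0, _RET, bio_cv=0.3
    )
    presets["piga_rbc"] = _poisson(
        "piga_mf_rbc", "blood_rbc", 1e-6, 69.7, 9.0, _RBC, bio_cv=0.3
    )
    # micronuclei (% micronucleated); shallow dynamic range
    presets["mn_ret"] = _binomial("mn_ret", "blood_ret", 2e-3, 4.5, 16.0, _MN)
    presets["mn_nce"] = _binomial("mn_nce", "blood_nce", 1e-3, 3.7, 18.0, _MN)
    return presets


PRESETS: dict[str, EndpointModel] = _build_presets()

#: presets entering the hematopoietic cross-endpoint comparison
HEMATOPOIETIC_PRESETS = ("adducts_bone_marrow", "lacz_bone_marrow", "mn_ret")

#: tissues with a Ki-67 proliferation index in the study (synthetic stand-ins)
KI67_INDEX = {"small_intestine": 18.0, "lung": 2.4, "liver": 1.1}

LACZ_PRESETS = tuple(sorted(k for k in PRESETS if k.startswith("lacz_")))
ADDUCT_PRESETS = tuple(sorted(k for k in PRESETS if k.startswith("adducts_")))


def preset(name: str) -> tuple[StudyDesign, EndpointModel]:
    """Look up one preset; returns the default design plus its endpoint model."""
    if name not in PRESETS:
        raise ContractError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        )
    return StudyDesign(), PRESETS[name]


def generate_preset(name: str, seed: int) -> DoseResponseDataset:
    design, em = preset(name)
    return generate(design, em, seed)
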