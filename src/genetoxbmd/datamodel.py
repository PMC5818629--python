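"""Core domain types, validation and CSV I/O for dose-response datasets.

The unit of observation is one animal's measurement for one tissue x endpoint
combination.  Continuous endpoints (DNA adduct frequency) carry a positive
``response``; count endpoints (lacZ MF, Pig-a MF, micronuclei) carry a
``count`` and a positive ``denominator`` (total pfu, cells interrogated,
cells scored).  A dataset is uniformly one kind or the other.
"""

from __future__ import annotations

import dataclasses
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, SchemaError, ValidationError

#: Endpoints recognised across the package, with the scale factor that maps a
#: raw frequency (count / denominator) onto the endpoint's reporting unit.
ENDPOINTS: dict[str, dict] = {
    "dna_adducts": {
        "kind": "continuous",
        "response_units": "adducts per 10^8 nucleotides",
        "unit_scale": 1.0,
    },
    "lacz_mf": {
        "kind": "count",
        "response_units": "mutants per 10^5 pfu",
        "unit_scale": 1e5,
    },
    "piga_mf_ret": {
        "kind": "count",
        "response_units": "mutants per 10^6 RETs",
        "unit_scale": 1e6,
    },
    "piga_mf_rbc": {
        "kind": "count",
        "response_units": "mutants per 10^6 RBCs",
        "unit_scale": 1e6,
    },
    "mn_ret": {
        "kind": "count",
        "response_units": "% micronucleated RETs",
        "unit_scale": 100.0,
    },
    "mn_nce": {
        "kind": "count",
        "response_units": "% micronucleated NCEs",
        "unit_scale": 100.0,
    },
}

DOSE_UNITS = "mg/kg BW/day"

ZeroRule = Literal["half-minimum", "exclude"]


@dataclass(frozen=True)
class AnimalRecord:
    """One animal's measurement: either continuous or count-type, never both."""

    animal_id: str
    dose: float
    response: float | None = None
    count: int | None = None
    denominator: float | None = None

    def __post_init__(self):
        if self.dose < 0:
            raise ValidationError(f"animal {self.animal_id}: negative dose {self.dose}")
        has_resp = self.response is not None
        has_count = self.count is not None or self.denominator is not None
        if has_resp == has_count:
            raise ValidationError(
                f"animal {self.animal_id}: exactly one of response or "
                "count/denominator must be populated"
            )
        if has_count:
            if self.count is None or self.denominator is None:
                raise ValidationError(
                    f"animal {self.animal_id}: count and denominator must both be given"
                )
            if self.denominator <= 0:
                raise ValidationError(
                    f"animal {self.animal_id}: nonpositive denominator {self.denominator}"
                )
            if self.count < 0 or self.count > self.denominator:
                raise ValidationError(
                    f"animal {self.animal_id}: count {self.count} outside "
                    f"[0, denominator={self.denominator}]"
                )

    @property
    def is_count(self) -> bool:
        return self.count is not None


@dataclass(frozen=True)
class DoseResponseDataset:
    """Animal-level records for one tissue x endpoint combination."""

    tissue: str
    endpoint: str
    records: tuple[AnimalRecord, ...]
    dose_units: str = DOSE_UNITS
    response_units: str | None = None

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(
                f"unknown endpoint {self.endpoint!r}; expected one of {sorted(ENDPOINTS)}"
            )
        object.__setattr__(self, "records", tuple(self.records))
        if self.response_units is None:
            object.__setattr__(
                self, "response_units", ENDPOINTS[self.endpoint]["response_units"]
            )
        self._validate()

    def _validate(self) -> None:
        if not self.records:
            raise ValidationError("dataset has no records")
        kinds = {r.is_count for r in self.records}
        if len(kinds) > 1:
            raise ValidationError(
                "dataset mixes continuous and count records; must be uniform"
            )
        expected = ENDPOINTS[self.endpoint]["kind"] == "count"
        if kinds != {expected}:
            raise ValidationError(
                f"endpoint {self.endpoint} expects "
                f"{'count' if expected else 'continuous'} records"
            )
        if not expected:
            bad = [r.animal_id for r in self.records if r.response is not None and r.response <= 0]
            if bad:
                raise ValidationError(
                    "continuous responses must be strictly positive for "
                    f"log-normal modelling; offending animals: {bad}"
                )
        doses = self.dose_levels()
        if 0.0 not in doses:
            raise ValidationError("dataset must contain records at dose 0 (control)")
        if len(doses) < 3:
            raise ValidationError(
                f"at least 3 distinct dose levels required for modelling; got {len(doses)}"
            )

    @property
    def is_count(self) -> bool:
        return self.records[0].is_count

    def dose_levels(self) -> tuple[float, ...]:
        return tuple(sorted({r.dose for r in self.records}))

    def doses(self) -> np.ndarray:
        return np.array([r.dose for r in self.records], dtype=float)

    def __len__(self) -> int:
        return len(self.records)

    def key(self) -> str:
        return f"{self.tissue}:{self.endpoint}"


# ---------------------------------------------------------------------------
# CSV read / write
# ---------------------------------------------------------------------------

_BASE_COLS = {"animal_id", "dose"}


def read_datasets(path: str | Path | io.TextIOBase) -> list[DoseResponseDataset]:
    """Read a dose-response CSV, returning one dataset per tissue x endpoint.

    Expected columns: ``tissue``, ``endpoint``, ``animal_id``, ``dose`` and
    either ``response`` (continuous endpoints) or ``count`` + ``denominator``
    (count endpoints).  Rows are grouped by tissue x endpoint.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    missing = ({"tissue", "endpoint"} | _BASE_COLS) - cols
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    has_resp = "response" in cols
    has_count = {"count", "denominator"} <= cols
    if not (has_resp or has_count):
        raise SchemaError(
            "need a 'response' column or 'count' and 'denominator' columns"
        )
    datasets = []
    for (tissue, endpoint), grp in df.groupby(["tissue", "endpoint"], sort=True):
        datasets.append(_group_to_dataset(str(tissue), str(endpoint), grp))
    return datasets


def read_dataset(
    path: str | Path | io.TextIOBase,
    tissue: str | None = None,
    endpoint: str | None = None,
) -> DoseResponseDataset:
    """Read a CSV expected to contain exactly one tissue x endpoint dataset.

    ``tissue``/``endpoint`` may be supplied when the CSV lacks those columns.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    missing = _BASE_COLS - cols
    if missing:
        raise SchemaError(f"missing required columns: {sorted(missing)}")
    if "tissue" not in cols:
        if tissue is None:
            raise SchemaError("no 'tissue' column and no tissue argument supplied")
        df = df.assign(tissue=tissue)
    if "endpoint" not in cols:
        if endpoint is None:
            raise SchemaError("no 'endpoint' column and no endpoint argument supplied")
        df = df.assign(endpoint=endpoint)
    groups = df.groupby(["tissue", "endpoint"])
    if groups.ngroups != 1:
        raise SchemaError(
            f"expected a single tissue x endpoint, found {groups.ngroups}; "
            "use read_datasets() for multi-group files"
        )
    (tis, ep), grp = next(iter(groups))
    return _group_to_dataset(str(tis), str(ep), grp)


def _group_to_dataset(tissue: str, endpoint: str, df: pd.DataFrame) -> DoseResponseDataset:
    if endpoint not in ENDPOINTS:
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    kind = ENDPOINTS[endpoint]["kind"]
    problems: list[str] = []
    records: list[AnimalRecord] = []
    for idx, row in df.iterrows():
        try:
            if kind == "count":
                if pd.isna(row.get("count")) or pd.isna(row.get("denominator")):
                    problems.append(f"row {idx}: missing count/denominator")
                    continue
                rec = AnimalRecord(
                    animal_id=str(row["animal_id"]),
                    dose=float(row["dose"]),
                    count=int(row["count"]),
                    denominator=float(row["denominator"]),
                )
            else:
                if pd.isna(row.get("response")):
                    problems.append(f"row {idx}: missing response")
                    continue
                rec = AnimalRecord(
                    animal_id=str(row["animal_id"]),
                    dose=float(row["dose"]),
                    response=float(row["response"]),
                )
        except ValidationError as exc:
            problems.append(f"row {idx}: {exc}")
            continue
        records.append(rec)
    if problems:
        raise ValidationError(
            f"{tissue}/{endpoint}: invalid rows:\n  " + "\n  ".join(problems)
        )
    return DoseResponseDataset(tissue=tissue, endpoint=endpoint, records=tuple(records))


def to_frame(ds: DoseResponseDataset) -> pd.DataFrame:
    rows = []
    for r in ds.records:
        row = {
            "tissue": ds.tissue,
            "endpoint": ds.endpoint,
            "animal_id": r.animal_id,
            "dose": r.dose,
        }
        if r.is_count:
            row["count"] = r.count
            row["denominator"] = r.denominator
        else:
            row["response"] = r.response
        rows.append(row)
    return pd.DataFrame(rows)


def write_datasets(datasets: Sequence[DoseResponseDataset], path: str | Path) -> None:
    """Write datasets to a single CSV readable by :func:`read_datasets`."""
    pd.concat([to_frame(ds) for ds in datasets], ignore_index=True).to_csv(
        path, index=False
    )


def write_dataset(ds: DoseResponseDataset, path: str | Path) -> None:
    to_frame(ds).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Adapter: per-animal positive response series for log-normal BMD modelling
# ---------------------------------------------------------------------------

def to_modelling_response(
    ds: DoseResponseDataset, zero_rule: ZeroRule = "half-minimum"
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(doses, responses)`` with strictly positive responses.

    Continuous endpoints pass through.  Count endpoints are converted to
    frequencies scaled to the endpoint's reporting unit (e.g. mutants per
    10^5 pfu).  Zero counts are handled per ``zero_rule``:

    - ``"half-minimum"`` (default): replaced by half the smallest nonzero
      per-animal value in the same dataset;
    - ``"exclude"``: dropped (raises if that empties a dose group).
    """
    if not ds.is_count:
        doses = ds.doses()
        resp = np.array([r.response for r in ds.records], dtype=float)
        return doses, resp
    scale = ENDPOINTS[ds.endpoint]["unit_scale"]
    doses = ds.doses()
    raw = np.array(
        [r.count / r.denominator * scale for r in ds.records], dtype=float
    )
    if (raw > 0).all():
        return doses, raw
    nonzero = raw[raw > 0]
    if nonzero.size == 0:
        raise ValidationError("all counts are zero; no positive response to model")
    if zero_rule == "half-minimum":
        return doses, np.where(raw > 0, raw, nonzero.min() / 2.0)
    if zero_rule == "exclude":
        keep = raw > 0
        kept_levels = set(np.unique(doses[keep]))
        lost = sorted(set(np.unique(doses)) - kept_levels)
        if lost:
            raise ValidationError(
                f"zero-rule 'exclude' would empty dose group(s) {lost}; "
                "use the 'half-minimum' rule"
            )
        return doses[keep], raw[keep]
    raise ContractError(f"unknown zero rule {zero_rule!r}")
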