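"""Reading, writing and validation of qPCR Ct tables, patient cohort tables,
and the JSON analysis report.

CSV dialect: comma-separated, UTF-8, first row is the header. In Ct tables the
strings ``NA`` and ``Undetermined`` (and an empty cell) denote a reaction that
never crossed the detection threshold and map to the no-amplification sentinel
(NaN). Reals are serialized with Python's shortest round-trip representation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, MiripIOError, ValidationError

#: Sentinel Ct for a reaction with no detectable amplification.
NO_AMPLIFICATION: float = math.nan

CT_CONDITIONS = frozenset(
    {"input", "IP-IgG", "IP-m6A", "IP-GW182", "IP-TNRC6B", "sample", "reference"}
)

CT_COLUMNS = ["sample_id", "target_id", "condition", "ct", "replicate"]
COHORT_COLUMNS = [
    "patient_id",
    "mir_exp",
    "pct_m6a",
    "akg_level",
    "fto_level",
    "mettl3_level",
    "xiap_level",
    "devdase_activity",
    "surv_time",
    "event",
]
COHORT_OPTIONAL_COLUMNS = ["group", "signature", "afm_score"]

#: Strings in a Ct cell meaning "no amplification".
_NO_AMP_STRINGS = {"NA", "Undetermined", ""}


def is_no_amplification(ct: float) -> bool:
    """True iff *ct* is the no-amplification sentinel."""
    return isinstance(ct, float) and math.isnan(ct)


@dataclass(frozen=True)
class QpcrMeasurement:
    """One Ct reading for a (sample, target, condition, replicate) well."""

    sample_id: str
    target_id: str
    condition: str
    ct: float
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in CT_CONDITIONS:
            raise ValidationError(
                f"unknown qPCR condition {self.condition!r}; "
                f"expected one of {sorted(CT_CONDITIONS)}"
            )
        if not is_no_amplification(self.ct):
            if not math.isfinite(self.ct) or not (0.0 <= self.ct <= 50.0):
                raise ValidationError(
                    f"ct must be the no-amplification sentinel or in [0, 50], "
                    f"got {self.ct!r}"
                )
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def key(self) -> tuple[str, str, str, int]:
        return (self.sample_id, self.target_id, self.condition, self.replicate)


# Derived labels are Optional and left unset (None) until scoring runs.
@dataclass
class PatientRecord:
    """One tumor's measured quantities plus derived stratification labels."""

    patient_id: str
    mir_exp: float
    pct_m6a: float
    akg_level: float
    fto_level: float
    mettl3_level: float
    xiap_level: float
    devdase_activity: float
    surv_time: float
    event: bool
    group: int | None = None
    signature: str | None = None
    afm_score: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_m6a <= 100.0):
            raise ValidationError(
                f"patient {self.patient_id}: pct_m6a must be in [0, 100], "
                f"got {self.pct_m6a}"
            )
        if not self.surv_time > 0:
            raise ValidationError(
                f"patient {self.patient_id}: surv_time must be > 0, "
                f"got {self.surv_time}"
            )
        if self.group is not None and self.group not in (1, 2, 3):
            raise ValidationError(
                f"patient {self.patient_id}: group must be 1, 2 or 3"
            )
        if self.signature is not None and self.signature not in ("poor", "standard"):
            raise ValidationError(
                f"patient {self.patient_id}: signature must be 'poor' or 'standard'"
            )
        if self.afm_score is not None and self.afm_score not in (-3, -1, 1, 3):
            raise ValidationError(
                f"patient {self.patient_id}: afm_score must be in {{-3,-1,+1,+3}}"
            )


_MEDIAN_FIELDS = (
    "mir_exp",
    "pct_m6a",
    "akg_level",
    "fto_level",
    "mettl3_level",
    "xiap_level",
    "devdase_activity",
)


class CohortTable:
    """Ordered collection of :class:`PatientRecord` with cohort medians.

    Medians are recomputed on every access so mutation of the record list can
    never expose a stale cache.
    """

    def __init__(self, records: Iterable[PatientRecord]):
        self.records: list[PatientRecord] = list(records)
        if not self.records:
            raise ValidationError("cohort table is empty")
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    @property
    def medians(self) -> dict[str, float]:
        """Cohort median of every measured (non-derived) numeric field."""
        return {
            name: float(np.median([getattr(r, name) for r in self.records]))
            for name in _MEDIAN_FIELDS
        }

    def to_frame(self) -> pd.DataFrame:
        """Return the cohort as a DataFrame, derived columns included."""
        cols = COHORT_COLUMNS + COHORT_OPTIONAL_COLUMNS
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records]
        )

    def column(self, name: str) -> list[float]:
        return [getattr(r, name) for r in self.records]


def _parse_ct_cell(raw: str, row: int) -> float:
    text = raw.strip()
    if text in _NO_AMP_STRINGS:
        return NO_AMPLIFICATION
    try:
        return float(text)
    except ValueError:
        raise FormatError(f"row {row}: cannot parse ct value {raw!r}") from None


def read_ct_table(path: str | Path) -> list[QpcrMeasurement]:
    """Read a Ct-level qPCR CSV into validated measurements.

    The whole read fails on the first malformed row; ``NA``/``Undetermined``
    cells map to the no-amplification sentinel.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"Ct table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in CT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"Ct table {path} is missing column {col!r}")
    measurements: list[QpcrMeasurement] = []
    seen: set[tuple[str, str, str, int]] = set()
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            replicate = int(str(row.replicate).strip())
        except ValueError:
            raise FormatError(
                f"row {idx}: replicate must be an integer, got {row.replicate!r}"
            ) from None
        m = QpcrMeasurement(
            sample_id=str(row.sample_id).strip(),
            target_id=str(row.target_id).strip(),
            condition=str(row.condition).strip(),
            ct=_parse_ct_cell(str(row.ct), idx),
            replicate=replicate,
        )
        if m.key in seen:
            raise ValidationError(
                f"row {idx}: duplicate (sample, target, condition, replicate) "
                f"key {m.key}"
            )
        seen.add(m.key)
        measurements.append(m)
    return measurements


def write_ct_table(measurements: Sequence[QpcrMeasurement], path: str | Path) -> None:
    """Write measurements in the documented Ct CSV dialect."""
    rows = []
    for m in measurements:
        ct = "NA" if is_no_amplification(m.ct) else repr(m.ct)
        rows.append(
            {
                "sample_id": m.sample_id,
                "target_id": m.target_id,
                "condition": m.condition,
                "ct": ct,
                "replicate": m.replicate,
            }
        )
    pd.DataFrame(rows, columns=CT_COLUMNS).to_csv(path, index=False)


_TRUTHY = {"true", "1", "yes"}
_FALSY = {"false", "0", "no"}


def _parse_event(raw: str, row: int) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise FormatError(f"row {row}: cannot parse event flag {raw!r}")


def read_cohort_table(path: str | Path) -> CohortTable:
    """Read and validate a patient-level cohort CSV.

    Derived columns (group, signature, afm_score) are optional and left unset
    when absent or empty.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cohort table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"cohort table {path} is missing column {col!r}")
    if len(df) == 0:
        raise ValidationError(f"cohort table {path} has no data rows")
    records: list[PatientRecord] = []
    for idx, row in enumerate(df.to_dict("records"), start=2):
        kwargs: dict = {"patient_id": str(row["patient_id"]).strip()}
        for col in COHORT_COLUMNS[1:-2]:
            try:
                kwargs[col] = float(row[col])
            except ValueError:
                raise FormatError(
                    f"row {idx}: cannot parse {col} value {row[col]!r}"
                ) from None
        try:
            kwargs["surv_time"] = float(row["surv_time"])
        except ValueError:
            raise FormatError(
                f"row {idx}: cannot parse surv_time value {row['surv_time']!r}"
            ) from None
        kwargs["event"] = _parse_event(row["event"], idx)
        if str(row.get("group", "")).strip():
            kwargs["group"] = int(float(row["group"]))
        if str(row.get("signature", "")).strip():
            kwargs["signature"] = str(row["signature"]).strip()
        if str(row.get("afm_score", "")).strip():
            kwargs["afm_score"] = int(float(row["afm_score"]))
        records.append(PatientRecord(**kwargs))
    return CohortTable(records)


def write_cohort_table(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort CSV; unset derived columns serialize as empty cells."""
    rows = []
    for r in cohort:
        row: dict = {}
        for col in COHORT_COLUMNS:
            v = getattr(r, col)
            if col == "patient_id":
                row[col] = v
            elif col == "event":
                row[col] = "true" if v else "false"
            else:
                row[col] = repr(float(v))
        row["group"] = "" if r.group is None else r.group
        row["signature"] = "" if r.signature is None else r.signature
        row["afm_score"] = "" if r.afm_score is None else r.afm_score
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS + COHORT_OPTIONAL_COLUMNS).to_csv(
        path, index=False
    )


def write_report(report: Mapping, path: str | Path) -> None:
    """Serialize an analysis report to JSON (lossless float round-trip)."""
    path = Path(path)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, allow_nan=False)
            fh.write("\n")
    except OSError as exc:
        raise MiripIOError(f"cannot write report to {path}: {exc}") from exc


def read_report(path: str | Path) -> dict:
    """Read back a JSON analysis report."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
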