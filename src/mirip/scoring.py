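"""Median-dichotomized biomarker scoring and cohort stratification.

The αFM score summarizes the predicted joint effect of three m6A regulators
on miRNA adenosine methylation. Each marker contributes +1 when it sits in
its methylation-promoting half of the cohort and -1 otherwise:

* αKG (demethylase co-substrate): +1 when <= cohort median,
* FTO (demethylase/eraser):       +1 when <= cohort median,
* METTL3 (methyltransferase/writer): +1 when > cohort median.

The sum therefore takes values in {-3, -1, +1, +3}. All thresholds are
cohort-internal: medians are always computed on the cohort being scored,
never carried over from another dataset, so the rules are rank-based and
invariant under strictly increasing transforms of any marker.

Stratification rules:

* three groups — group 1: percent-m6A above the cutoff (default 10%);
  group 2: at/below the cutoff and expression <= cohort median (exp-low);
  group 3: at/below the cutoff and expression above the median (exp-high);
* FTO-low/αKG-low subgroup — both markers strictly below their medians;
* poor-prognosis signature — percent-m6A above the cutoff OR expression
  <= median (group 1 or 2); everyone else is "standard".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .exceptions import MissingDataError, ValidationError
from .io import CohortTable, PatientRecord

AFM_MARKERS = ("akg_level", "fto_level", "mettl3_level")


def cohort_median(values: Iterable[float]) -> float:
    """Median with the even-n mean-of-central-pair convention."""
    vals = [float(v) for v in values]
    if not vals:
        raise MissingDataError("cannot take the median of an empty collection")
    if any(not math.isfinite(v) for v in vals):
        raise ValidationError("median input contains non-finite values")
    return float(np.median(vals))


@dataclass(frozen=True)
class ScoringThresholds:
    """Percent-m6A cutoff plus the cohort medians the rank rules dichotomize on."""

    medians: Mapping[str, float]
    m6a_cutoff: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.m6a_cutoff < 100.0):
            raise ValidationError(
                f"m6a_cutoff must be in (0, 100), got {self.m6a_cutoff}"
            )

    @classmethod
    def from_cohort(cls, cohort: CohortTable, m6a_cutoff: float = 10.0) -> "ScoringThresholds":
        """Compute all medians from the cohort being scored."""
        medians = {
            name: cohort_median(cohort.column(name))
            for name in ("mir_exp",) + AFM_MARKERS
        }
        return cls(medians=medians, m6a_cutoff=m6a_cutoff)

    def median(self, name: str) -> float:
        try:
            return self.medians[name]
        except KeyError:
            raise MissingDataError(f"no cohort median available for {name!r}") from None


def _require(value: float | None, what: str, patient: str) -> float:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise MissingDataError(f"patient {patient}: missing {what}")
    return float(value)


def afm_score(
    akg: float, fto: float, mettl3: float, thresholds: ScoringThresholds
) -> int:
    """Sum of the three per-marker methylation-direction terms.

    +1 for αKG <= median, FTO <= median, METTL3 > median; -1 otherwise for
    each marker. Always odd, in {-3, -1, +1, +3}.
    """
    for name, v in (("akg", akg), ("fto", fto), ("mettl3", mettl3)):
        if v is None or not math.isfinite(v):
            raise MissingDataError(f"missing {name} marker value")
    score = 0
    score += 1 if akg <= thresholds.median("akg_level") else -1
    score += 1 if fto <= thresholds.median("fto_level") else -1
    score += 1 if mettl3 > thresholds.median("mettl3_level") else -1
    return score


def stratify_three_groups(
    cohort: CohortTable, thresholds: ScoringThresholds
) -> list[int]:
    """Assign every patient to exactly one of three groups.

    Group 1: pct_m6a strictly above the cutoff (a tie at the cutoff falls
    through to groups 2/3). Group 2: expression <= cohort median. Group 3:
    the rest.
    """
    exp_median = thresholds.median("mir_exp")
    labels = []
    for r in cohort:
        pct = _require(r.pct_m6a, "pct_m6a", r.patient_id)
        exp = _require(r.mir_exp, "mir_exp", r.patient_id)
        if pct > thresholds.m6a_cutoff:
            labels.append(1)
        elif exp <= exp_median:
            labels.append(2)
        else:
            labels.append(3)
    return labels


FTO_AKG_LOW = "FTOlow_aKGlow"
FTO_AKG_OTHER = "other"


def fto_akg_subgroup(
    cohort: CohortTable, thresholds: ScoringThresholds
) -> list[str]:
    """Label patients with both FTO and αKG strictly below their medians."""
    fto_median = thresholds.median("fto_level")
    akg_median = thresholds.median("akg_level")
    labels = []
    for r in cohort:
        fto = _require(r.fto_level, "fto_level", r.patient_id)
        akg = _require(r.akg_level, "akg_level", r.patient_id)
        low = fto < fto_median and akg < akg_median
        labels.append(FTO_AKG_LOW if low else FTO_AKG_OTHER)
    return labels


def signature_label(record: PatientRecord, thresholds: ScoringThresholds) -> str:
    """Poor-prognosis signature: high percent-m6A OR expression-low."""
    pct = _require(record.pct_m6a, "pct_m6a", record.patient_id)
    exp = _require(record.mir_exp, "mir_exp", record.patient_id)
    poor = pct > thresholds.m6a_cutoff or exp <= thresholds.median("mir_exp")
    return "poor" if poor else "standard"


def score_cohort(
    cohort: CohortTable,
    thresholds: ScoringThresholds | None = None,
    m6a_cutoff: float = 10.0,
) -> ScoringThresholds:
    """Apply all scoring rules in place; returns the thresholds used.

    Sets ``afm_score``, ``group`` and ``signature`` on every record.
    """
    if thresholds is None:
        thresholds = ScoringThresholds.from_cohort(cohort, m6a_cutoff=m6a_cutoff)
    groups = stratify_three_groups(cohort, thresholds)
    for r, g in zip(cohort, groups):
        r.afm_score = afm_score(r.akg_level, r.fto_level, r.mettl3_level, thresholds)
        r.group = g
        r.signature = signature_label(r, thresholds)
    return thresholds
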