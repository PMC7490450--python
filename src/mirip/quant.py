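"""Ct-level qPCR arithmetic.

All quantities derive from the standard exponential amplification model with
efficiency 2: one cycle difference corresponds to a twofold difference in
template.  The module provides

* ``delta_delta_ct`` — the 2^-ΔΔCt relative-quantification fold change,
* ``relative_expression`` — miRNA expression relative to a housekeeping RNA
  (SNORD6.1 by convention) and a reference tissue,
* ``ip_fold_enrichment`` — fold enrichment of a specific immunoprecipitation
  over its IgG control,
* ``percent_m6a`` — percent of miRNA copies recovered by anti-m6A IP, as
  IgG-subtracted percent-of-input,
* ``aggregate_replicates`` — replicate averaging on the Ct scale.

No amplification-efficiency correction is applied; efficiency 2 is implicit
in the 2^-ΔΔCt formulation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import MissingDataError, NoAmplificationError, ValidationError
from .io import NO_AMPLIFICATION, QpcrMeasurement, is_no_amplification

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QuantConfig:
    """Configuration of the percent-m6A computation.

    Parameters
    ----------
    input_fraction
        Fraction of the IP material reserved as the input aliquot, in (0, 1].
        The input Ct is shifted by log2(input_fraction) so that recoveries are
        expressed relative to 100% of material. Default 1 (input treated as
        100% equivalents).
    clip_to_range
        Cap the percent at 100 (recoveries slightly above input can arise
        from Ct noise).
    subtract_igg
        Subtract nonspecific (IgG) recovery from the anti-m6A recovery.
        Raw percent-of-input is available by switching this off.
    """

    input_fraction: float = 1.0
    clip_to_range: bool = True
    subtract_igg: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.input_fraction <= 1.0):
            raise ValidationError(
                f"input_fraction must be in (0, 1], got {self.input_fraction}"
            )


def _require_finite(name: str, ct: float) -> None:
    if is_no_amplification(ct):
        raise NoAmplificationError(f"{name} Ct shows no amplification")
    if not math.isfinite(ct):
        raise ValidationError(f"{name} Ct must be finite, got {ct!r}")


def delta_delta_ct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """2^-ΔΔCt fold change of target vs reference between case and control.

    Returns ``2 ** -((ct_target_case - ct_ref_case)
    - (ct_target_ctrl - ct_ref_ctrl))``.

    Raises
    ------
    NoAmplificationError
        If any of the four Ct values is the no-amplification sentinel; the
        caller decides how to handle the well.
    """
    for name, ct in (
        ("target/case", ct_target_case),
        ("reference/case", ct_ref_case),
        ("target/control", ct_target_ctrl),
        ("reference/control", ct_ref_ctrl),
    ):
        _require_finite(name, ct)
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def relative_expression(
    ct_mir_sample: float,
    ct_hk_sample: float,
    ct_mir_ref: float,
    ct_hk_ref: float,
) -> float:
    """Relative miRNA expression vs a housekeeping RNA and a reference tissue.

    This is :func:`delta_delta_ct` with the sample as case and the reference
    (e.g. non-tumor brain) as control; the housekeeping target is SNORD6.1 by
    convention but any target is accepted.
    """
    _require_finite("housekeeping/sample", ct_hk_sample)
    _require_finite("housekeeping/reference", ct_hk_ref)
    return delta_delta_ct(ct_mir_sample, ct_hk_sample, ct_mir_ref, ct_hk_ref)


def ip_fold_enrichment(ct_ip: float, ct_igg: float) -> float:
    """Fold enrichment of a specific IP over the IgG negative control.

    Returns ``2 ** (ct_igg - ct_ip)``. A sentinel IgG Ct with a finite IP Ct
    means no detectable background: +inf is returned and a warning logged.
    A sentinel IP Ct with finite IgG means no specific recovery: 0.0 with a
    warning. Both sentinel raises :class:`NoAmplificationError`.
    """
    ip_missing = is_no_amplification(ct_ip)
    igg_missing = is_no_amplification(ct_igg)
    if ip_missing and igg_missing:
        raise NoAmplificationError("neither IP nor IgG condition amplified")
    if igg_missing:
        logger.warning(
            "IgG control did not amplify (IP Ct %.3f); enrichment is +inf", ct_ip
        )
        return math.inf
    if ip_missing:
        logger.warning(
            "IP condition did not amplify (IgG Ct %.3f); enrichment is 0", ct_igg
        )
        return 0.0
    return 2.0 ** (ct_igg - ct_ip)


def percent_m6a(
    ct_input: float,
    ct_igg: float,
    ct_m6a: float,
    config: QuantConfig | None = None,
) -> float:
    """Percent of miRNA copies carrying m6A, from a three-condition RIP-qPCR.

    With the input Ct adjusted for the input fraction,
    ``c = ct_input + log2(input_fraction)``, the anti-m6A and IgG recoveries
    are ``2 ** (c - ct)`` (a sentinel Ct counts as zero recovery), and the
    percentage is ``100 * max(0, recovery_m6a - recovery_igg)``, capped at
    100 when ``clip_to_range`` is set.
    """
    if config is None:
        config = QuantConfig()
    if is_no_amplification(ct_input):
        raise NoAmplificationError("input condition did not amplify")
    _require_finite("input", ct_input)
    c = ct_input + math.log2(config.input_fraction)
    rec_m6a = 0.0 if is_no_amplification(ct_m6a) else 2.0 ** (c - ct_m6a)
    rec_igg = 0.0 if is_no_amplification(ct_igg) else 2.0 ** (c - ct_igg)
    if not config.subtract_igg:
        rec_igg = 0.0
    pct = 100.0 * max(0.0, rec_m6a - rec_igg)
    if config.clip_to_range:
        pct = min(pct, 100.0)
    return pct


def aggregate_replicates(
    measurements: Iterable[QpcrMeasurement],
    key: tuple[str, str, str],
) -> float:
    """Mean Ct over replicates of one (sample, target, condition) reaction.

    Averaging is done on the Ct (log) scale, the convention for ΔΔCt
    workflows. All-sentinel replicates yield the sentinel; a mix of finite
    and sentinel replicates averages the finite ones with a logged warning.
    """
    sample_id, target_id, condition = key
    cts = [
        m.ct
        for m in measurements
        if (m.sample_id, m.target_id, m.condition) == (sample_id, target_id, condition)
    ]
    if not cts:
        raise MissingDataError(f"no measurement for key {key}")
    finite = [ct for ct in cts if not is_no_amplification(ct)]
    if not finite:
        return NO_AMPLIFICATION
    if len(finite) < len(cts):
        logger.warning(
            "key %s: %d of %d replicates did not amplify; averaging the rest",
            key,
            len(cts) - len(finite),
            len(cts),
        )
    return sum(finite) / len(finite)


# Target/condition conventions used by quantify_samples and the synthetic
# Ct generator.
MIR_TARGET = "miR-200b-3p"
HK_TARGET = "SNORD6.1"
REFERENCE_SAMPLE = "reference"


def quantify_samples(
    measurements: Sequence[QpcrMeasurement],
    config: QuantConfig | None = None,
    mir_target: str = MIR_TARGET,
    hk_target: str = HK_TARGET,
    reference_sample: str = REFERENCE_SAMPLE,
) -> pd.DataFrame:
    """Per-sample relative expression and percent-m6A from a Ct table.

    Expects, per sample, ``sample``-condition rows for the miRNA and
    housekeeping targets plus ``input``/``IP-IgG``/``IP-m6A`` rows for the
    miRNA, and one reference pseudo-sample with ``reference``-condition rows.
    Returns a DataFrame with columns sample_id, mir_exp, pct_m6a.
    """
    if config is None:
        config = QuantConfig()
    ct_mir_ref = aggregate_replicates(
        measurements, (reference_sample, mir_target, "reference")
    )
    ct_hk_ref = aggregate_replicates(
        measurements, (reference_sample, hk_target, "reference")
    )
    sample_ids: list[str] = []
    for m in measurements:
        if m.sample_id != reference_sample and m.sample_id not in sample_ids:
            sample_ids.append(m.sample_id)
    rows = []
    for sid in sample_ids:
        ct_mir = aggregate_replicates(measurements, (sid, mir_target, "sample"))
        ct_hk = aggregate_replicates(measurements, (sid, hk_target, "sample"))
        ct_in = aggregate_replicates(measurements, (sid, mir_target, "input"))
        ct_igg = aggregate_replicates(measurements, (sid, mir_target, "IP-IgG"))
        ct_m6a = aggregate_replicates(measurements, (sid, mir_target, "IP-m6A"))
        rows.append(
            {
                "sample_id": sid,
                "mir_exp": relative_expression(ct_mir, ct_hk, ct_mir_ref, ct_hk_ref),
                "pct_m6a": percent_m6a(ct_in, ct_igg, ct_m6a, config),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "mir_exp", "pct_m6a"])
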