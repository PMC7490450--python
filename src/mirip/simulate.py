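"""Seeded generator of synthetic GBM-like cohorts.

No patient-level data accompany the study this pipeline targets, so every
stage is exercised on simulated cohorts that plant the qualitative structure
the analysis assumes:

* regulator levels (αKG, FTO, METTL3) log-normal with unit median;
* percent-m6A of the miRNA on the logit scale, driven up by METTL3 (writer)
  and down by FTO and αKG (eraser and its co-substrate), so a subpopulation
  exceeds the 10% cutoff;
* miRNA expression log-normal, its location coupled to methylation
  (default coupling positive; the sign is configurable);
* XIAP inversely coupled to the *effective* unmethylated miRNA dose
  ``mir_exp * (1 - m)`` — methylated copies do not repress;
* caspase (DEVDase) activity inversely coupled to XIAP;
* exponential survival with a planted hazard ratio for patients meeting the
  poor-prognosis signature on their true (noise-free rule) values, plus
  independent uniform censoring.

``generate_cohort`` is a pure function of its config (which includes the
seed): identical config gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ValidationError
from .io import NO_AMPLIFICATION, CohortTable, PatientRecord, QpcrMeasurement
from .quant import HK_TARGET, MIR_TARGET, REFERENCE_SAMPLE

# Ct anchors used when back-computing Ct-level tables (cycles).
_HK_CT = 20.0          # housekeeping Ct in every sample and the reference
_REF_MIR_CT = 25.0     # miRNA Ct in the non-tumor reference
_IGG_BACKGROUND = 1e-3  # nonspecific IgG recovery as a fraction of input


@dataclass(frozen=True)
class GeneratorConfig:
    """All planted effect sizes, noise levels, and the seed.

    Defaults emulate a 32-patient GBM cohort with heterogeneous miRNA
    expression, a subpopulation above the 10% methylation cutoff, and a
    hazard ratio of 2.5 for the poor signature.
    """

    n_patients: int = 32
    seed: int = 0
    #: methylation drive per SD of METTL3 (logit scale)
    beta_mettl3: float = 1.0
    #: demethylation drive per SD of FTO / αKG (logit scale)
    beta_fto: float = 0.8
    beta_akg: float = 0.8
    m6a_noise_sd: float = 0.7
    m6a_baseline: float = -2.2
    #: shift of log-expression per SD of methylation; sign configurable
    exp_m6a_coupling: float = 0.5
    exp_lognormal_sd: float = 1.0
    #: XIAP drop per unit of effective unmethylated miRNA dose
    xiap_repression: float = 1.2
    xiap_noise_sd: float = 0.3
    #: DEVDase change per unit XIAP (must be <= 0: XIAP blocks caspases)
    devdase_xiap_slope: float = -0.8
    hazard_ratio_poor: float = 2.5
    baseline_median_survival: float = 14.0
    censoring_fraction: float = 0.2
    emit_ct_level: bool = False
    # secondary shape parameters
    regulator_lognormal_sd: float = 0.5
    xiap_baseline: float = 2.5
    devdase_baseline: float = 2.0
    devdase_noise_sd: float = 0.3
    m6a_cutoff: float = 10.0
    ct_noise_sd: float = 0.15
    n_ct_replicates: int = 3

    def __post_init__(self) -> None:
        positive = (
            "m6a_noise_sd",
            "exp_lognormal_sd",
            "xiap_noise_sd",
            "hazard_ratio_poor",
            "baseline_median_survival",
            "regulator_lognormal_sd",
            "devdase_noise_sd",
        )
        nonneg = ("beta_mettl3", "beta_fto", "beta_akg", "xiap_repression",
                  "ct_noise_sd")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if self.devdase_xiap_slope > 0:
            raise ValidationError("devdase_xiap_slope must be <= 0")
        if not (0.0 <= self.censoring_fraction < 1.0):
            raise ValidationError("censoring_fraction must be in [0, 1)")
        if not (0.0 < self.m6a_cutoff < 100.0):
            raise ValidationError("m6a_cutoff must be in (0, 100)")
        if self.n_ct_replicates < 1:
            raise ValidationError("n_ct_replicates must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SyntheticTruth:
    """Per-patient latent values, aligned one-to-one with the cohort records."""

    patient_ids: tuple[str, ...]
    true_pct_m6a: tuple[float, ...]
    true_group: tuple[int, ...]
    true_signature: tuple[str, ...]
    hazard_multiplier: tuple[float, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "true_pct_m6a": self.true_pct_m6a,
                "true_group": self.true_group,
                "true_signature": self.true_signature,
                "hazard_multiplier": self.hazard_multiplier,
            }
        )


def generate_cohort(config: GeneratorConfig) -> tuple[CohortTable, SyntheticTruth]:
    """Draw one synthetic cohort (patient table plus latent truth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    z_akg = rng.standard_normal(n)
    z_fto = rng.standard_normal(n)
    z_mettl3 = rng.standard_normal(n)
    akg = np.exp(config.regulator_lognormal_sd * z_akg)
    fto = np.exp(config.regulator_lognormal_sd * z_fto)
    mettl3 = np.exp(config.regulator_lognormal_sd * z_mettl3)

    eta = (
        config.m6a_baseline
        + config.beta_mettl3 * z_mettl3
        - config.beta_fto * z_fto
        - config.beta_akg * z_akg
        + config.m6a_noise_sd * rng.standard_normal(n)
    )
    m = expit(eta)  # methylated fraction in (0, 1)
    pct_m6a = 100.0 * m

    # expression coupled to cohort-standardized methylation
    if n > 1 and float(np.std(m)) > 0:
        z_m = (m - m.mean()) / m.std()
    else:
        z_m = np.zeros(n)
    mir_exp = np.exp(
        config.exp_m6a_coupling * z_m
        + config.exp_lognormal_sd * rng.standard_normal(n)
    )

    # only unmethylated copies repress XIAP
    dose = mir_exp * (1.0 - m)
    xiap = np.maximum(
        0.0,
        config.xiap_baseline
        - config.xiap_repression * dose
        + config.xiap_noise_sd * rng.standard_normal(n),
    )
    devdase = np.maximum(
        0.0,
        config.devdase_baseline
        + config.devdase_xiap_slope * xiap
        + config.devdase_noise_sd * rng.standard_normal(n),
    )

    # true stratification on latent (pre-measurement) values
    exp_median = float(np.median(mir_exp))
    true_group = np.where(
        pct_m6a > config.m6a_cutoff, 1, np.where(mir_exp <= exp_median, 2, 3)
    )
    poor = (pct_m6a > config.m6a_cutoff) | (mir_exp <= exp_median)
    hazard_mult = np.where(poor, config.hazard_ratio_poor, 1.0)

    base_rate = math.log(2.0) / config.baseline_median_survival
    latent_t = rng.exponential(1.0, size=n) / (base_rate * hazard_mult)
    censored = rng.random(n) < config.censoring_fraction
    cens_frac = rng.random(n)
    surv_time = np.where(censored, latent_t * cens_frac, latent_t)
    surv_time = np.maximum(surv_time, 1e-6)
    event = ~censored

    records = [
        PatientRecord(
            patient_id=f"GBM{i + 1:03d}",
            mir_exp=float(mir_exp[i]),
            pct_m6a=float(pct_m6a[i]),
            akg_level=float(akg[i]),
            fto_level=float(fto[i]),
            mettl3_level=float(mettl3[i]),
            xiap_level=float(xiap[i]),
            devdase_activity=float(devdase[i]),
            surv_time=float(surv_time[i]),
            event=bool(event[i]),
        )
        for i in range(n)
    ]
    cohort = CohortTable(records)
    truth = SyntheticTruth(
        patient_ids=tuple(r.patient_id for r in records),
        true_pct_m6a=tuple(float(v) for v in pct_m6a),
        true_group=tuple(int(g) for g in true_group),
        true_signature=tuple("poor" if p else "standard" for p in poor),
        hazard_multiplier=tuple(float(h) for h in hazard_mult),
    )
    return cohort, truth


def generate_ct_tables(
    cohort: CohortTable,
    truth: SyntheticTruth,
    config: GeneratorConfig,
) -> list[QpcrMeasurement]:
    """Back-compute Ct-level tables consistent with each patient's values.

    Ct values are constructed so that, at zero Ct noise, ``relative_expression``
    and ``percent_m6a`` recover mir_exp and pct_m6a exactly; Gaussian noise of
    sd ``ct_noise_sd`` cycles is then added independently per replicate.
    Patients with a true percent-m6A of 0 get a no-amplification sentinel in
    the anti-m6A IP rows.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    measurements: list[QpcrMeasurement] = []

    def add(sample: str, target: str, condition: str, ct_true: float) -> None:
        for rep in range(1, config.n_ct_replicates + 1):
            if math.isnan(ct_true):
                ct = NO_AMPLIFICATION
            else:
                ct = ct_true + config.ct_noise_sd * rng.standard_normal()
                ct = min(max(ct, 0.0), 50.0)
            measurements.append(
                QpcrMeasurement(sample, target, condition, float(ct), rep)
            )

    # shared non-tumor reference pseudo-sample
    add(REFERENCE_SAMPLE, MIR_TARGET, "reference", _REF_MIR_CT)
    add(REFERENCE_SAMPLE, HK_TARGET, "reference", _HK_CT)

    for rec, true_pct in zip(cohort, truth.true_pct_m6a):
        ct_mir = _REF_MIR_CT - math.log2(rec.mir_exp)
        add(rec.patient_id, MIR_TARGET, "sample", ct_mir)
        add(rec.patient_id, HK_TARGET, "sample", _HK_CT)

        ct_input = ct_mir
        ct_igg = ct_input - math.log2(_IGG_BACKGROUND)
        add(rec.patient_id, MIR_TARGET, "input", ct_input)
        add(rec.patient_id, MIR_TARGET, "IP-IgG", ct_igg)
        if true_pct <= 0.0:
            add(rec.patient_id, MIR_TARGET, "IP-m6A", math.nan)
        else:
            recovery = true_pct / 100.0 + _IGG_BACKGROUND
            add(rec.patient_id, MIR_TARGET, "IP-m6A", ct_input - math.log2(recovery))
    return measurements
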