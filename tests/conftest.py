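import numpy as np
import pytest

from mirip import CohortTable, GeneratorConfig, PatientRecord, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def default_cohort():
    """One default synthetic cohort (n=32, fixed seed) with its truth."""
    return generate_cohort(GeneratorConfig(seed=7))


def make_record(patient_id="P1", **kwargs) -> PatientRecord:
    base = dict(
        patient_id=patient_id,
        mir_exp=1.0,
        pct_m6a=5.0,
        akg_level=1.0,
        fto_level=1.0,
        mettl3_level=1.0,
        xiap_level=1.0,
        devdase_activity=1.0,
        surv_time=12.0,
        event=True,
    )
    base.update(kwargs)
    return PatientRecord(**base)


def random_cohort(rng: np.random.Generator, n: int = 32) -> CohortTable:
    """Cohort with independent random columns (no planted structure)."""
    return CohortTable(
        [
            make_record(
                patient_id=f"R{i}",
                mir_exp=float(rng.lognormal()),
                pct_m6a=float(rng.uniform(0, 40)),
                akg_level=float(rng.lognormal()),
                fto_level=float(rng.lognormal()),
                mettl3_level=float(rng.lognormal()),
                xiap_level=float(rng.lognormal()),
                devdase_activity=float(rng.lognormal()),
                surv_time=float(rng.exponential(14) + 0.01),
                event=bool(rng.random() < 0.8),
            )
            for i in range(n)
        ]
    )
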