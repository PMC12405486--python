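"""Synthetic stand-ins for the unreleased patient cohort and life table.

``generate_cohort`` emulates the statistical shape of a treat-to-target RA
outpatient cohort: baseline CDAI is drawn from a normal distribution
(mean 19.8, SD 12.8) truncated to the CDAI range, and follow-up visits decay
toward the treatment target, reflecting patients escalating therapy until
remission or low disease activity. EQ-5D-5L levels are drawn conditionally
on the visit's CDAI band so that, under the bundled toy value set, the
expected band-mean utilities equal the published band targets
(0.87 / 0.72 / 0.57 / 0.21) and the pooled mean lands near 0.62.

``generate_lifetable`` writes a smooth Gompertz-shaped female life table
anchored at a chosen annual mortality probability at age 45, standing in for
the national life table a user would normally supply.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .states import HealthState
from .utilities import (
    DIMENSIONS,
    CDAI_MAX,
    EQ5DProfile,
    PatientVisitRecord,
    ValueSet,
    cdai_category,
)

#: Band-mean utility targets the generator reproduces in expectation.
BAND_UTILITY_TARGETS = {
    HealthState.REMISSION: 0.87,
    HealthState.LDA: 0.72,
    HealthState.MDA: 0.57,
    HealthState.HDA: 0.21,
}

BASELINE_CDAI_MEAN = 19.8
BASELINE_CDAI_SD = 12.8

# Multiplicative per-visit CDAI decay and additive noise SD for follow-up
# visits. The decay emulates treat-to-target escalation between visits and is
# calibrated once so the pooled visit-level mean utility sits near the
# cohort's published 0.62 (see docs/methods.md).
CDAI_DECAY = 0.68
CDAI_NOISE_SD = 5.0

_TOY_STEP = 0.05  # per-level decrement of the toy value set


def toy_value_set() -> ValueSet:
    """Synthetic, documented toy value set: every dimension contributes a
    decrement of 0.05 x (level - 1), so full health scores 1.0 and the worst
    profile (5,5,5,5,5) scores 0.0. It is a stand-in for a country value set
    (e.g. the Ugandan tariff), not an estimate of one."""
    decs = {
        (dim, level): _TOY_STEP * (level - 1)
        for dim in DIMENSIONS
        for level in (1, 2, 3, 4, 5)
    }
    return ValueSet(decrements=decs, anchor=1.0)


def _level_prob(band: HealthState) -> float:
    """Binomial success probability for EQ-5D levels in a band.

    Levels are 1 + Binomial(4, p) per dimension, so the expected total
    decrement under the toy value set is 5 x 0.05 x 4p = p; choosing
    p = 1 - target utility makes the band mean exact in expectation.
    """
    return 1.0 - BAND_UTILITY_TARGETS[band]


def generate_cohort(
    n_patients: int = 102,
    visits_per_patient: int = 5,
    seed: int = 1,
) -> list[PatientVisitRecord]:
    """Generate a synthetic patient-visit cohort (deterministic given seed)."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if visits_per_patient < 1:
        raise ValueError("visits_per_patient must be >= 1")
    rng = np.random.default_rng(seed)

    a = (0.0 - BASELINE_CDAI_MEAN) / BASELINE_CDAI_SD
    b = (CDAI_MAX - BASELINE_CDAI_MEAN) / BASELINE_CDAI_SD
    baseline = stats.truncnorm.rvs(
        a, b, loc=BASELINE_CDAI_MEAN, scale=BASELINE_CDAI_SD,
        size=n_patients, random_state=rng,
    )

    records: list[PatientVisitRecord] = []
    width = len(str(n_patients))
    for i, cdai0 in enumerate(baseline):
        pid = f"P{i + 1:0{width}d}"
        cdai = float(cdai0)
        for visit in range(1, visits_per_patient + 1):
            if visit > 1:
                cdai = cdai * CDAI_DECAY + rng.normal(0.0, CDAI_NOISE_SD)
                cdai = float(np.clip(cdai, 0.0, CDAI_MAX))
            band = cdai_category(cdai)
            levels = 1 + rng.binomial(4, _level_prob(band), size=len(DIMENSIONS))
            records.append(
                PatientVisitRecord(
                    patient_id=pid,
                    visit=visit,
                    cdai=cdai,
                    profile=EQ5DProfile(*(int(v) for v in levels)),
                )
            )
    return records


def generate_lifetable(
    base_annual_prob: float = 0.004,
    seed: int = 0,
    anchor_age: int = 45,
    gompertz_slope: float = 0.09,
) -> pd.DataFrame:
    """Smooth synthetic female life table, ages 15-100, anchored so the
    annual mortality probability at ``anchor_age`` equals ``base_annual_prob``
    and rising exponentially with age (Gompertz shape). Deterministic; the
    seed argument is accepted for interface symmetry."""
    if not (0.0 <= base_annual_prob < 1.0):
        raise ValueError("base_annual_prob must lie in [0, 1)")
    ages = np.arange(15, 101)
    q = base_annual_prob * np.exp(gompertz_slope * (ages - anchor_age))
    q = np.minimum(q, 0.999)
    return pd.DataFrame(
        {"age": ages, "sex": "female", "annual_mortality_prob": q}
    )


def lifetable_lookup(table: pd.DataFrame, age: float, sex: str = "female") -> float:
    """Annual mortality probability for a given age (nearest row at or below)."""
    sub = table[table["sex"] == sex]
    sub = sub[sub["age"] <= age]
    if sub.empty:
        raise ValueError(f"life table has no rows for sex={sex!r} age<={age}")
    return float(sub.iloc[-1]["annual_mortality_prob"])


def write_lifetable(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)
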