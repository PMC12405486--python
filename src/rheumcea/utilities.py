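"""EQ-5D-5L utility scoring and CDAI-banded utility derivation.

Patient-visit records carry a CDAI disease-activity score and an EQ-5D-5L
profile (five dimensions, levels 1-5). A value set maps each (dimension,
level) pair to a utility decrement; the utility of a profile is the
full-health anchor minus the five decrements, so worse-than-dead states are
possible. Visits are grouped into the standard CDAI bands (remission <= 2.8,
low <= 10, moderate <= 22, high > 22) and band means with bootstrap
percentile confidence intervals yield the utility set consumed by the cohort
model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .states import HealthState, LIVE_STATES, TARGET_STATES

DIMENSIONS = ("mo", "sc", "ua", "pd", "ad")
#: mobility, self-care, usual activities, pain/discomfort, anxiety/depression

CDAI_MAX = 76.0
# Standard CDAI cut-points: remission <=2.8 < low <=10 < moderate <=22 < high
CDAI_CUTPOINTS = (2.8, 10.0, 22.0)


@dataclass(frozen=True)
class EQ5DProfile:
    mo: int
    sc: int
    ua: int
    pd: int
    ad: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in (1, 2, 3, 4, 5):
                raise ValueError(f"EQ-5D level for {dim!r} must be 1..5, got {level}")

    def levels(self) -> tuple[int, ...]:
        return tuple(getattr(self, d) for d in DIMENSIONS)


@dataclass
class ValueSet:
    """Country value set: utility decrement per (dimension, level)."""

    decrements: dict[tuple[str, int], float]
    anchor: float = 1.0

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            if self.decrements.get((dim, 1), 0.0) != 0.0:
                raise ValueError(f"level-1 decrement for {dim!r} must be 0")

    def decrement(self, dim: str, level: int) -> float:
        try:
            return self.decrements[(dim, level)]
        except KeyError:
            raise KeyError(
                f"value set has no entry for dimension {dim!r} level {level}"
            ) from None

    @classmethod
    def from_csv(cls, path: str | Path, anchor: float = 1.0) -> "ValueSet":
        """Read a value set from CSV with columns dimension, level, decrement."""
        decs: dict[tuple[str, int], float] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                decs[(row["dimension"], int(row["level"]))] = float(row["decrement"])
        return cls(decrements=decs, anchor=anchor)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["dimension", "level", "decrement"])
            for (dim, level), dec in sorted(self.decrements.items()):
                writer.writerow([dim, level, dec])


@dataclass(frozen=True)
class PatientVisitRecord:
    patient_id: str
    visit: int
    cdai: float
    profile: EQ5DProfile

    def __post_init__(self) -> None:
        if not (0.0 <= self.cdai <= CDAI_MAX):
            raise ValueError(f"CDAI must lie in [0, {CDAI_MAX}], got {self.cdai}")


def profile_to_utility(profile: EQ5DProfile, value_set: ValueSet) -> float:
    """Utility of one EQ-5D-5L response: anchor minus the five dimension
    decrements (additive; may be negative)."""
    total = value_set.anchor
    for dim in DIMENSIONS:
        total -= value_set.decrement(dim, getattr(profile, dim))
    return total


def cdai_category(cdai: float) -> HealthState:
    """Map a CDAI score to its disease-activity band."""
    if cdai < 0:
        raise ValueError(f"CDAI cannot be negative, got {cdai}")
    lo, mid, hi = CDAI_CUTPOINTS
    if cdai <= lo:
        return HealthState.REMISSION
    if cdai <= mid:
        return HealthState.LDA
    if cdai <= hi:
        return HealthState.MDA
    return HealthState.HDA


@dataclass
class BandUtility:
    state: HealthState
    mean: float
    ci_low: float
    ci_high: float
    n_visits: int


@dataclass
class DerivedUtilities:
    """CDAI-band utility means with bootstrap CIs, plus the pooled
    target / non-target means."""

    bands: dict[HealthState, BandUtility]
    target_mean: float
    nontarget_mean: float
    weighting: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "band": b.state.value,
                    "mean_utility": b.mean,
                    "ci_low": b.ci_low,
                    "ci_high": b.ci_high,
                    "n_visits": b.n_visits,
                }
                for b in self.bands.values()
            ]
        )


def derive_state_utilities(
    records: Sequence[PatientVisitRecord],
    value_set: ValueSet,
    n_bootstrap: int = 1000,
    seed: int = 0,
    weighting: str = "visit",
) -> DerivedUtilities:
    """Per-band mean utilities over all visits, with seeded bootstrap
    percentile CIs.

    ``weighting='visit'`` pools every questionnaire (default);
    ``weighting='patient'`` first averages within patients, then across them.
    """
    if weighting not in ("visit", "patient"):
        raise ValueError("weighting must be 'visit' or 'patient'")
    rows = [
        {
            "patient_id": r.patient_id,
            "band": cdai_category(r.cdai),
            "utility": profile_to_utility(r.profile, value_set),
        }
        for r in records
    ]
    if not rows:
        raise ValueError(
            f"no visits in band(s): {[s.value for s in LIVE_STATES]}"
        )
    frame = pd.DataFrame(rows)
    present = set(frame["band"])
    empty = [s.value for s in LIVE_STATES if s not in present]
    if empty:
        raise ValueError(f"no visits in band(s): {empty}")

    rng = np.random.default_rng(seed)
    bands: dict[HealthState, BandUtility] = {}
    for state in LIVE_STATES:
        sub = frame[frame["band"] == state]
        if weighting == "patient":
            values = sub.groupby("patient_id")["utility"].mean().to_numpy()
        else:
            values = sub["utility"].to_numpy()
        mean = float(values.mean())
        if len(values) > 1 and values.std() > 0:
            idx = rng.integers(0, len(values), size=(n_bootstrap, len(values)))
            boot = values[idx].mean(axis=1)
            lo, hi = np.percentile(boot, [2.5, 97.5])
        else:
            lo = hi = mean
        bands[state] = BandUtility(state, mean, float(lo), float(hi), len(sub))

    target = frame["band"].map(lambda b: b in TARGET_STATES)
    if weighting == "patient":
        t_mean = float(
            frame[target].groupby("patient_id")["utility"].mean().mean()
        )
        nt_mean = float(
            frame[~target].groupby("patient_id")["utility"].mean().mean()
        )
    else:
        t_mean = float(frame.loc[target, "utility"].mean())
        nt_mean = float(frame.loc[~target, "utility"].mean())
    return DerivedUtilities(
        bands=bands, target_mean=t_mean, nontarget_mean=nt_mean, weighting=weighting
    )


def records_from_csv(path: str | Path) -> list[PatientVisitRecord]:
    """Read patient-visit records from CSV with columns
    patient_id, visit, cdai, mo, sc, ua, pd, ad."""
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                PatientVisitRecord(
                    patient_id=row["patient_id"],
                    visit=int(row["visit"]),
                    cdai=float(row["cdai"]),
                    profile=EQ5DProfile(
                        *(int(row[d]) for d in DIMENSIONS)
                    ),
                )
            )
    return records


def records_to_csv(records: Iterable[PatientVisitRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "visit", "cdai", *DIMENSIONS])
        for r in records:
            writer.writerow(
                [r.patient_id, r.visit, f"{r.cdai:.2f}", *r.profile.levels()]
            )
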