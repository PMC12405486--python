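"""Disease-activity health states of the cohort model.

The model tracks rheumatoid-arthritis disease activity in four live bands
(CDAI-based: remission, low, moderate, high) plus an absorbing death state.
Remission and low disease activity together constitute the treat-to-target
treatment target.
"""

from __future__ import annotations

from enum import Enum


class HealthState(str, Enum):
    REMISSION = "remission"
    LDA = "lda"
    MDA = "mda"
    HDA = "hda"
    DEAD = "dead"

    @property
    def is_alive(self) -> bool:
        return self is not HealthState.DEAD

    @property
    def at_target(self) -> bool:
        """Remission or low disease activity (the treatment target)."""
        return self in (HealthState.REMISSION, HealthState.LDA)


#: The four live states, in decreasing order of health.
LIVE_STATES = (
    HealthState.REMISSION,
    HealthState.LDA,
    HealthState.MDA,
    HealthState.HDA,
)

TARGET_STATES = (HealthState.REMISSION, HealthState.LDA)
NONTARGET_STATES = (HealthState.MDA, HealthState.HDA)
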