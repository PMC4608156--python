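"""Health-state space of the colorectal neoplasm Markov model.

Fourteen states in four sections: a pre-cancer section (normal colonic
epithelium, low-risk polyps, high-risk polyps), undiagnosed CRC stages
I-IV, diagnosed CRC stages I-IV, and three absorbing death states (CRC,
screening complication, other causes).

For the screening overlay the cohort is additionally tracked over
post-polypectomy surveillance sub-states ("tracks"): none, post low-risk
polypectomy (5-yearly surveillance colonoscopy) and post high-risk
polypectomy (annual surveillance colonoscopy), each carrying a
years-since-last-colonoscopy counter.
"""

from __future__ import annotations

import enum
from typing import NamedTuple


class HealthState(enum.IntEnum):
    NORMAL = 0
    LOW_RISK_POLYP = 1
    HIGH_RISK_POLYP = 2
    UNDIAG_CRC_I = 3
    UNDIAG_CRC_II = 4
    UNDIAG_CRC_III = 5
    UNDIAG_CRC_IV = 6
    DIAG_CRC_I = 7
    DIAG_CRC_II = 8
    DIAG_CRC_III = 9
    DIAG_CRC_IV = 10
    DEATH_CRC = 11
    DEATH_COMPLICATION = 12
    DEATH_OTHER = 13


class Section(enum.Enum):
    PRE_CRC = "pre_crc"
    UNDIAGNOSED_CRC = "undiagnosed_crc"
    DIAGNOSED_CRC = "diagnosed_crc"
    DEATH = "death"


SECTION_OF = {
    HealthState.NORMAL: Section.PRE_CRC,
    HealthState.LOW_RISK_POLYP: Section.PRE_CRC,
    HealthState.HIGH_RISK_POLYP: Section.PRE_CRC,
    HealthState.UNDIAG_CRC_I: Section.UNDIAGNOSED_CRC,
    HealthState.UNDIAG_CRC_II: Section.UNDIAGNOSED_CRC,
    HealthState.UNDIAG_CRC_III: Section.UNDIAGNOSED_CRC,
    HealthState.UNDIAG_CRC_IV: Section.UNDIAGNOSED_CRC,
    HealthState.DIAG_CRC_I: Section.DIAGNOSED_CRC,
    HealthState.DIAG_CRC_II: Section.DIAGNOSED_CRC,
    HealthState.DIAG_CRC_III: Section.DIAGNOSED_CRC,
    HealthState.DIAG_CRC_IV: Section.DIAGNOSED_CRC,
    HealthState.DEATH_CRC: Section.DEATH,
    HealthState.DEATH_COMPLICATION: Section.DEATH,
    HealthState.DEATH_OTHER: Section.DEATH,
}

N_STATES = 14

UNDIAG_STATES = (
    HealthState.UNDIAG_CRC_I,
    HealthState.UNDIAG_CRC_II,
    HealthState.UNDIAG_CRC_III,
    HealthState.UNDIAG_CRC_IV,
)
DIAG_STATES = (
    HealthState.DIAG_CRC_I,
    HealthState.DIAG_CRC_II,
    HealthState.DIAG_CRC_III,
    HealthState.DIAG_CRC_IV,
)
DEATH_STATES = (
    HealthState.DEATH_CRC,
    HealthState.DEATH_COMPLICATION,
    HealthState.DEATH_OTHER,
)
ALIVE_STATES = tuple(s for s in HealthState if s not in DEATH_STATES)
POLYP_STATES = (HealthState.LOW_RISK_POLYP, HealthState.HIGH_RISK_POLYP)


def stage_index(state: HealthState) -> int:
    """0-based CRC stage (0..3 for I..IV) of an undiagnosed or diagnosed state."""
    if state in UNDIAG_STATES:
        return int(state) - int(HealthState.UNDIAG_CRC_I)
    if state in DIAG_STATES:
        return int(state) - int(HealthState.DIAG_CRC_I)
    raise ValueError(f"{state!r} carries no CRC stage")


# ---------------------------------------------------------------------------
# Surveillance tracks


class Track(NamedTuple):
    kind: str  # 'none' | 'post_low_risk_polypectomy' | 'post_high_risk_polypectomy'
    years_since: int


SURVEILLANCE_INTERVALS = {
    "post_low_risk_polypectomy": 5,
    "post_high_risk_polypectomy": 1,
}

# Track enumeration: the counter saturates at the surveillance interval so a
# missed surveillance round stays due in every subsequent cycle.
TRACKS: list[Track] = [Track("none", 0)]
TRACKS += [Track("post_low_risk_polypectomy", y) for y in range(6)]
TRACKS += [Track("post_high_risk_polypectomy", y) for y in range(2)]

N_TRACKS = len(TRACKS)
TRACK_INDEX = {t: i for i, t in enumerate(TRACKS)}
TRACK_NONE = TRACK_INDEX[Track("none", 0)]
TRACK_LOW0 = TRACK_INDEX[Track("post_low_risk_polypectomy", 0)]
TRACK_HIGH0 = TRACK_INDEX[Track("post_high_risk_polypectomy", 0)]

N_EXPANDED = N_TRACKS * N_STATES


def track_shift_index(i: int) -> int:
    """Track index after one elapsed cycle (counter +1, saturating)."""
    kind, y = TRACKS[i]
    if kind == "none":
        return i
    cap = SURVEILLANCE_INTERVALS[kind]
    return TRACK_INDEX[Track(kind, min(y + 1, cap))]


def expanded_index(track: int, state: HealthState | int) -> int:
    return track * N_STATES + int(state)
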