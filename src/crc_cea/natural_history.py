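"""Annual transition structure of the unscreened disease process.

Each (age, sex) pair yields a 14x14 row-stochastic matrix.  Within a cycle
competing risks are resolved by sequential conditioning in a fixed order:
death first (CRC-specific mortality for cancer states, other-cause
mortality for every alive state), then symptomatic diagnosis, then at most
one step of disease progression.  Age enters only through other-cause
mortality; disease progression probabilities are age-invariant.

Disease flow is one-directional: normal epithelium -> low-risk polyp ->
high-risk polyp -> undiagnosed CRC stage I..IV -> (symptomatic) diagnosed
CRC, with no return edges (polypectomy, which does return polyp carriers
to normal epithelium, belongs to the screening overlay, not to natural
history).  Diagnosis freezes stage progression but not mortality.
"""

from __future__ import annotations

import logging

import numpy as np

from .params import ModelParameters, MortalityTable
from .states import HealthState as S
from .states import N_STATES

logger = logging.getLogger(__name__)


def other_cause_mortality(
    mortality: MortalityTable, sex: str, age: float
) -> float:
    """Annual non-CRC death probability for the quinquennial band covering
    ``age``: max(all_cause - crc, 0).

    Raises ``KeyError`` when no band covers (sex, age).  A CRC rate
    exceeding the all-cause rate is clamped to zero with a warning.
    """
    band = mortality.lookup(sex, age)
    other = band.all_cause - band.crc
    if other < 0:
        logger.warning(
            "CRC mortality %.6f exceeds all-cause %.6f for %s aged %d-%d; clamping to 0",
            band.crc, band.all_cause, band.sex, band.age_lo, band.age_hi,
        )
        return 0.0
    return other


def build_transition_matrix(
    params: ModelParameters, age: float, sex: str
) -> np.ndarray:
    """Natural-history transition matrix for one cycle at (age, sex).

    Rows sum to one exactly; death rows are absorbing.  Symptomatic
    presentation routes undiagnosed stage k to diagnosed stage k with
    probability p_symptomatic[k] * c_symptomatic.
    """
    nh = params.natural_history
    m_oth = other_cause_mortality(params.mortality, sex, age)
    c_symp = params.compliance.c_symptomatic
    M = np.zeros((N_STATES, N_STATES))

    # Pre-CRC states: other-cause death, then one disease step.
    surv = 1.0 - m_oth
    M[S.NORMAL, S.DEATH_OTHER] = m_oth
    M[S.NORMAL, S.LOW_RISK_POLYP] = surv * nh.p_normal_to_low
    M[S.NORMAL, S.NORMAL] = surv * (1.0 - nh.p_normal_to_low)

    M[S.LOW_RISK_POLYP, S.DEATH_OTHER] = m_oth
    M[S.LOW_RISK_POLYP, S.HIGH_RISK_POLYP] = surv * nh.p_low_to_high
    M[S.LOW_RISK_POLYP, S.LOW_RISK_POLYP] = surv * (1.0 - nh.p_low_to_high)

    M[S.HIGH_RISK_POLYP, S.DEATH_OTHER] = m_oth
    onset = surv * nh.p_high_to_crc
    for k, frac in enumerate(nh.crc_entry_distribution):
        M[S.HIGH_RISK_POLYP, S.UNDIAG_CRC_I + k] = onset * frac
    M[S.HIGH_RISK_POLYP, S.HIGH_RISK_POLYP] = surv * (1.0 - nh.p_high_to_crc)

    # Undiagnosed CRC: CRC death, other death, diagnosis, progression.
    for k in range(4):
        row = S.UNDIAG_CRC_I + k
        m_crc = nh.m_crc[k]
        M[row, S.DEATH_CRC] = m_crc
        M[row, S.DEATH_OTHER] = (1.0 - m_crc) * m_oth
        alive = (1.0 - m_crc) * (1.0 - m_oth)
        p_dx = nh.p_symptomatic[k] * c_symp
        M[row, S.DIAG_CRC_I + k] = alive * p_dx
        undx = alive * (1.0 - p_dx)
        if k < 3:
            p_prog = nh.p_stage_progress[k]
            M[row, S.UNDIAG_CRC_I + k + 1] = undx * p_prog
            M[row, row] = undx * (1.0 - p_prog)
        else:
            # Stage IV is terminal within the disease ladder: mortality only.
            M[row, row] = undx

    # Diagnosed CRC: progression eliminated; mortality continues.
    for k in range(4):
        row = S.DIAG_CRC_I + k
        m_crc = nh.m_crc[k]
        M[row, S.DEATH_CRC] = m_crc
        M[row, S.DEATH_OTHER] = (1.0 - m_crc) * m_oth
        M[row, row] = (1.0 - m_crc) * (1.0 - m_oth)

    # Absorbing death states.
    for d in (S.DEATH_CRC, S.DEATH_COMPLICATION, S.DEATH_OTHER):
        M[d, d] = 1.0

    return M
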