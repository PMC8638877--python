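"""Canned toy sessions with known scores, for demos and pipeline checks.

All fixtures are synthetic sessions constructed in code (no recorded data).
"""

from __future__ import annotations

from .scoring import Session, TrialRecord
from .task import (
    ECITT_S1,
    INHIBITORY,
    PREPOTENT,
    BlockConfig,
    Counterbalance,
    generate_sequence,
    other_location,
)

__all__ = ["worked_example_session", "perfect_session"]


def _record(spec, correct: bool, rt: float, validity: str = "valid") -> TrialRecord:
    touched = spec.smiley_location if correct else other_location(spec.smiley_location)
    return TrialRecord(spec, touched, correct, rt, validity, ((rt, touched),))


def worked_example_session(participant_id: str = "toy_worked_example") -> Session:
    """Synthetic toddler session scoring exactly 62.5% prepotent / 50% inhibitory.

    After discarding the (pointed-to) first trial, 7 prepotent trials carry
    intervention codes, leaving 16 valid prepotent trials (10 correct) and all
    8 inhibitory trials valid (4 correct) — so AccD = 12.5 and adjusted
    AccD = 20.0, the canonical weak-prepotency example.
    """
    cb = Counterbalance(participant_id, "top")
    seq = generate_sequence(BlockConfig.ecitt(), cb, seed=0)
    trials: list[TrialRecord] = []
    n_invalid_prep = n_valid_prep = n_inhib = 0
    for i, spec in enumerate(seq):
        rt = 900.0 + 25.0 * i
        if i == 0:
            trials.append(_record(spec, True, rt))  # discarded by scoring
        elif spec.condition == PREPOTENT and n_invalid_prep < 7:
            n_invalid_prep += 1
            trials.append(_record(spec, True, rt, validity="invalid_intervention"))
        elif spec.condition == PREPOTENT:
            correct = n_valid_prep < 10  # 10 / 16 = 62.5%
            n_valid_prep += 1
            trials.append(_record(spec, correct, rt))
        else:
            assert spec.condition == INHIBITORY
            correct = n_inhib < 4  # 4 / 8 = 50%
            n_inhib += 1
            trials.append(_record(spec, correct, rt + 300.0))
    return Session(participant_id, ECITT_S1, cb, trials, age_months=24.0)


def perfect_session(participant_id: str = "toy_perfect") -> Session:
    """All-correct, all-valid toddler session: AccD = adjusted AccD = 0."""
    cb = Counterbalance(participant_id, "top")
    seq = generate_sequence(BlockConfig.ecitt(), cb, seed=1)
    trials = [
        _record(spec, True, 800.0 + 20.0 * i + (250.0 if spec.condition == INHIBITORY else 0.0))
        for i, spec in enumerate(seq)
    ]
    return Session(participant_id, ECITT_S1, cb, trials, age_months=30.0)
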