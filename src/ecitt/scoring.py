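"""Trial cleaning, session inclusion, condition summaries, and inhibition scores.

Cleaning follows the task's coding rules: trials faster than the variant's RT
floor are invalid (anticipations / finger-on-screen at onset), externally coded
invalid trials (experimenter/parent intervention, accidental touches) are
dropped, and the first trial of a toddler session is discarded because the
experimenter points to the correct location on it.  Accuracy is computed over
all remaining valid trials; reaction time only over valid *correct* trials
faster than the ceiling (5000 ms by default).

Three per-session inhibition scores are derived:

* ``AccD``   — prepotent %correct minus inhibitory %correct (percentage points;
  higher = poorer inhibition),
* adjusted ``AccD`` — AccD divided by the prepotent proportion correct,
  correcting for weakly established prepotency,
* ``RTD``    — median correct inhibitory RT minus median correct prepotent RT.

A session is included in group analyses only when prepotent accuracy is
strictly above 60% (otherwise no prepotent response was built up and the task
cannot be measuring response inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import (
    INHIBITORY,
    PREPOTENT,
    Counterbalance,
    TrialSpec,
    Variant,
    get_variant,
)

__all__ = [
    "VALIDITY_CODES",
    "TrialRecord",
    "Session",
    "ConditionSummary",
    "InhibitionScores",
    "SessionScore",
    "clean_trials",
    "summarize_conditions",
    "inhibition_scores",
    "score_session",
    "scores_frame",
    "flag_outliers",
]

VALIDITY_CODES = (
    "valid",
    "invalid_fast",
    "invalid_finger_at_onset",
    "invalid_intervention",
    "invalid_accidental",
)

#: Validity codes assigned by the (human) coder rather than the RT floor rule.
EXTERNAL_INVALID_CODES = (
    "invalid_finger_at_onset",
    "invalid_intervention",
    "invalid_accidental",
)

INCLUSION_THRESHOLD_PCT = 60.0


@dataclass(frozen=True)
class TrialRecord:
    """Observed outcome of one trial.

    ``correct`` and ``rt_ms`` refer to the *first* touch after trial onset;
    later touches (e.g. a corrective press in the unresponsive variant) are
    kept in ``touch_events``.
    """

    spec: TrialSpec
    touched_location: str  # top | bottom | none
    correct: bool
    rt_ms: float | None
    validity: str = "valid"
    touch_events: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        if self.validity not in VALIDITY_CODES:
            raise ValueError(f"unknown validity code {self.validity!r}")
        if self.rt_ms is not None and self.rt_ms < 0:
            raise ValueError("rt_ms must be non-negative")


@dataclass
class Session:
    """One participant x visit administration: variant, counterbalance, trials."""

    participant_id: str
    variant: Variant
    counterbalance: Counterbalance
    trials: list[TrialRecord] = field(default_factory=list)
    age_months: float | None = None
    visit: int = 0
    group: str | None = None
    seed: int | None = None
    software_version: str = "0.1.0"


@dataclass(frozen=True)
class ConditionSummary:
    condition: str
    n_valid: int
    n_correct: int
    pct_correct: float | None
    n_rt_trials: int
    median_rt_ms: float | None


@dataclass(frozen=True)
class InhibitionScores:
    accd: float | None
    accd_adjusted: float | None
    rtd_ms: float | None
    included: bool
    exclusion_reason: str | None


@dataclass(frozen=True)
class SessionScore:
    """Scores plus per-condition summaries for one session."""

    participant_id: str
    visit: int
    variant: str
    prepotent: ConditionSummary
    inhibitory: ConditionSummary
    scores: InhibitionScores
    age_months: float | None = None
    group: str | None = None


def clean_trials(
    session: Session, variant: Variant | None = None
) -> tuple[list[TrialRecord], list[TrialRecord]]:
    """Apply the cleaning rules, returning ``(accuracy_set, rt_set)``.

    The accuracy set holds valid trials (first trial discarded for toddler
    variants; sub-floor RTs recoded ``invalid_fast`` and dropped).  The RT set
    is the subset of the accuracy set that is correct with RT below the
    ceiling.  Both sets may be empty.
    """
    v = variant if variant is not None else session.variant
    trials = list(session.trials)
    if v.discard_first_trial and trials:
        trials = trials[1:]
    accuracy_set: list[TrialRecord] = []
    for t in trials:
        if t.rt_ms is not None and t.rt_ms < v.rt_floor_ms:
            continue  # anticipation: coded invalid_fast, in neither set
        if t.validity != "valid":
            continue
        accuracy_set.append(t)
    rt_set = [
        t
        for t in accuracy_set
        if t.correct and t.rt_ms is not None and t.rt_ms < v.rt_ceiling_ms
    ]
    return accuracy_set, rt_set


def _summarize(condition: str, acc: list[TrialRecord], rt: list[TrialRecord]) -> ConditionSummary:
    acc_c = [t for t in acc if t.spec.condition == condition]
    rt_c = [t.rt_ms for t in rt if t.spec.condition == condition]
    n_valid = len(acc_c)
    n_correct = sum(t.correct for t in acc_c)
    pct = 100.0 * n_correct / n_valid if n_valid else None
    median = float(np.median(rt_c)) if rt_c else None
    return ConditionSummary(condition, n_valid, n_correct, pct, len(rt_c), median)


def summarize_conditions(
    accuracy_set: list[TrialRecord], rt_set: list[TrialRecord]
) -> tuple[ConditionSummary, ConditionSummary]:
    """Per-condition counts, percent correct, and median correct RT.

    The median of an even count is the mean of the two central values; it is
    undefined (``None``) when a condition has no scorable correct RT.
    Returns ``(prepotent, inhibitory)``.
    """
    return (
        _summarize(PREPOTENT, accuracy_set, rt_set),
        _summarize(INHIBITORY, accuracy_set, rt_set),
    )


def inhibition_scores(
    summaries: tuple[ConditionSummary, ConditionSummary]
) -> InhibitionScores:
    """Compute AccD, adjusted AccD, RTD and the inclusion flag.

    Sessions failing the strict >60% prepotent-accuracy criterion still get
    scores but are flagged ``included=False``; a condition without valid
    trials yields undefined scores with a reason.
    """
    prep, inhib = summaries
    if prep.condition != PREPOTENT or inhib.condition != INHIBITORY:
        raise ValueError("summaries must be (prepotent, inhibitory)")
    if prep.n_valid == 0 or inhib.n_valid == 0:
        missing = PREPOTENT if prep.n_valid == 0 else INHIBITORY
        return InhibitionScores(
            accd=None,
            accd_adjusted=None,
            rtd_ms=None,
            included=False,
            exclusion_reason=f"no valid {missing} trials",
        )
    accd = prep.pct_correct - inhib.pct_correct
    accd_adjusted = accd / (prep.pct_correct / 100.0) if prep.pct_correct > 0 else None
    rtd = (
        inhib.median_rt_ms - prep.median_rt_ms
        if prep.median_rt_ms is not None and inhib.median_rt_ms is not None
        else None
    )
    included = prep.pct_correct > INCLUSION_THRESHOLD_PCT
    reason = None if included else (
        f"prepotent accuracy {prep.pct_correct:.1f}% not above {INCLUSION_THRESHOLD_PCT:.0f}%"
    )
    return InhibitionScores(accd, accd_adjusted, rtd, included, reason)


def score_session(session: Session, variant: Variant | None = None) -> SessionScore:
    """Clean, summarise and score a session in one step."""
    v = variant if variant is not None else session.variant
    if isinstance(v, str):
        v = get_variant(v)
    acc, rt = clean_trials(session, v)
    prep, inhib = summarize_conditions(acc, rt)
    return SessionScore(
        participant_id=session.participant_id,
        visit=session.visit,
        variant=v.name,
        prepotent=prep,
        inhibitory=inhib,
        scores=inhibition_scores((prep, inhib)),
        age_months=session.age_months,
        group=session.group,
    )


def scores_frame(scored: list[SessionScore]) -> pd.DataFrame:
    """Tabulate per-session score rows (one row per session)."""
    rows = []
    for s in scored:
        rows.append(
            {
                "participant": s.participant_id,
                "visit": s.visit,
                "variant": s.variant,
                "group": s.group,
                "age_months": s.age_months,
                "n_valid_prepotent": s.prepotent.n_valid,
                "n_valid_inhibitory": s.inhibitory.n_valid,
                "pct_correct_prepotent": s.prepotent.pct_correct,
                "pct_correct_inhibitory": s.inhibitory.pct_correct,
                "median_rt_prepotent": s.prepotent.median_rt_ms,
                "median_rt_inhibitory": s.inhibitory.median_rt_ms,
                "accd": s.scores.accd,
                "accd_adjusted": s.scores.accd_adjusted,
                "rtd": s.scores.rtd_ms,
                "included": s.scores.included,
                "exclusion_reason": s.scores.exclusion_reason,
            }
        )
    return pd.DataFrame(rows)


def flag_outliers(values, z: float = 3.0) -> np.ndarray:
    """Flag values more than ``z`` sample SDs from the mean (no silent removal).

    Mirrors the optional >3 SD screen applied to RT difference scores; the
    caller decides what to do with flagged sessions.  NaNs are never flagged.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        return np.zeros_like(x, dtype=bool)
    m = x[finite].mean()
    sd = x[finite].std(ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=bool)
    out = np.zeros_like(x, dtype=bool)
    out[finite] = np.abs(x[finite] - m) > z * sd
    return out
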