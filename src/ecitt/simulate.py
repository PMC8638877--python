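"""Generative models of participant behaviour.

A :class:`ParticipantModel` turns a planned trial sequence into a realistic
session log: condition-dependent accuracy, right-skewed (ex-Gaussian) reaction
times with slowing on correct inhibitory trials, anticipatory touches below
the RT floor, long "distracted" responses above the ceiling, and externally
coded invalid trials.  :func:`simulate_cohort` layers between-subject
heterogeneity and a latent longitudinal trait on top, so reliability and
stability analyses can be run against known ground truth.

Stop-signal behaviour follows the independent horse-race account: a go process
with an ex-Gaussian finish time races a stop process of fixed latency
(``ssrt_true``) started at the stop-signal delay; the response is inhibited
iff the stop process finishes first.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from .profiles import AgeProfile, get_profile, load_profiles  # noqa: F401  (re-export)
from .scoring import EXTERNAL_INVALID_CODES, Session, TrialRecord
from .task import (
    INHIBITORY,
    PREPOTENT,
    BlockConfig,
    Counterbalance,
    TrialSpec,
    Variant,
    assign_counterbalance,
    default_config,
    generate_sequence,
    other_location,
)

__all__ = [
    "ExGauss",
    "ParticipantModel",
    "RaceModelParams",
    "StopTrialOutcome",
    "CohortMember",
    "simulate_session",
    "simulate_cohort",
    "simulate_stop_trial",
    "AgeProfile",
    "get_profile",
    "load_profiles",
]


@dataclass(frozen=True)
class ExGauss:
    """Ex-Gaussian RT law: Normal(mu, sigma) + Exponential(tau), in ms."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau <= 0:
            raise ValueError("sigma and tau must be > 0")

    def draw(self, rng: np.random.Generator, size: int | None = None):
        return rng.normal(self.mu, self.sigma, size) + rng.exponential(self.tau, size)


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class ParticipantModel:
    """Behavioural parameters of one simulated participant.

    ``inhibitory_cost_ms`` shifts the RT location upward on *correct*
    inhibitory trials only (error RTs are generated but never scored).
    ``p_anticipation`` / ``p_distraction`` inject sub-floor and above-ceiling
    responses; ``p_invalid`` injects externally coded invalid trials.
    """

    p_correct_prepotent: float
    p_correct_inhibitory: float
    rt_prepotent: ExGauss
    inhibitory_cost_ms: float = 0.0
    p_anticipation: float = 0.0
    p_distraction: float = 0.0
    p_invalid: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        _check_prob("p_correct_prepotent", self.p_correct_prepotent)
        _check_prob("p_correct_inhibitory", self.p_correct_inhibitory)
        for name in ("p_anticipation", "p_distraction", "p_invalid"):
            _check_prob(name, getattr(self, name))
        if self.p_anticipation + self.p_distraction + self.p_invalid > 1.0:
            raise ValueError("event probabilities must sum to <= 1")


@dataclass(frozen=True)
class RaceModelParams:
    """Ground-truth race-model parameters for stop-signal simulation."""

    go_rt: ExGauss
    ssrt_true: float
    p_trigger_failure: float = 0.0

    def __post_init__(self) -> None:
        if self.ssrt_true <= 0:
            raise ValueError("ssrt_true must be > 0")
        _check_prob("p_trigger_failure", self.p_trigger_failure)


@dataclass(frozen=True)
class StopTrialOutcome:
    inhibited: bool
    rt_ms: float | None


def _draw_scored_rt(
    rng: np.random.Generator, law: ExGauss, variant: Variant
) -> float:
    """Draw an RT in [floor, ceiling); resample so injected event rates stay exact."""
    for _ in range(1000):
        rt = float(law.draw(rng))
        if variant.rt_floor_ms <= rt < variant.rt_ceiling_ms:
            return rt
    return float(np.clip(rt, variant.rt_floor_ms, variant.rt_ceiling_ms - 1))


def simulate_session(
    seq: list[TrialSpec],
    variant: Variant,
    model: ParticipantModel,
    rng: np.random.Generator | None = None,
    participant_id: str = "sim",
    **session_kwargs,
) -> Session:
    """Simulate one session log from a trial sequence.

    One :class:`~ecitt.scoring.TrialRecord` per spec.  In the unresponsive
    variant an incorrect first touch is followed by a corrective touch to the
    correct button (both kept in ``touch_events``); accuracy and RT are always
    taken from the first touch.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    records: list[TrialRecord] = []
    for spec in seq:
        p_correct = (
            model.p_correct_prepotent
            if spec.condition == PREPOTENT
            else model.p_correct_inhibitory
        )
        u = rng.random()
        validity = "valid"
        if u < model.p_invalid:
            validity = EXTERNAL_INVALID_CODES[int(rng.integers(len(EXTERNAL_INVALID_CODES)))]
            correct = bool(rng.random() < p_correct)
            rt = _draw_scored_rt(rng, model.rt_prepotent, variant)
        elif u < model.p_invalid + model.p_anticipation:
            # finger at/near the screen at onset: sub-floor RT, coded invalid
            touched = (spec.smiley_location, other_location(spec.smiley_location))[
                int(rng.integers(2))
            ]
            correct = touched == spec.smiley_location
            rt = float(rng.uniform(80.0, variant.rt_floor_ms))
            validity = "invalid_fast"
            records.append(
                TrialRecord(spec, touched, correct, rt, validity, ((rt, touched),))
            )
            continue
        elif u < model.p_invalid + model.p_anticipation + model.p_distraction:
            correct = bool(rng.random() < p_correct)
            rt = variant.rt_ceiling_ms + float(rng.exponential(1500.0))
        else:
            correct = bool(rng.random() < p_correct)
            law = model.rt_prepotent
            if correct and spec.condition == INHIBITORY:
                law = replace(law, mu=law.mu + model.inhibitory_cost_ms)
            rt = _draw_scored_rt(rng, law, variant)
        touched = spec.smiley_location if correct else other_location(spec.smiley_location)
        events: tuple[tuple[float, str], ...] = ((rt, touched),)
        if variant.incorrect_behavior == "unresponsive" and not correct:
            # the trial only advances on a correct touch; log the correction
            correction_rt = rt + float(rng.uniform(300.0, 1200.0))
            events = ((rt, touched), (correction_rt, spec.smiley_location))
        records.append(TrialRecord(spec, touched, correct, rt, validity, events))
    prep_locs = {s.smiley_location for s in seq if s.condition == PREPOTENT}
    cb = Counterbalance(participant_id, prep_locs.pop() if prep_locs else "top")
    return Session(
        participant_id=participant_id,
        variant=variant,
        counterbalance=cb,
        trials=records,
        **session_kwargs,
    )


# --- cohort simulation -----------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(48)


@functools.lru_cache(maxsize=256)
def _logit_center(target_mean: float, sd: float) -> float:
    """Logit-scale center m such that E[expit(m + sd*Z)] = target_mean, Z ~ N(0,1).

    Without this correction, Gaussian heterogeneity on the logit scale would
    shrink group-mean accuracy toward 50% (Jensen's inequality), so profile
    group means would no longer match their targets.
    """
    if sd == 0.0:
        return float(logit(target_mean))

    def pop_mean(m: float) -> float:
        z = np.sqrt(2.0) * _GH_NODES
        return float(np.sum(_GH_WEIGHTS * expit(m + sd * z)) / np.sqrt(np.pi))

    return float(brentq(lambda m: pop_mean(m) - target_mean, -40.0, 40.0, xtol=1e-10))


def _heterogeneous_prob(target_mean: float, sd: float, z: float) -> float:
    """Draw an individual accuracy with population mean ``target_mean``."""
    if sd == 0.0 or not 0.0 < target_mean < 1.0:
        return float(target_mean)
    return float(expit(_logit_center(target_mean, sd) + sd * z))


def _individual_model(
    profile: AgeProfile, trait_z: float, rng: np.random.Generator
) -> ParticipantModel:
    """Participant-level parameters drawn around a profile.

    ``trait_z`` is the participant's (visit-specific) inhibition trait; it
    drives inhibitory accuracy.  Prepotent accuracy and RT location get
    smaller, independent dispersion (log-normal for RT).
    """
    m = profile.model
    sd = profile.between_subject_sd
    p_inhib = _heterogeneous_prob(m.p_correct_inhibitory, sd, trait_z)
    p_prep = _heterogeneous_prob(m.p_correct_prepotent, 0.5 * sd, float(rng.normal()))
    rt = replace(m.rt_prepotent, mu=m.rt_prepotent.mu * float(np.exp(0.10 * rng.normal())))
    return replace(m, p_correct_inhibitory=p_inhib, p_correct_prepotent=p_prep,
                   rt_prepotent=rt)


@dataclass(frozen=True)
class CohortMember:
    participant_id: str
    profile_label: str
    visit: int
    session: Session
    true_p_inhibitory: float = field(default=float("nan"), compare=False)


def simulate_cohort(
    profiles: list[AgeProfile],
    n_per_profile: int,
    design: str = "cross_sectional",
    stability_r: float = 0.0,
    seed: int = 0,
    variant: Variant | None = None,
    config: BlockConfig | None = None,
) -> list[CohortMember]:
    """Simulate a cohort of sessions.

    ``cross_sectional``: each profile gets ``n_per_profile`` fresh participants
    with one session each.  ``longitudinal``: the profile list is an ordered
    sequence of visits; every participant is simulated at each visit, with the
    visit-level inhibition trait drawn from a shared latent trait so that any
    two visits correlate ``stability_r`` at the latent level.  Counterbalance
    alternates across participants and persists across a participant's visits.
    """
    if n_per_profile < 2:
        raise ValueError("n_per_profile must be >= 2")
    if not -1.0 <= stability_r <= 1.0:
        raise ValueError("stability_r must be in [-1, 1]")
    if design not in {"cross_sectional", "longitudinal"}:
        raise ValueError("design must be 'cross_sectional' or 'longitudinal'")
    from .task import ECITT_S1  # default toddler variant

    variant = variant if variant is not None else ECITT_S1
    config = config if config is not None else default_config(variant)

    members: list[CohortMember] = []
    if design == "longitudinal":
        ids = [f"P{i:03d}" for i in range(n_per_profile)]
        cbs = assign_counterbalance(ids)
        for i, (pid, cb) in enumerate(zip(ids, cbs)):
            prng = np.random.default_rng(np.random.SeedSequence([seed, i]))
            z_shared = float(prng.normal())
            for visit, profile in enumerate(profiles):
                e = float(prng.normal())
                sr = abs(stability_r)
                trait = np.sqrt(sr) * z_shared + np.sqrt(1.0 - sr) * e
                if stability_r < 0 and visit % 2 == 1:
                    trait = -trait
                model = _individual_model(profile, float(trait), prng)
                seq = generate_sequence(config, cb, seed=int(prng.integers(2**31)))
                session = simulate_session(
                    seq, variant, model, rng=prng, participant_id=pid,
                    visit=visit, group=profile.label, age_months=profile.age_months,
                )
                members.append(CohortMember(pid, profile.label, visit, session,
                                            model.p_correct_inhibitory))
    else:
        counter = 0
        for profile in profiles:
            ids = [f"{profile.label}_{i:03d}" for i in range(n_per_profile)]
            cbs = assign_counterbalance(ids)
            for pid, cb in zip(ids, cbs):
                prng = np.random.default_rng(np.random.SeedSequence([seed, counter]))
                counter += 1
                model = _individual_model(profile, float(prng.normal()), prng)
                seq = generate_sequence(config, cb, seed=int(prng.integers(2**31)))
                session = simulate_session(
                    seq, variant, model, rng=prng, participant_id=pid,
                    visit=0, group=profile.label, age_months=profile.age_months,
                )
                members.append(CohortMember(pid, profile.label, 0, session,
                                            model.p_correct_inhibitory))
    return members


def simulate_stop_trial(
    params: RaceModelParams, ssd: float, rng: np.random.Generator
) -> StopTrialOutcome:
    """One stop trial of the independent race.

    The go finish time is drawn from ``go_rt``; the response is inhibited iff
    the stop process (started at ``ssd``, latency ``ssrt_true``) finishes
    strictly first and the stop process was triggered at all.
    """
    if ssd < 0:
        raise ValueError("ssd must be >= 0")
    t_go = float(params.go_rt.draw(rng))
    triggered = rng.random() >= params.p_trigger_failure
    if triggered and ssd + params.ssrt_true < t_go:
        return StopTrialOutcome(inhibited=True, rt_ms=None)
    return StopTrialOutcome(inhibited=False, rt_ms=t_go)
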