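"""Task configuration, constrained trial-sequence generation, and counterbalancing.

The inhibitory touchscreen task presents a target ("smiley") in one of two
screen locations.  One location carries the target on 75% of trials (prepotent
trials, building up a dominant motor response); on the remaining 25% the target
switches to the other location (inhibitory trials, requiring suppression of the
dominant response).  Trial order within a block is randomised under constraints:
a forced prepotent lead-in, an exact inhibitory-trial count, and caps on the
length of same-condition runs.

Sequences are sampled *exactly uniformly* over the set of constraint-satisfying
arrangements.  A dynamic program counts, for each partial state (trials left,
inhibitory trials left, last condition, current run length), the number of valid
completions; each trial is then drawn with probability proportional to the
completion counts.  A config whose valid set is empty raises
:class:`UnsatisfiableConfigError` instead of looping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PREPOTENT",
    "INHIBITORY",
    "TOP",
    "BOTTOM",
    "BlockConfig",
    "Variant",
    "TrialSpec",
    "Counterbalance",
    "Violation",
    "UnsatisfiableConfigError",
    "ECITT_S1",
    "ECITT_S2",
    "ECITT_A",
    "VARIANTS",
    "get_variant",
    "default_config",
    "generate_sequence",
    "validate_sequence",
    "assign_counterbalance",
    "other_location",
]

PREPOTENT = "prepotent"
INHIBITORY = "inhibitory"
TOP = "top"
BOTTOM = "bottom"


class UnsatisfiableConfigError(ValueError):
    """No trial arrangement satisfies the block constraints."""


def other_location(location: str) -> str:
    if location == TOP:
        return BOTTOM
    if location == BOTTOM:
        return TOP
    raise ValueError(f"unknown location: {location!r}")


@dataclass(frozen=True)
class BlockConfig:
    """Constraint set for one experimental block (repeated ``n_blocks`` times).

    Defaults are the toddler task: a single 32-trial block with 8 inhibitory
    trials (25%), a 3-trial prepotent lead-in, and run caps of 5 prepotent /
    2 inhibitory trials in a row.  The adult version uses the same block
    structure three times (96 trials).
    """

    n_trials: int = 32
    n_inhibitory: int = 8
    lead_in: int = 3
    max_run_prepotent: int = 5
    max_run_inhibitory: int = 2
    n_blocks: int = 1

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.n_inhibitory < self.n_trials:
            raise ValueError("n_inhibitory must satisfy 0 <= n_inhibitory < n_trials")
        if self.lead_in < 0 or self.lead_in > self.n_trials - self.n_inhibitory:
            raise ValueError("lead_in must satisfy 0 <= lead_in <= n_trials - n_inhibitory")
        if self.max_run_prepotent < 1 or self.max_run_inhibitory < 1:
            raise ValueError("run caps must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")

    @classmethod
    def ecitt(cls) -> "BlockConfig":
        """Toddler task: one block of 32 trials."""
        return cls()

    @classmethod
    def ecitt_a(cls) -> "BlockConfig":
        """Adult task: three blocks of 32 trials (96 trials in total)."""
        return cls(n_blocks=3)


@dataclass(frozen=True)
class Variant:
    """Administration variant of the task.

    ``incorrect_behavior`` describes what the software does after an incorrect
    touch: ``blank_1s`` (buttons disappear, 1 s blank screen, then next trial),
    ``unresponsive`` (the incorrect button does nothing; the trial only advances
    once the correct button is pressed), or ``next_after_iti`` (adult pacing:
    the next trial follows automatically after a fixed inter-trial interval).
    """

    name: str
    incorrect_behavior: str
    rt_floor_ms: int
    rt_ceiling_ms: int = 5000
    discard_first_trial: bool = True

    def __post_init__(self) -> None:
        if self.rt_floor_ms >= self.rt_ceiling_ms:
            raise ValueError("rt_floor_ms must be < rt_ceiling_ms")
        if self.incorrect_behavior not in {"blank_1s", "unresponsive", "next_after_iti"}:
            raise ValueError(f"unknown incorrect_behavior: {self.incorrect_behavior!r}")
        if self.name == "ECITT_S2" and self.incorrect_behavior != "unresponsive":
            raise ValueError("ECITT_S2 requires incorrect_behavior='unresponsive'")


#: Toddler variant with a 1-s blank screen after incorrect touches.
ECITT_S1 = Variant("ECITT_S1", "blank_1s", rt_floor_ms=300, discard_first_trial=True)
#: Toddler variant where the incorrect button is completely unresponsive.
ECITT_S2 = Variant("ECITT_S2", "unresponsive", rt_floor_ms=300, discard_first_trial=True)
#: Fast-paced adult variant (1000 ms ITI, 200 ms RT floor, no first-trial discard).
ECITT_A = Variant("ECITT_A", "next_after_iti", rt_floor_ms=200, discard_first_trial=False)

VARIANTS = {v.name: v for v in (ECITT_S1, ECITT_S2, ECITT_A)}


def get_variant(name: str) -> Variant:
    try:
        return VARIANTS[name]
    except KeyError:
        raise ValueError(f"unknown variant {name!r}; expected one of {sorted(VARIANTS)}") from None


def default_config(variant: "Variant | str") -> BlockConfig:
    """Block configuration conventionally paired with a task variant."""
    name = variant.name if isinstance(variant, Variant) else variant
    if name == "ECITT_A":
        return BlockConfig.ecitt_a()
    if name in VARIANTS:
        return BlockConfig.ecitt()
    raise ValueError(f"unknown variant {name!r}")


@dataclass(frozen=True)
class TrialSpec:
    """Planned stimulus for one trial (0-based indices; files use 1-based)."""

    index: int
    block: int
    condition: str
    smiley_location: str


@dataclass(frozen=True)
class Counterbalance:
    """Which location is the frequent (prepotent) one for a participant.

    Fixed across a participant's longitudinal sessions.
    """

    participant_id: str
    prepotent_location: str

    def __post_init__(self) -> None:
        if self.prepotent_location not in (TOP, BOTTOM):
            raise ValueError("prepotent_location must be 'top' or 'bottom'")


@dataclass(frozen=True)
class Violation:
    block: int
    index: int
    rule: str
    message: str


class _BlockSampler:
    """Exact-uniform sampler over valid condition sequences for one block."""

    def __init__(self, config: BlockConfig) -> None:
        self.config = config
        self._memo: dict[tuple[int, int, str | None, int], int] = {}
        if config.lead_in > config.max_run_prepotent:
            raise UnsatisfiableConfigError(
                f"lead_in={config.lead_in} exceeds max_run_prepotent={config.max_run_prepotent}"
            )
        self._start = (
            config.n_trials - config.lead_in,
            config.n_inhibitory,
            PREPOTENT if config.lead_in > 0 else None,
            config.lead_in,
        )
        self.total = self._count(*self._start)
        if self.total == 0:
            raise UnsatisfiableConfigError(
                f"no sequence satisfies {config!r}: run caps and trial counts are incompatible"
            )

    def _count(self, n_left: int, r: int, last: str | None, run: int) -> int:
        if n_left == 0:
            return 1 if r == 0 else 0
        key = (n_left, r, last, run)
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        cfg = self.config
        total = 0
        # place a prepotent trial
        if n_left - 1 >= r and not (last == PREPOTENT and run >= cfg.max_run_prepotent):
            total += self._count(
                n_left - 1, r, PREPOTENT, run + 1 if last == PREPOTENT else 1
            )
        # place an inhibitory trial
        if r >= 1 and not (last == INHIBITORY and run >= cfg.max_run_inhibitory):
            total += self._count(
                n_left - 1, r - 1, INHIBITORY, run + 1 if last == INHIBITORY else 1
            )
        self._memo[key] = total
        return total

    def _branch_counts(self, n_left: int, r: int, last: str | None, run: int) -> tuple[int, int]:
        cfg = self.config
        c_prep = c_inhib = 0
        if n_left - 1 >= r and not (last == PREPOTENT and run >= cfg.max_run_prepotent):
            c_prep = self._count(n_left - 1, r, PREPOTENT, run + 1 if last == PREPOTENT else 1)
        if r >= 1 and not (last == INHIBITORY and run >= cfg.max_run_inhibitory):
            c_inhib = self._count(n_left - 1, r - 1, INHIBITORY, run + 1 if last == INHIBITORY else 1)
        return c_prep, c_inhib

    def sample(self, rng: np.random.Generator) -> list[str]:
        cfg = self.config
        conditions = [PREPOTENT] * cfg.lead_in
        n_left, r, last, run = self._start
        while n_left > 0:
            c_prep, c_inhib = self._branch_counts(n_left, r, last, run)
            # draw an integer in [0, c_prep + c_inhib) -> exact uniformity
            pick_prep = int(rng.integers(c_prep + c_inhib)) < c_prep
            if pick_prep:
                run = run + 1 if last == PREPOTENT else 1
                last = PREPOTENT
                conditions.append(PREPOTENT)
            else:
                run = run + 1 if last == INHIBITORY else 1
                last = INHIBITORY
                r -= 1
                conditions.append(INHIBITORY)
            n_left -= 1
        return conditions

    def enumerate_valid(self) -> list[tuple[str, ...]]:
        """Exhaustively list all valid condition sequences (small configs only)."""
        out: list[tuple[str, ...]] = []

        def walk(prefix: list[str], n_left: int, r: int, last: str | None, run: int) -> None:
            if n_left == 0:
                if r == 0:
                    out.append(tuple(prefix))
                return
            c_prep, c_inhib = self._branch_counts(n_left, r, last, run)
            if c_prep:
                walk(prefix + [PREPOTENT], n_left - 1, r, PREPOTENT,
                     run + 1 if last == PREPOTENT else 1)
            if c_inhib:
                walk(prefix + [INHIBITORY], n_left - 1, r - 1, INHIBITORY,
                     run + 1 if last == INHIBITORY else 1)

        walk([PREPOTENT] * self.config.lead_in, *self._start)
        return out


def generate_sequence(config: BlockConfig, cb: Counterbalance, seed: int) -> list[TrialSpec]:
    """Generate a full trial sequence (all blocks) for one session.

    Each block is sampled independently and uniformly over the set of
    condition sequences satisfying the config's count, lead-in and run-cap
    constraints.  The same ``seed`` always yields the same sequence.  The
    smiley location follows the participant's counterbalance: prepotent trials
    show the smiley in the prepotent location, inhibitory trials in the other.

    Raises
    ------
    UnsatisfiableConfigError
        If no arrangement satisfies the constraints.
    """
    sampler = _BlockSampler(config)
    root = np.random.SeedSequence(seed)
    specs: list[TrialSpec] = []
    for block, child in enumerate(root.spawn(config.n_blocks)):
        rng = np.random.default_rng(child)
        for index, condition in enumerate(sampler.sample(rng)):
            location = (
                cb.prepotent_location
                if condition == PREPOTENT
                else other_location(cb.prepotent_location)
            )
            specs.append(TrialSpec(index=index, block=block, condition=condition,
                                   smiley_location=location))
    return specs


def validate_sequence(seq: list[TrialSpec], config: BlockConfig) -> list[Violation]:
    """Check a trial sequence against the block constraints.

    Returns an empty list iff the sequence satisfies every generator
    postcondition: block count and length, exact inhibitory count, prepotent
    lead-in, run caps, and a consistent condition/location mapping.
    """
    violations: list[Violation] = []
    blocks: dict[int, list[TrialSpec]] = {}
    for spec in seq:
        blocks.setdefault(spec.block, []).append(spec)
    if sorted(blocks) != list(range(config.n_blocks)):
        violations.append(Violation(-1, -1, "n_blocks",
                                    f"expected blocks 0..{config.n_blocks - 1}, got {sorted(blocks)}"))

    prep_locations = {s.smiley_location for s in seq if s.condition == PREPOTENT}
    inhib_locations = {s.smiley_location for s in seq if s.condition == INHIBITORY}
    if len(prep_locations) > 1 or len(inhib_locations) > 1 or (prep_locations & inhib_locations):
        violations.append(Violation(-1, -1, "location_consistency",
                                    "conditions must map to two fixed, distinct locations"))

    for block, trials in sorted(blocks.items()):
        trials = sorted(trials, key=lambda s: s.index)
        if len(trials) != config.n_trials:
            violations.append(Violation(block, -1, "block_length",
                                        f"block {block} has {len(trials)} trials, expected {config.n_trials}"))
        n_inhib = sum(s.condition == INHIBITORY for s in trials)
        if n_inhib != config.n_inhibitory:
            violations.append(Violation(block, -1, "n_inhibitory",
                                        f"block {block} has {n_inhib} inhibitory trials, expected {config.n_inhibitory}"))
        for s in trials[: config.lead_in]:
            if s.condition != PREPOTENT:
                violations.append(Violation(block, s.index, "lead_in",
                                            f"lead_in at index {s.index}: first {config.lead_in} trials must be prepotent"))
        run_cond: str | None = None
        run_len = 0
        for s in trials:
            if s.condition == run_cond:
                run_len += 1
            else:
                run_cond = s.condition
                run_len = 1
            cap = (config.max_run_prepotent if run_cond == PREPOTENT
                   else config.max_run_inhibitory)
            if run_len == cap + 1:  # report once per offending run
                rule = ("max_run_prepotent" if run_cond == PREPOTENT
                        else "max_run_inhibitory")
                violations.append(Violation(block, s.index, rule,
                                            f"{rule} at index {s.index}"))
    return violations


def assign_counterbalance(participant_ids: list[str]) -> list[Counterbalance]:
    """Alternate the prepotent location (top/bottom) across participants.

    Deterministic given the input order; the two locations differ in count by
    at most one.  Duplicate ids are rejected.
    """
    if not participant_ids:
        raise ValueError("participant_ids must be non-empty")
    if len(set(participant_ids)) != len(participant_ids):
        raise ValueError("duplicate participant ids")
    return [
        Counterbalance(pid, TOP if i % 2 == 0 else BOTTOM)
        for i, pid in enumerate(participant_ids)
    ]
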