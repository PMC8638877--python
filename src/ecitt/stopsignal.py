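"""Stop-signal task engine: staircase SSD tracking and SSRT estimation.

The task interleaves choice ("go") trials with rarer stop trials on which a
tone sounds at a stop-signal delay (SSD) after the go stimulus.  A one-up /
one-down staircase moves the SSD by a fixed step after every stop trial
(successful inhibition -> +step, failed stop -> -step), converging on the
delay at which stopping succeeds ~50% of the time.  The stop-signal reaction
time is then

    SSRT = median go RT - SSD(at 50% stopping),

both taken over the second half of sub-blocks, after the staircase has
stabilised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .simulate import RaceModelParams, simulate_stop_trial

__all__ = [
    "SSTConfig",
    "SSTTrial",
    "SSTResult",
    "build_sst_sequence",
    "run_staircase",
    "estimate_ssrt",
    "simple_rt_summary",
]


@dataclass(frozen=True)
class SSTConfig:
    """Stop-signal task structure and staircase parameters.

    Defaults: 5 blocks x 4 sub-blocks x 16 trials (12 go + 4 stop), 50 ms
    staircase step.  The initial SSD (250 ms) and the SSD clamp bounds
    (0-1150 ms) are configurable conventions.  ``ssd_estimator`` selects how
    "SSD at 50% stopping" is read off the tracking run: ``mean`` (mean SSD
    over second-half stop trials, the default) or ``last`` (final SSD).
    """

    n_practice: int = 16
    n_blocks: int = 5
    trials_per_subblock: int = 16
    go_per_subblock: int = 12
    stop_per_subblock: int = 4
    subblocks_per_block: int = 4
    ssd_step_ms: int = 50
    ssd_init_ms: int = 250
    ssd_bounds_ms: tuple[int, int] = (0, 1150)
    fixation_delay_ms: int = 500
    ssd_estimator: str = "mean"

    def __post_init__(self) -> None:
        if self.go_per_subblock + self.stop_per_subblock != self.trials_per_subblock:
            raise ValueError("go + stop trials must equal trials_per_subblock")
        if self.ssd_step_ms <= 0:
            raise ValueError("ssd_step_ms must be > 0")
        if self.ssd_bounds_ms[0] < 0 or self.ssd_bounds_ms[0] >= self.ssd_bounds_ms[1]:
            raise ValueError("ssd_bounds_ms must satisfy 0 <= floor < ceiling")
        if not self.ssd_bounds_ms[0] <= self.ssd_init_ms <= self.ssd_bounds_ms[1]:
            raise ValueError("ssd_init_ms must lie within ssd_bounds_ms")
        if self.ssd_estimator not in {"mean", "last"}:
            raise ValueError("ssd_estimator must be 'mean' or 'last'")

    @property
    def n_subblocks(self) -> int:
        return self.n_blocks * self.subblocks_per_block

    @property
    def n_trials(self) -> int:
        return self.n_subblocks * self.trials_per_subblock


@dataclass(frozen=True)
class SSTTrial:
    """One stop-signal task trial (spec before the run, outcome after)."""

    subblock_index: int
    direction: str  # left | right
    is_stop: bool
    ssd_ms: float | None = None
    responded: bool | None = None
    response_correct: bool | None = None
    rt_ms: float | None = None


@dataclass(frozen=True)
class SSTResult:
    """A completed stop-signal session plus second-half summary measures."""

    trials: tuple[SSTTrial, ...]
    ssd_trajectory: tuple[float, ...]
    pct_stopped: float
    median_go_rt_ms: float
    ssd_at_50_ms: float
    ssrt_ms: float
    config: SSTConfig = field(repr=False, default=SSTConfig())

    def to_dict(self) -> dict:
        return {
            "ssrt_ms": self.ssrt_ms,
            "ssd_at_50_ms": self.ssd_at_50_ms,
            "median_go_rt_ms": self.median_go_rt_ms,
            "pct_stopped": self.pct_stopped,
            "n_trials": len(self.trials),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def build_sst_sequence(config: SSTConfig, seed: int) -> list[SSTTrial]:
    """Build the trial order: per sub-block, the fixed go/stop mix shuffled.

    Each sub-block holds exactly ``go_per_subblock`` go and
    ``stop_per_subblock`` stop trials in seeded random order, with arrow
    directions balanced within trial type as evenly as the counts allow.
    """
    rng = np.random.default_rng(seed)
    trials: list[SSTTrial] = []
    for sb in range(config.n_subblocks):
        pool: list[tuple[bool, str]] = []
        for is_stop, count in ((False, config.go_per_subblock),
                               (True, config.stop_per_subblock)):
            half = count // 2
            dirs = ["left"] * half + ["right"] * (count - half)
            pool.extend((is_stop, d) for d in dirs)
        order = rng.permutation(len(pool))
        for i in order:
            is_stop, direction = pool[i]
            trials.append(SSTTrial(subblock_index=sb, direction=direction,
                                   is_stop=is_stop))
    return trials


def run_staircase(
    specs: list[SSTTrial],
    params: RaceModelParams,
    config: SSTConfig,
    seed: int | np.random.Generator | None = None,
) -> SSTResult:
    """Run a simulated participant through the staircase.

    The SSD changes only after stop trials (clamped to ``ssd_bounds_ms``);
    go-trial responses are always directionally correct (omission/choice
    errors are outside the scope of this engine).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    floor, ceiling = config.ssd_bounds_ms
    ssd = float(config.ssd_init_ms)
    done: list[SSTTrial] = []
    trajectory: list[float] = []
    for spec in specs:
        if spec.is_stop:
            trajectory.append(ssd)
            outcome = simulate_stop_trial(params, ssd, rng)
            done.append(replace(spec, ssd_ms=ssd, responded=not outcome.inhibited,
                                response_correct=None, rt_ms=outcome.rt_ms))
            step = config.ssd_step_ms if outcome.inhibited else -config.ssd_step_ms
            ssd = float(np.clip(ssd + step, floor, ceiling))
        else:
            rt = float(params.go_rt.draw(rng))
            done.append(replace(spec, responded=True, response_correct=True, rt_ms=rt))
    ssrt, ssd50, med_go, pct = estimate_ssrt(done, config, _full=True)
    return SSTResult(tuple(done), tuple(trajectory), pct, med_go, ssd50, ssrt, config)


def estimate_ssrt(trials: list[SSTTrial], config: SSTConfig, _full: bool = False):
    """SSRT from the second half of sub-blocks: median go RT minus SSD(50%).

    ``SSD at 50% stopping`` is the mean SSD over second-half stop trials
    under the default tracking estimator (or the final SSD with
    ``ssd_estimator='last'``).  Raises if the window has no responded go
    trial or no stop trial.
    """
    half_start = config.n_subblocks // 2
    window = [t for t in trials if t.subblock_index >= half_start]
    go_rts = [t.rt_ms for t in window if not t.is_stop and t.responded and t.rt_ms is not None]
    stops = [t for t in window if t.is_stop]
    if not go_rts or not stops:
        raise ValueError("second-half window lacks responded go trials or stop trials")
    if config.ssd_estimator == "last":
        ssd50 = float(stops[-1].ssd_ms)
    else:
        ssd50 = float(np.mean([t.ssd_ms for t in stops]))
    med_go = simple_rt_summary(go_rts)
    ssrt = med_go - ssd50
    if _full:
        pct = 100.0 * np.mean([not t.responded for t in stops])
        return float(ssrt), ssd50, med_go, float(pct)
    return float(ssrt)


def simple_rt_summary(rts) -> float:
    """Median RT (ms); the median of an even count is the mean of the two
    central values, matching the session-scoring convention."""
    rts = np.asarray(rts, dtype=float)
    if rts.size == 0:
        raise ValueError("need at least one RT")
    return float(np.median(rts))
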