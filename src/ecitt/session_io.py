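"""Session file formats: CSV trial tables with JSON metadata sidecars.

A session on disk is a pair ``<stem>.csv`` + ``<stem>.json``.  The CSV holds
one row per trial with 1-based trial numbering (columns: block, trial,
condition, smiley_location, touched_location, correct, rt_ms, validity,
touch_events); the JSON sidecar holds participant/visit metadata.  Reading is
strict: malformed rows are reported with their line numbers, and the trial
count is cross-checked against the variant's block structure.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .scoring import VALIDITY_CODES, Session, TrialRecord
from .task import (
    BOTTOM,
    INHIBITORY,
    PREPOTENT,
    TOP,
    Counterbalance,
    TrialSpec,
    default_config,
    get_variant,
)

__all__ = [
    "SESSION_COLUMNS",
    "SessionValidationError",
    "write_session",
    "read_session",
    "sequence_frame",
    "write_sequence",
    "RunConfig",
]

SESSION_COLUMNS = [
    "block",
    "trial",
    "condition",
    "smiley_location",
    "touched_location",
    "correct",
    "rt_ms",
    "validity",
    "touch_events",
]


class SessionValidationError(ValueError):
    """Raised on malformed session files; carries per-row error messages."""

    def __init__(self, path, errors: list[str]) -> None:
        self.errors = errors
        super().__init__(f"{path}: " + "; ".join(errors))


def _stem(path: "str | Path") -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix in {".csv", ".json"} else p


def write_session(session: Session, path: "str | Path") -> tuple[Path, Path]:
    """Write ``<stem>.csv`` + ``<stem>.json``; returns both paths."""
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SESSION_COLUMNS)
        for t in session.trials:
            writer.writerow(
                [
                    t.spec.block,
                    t.spec.index + 1,  # 1-based in files
                    t.spec.condition,
                    t.spec.smiley_location,
                    t.touched_location,
                    int(t.correct),
                    "" if t.rt_ms is None else repr(float(t.rt_ms)),
                    t.validity,
                    json.dumps([[float(ms), loc] for ms, loc in t.touch_events]),
                ]
            )
    header = {
        "participant_id": session.participant_id,
        "age_months": session.age_months,
        "visit": session.visit,
        "group": session.group,
        "variant": session.variant.name,
        "counterbalance": {
            "participant_id": session.counterbalance.participant_id,
            "prepotent_location": session.counterbalance.prepotent_location,
        },
        "seed": session.seed,
        "software_version": session.software_version,
    }
    json_path.write_text(json.dumps(header, indent=2) + "\n")
    return csv_path, json_path


def read_session(path: "str | Path") -> Session:
    """Read a session pair back; inverse of :func:`write_session`.

    Raises :class:`SessionValidationError` listing offending CSV rows (line
    numbers include the header line) for negative RTs, unknown validity or
    condition codes, and a trial count inconsistent with the header variant.
    """
    stem = _stem(path)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    header = json.loads(json_path.read_text())
    variant = get_variant(header["variant"])
    cb_raw = header["counterbalance"]
    cb = Counterbalance(cb_raw["participant_id"], cb_raw["prepotent_location"])

    errors: list[str] = []
    trials: list[TrialRecord] = []
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != SESSION_COLUMNS:
            raise SessionValidationError(
                csv_path, [f"bad header: {reader.fieldnames!r}"]
            )
        for lineno, row in enumerate(reader, start=2):
            row_errors: list[str] = []
            condition = row["condition"]
            if condition not in (PREPOTENT, INHIBITORY):
                row_errors.append(f"line {lineno}: unknown condition {condition!r}")
            for col in ("smiley_location", "touched_location"):
                if row[col] not in (TOP, BOTTOM, "none"):
                    row_errors.append(f"line {lineno}: bad {col} {row[col]!r}")
            if row["validity"] not in VALIDITY_CODES:
                row_errors.append(f"line {lineno}: unknown validity {row['validity']!r}")
            rt: float | None = None
            if row["rt_ms"] != "":
                try:
                    rt = float(row["rt_ms"])
                except ValueError:
                    row_errors.append(f"line {lineno}: non-numeric rt_ms {row['rt_ms']!r}")
                else:
                    if rt < 0:
                        row_errors.append(f"line {lineno}: negative rt_ms {rt}")
            if row_errors:
                errors.extend(row_errors)
                continue
            spec = TrialSpec(
                index=int(row["trial"]) - 1,
                block=int(row["block"]),
                condition=condition,
                smiley_location=row["smiley_location"],
            )
            trials.append(
                TrialRecord(
                    spec=spec,
                    touched_location=row["touched_location"],
                    correct=bool(int(row["correct"])),
                    rt_ms=rt,
                    validity=row["validity"],
                    touch_events=tuple(
                        (float(ms), loc) for ms, loc in json.loads(row["touch_events"])
                    ),
                )
            )
    if errors:
        raise SessionValidationError(csv_path, errors)

    config = default_config(variant)
    expected = config.n_trials * config.n_blocks
    if len(trials) != expected:
        raise SessionValidationError(
            csv_path,
            [f"structural error: variant {variant.name} expects {expected} trials, "
             f"file has {len(trials)}"],
        )
    return Session(
        participant_id=header["participant_id"],
        variant=variant,
        counterbalance=cb,
        trials=trials,
        age_months=header.get("age_months"),
        visit=header.get("visit", 0),
        group=header.get("group"),
        seed=header.get("seed"),
        software_version=header.get("software_version", "0.1.0"),
    )


def sequence_frame(seq: list[TrialSpec]) -> pd.DataFrame:
    """Planned sequence as a table (1-based trial numbering, as exported)."""
    return pd.DataFrame(
        {
            "block": [s.block for s in seq],
            "trial": [s.index + 1 for s in seq],
            "condition": [s.condition for s in seq],
            "smiley_location": [s.smiley_location for s in seq],
        }
    )


def write_sequence(seq: list[TrialSpec], path: "str | Path") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sequence_frame(seq).to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class RunConfig:
    """Serializable record of a toolkit invocation; a run is reproducible
    from this object alone."""

    command: str
    variant: str = "ECITT_S1"
    profiles: tuple[str, ...] = ()
    n: int = 0
    design: str = "cross_sectional"
    stability_r: float = 0.0
    seed: int = 0
    b_resamples: int = 1000
    out: str = ""
    extra: tuple[tuple[str, str], ...] = ()

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list)
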