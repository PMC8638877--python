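"""Age-profile library for the simulator.

Profiles are calibrated to the printed group-level accuracy pattern of the
task across age: toddler inhibitory accuracy rises from ~63% at 18 months to
~89% at 24 months (longitudinal cohort) and from ~74% at 24 months to ~92% at
30 months (cross-sectional cohorts), with prepotent accuracy above 90%
throughout; school-age children, young adults and older adults on the
fast-paced version are near ceiling, with small accuracy-difference and
RT-difference scores.  RT distribution shapes are not published for the
toddler task, so toddler ex-Gaussian parameters are field-plausible choices
(documented in the methods note) rather than fitted values.

The library ships as a structured text file (``data/profiles.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import TYPE_CHECKING

import yaml

if TYPE_CHECKING:  # pragma: no cover - import cycle guard (simulate imports us)
    from .simulate import ParticipantModel

__all__ = ["AgeProfile", "load_profiles", "get_profile"]


@dataclass(frozen=True)
class AgeProfile:
    """A participant-population: a central model plus between-subject spread.

    ``between_subject_sd`` is the SD of the Gaussian heterogeneity on the
    logit of inhibitory accuracy (prepotent accuracy gets half that spread;
    the RT location gets a 10% log-normal spread).
    """

    label: str
    model: "ParticipantModel"
    between_subject_sd: float
    age_months: float | None = None


def _profiles_text() -> str:
    return resources.files("ecitt").joinpath("data/profiles.yaml").read_text()


def load_profiles() -> dict[str, AgeProfile]:
    """Load the shipped profile library, keyed by label."""
    from .simulate import ExGauss, ParticipantModel

    raw = yaml.safe_load(_profiles_text())
    out: dict[str, AgeProfile] = {}
    for label, p in raw.items():
        model = ParticipantModel(
            p_correct_prepotent=p["p_correct_prepotent"],
            p_correct_inhibitory=p["p_correct_inhibitory"],
            rt_prepotent=ExGauss(**p["rt_prepotent"]),
            inhibitory_cost_ms=p["inhibitory_cost_ms"],
            p_anticipation=p.get("p_anticipation", 0.0),
            p_distraction=p.get("p_distraction", 0.0),
            p_invalid=p.get("p_invalid", 0.0),
        )
        out[label] = AgeProfile(
            label=label,
            model=model,
            between_subject_sd=p.get("between_subject_sd", 0.0),
            age_months=p.get("age_months"),
        )
    return out


def get_profile(label: str) -> AgeProfile:
    profiles = load_profiles()
    try:
        return profiles[label]
    except KeyError:
        raise ValueError(
            f"unknown profile {label!r}; available: {sorted(profiles)}"
        ) from None
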