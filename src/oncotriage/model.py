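"""Core domain records for digital symptom triage.

Patients on systemic anticancer therapy submit one daily check-in scoring
eleven symptoms on a 0-3 ordinal scale.  Each check-in maps to a single
red/amber/green acuity tier; amber/red alerts are later consolidated into
episode-level review events, and acute-care encounters are cross-referenced
against the preceding 48 hours for safety case-finding.

These types are deliberately passive records; behaviour lives in
:mod:`oncotriage.triage`, :mod:`oncotriage.episodes`,
:mod:`oncotriage.analytics` and :mod:`oncotriage.safety`.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime
from typing import Mapping

from .errors import UnknownSymptom

__all__ = [
    "Symptom",
    "SymptomDomain",
    "Tier",
    "Guidance",
    "Action",
    "EncounterSetting",
    "SafetyCategory",
    "GUIDANCE_BY_TIER",
    "CheckIn",
    "Alert",
    "Episode",
    "ReviewEvent",
    "EpisodeOutcome",
    "EpisodeStats",
    "EnrollmentWindow",
    "ClinicalResponse",
    "AcuteEncounter",
    "SafetyFinding",
    "EncounterAudit",
]


class Symptom(str, enum.Enum):
    """The eleven daily check-in items. The enumeration is closed."""

    TEMPERATURE = "temperature"
    DYSPNEA = "dyspnea"
    NAUSEA_VOMITING = "nausea_vomiting"
    DIARRHEA = "diarrhea"
    CONSTIPATION = "constipation"
    PAIN = "pain"
    BLEEDING_BRUISING = "bleeding_bruising"
    FATIGUE = "fatigue"
    SKIN_RASH = "skin_rash"
    PERIPHERAL_NEUROPATHY = "peripheral_neuropathy"
    ORAL_MUCOSITIS = "oral_mucositis"

    @classmethod
    def parse(cls, name: str) -> "Symptom":
        try:
            return cls(name)
        except ValueError:
            raise UnknownSymptom(name) from None


class SymptomDomain(str, enum.Enum):
    """The nine symptom domains used for episode continuity."""

    GASTROINTESTINAL = "gastrointestinal"
    RESPIRATORY = "respiratory"
    FEVER_TEMPERATURE = "fever_temperature"
    PAIN = "pain"
    MUCOSITIS = "mucositis"
    NEUROPATHY = "neuropathy"
    FATIGUE_WELLBEING = "fatigue_wellbeing"
    BLEEDING_BRUISING = "bleeding_bruising"
    SKIN = "skin"


class Tier(enum.IntEnum):
    """Acuity tier, totally ordered GREEN < AMBER < RED."""

    GREEN = 0
    AMBER = 1
    RED = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def parse(cls, label: str) -> "Tier":
        return cls[label.strip().upper()]


class Guidance(str, enum.Enum):
    """Tier-specific end-screen guidance shown to the patient."""

    REASSURANCE = "reassurance"
    MONITOR_AWAIT_REVIEW = "monitor_await_review"
    URGENT_CONTACT = "urgent_contact"


GUIDANCE_BY_TIER: Mapping[Tier, Guidance] = {
    Tier.GREEN: Guidance.REASSURANCE,
    Tier.AMBER: Guidance.MONITOR_AWAIT_REVIEW,
    Tier.RED: Guidance.URGENT_CONTACT,
}


class Action(enum.IntEnum):
    """Clinical action recorded for an episode, ordered by severity."""

    NONE = 0
    TELEPHONE_ADVICE = 1
    OHAU_ASSESSMENT = 2
    ED_REFERRAL = 3
    ADMISSION = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def parse(cls, label: str) -> "Action":
        return cls[label.strip().upper()]


class EncounterSetting(str, enum.Enum):
    """Acute-care pathway of an encounter."""

    OHAU = "OHAU"
    ED = "ED"
    ADMISSION = "admission"

    @classmethod
    def parse(cls, label: str) -> "EncounterSetting":
        for member in cls:
            if member.value.lower() == label.strip().lower():
                return member
        raise ValueError(f"unknown encounter setting {label!r}")


class SafetyCategory(str, enum.Enum):
    """Predefined safety-signal categories for structured case-finding."""

    MISSED_DETERIORATION = "missed_deterioration"
    DELAYED_ESCALATION = "delayed_escalation"
    INAPPROPRIATE_REASSURANCE = "inappropriate_reassurance"
    TECHNICAL_FAILURE = "technical_failure"


@dataclass(frozen=True)
class CheckIn:
    """One patient-day symptom submission.

    ``scores`` is a total map over the eleven symptoms, each value in
    {0,1,2,3}; ``submitted_at`` must carry an explicit timezone offset.
    ``temperature_c`` is an optional measured temperature used only when the
    policy configures numeric cutpoints.
    """

    checkin_id: str
    patient_id: str
    submitted_at: datetime
    scores: Mapping[Symptom, int]
    temperature_c: float | None = None


@dataclass(frozen=True)
class Alert:
    """Triage output of exactly one check-in."""

    alert_id: str
    checkin_id: str
    patient_id: str
    raised_at: datetime
    tier: Tier
    contributing_symptoms: frozenset[Symptom]
    domains: frozenset[SymptomDomain]
    guidance: Guidance
    in_hours: bool


@dataclass(frozen=True)
class Episode:
    """A group of one patient's amber/red alerts linked by the 48-hour
    window and symptom-domain continuity."""

    episode_id: str
    patient_id: str
    alerts: tuple[Alert, ...]
    domain_set: frozenset[SymptomDomain]
    started_at: datetime
    last_alert_at: datetime
    max_tier: Tier

    def __len__(self) -> int:
        return len(self.alerts)


@dataclass(frozen=True)
class ReviewEvent:
    """One row of the clinician review log."""

    episode_id: str
    responded_at: datetime
    action: Action


@dataclass(frozen=True)
class EpisodeOutcome:
    episode_id: str
    actionable: bool
    action: Action


@dataclass(frozen=True)
class EpisodeStats:
    """Episode-level workload summary."""

    n_alerts_in: int
    n_episodes: int
    mean_alerts_per_episode: float
    alerts_per_episode_range: tuple[int, int]
    episodes_per_patient_median: float
    episodes_per_patient_range: tuple[int, int]
    consolidation_factor: float


@dataclass(frozen=True)
class EnrollmentWindow:
    """Enrollment interval; both endpoints count as expected patient-days."""

    patient_id: str
    enrolled_from: date
    enrolled_to: date

    @property
    def expected_days(self) -> int:
        return (self.enrolled_to - self.enrolled_from).days + 1


@dataclass(frozen=True)
class ClinicalResponse:
    alert_id: str
    responded_at: datetime


@dataclass(frozen=True)
class AcuteEncounter:
    encounter_id: str
    patient_id: str
    occurred_at: datetime
    setting: EncounterSetting
    reason: str = ""


@dataclass(frozen=True)
class SafetyFinding:
    """One candidate safety signal attached to an encounter.

    ``candidate`` is always True: adjudication is a human step and the tool
    only surfaces evidence for review.
    """

    encounter_id: str
    category: SafetyCategory
    evidence: Mapping
    candidate: bool = True


@dataclass(frozen=True)
class EncounterAudit:
    """The 48-hour lookback review of one acute-care encounter.

    Every encounter yields exactly one audit, whether or not any candidate
    findings were flagged; ``evidence`` summarises the check-ins, alerts and
    responses inside the lookback window.
    """

    encounter: AcuteEncounter
    window_start: datetime
    window_end: datetime
    evidence: Mapping
    findings: tuple[SafetyFinding, ...] = field(default_factory=tuple)
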