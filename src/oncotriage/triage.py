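"""Check-in validation and tier mapping.

Each validated check-in yields exactly one alert.  The base tier is the
maximum of the per-symptom tiers; when the multi-amber upgrade is enabled, a
check-in with at least ``multi_amber_threshold`` individually-amber symptoms
is escalated to red.  Contributing symptoms are those whose individual tier
is amber or worse; their image under the policy's domain map gives the
alert's domain set used later for episode continuity.
"""
from __future__ import annotations

from datetime import datetime
from typing import Iterable, Mapping

from .errors import (
    BadTimestamp,
    DuplicateCheckinId,
    MissingSymptom,
    ScoreOutOfRange,
)
from .model import (
    GUIDANCE_BY_TIER,
    Alert,
    CheckIn,
    Symptom,
    Tier,
)
from .policy import MonitoringSchedule, TriagePolicy, default_policy

__all__ = [
    "validate_checkin",
    "map_symptom_tier",
    "triage_checkin",
    "triage_checkins",
    "classify_coverage",
    "alert_id_for",
]


def _parse_timestamp(value) -> datetime:
    if isinstance(value, datetime):
        ts = value
    else:
        try:
            ts = datetime.fromisoformat(str(value))
        except ValueError:
            raise BadTimestamp(value, "unparseable ISO 8601 timestamp") from None
    if ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
        raise BadTimestamp(value, "timestamp lacks an explicit timezone offset")
    return ts


def _score_from_temperature(temp_c: float, policy: TriagePolicy) -> int:
    cut = policy.temperature_cutpoints_c
    assert cut is not None
    return sum(temp_c >= c for c in cut)


def validate_checkin(
    raw_record: Mapping,
    policy: TriagePolicy | None = None,
    *,
    seen_ids: set[str] | None = None,
) -> CheckIn:
    """Validate one raw check-in record (e.g. a CSV/JSONL row).

    The record must supply ``checkin_id``, ``patient_id``, ``submitted_at``
    (ISO 8601 with offset) and a score in {0,1,2,3} for every one of the
    eleven symptoms.  Missing symptoms are never imputed.  When the policy
    configures numeric temperature cutpoints, a ``temperature_c`` field may
    stand in for the ordinal temperature score.

    ``seen_ids`` (optional, mutated in place) enables duplicate-id detection
    across a stream of records.
    """
    policy = policy or default_policy()
    checkin_id = str(raw_record.get("checkin_id", "")).strip()
    patient_id = str(raw_record.get("patient_id", "")).strip()
    if not checkin_id or not patient_id:
        raise MissingSymptom("checkin_id/patient_id", checkin_id or None)
    if seen_ids is not None:
        if checkin_id in seen_ids:
            raise DuplicateCheckinId(checkin_id)
        seen_ids.add(checkin_id)

    submitted_at = _parse_timestamp(raw_record.get("submitted_at"))

    temp_c = raw_record.get("temperature_c")
    temp_c = float(temp_c) if temp_c not in (None, "") else None

    scores: dict[Symptom, int] = {}
    for symptom in Symptom:
        value = raw_record.get(symptom.value)
        if value is None or value == "":
            if (
                symptom is Symptom.TEMPERATURE
                and temp_c is not None
                and policy.temperature_cutpoints_c is not None
            ):
                scores[symptom] = _score_from_temperature(temp_c, policy)
                continue
            raise MissingSymptom(symptom.value, checkin_id)
        try:
            score = int(value)
        except (TypeError, ValueError):
            raise ScoreOutOfRange(symptom.value, value, checkin_id) from None
        if not (isinstance(value, (int, str)) or float(value).is_integer()):
            raise ScoreOutOfRange(symptom.value, value, checkin_id)
        if score not in (0, 1, 2, 3):
            raise ScoreOutOfRange(symptom.value, score, checkin_id)
        scores[symptom] = score

    return CheckIn(
        checkin_id=checkin_id,
        patient_id=patient_id,
        submitted_at=submitted_at,
        scores=scores,
        temperature_c=temp_c,
    )


def map_symptom_tier(symptom: Symptom, score: int, policy: TriagePolicy) -> Tier:
    """Tier of a single symptom score under the policy map."""
    if score not in (0, 1, 2, 3):
        raise ScoreOutOfRange(symptom.value, score)
    return policy.tier_for(symptom, score)


def classify_coverage(ts: datetime, schedule: MonitoringSchedule) -> bool:
    """True iff ``ts`` falls inside the staffed dashboard-monitoring window.

    The timestamp is converted to the schedule's local timezone; the window
    is half-open, so the end time itself is out-of-hours.
    """
    if not isinstance(ts, datetime) or ts.tzinfo is None:
        raise BadTimestamp(ts, "coverage classification needs an aware timestamp")
    local = ts.astimezone(schedule.tzinfo())
    if local.weekday() not in schedule.staffed_weekdays:
        return False
    return schedule.window_start <= local.time() < schedule.window_end


def alert_id_for(checkin_id: str) -> str:
    return f"A-{checkin_id}"


def triage_checkin(checkin: CheckIn, policy: TriagePolicy | None = None) -> Alert:
    """Map one validated check-in to its alert."""
    policy = policy or default_policy()
    symptom_tiers = {
        s: policy.tier_for(s, score) for s, score in checkin.scores.items()
    }
    tier = max(symptom_tiers.values())
    n_amber = sum(1 for t in symptom_tiers.values() if t is Tier.AMBER)
    if (
        policy.multi_amber_upgrade
        and tier < Tier.RED
        and n_amber >= policy.multi_amber_threshold
    ):
        tier = Tier.RED
    contributing = frozenset(s for s, t in symptom_tiers.items() if t >= Tier.AMBER)
    domains = frozenset(policy.domain_map[s] for s in contributing)
    return Alert(
        alert_id=alert_id_for(checkin.checkin_id),
        checkin_id=checkin.checkin_id,
        patient_id=checkin.patient_id,
        raised_at=checkin.submitted_at,
        tier=tier,
        contributing_symptoms=contributing,
        domains=domains,
        guidance=GUIDANCE_BY_TIER[tier],
        in_hours=classify_coverage(checkin.submitted_at, policy.schedule),
    )


def triage_checkins(
    checkins: Iterable[CheckIn], policy: TriagePolicy | None = None
) -> list[Alert]:
    """Triage a stream of check-ins; exactly one alert per check-in."""
    policy = policy or default_policy()
    return [triage_checkin(c, policy) for c in checkins]
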