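"""Shared fixtures: policies, record builders, and small alert streams."""
from __future__ import annotations

import itertools
from datetime import datetime, timedelta
from zoneinfo import ZoneInfo

import pytest

from oncotriage.model import Alert, CheckIn, GUIDANCE_BY_TIER, Symptom, Tier
from oncotriage.policy import default_policy
from oncotriage.triage import alert_id_for, classify_coverage

LONDON = ZoneInfo("Europe/London")
#: A Tuesday well inside the study window (BST).
T0 = datetime(2025, 7, 15, 10, 0, tzinfo=LONDON)

_counter = itertools.count(1)


@pytest.fixture
def policy():
    return default_policy()


def make_checkin(
    scores: dict | None = None,
    *,
    at: datetime = T0,
    patient_id: str = "P001",
    checkin_id: str | None = None,
) -> CheckIn:
    """A complete check-in; unnamed symptoms score 0."""
    full = {s: 0 for s in Symptom}
    for name, value in (scores or {}).items():
        key = name if isinstance(name, Symptom) else Symptom(name)
        full[key] = value
    return CheckIn(
        checkin_id=checkin_id or f"C{next(_counter):05d}",
        patient_id=patient_id,
        submitted_at=at,
        scores=full,
    )


def make_alert(
    *,
    tier: Tier,
    domains,
    at: datetime,
    patient_id: str = "P001",
    checkin_id: str | None = None,
    policy=None,
) -> Alert:
    """A bare alert for episode-engine tests (domains given directly)."""
    policy = policy or default_policy()
    cid = checkin_id or f"C{next(_counter):05d}"
    return Alert(
        alert_id=alert_id_for(cid),
        checkin_id=cid,
        patient_id=patient_id,
        raised_at=at,
        tier=tier,
        contributing_symptoms=frozenset(),
        domains=frozenset(domains),
        guidance=GUIDANCE_BY_TIER[tier],
        in_hours=classify_coverage(at, policy.schedule),
    )


def hours(h: float) -> timedelta:
    return timedelta(hours=h)
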