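"""Structured safety case-finding.

Every acute-care encounter (OHAU attendance, ED presentation, unplanned
admission) is cross-referenced against the preceding 48 hours of check-ins,
alerts and clinical responses.  Four predefined candidate rules are applied:

* ``missed_deterioration`` — no amber/red alert in the lookback, but a green
  check-in exists on the encounter's local calendar day before presentation;
* ``delayed_escalation`` — an in-hours red alert in the lookback whose first
  clinical response exceeded the threshold (default 2 hours; a red alert
  with no response at all counts as exceeded);
* ``inappropriate_reassurance`` — a check-in tiered green by the production
  policy contains a symptom score that a reference audit policy would tier
  amber or worse;
* ``technical_failure`` — a check-in in the lookback with no corresponding
  alert record.

Findings are candidates for human adjudication only; the tool never asserts
that harm occurred or was attributable to the workflow.
"""
from __future__ import annotations

from datetime import timedelta
from typing import Iterable, Mapping, Sequence

from .errors import UnknownPatient
from .model import (
    AcuteEncounter,
    Alert,
    CheckIn,
    ClinicalResponse,
    EncounterAudit,
    EnrollmentWindow,
    SafetyCategory,
    SafetyFinding,
    Tier,
)
from .policy import TriagePolicy, default_policy
from .triage import map_symptom_tier

__all__ = ["case_find", "safety_report", "LOOKBACK_HOURS"]

LOOKBACK_HOURS = 48.0


def _evidence(checkins, alerts, responses) -> dict:
    return {
        "checkins": [
            {
                "checkin_id": c.checkin_id,
                "submitted_at": c.submitted_at.isoformat(),
                "scores": {s.value: v for s, v in sorted(c.scores.items())},
            }
            for c in checkins
        ],
        "alerts": [
            {
                "alert_id": a.alert_id,
                "raised_at": a.raised_at.isoformat(),
                "tier": a.tier.label,
                "in_hours": a.in_hours,
                "domains": sorted(d.value for d in a.domains),
            }
            for a in alerts
        ],
        "responses": [
            {"alert_id": r.alert_id, "responded_at": r.responded_at.isoformat()}
            for r in responses
        ],
    }


def case_find(
    encounters: Iterable[AcuteEncounter],
    checkins: Sequence[CheckIn],
    alerts: Sequence[Alert],
    responses: Sequence[ClinicalResponse],
    policy: TriagePolicy | None = None,
    *,
    windows: Sequence[EnrollmentWindow] | None = None,
    audit_policy: TriagePolicy | None = None,
    delayed_threshold_hours: float = 2.0,
) -> list[EncounterAudit]:
    """Audit every encounter against its 48-hour lookback.

    Returns exactly one :class:`EncounterAudit` per encounter, in
    (patient, time) order, each carrying the full lookback evidence and a
    possibly-empty tuple of candidate findings.  When enrollment ``windows``
    are supplied, an encounter for a patient without an enrollment record
    raises :class:`UnknownPatient`.
    """
    policy = policy or default_policy()
    audit_policy = audit_policy or policy
    tz = policy.schedule.tzinfo()
    lookback = timedelta(hours=LOOKBACK_HOURS)
    threshold = timedelta(hours=delayed_threshold_hours)

    enrolled = {w.patient_id for w in windows} if windows is not None else None
    alerts_by_checkin = {a.checkin_id: a for a in alerts}
    first_response: dict[str, object] = {}
    for r in responses:
        prev = first_response.get(r.alert_id)
        if prev is None or r.responded_at < prev:
            first_response[r.alert_id] = r.responded_at

    audits: list[EncounterAudit] = []
    ordered = sorted(encounters, key=lambda e: (e.patient_id, e.occurred_at, e.encounter_id))
    for enc in ordered:
        if enrolled is not None and enc.patient_id not in enrolled:
            raise UnknownPatient(enc.patient_id)
        t0, t1 = enc.occurred_at - lookback, enc.occurred_at
        lb_checkins = sorted(
            (
                c
                for c in checkins
                if c.patient_id == enc.patient_id and t0 <= c.submitted_at <= t1
            ),
            key=lambda c: (c.submitted_at, c.checkin_id),
        )
        lb_alerts = sorted(
            (
                a
                for a in alerts
                if a.patient_id == enc.patient_id and t0 <= a.raised_at <= t1
            ),
            key=lambda a: (a.raised_at, a.alert_id),
        )
        lb_responses = sorted(
            (
                r
                for r in responses
                if r.alert_id in {a.alert_id for a in lb_alerts}
            ),
            key=lambda r: (r.alert_id, r.responded_at),
        )
        evidence = _evidence(lb_checkins, lb_alerts, lb_responses)
        findings: list[SafetyFinding] = []

        # missed deterioration: only green signal in the lookback, yet the
        # patient presented acutely later the same day.
        enc_date = enc.occurred_at.astimezone(tz).date()
        any_escalating = any(a.tier >= Tier.AMBER for a in lb_alerts)
        green_same_day = any(
            a.tier is Tier.GREEN
            and a.raised_at.astimezone(tz).date() == enc_date
            and a.raised_at <= enc.occurred_at
            for a in lb_alerts
        )
        if not any_escalating and green_same_day:
            findings.append(
                SafetyFinding(enc.encounter_id, SafetyCategory.MISSED_DETERIORATION, evidence)
            )

        # delayed escalation: in-hours red with slow (or absent) first response.
        for a in lb_alerts:
            if a.tier is Tier.RED and a.in_hours:
                responded = first_response.get(a.alert_id)
                delay = None if responded is None else responded - a.raised_at
                if delay is None or delay > threshold:
                    findings.append(
                        SafetyFinding(
                            enc.encounter_id, SafetyCategory.DELAYED_ESCALATION, evidence
                        )
                    )
                    break

        # inappropriate reassurance: green under the production policy but a
        # score the audit policy would tier amber or worse.
        for c in lb_checkins:
            produced = alerts_by_checkin.get(c.checkin_id)
            if produced is None or produced.tier is not Tier.GREEN:
                continue
            if any(
                map_symptom_tier(s, v, audit_policy) >= Tier.AMBER
                for s, v in c.scores.items()
            ):
                findings.append(
                    SafetyFinding(
                        enc.encounter_id,
                        SafetyCategory.INAPPROPRIATE_REASSURANCE,
                        evidence,
                    )
                )
                break

        # technical failure: check-in present with no alert record at all.
        if any(c.checkin_id not in alerts_by_checkin for c in lb_checkins):
            findings.append(
                SafetyFinding(enc.encounter_id, SafetyCategory.TECHNICAL_FAILURE, evidence)
            )

        audits.append(
            EncounterAudit(
                encounter=enc,
                window_start=t0,
                window_end=t1,
                evidence=evidence,
                findings=tuple(findings),
            )
        )
    return audits


def safety_report(audits: Sequence[EncounterAudit]) -> dict:
    """Per-category counts plus narrative lines.

    Zero candidate findings yields an explicit statement, never an empty
    report.
    """
    counts = {c.value: 0 for c in SafetyCategory}
    for audit in audits:
        for f in audit.findings:
            counts[f.category.value] += 1
    total = sum(counts.values())
    lines = [
        f"Encounters reviewed: {len(audits)}",
        f"Candidate safety findings: {total}",
    ]
    if total == 0:
        lines.append(
            "No candidate safety signals identified by structured case-finding."
        )
    else:
        for cat in SafetyCategory:
            if counts[cat.value]:
                lines.append(f"  {cat.value}: {counts[cat.value]} candidate(s) for review")
    return {
        "n_encounters": len(audits),
        "n_findings": total,
        "by_category": counts,
        "lines": lines,
    }
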