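"""Table readers/writers for the pipeline's CSV/JSONL artifacts.

Schemas are strict: a missing required column fails with
:class:`SchemaMismatch`; unknown columns log a warning and are ignored.
All timestamps must be ISO 8601 with an explicit offset and are normalized
to the configured service timezone at load.  Check-ins may be CSV or JSONL
(``.jsonl``/``.ndjson``) interchangeably.
"""
from __future__ import annotations

import csv
import json
import logging
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence
from zoneinfo import ZoneInfo

from .errors import BadTimestamp, DataError, IOFailure, SchemaMismatch
from .model import (
    AcuteEncounter,
    Action,
    Alert,
    CheckIn,
    ClinicalResponse,
    EncounterSetting,
    EnrollmentWindow,
    Episode,
    EpisodeOutcome,
    ReviewEvent,
    Symptom,
    SymptomDomain,
    Tier,
)
from .model import GUIDANCE_BY_TIER, Guidance
from .policy import TriagePolicy, default_policy
from .triage import validate_checkin

logger = logging.getLogger("oncotriage")

CHECKIN_COLUMNS = ["checkin_id", "patient_id", "submitted_at"] + [
    s.value for s in Symptom
]
_OPTIONAL_CHECKIN = {"temperature_c"}


def _require(path: Path) -> Path:
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    return path


def _read_rows(path: Path) -> tuple[list[str], list[dict]]:
    path = _require(path)
    try:
        if path.suffix in (".jsonl", ".ndjson"):
            rows = [
                json.loads(line)
                for line in path.read_text(encoding="utf-8").splitlines()
                if line.strip()
            ]
            header = sorted({k for r in rows for k in r})
            return header, rows
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return [], []
            return list(reader.fieldnames), list(reader)
    except (OSError, json.JSONDecodeError) as exc:
        raise IOFailure(f"cannot read {path}: {exc}") from exc


def _check_schema(path: Path, header: Sequence[str], required: Sequence[str], optional=()):
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaMismatch(path, missing)
    unknown = [c for c in header if c not in set(required) | set(optional)]
    if unknown:
        logger.warning("%s: ignoring unknown column(s) %s", path, sorted(unknown))


def _parse_ts(value, row_label: str, tz: ZoneInfo) -> datetime:
    try:
        ts = datetime.fromisoformat(str(value))
    except ValueError:
        raise BadTimestamp(value, f"unparseable timestamp in {row_label}") from None
    if ts.tzinfo is None or ts.tzinfo.utcoffset(ts) is None:
        raise BadTimestamp(value, f"timestamp lacks offset in {row_label}")
    return ts.astimezone(tz)


# ---------------------------------------------------------------------------
# check-ins


def read_checkins(path, policy: TriagePolicy | None = None) -> list[CheckIn]:
    policy = policy or default_policy()
    tz = policy.schedule.tzinfo()
    header, rows = _read_rows(Path(path))
    _check_schema(Path(path), header, CHECKIN_COLUMNS, _OPTIONAL_CHECKIN)
    seen: set[str] = set()
    out = []
    for i, row in enumerate(rows, start=1):
        try:
            checkin = validate_checkin(row, policy, seen_ids=seen)
        except BadTimestamp as exc:
            raise BadTimestamp(exc.value, f"row {i} of {path}") from None
        out.append(
            CheckIn(
                checkin_id=checkin.checkin_id,
                patient_id=checkin.patient_id,
                submitted_at=checkin.submitted_at.astimezone(tz),
                scores=checkin.scores,
                temperature_c=checkin.temperature_c,
            )
        )
    logger.info("read %d check-ins from %s", len(out), path)
    return out


def write_checkins(checkins: Iterable[CheckIn], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CHECKIN_COLUMNS)
        for c in checkins:
            writer.writerow(
                [c.checkin_id, c.patient_id, c.submitted_at.isoformat()]
                + [c.scores[s] for s in Symptom]
            )


# ---------------------------------------------------------------------------
# alerts


ALERT_COLUMNS = [
    "alert_id",
    "checkin_id",
    "patient_id",
    "raised_at",
    "tier",
    "contributing_symptoms",
    "domains",
    "guidance",
    "in_hours",
]


def write_alerts(alerts: Iterable[Alert], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ALERT_COLUMNS)
        for a in alerts:
            writer.writerow(
                [
                    a.alert_id,
                    a.checkin_id,
                    a.patient_id,
                    a.raised_at.isoformat(),
                    a.tier.label,
                    ";".join(sorted(s.value for s in a.contributing_symptoms)),
                    ";".join(sorted(d.value for d in a.domains)),
                    a.guidance.value,
                    str(a.in_hours).lower(),
                ]
            )


def read_alerts(path, policy: TriagePolicy | None = None) -> list[Alert]:
    policy = policy or default_policy()
    tz = policy.schedule.tzinfo()
    header, rows = _read_rows(Path(path))
    _check_schema(Path(path), header, ALERT_COLUMNS)
    out = []
    for i, row in enumerate(rows, start=1):
        tier = Tier.parse(row["tier"])
        contributing = frozenset(
            Symptom(v) for v in row["contributing_symptoms"].split(";") if v
        )
        domains = frozenset(
            SymptomDomain(v) for v in row["domains"].split(";") if v
        )
        out.append(
            Alert(
                alert_id=row["alert_id"],
                checkin_id=row["checkin_id"],
                patient_id=row["patient_id"],
                raised_at=_parse_ts(row["raised_at"], f"row {i} of {path}", tz),
                tier=tier,
                contributing_symptoms=contributing,
                domains=domains,
                guidance=Guidance(row["guidance"]) if row.get("guidance") else GUIDANCE_BY_TIER[tier],
                in_hours=str(row["in_hours"]).strip().lower() in ("true", "1", "yes"),
            )
        )
    logger.info("read %d alerts from %s", len(out), path)
    return out


# ---------------------------------------------------------------------------
# simple tables


def write_patients(patients: Iterable[str], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id"])
        for p in patients:
            writer.writerow([p])


def read_patients(path) -> list[str]:
    header, rows = _read_rows(Path(path))
    _check_schema(Path(path), header, ["patient_id"])
    return [row["patient_id"] for row in rows]


def write_enrollment(windows: Iterable[EnrollmentWindow], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "enrolled_from", "enrolled_to"])
        for w in windows:
            writer.writerow(
                [w.patient_id, w.enrolled_from.isoformat(), w.enrolled_to.isoformat()]
            )


def read_enrollment(path) -> list[EnrollmentWindow]:
    header, rows = _read_rows(Path(path))
    _check_schema(Path(path), header, ["patient_id", "enrolled_from", "enrolled_to"])
    return [
        EnrollmentWindow(
            patient_id=row["patient_id"],
            enrolled_from=date.fromisoformat(row["enrolled_from"]),
            enrolled_to=date.fromisoformat(row["enrolled_to"]),
        )
        for row in rows
    ]


def write_responses(responses: Iterable[ClinicalResponse], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["alert_id", "responded_at"])
        for r in responses:
            writer.writerow([r.alert_id, r.responded_at.isoformat()])


def read_responses(path, policy: TriagePolicy | None = None) -> list[ClinicalResponse]:
    policy = policy or default_policy()
    tz = policy.schedule.tzinfo()
    header, rows = _read_rows(Path(path))
    _check_schema(Path(path), header, ["alert_id", "responded_at"])
    return [
        ClinicalResponse(
            alert_id=row["alert_id"],
            responded_at=_parse_ts(row["responded_at"], f"row {i} of {path}", tz),
        )
        for i, row in enumerate(rows, start=1)
    ]


def write_review_log(events: Iterable[ReviewEvent], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["episode_id", "responded_at", "action"])
        for e in events:
            writer.writerow([e.episode_id, e.responded_at.isoformat(), e.action.label])


def read_review_log(path, policy: TriagePolicy | None = None) -> list[ReviewEvent]:
    policy = policy or default_policy()
    tz = policy.schedule.tzinfo()
    header, rows = _read_rows(Path(path))
    _check_schema(Path(path), header, ["episode_id", "responded_at", "action"])
    return [
        ReviewEvent(
            episode_id=row["episode_id"],
            responded_at=_parse_ts(row["responded_at"], f"row {i} of {path}", tz),
            action=Action.parse(row["action"]),
        )
        for i, row in enumerate(rows, start=1)
    ]


def write_encounters(encounters: Iterable[AcuteEncounter], path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["encounter_id", "patient_id", "occurred_at", "setting", "reason"])
        for e in encounters:
            writer.writerow(
                [e.encounter_id, e.patient_id, e.occurred_at.isoformat(),
                 e.setting.value, e.reason]
            )


def read_encounters(path, policy: TriagePolicy | None = None) -> list[AcuteEncounter]:
    policy = policy or default_policy()
    tz = policy.schedule.tzinfo()
    header, rows = _read_rows(Path(path))
    _check_schema(
        Path(path), header,
        ["encounter_id", "patient_id", "occurred_at", "setting"], ["reason"],
    )
    return [
        AcuteEncounter(
            encounter_id=row["encounter_id"],
            patient_id=row["patient_id"],
            occurred_at=_parse_ts(row["occurred_at"], f"row {i} of {path}", tz),
            setting=EncounterSetting.parse(row["setting"]),
            reason=row.get("reason", ""),
        )
        for i, row in enumerate(rows, start=1)
    ]


# ---------------------------------------------------------------------------
# episodes and reports


def write_episodes_json(episodes: Sequence[Episode], path) -> None:
    doc = {
        "episodes": [
            {
                "episode_id": e.episode_id,
                "patient_id": e.patient_id,
                "alert_ids": [a.alert_id for a in e.alerts],
                "n_alerts": len(e),
                "domain_set": sorted(d.value for d in e.domain_set),
                "started_at": e.started_at.isoformat(),
                "last_alert_at": e.last_alert_at.isoformat(),
                "max_tier": e.max_tier.label,
            }
            for e in episodes
        ]
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def write_episodes_csv(
    episodes: Sequence[Episode], path, outcomes: Sequence[EpisodeOutcome] = ()
) -> None:
    action_by_id = {o.episode_id: o for o in outcomes}
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["episode_id", "patient_id", "n_alerts", "domain_set", "started_at",
             "last_alert_at", "max_tier", "actionable", "action"]
        )
        for e in episodes:
            o = action_by_id.get(e.episode_id)
            writer.writerow(
                [
                    e.episode_id,
                    e.patient_id,
                    len(e),
                    ";".join(sorted(d.value for d in e.domain_set)),
                    e.started_at.isoformat(),
                    e.last_alert_at.isoformat(),
                    e.max_tier.label,
                    "" if o is None else str(o.actionable).lower(),
                    "" if o is None else o.action.label,
                ]
            )


def write_json(doc, path) -> None:
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def write_findings_jsonl(audits, path) -> None:
    """One JSON line per encounter audit, with embedded lookback evidence."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for audit in audits:
            fh.write(
                json.dumps(
                    {
                        "encounter_id": audit.encounter.encounter_id,
                        "patient_id": audit.encounter.patient_id,
                        "occurred_at": audit.encounter.occurred_at.isoformat(),
                        "setting": audit.encounter.setting.value,
                        "window": [
                            audit.window_start.isoformat(),
                            audit.window_end.isoformat(),
                        ],
                        "categories": [f.category.value for f in audit.findings],
                        "candidate": bool(audit.findings),
                        "evidence": audit.evidence,
                    }
                )
                + "\n"
            )
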