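"""Triage policy: score-to-tier mapping, symptom-domain map, monitoring
schedule, and the episode window.

The published description of the platform states only that the 0-3 ordinal
scores were "UKONS-informed"; the concrete cutpoints are a service
configuration.  The default policy here maps 0 and 1 to green, 2 to amber
and 3 to red for every symptom, and upgrades a check-in with two or more
individually-amber symptoms to red (the multi-amber convention of the UKONS
triage toolkit).  Everything is overridable from a YAML/JSON document; see
:func:`policy_from_dict` for the schema.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from datetime import time
from pathlib import Path
from typing import Mapping
from zoneinfo import ZoneInfo

import yaml

from .errors import InvalidConfig
from .model import Symptom, SymptomDomain, Tier

__all__ = [
    "MonitoringSchedule",
    "TriagePolicy",
    "DEFAULT_DOMAIN_MAP",
    "default_policy",
    "policy_from_dict",
    "load_policy",
]

#: Default symptom -> domain map; the codomain covers all nine domains.
DEFAULT_DOMAIN_MAP: Mapping[Symptom, SymptomDomain] = {
    Symptom.TEMPERATURE: SymptomDomain.FEVER_TEMPERATURE,
    Symptom.DYSPNEA: SymptomDomain.RESPIRATORY,
    Symptom.NAUSEA_VOMITING: SymptomDomain.GASTROINTESTINAL,
    Symptom.DIARRHEA: SymptomDomain.GASTROINTESTINAL,
    Symptom.CONSTIPATION: SymptomDomain.GASTROINTESTINAL,
    Symptom.PAIN: SymptomDomain.PAIN,
    Symptom.BLEEDING_BRUISING: SymptomDomain.BLEEDING_BRUISING,
    Symptom.FATIGUE: SymptomDomain.FATIGUE_WELLBEING,
    Symptom.SKIN_RASH: SymptomDomain.SKIN,
    Symptom.PERIPHERAL_NEUROPATHY: SymptomDomain.NEUROPATHY,
    Symptom.ORAL_MUCOSITIS: SymptomDomain.MUCOSITIS,
}

_DEFAULT_SCORE_TIERS = (Tier.GREEN, Tier.GREEN, Tier.AMBER, Tier.RED)


@dataclass(frozen=True)
class MonitoringSchedule:
    """Staffed dashboard-monitoring window.

    Default: Monday-Friday, [09:00, 17:00) in the service's local timezone.
    The window is half-open, so an alert at exactly 17:00 is out-of-hours.
    """

    staffed_weekdays: frozenset[int] = frozenset({0, 1, 2, 3, 4})
    window_start: time = time(9, 0)
    window_end: time = time(17, 0)
    timezone: str = "Europe/London"

    def tzinfo(self) -> ZoneInfo:
        return ZoneInfo(self.timezone)


@dataclass(frozen=True)
class TriagePolicy:
    """Full triage configuration.

    ``symptom_tier_map`` is total over 11 symptoms x scores 0-3 and
    non-decreasing in score for every symptom; ``domain_map`` is total over
    the symptoms with codomain equal to the nine domains.
    """

    symptom_tier_map: Mapping[tuple[Symptom, int], Tier] = field(
        default_factory=lambda: {
            (s, k): _DEFAULT_SCORE_TIERS[k] for s in Symptom for k in range(4)
        }
    )
    multi_amber_upgrade: bool = True
    multi_amber_threshold: int = 2
    domain_map: Mapping[Symptom, SymptomDomain] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_MAP)
    )
    schedule: MonitoringSchedule = field(default_factory=MonitoringSchedule)
    episode_window_hours: float = 48.0
    #: Optional ascending Celsius thresholds for scores 1, 2, 3, used to derive
    #: a temperature score from a measured value when the ordinal score is
    #: absent. Off by default; the ordinal scale applies to temperature too.
    temperature_cutpoints_c: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for s in Symptom:
            tiers = []
            for k in range(4):
                t = self.symptom_tier_map.get((s, k))
                if t is None:
                    raise InvalidConfig(f"symptom_tier_map missing ({s.value}, {k})")
                tiers.append(t)
            if any(b < a for a, b in zip(tiers, tiers[1:])):
                raise InvalidConfig(
                    f"tier map for {s.value} is not non-decreasing in score: "
                    f"{[t.label for t in tiers]}"
                )
            if s not in self.domain_map:
                raise InvalidConfig(f"domain_map missing symptom {s.value}")
        covered = set(self.domain_map.values())
        if covered != set(SymptomDomain):
            missing = {d.value for d in set(SymptomDomain) - covered}
            raise InvalidConfig(f"domain_map codomain misses domain(s) {sorted(missing)}")
        if self.episode_window_hours <= 0:
            raise InvalidConfig("episode_window_hours must be positive")
        if self.multi_amber_threshold < 1:
            raise InvalidConfig("multi_amber_threshold must be >= 1")
        if self.temperature_cutpoints_c is not None:
            c = self.temperature_cutpoints_c
            if len(c) != 3 or list(c) != sorted(c):
                raise InvalidConfig("temperature_cutpoints_c must be 3 ascending values")

    def tier_for(self, symptom: Symptom, score: int) -> Tier:
        return self.symptom_tier_map[(symptom, score)]

    def to_dict(self) -> dict:
        overrides: dict[str, list[str]] = {}
        for s in Symptom:
            tiers = [self.symptom_tier_map[(s, k)] for k in range(4)]
            if tuple(tiers) != _DEFAULT_SCORE_TIERS:
                overrides[s.value] = [t.label for t in tiers]
        domain_overrides = {
            s.value: d.value
            for s, d in self.domain_map.items()
            if DEFAULT_DOMAIN_MAP[s] is not d
        }
        return {
            "tiers": {
                "default": [t.label for t in _DEFAULT_SCORE_TIERS],
                "overrides": overrides,
            },
            "multi_amber_upgrade": {
                "enabled": self.multi_amber_upgrade,
                "threshold": self.multi_amber_threshold,
            },
            "domain_overrides": domain_overrides,
            "schedule": {
                "weekdays": sorted(self.staffed_weekdays()),
                "start": self.schedule.window_start.isoformat(timespec="minutes"),
                "end": self.schedule.window_end.isoformat(timespec="minutes"),
                "timezone": self.schedule.timezone,
            },
            "episode_window_hours": self.episode_window_hours,
            "temperature_cutpoints_c": (
                list(self.temperature_cutpoints_c)
                if self.temperature_cutpoints_c
                else None
            ),
        }

    def staffed_weekdays(self) -> frozenset[int]:
        return self.schedule.staffed_weekdays


def default_policy() -> TriagePolicy:
    """The package's default policy (see module docstring)."""
    return TriagePolicy()


def _parse_tier_row(name: str, row) -> list[Tier]:
    if not isinstance(row, (list, tuple)) or len(row) != 4:
        raise InvalidConfig(f"tier row for {name!r} must list 4 tiers (scores 0-3)")
    try:
        return [Tier.parse(str(t)) for t in row]
    except KeyError as exc:
        raise InvalidConfig(f"unknown tier in row for {name!r}: {exc}") from None


def policy_from_dict(doc: Mapping) -> TriagePolicy:
    """Build a :class:`TriagePolicy` from a plain config mapping.

    Schema (all keys optional; omitted keys take package defaults)::

        tiers:
          default: [green, green, amber, red]   # tiers for scores 0..3
          overrides: {pain: [green, amber, amber, red]}
        multi_amber_upgrade: {enabled: true, threshold: 2}
        domain_overrides: {constipation: gastrointestinal}
        schedule:
          weekdays: [0, 1, 2, 3, 4]             # Monday=0
          start: "09:00"
          end: "17:00"
          timezone: Europe/London
        episode_window_hours: 48
        temperature_cutpoints_c: [37.5, 38.0, 38.5]   # optional
    """
    if not isinstance(doc, Mapping):
        raise InvalidConfig("policy document must be a mapping")
    base = default_policy()

    tiers_doc = doc.get("tiers", {}) or {}
    default_row = (
        _parse_tier_row("default", tiers_doc["default"])
        if "default" in tiers_doc
        else list(_DEFAULT_SCORE_TIERS)
    )
    tier_map = {(s, k): default_row[k] for s in Symptom for k in range(4)}
    for name, row in (tiers_doc.get("overrides") or {}).items():
        s = Symptom.parse(name)
        for k, t in enumerate(_parse_tier_row(name, row)):
            tier_map[(s, k)] = t

    mau = doc.get("multi_amber_upgrade", {})
    if isinstance(mau, bool):
        mau = {"enabled": mau}
    enabled = bool(mau.get("enabled", base.multi_amber_upgrade))
    threshold = int(mau.get("threshold", base.multi_amber_threshold))

    domain_map = dict(DEFAULT_DOMAIN_MAP)
    for name, dom in (doc.get("domain_overrides") or {}).items():
        domain_map[Symptom.parse(name)] = SymptomDomain(dom)

    sched_doc = doc.get("schedule", {}) or {}
    schedule = MonitoringSchedule(
        staffed_weekdays=frozenset(
            int(d) for d in sched_doc.get("weekdays", sorted(base.staffed_weekdays()))
        ),
        window_start=time.fromisoformat(str(sched_doc.get("start", "09:00"))),
        window_end=time.fromisoformat(str(sched_doc.get("end", "17:00"))),
        timezone=str(sched_doc.get("timezone", base.schedule.timezone)),
    )
    try:
        schedule.tzinfo()
    except Exception as exc:  # unknown IANA name
        raise InvalidConfig(f"unknown timezone {schedule.timezone!r}") from exc

    cut = doc.get("temperature_cutpoints_c")
    return TriagePolicy(
        symptom_tier_map=tier_map,
        multi_amber_upgrade=enabled,
        multi_amber_threshold=threshold,
        domain_map=domain_map,
        schedule=schedule,
        episode_window_hours=float(doc.get("episode_window_hours", 48.0)),
        temperature_cutpoints_c=tuple(cut) if cut else None,
    )


def load_policy(path: str | Path) -> TriagePolicy:
    """Load a policy from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return policy_from_dict(doc or {})


def with_window(policy: TriagePolicy, hours: float) -> TriagePolicy:
    """Copy of ``policy`` with a different episode window."""
    return replace(policy, episode_window_hours=hours)
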