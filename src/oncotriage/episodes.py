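"""Consolidation of amber/red alerts into episode-level triage events.

An episode is initiated by any amber or red alert.  A subsequent amber/red
alert from the same patient joins an open episode when it occurs within the
episode window (default 48 hours, inclusive) of that episode's most recent
alert AND shares at least one symptom domain with the episode's cumulative
domain set.  Otherwise it starts a new episode, so one patient can carry
several concurrent open episodes with distinct symptom patterns.

Tie-breaks when an alert is eligible for more than one open episode: the
episode with the most recent last alert wins, then the larger domain
intersection, then the earliest episode start.  Episodes are never merged.
The whole construction is deterministic for a given input multiset: alerts
are processed per patient in (timestamp, check-in id) order.
"""
from __future__ import annotations

from collections import defaultdict
from datetime import timedelta
from typing import Iterable, Sequence

from .errors import EmptyInput, MixedPatientEpisode, UnknownEpisodeReference
from .model import (
    Action,
    Alert,
    Episode,
    EpisodeOutcome,
    EpisodeStats,
    ReviewEvent,
    SymptomDomain,
    Tier,
)
from .policy import TriagePolicy, default_policy

__all__ = ["build_episodes", "attach_outcomes", "episode_stats"]


class _OpenEpisode:
    __slots__ = ("patient_id", "alerts", "domain_set", "order")

    def __init__(self, patient_id: str, order: int):
        self.patient_id = patient_id
        self.alerts: list[Alert] = []
        self.domain_set: set[SymptomDomain] = set()
        self.order = order  # creation index, final determinism tie-break

    def add(self, alert: Alert) -> None:
        if alert.patient_id != self.patient_id:
            raise MixedPatientEpisode(
                f"alert {alert.alert_id} ({alert.patient_id}) assigned to an "
                f"episode of patient {self.patient_id}"
            )
        self.alerts.append(alert)
        self.domain_set |= alert.domains

    @property
    def last_alert_at(self):
        return self.alerts[-1].raised_at

    @property
    def started_at(self):
        return self.alerts[0].raised_at


def build_episodes(
    alerts: Iterable[Alert], policy: TriagePolicy | None = None
) -> list[Episode]:
    """Group amber/red alerts into episodes.

    Green alerts in the input are ignored.  Returns episodes sorted by
    (patient id, start time), with ids ``{patient_id}-E{k}`` numbered per
    patient in start order.
    """
    policy = policy or default_policy()
    window = timedelta(hours=policy.episode_window_hours)

    by_patient: dict[str, list[Alert]] = defaultdict(list)
    for alert in alerts:
        if alert.tier >= Tier.AMBER:
            by_patient[alert.patient_id].append(alert)

    episodes: list[Episode] = []
    for patient_id in sorted(by_patient):
        stream = sorted(by_patient[patient_id], key=lambda a: (a.raised_at, a.checkin_id))
        open_eps: list[_OpenEpisode] = []
        for alert in stream:
            eligible = [
                ep
                for ep in open_eps
                if alert.raised_at - ep.last_alert_at <= window
                and ep.domain_set & alert.domains
            ]
            if eligible:
                # most recent last alert; then larger domain overlap;
                # then earliest episode start; creation order as final tie.
                target = max(
                    eligible,
                    key=lambda ep: (
                        ep.last_alert_at,
                        len(ep.domain_set & alert.domains),
                        -ep.started_at.timestamp(),
                        -ep.order,
                    ),
                )
            else:
                target = _OpenEpisode(patient_id, order=len(open_eps))
                open_eps.append(target)
            target.add(alert)
        for k, ep in enumerate(
            sorted(open_eps, key=lambda e: (e.started_at, e.order)), start=1
        ):
            episodes.append(
                Episode(
                    episode_id=f"{patient_id}-E{k:03d}",
                    patient_id=patient_id,
                    alerts=tuple(ep.alerts),
                    domain_set=frozenset(ep.domain_set),
                    started_at=ep.started_at,
                    last_alert_at=ep.last_alert_at,
                    max_tier=max(a.tier for a in ep.alerts),
                )
            )
    episodes.sort(key=lambda e: (e.patient_id, e.started_at, e.episode_id))
    return episodes


def attach_outcomes(
    episodes: Sequence[Episode], review_log: Iterable[ReviewEvent]
) -> list[EpisodeOutcome]:
    """Resolve each episode's review outcome from the clinician review log.

    The recorded action is the highest-severity action among the episode's
    review events (none < telephone advice < OHAU assessment < ED referral <
    admission); episodes without review events get ``Action.NONE``.  An
    episode is actionable iff its action is not ``NONE``.
    """
    known = {e.episode_id for e in episodes}
    best: dict[str, Action] = {}
    for event in review_log:
        if event.episode_id not in known:
            raise UnknownEpisodeReference(event.episode_id)
        current = best.get(event.episode_id, Action.NONE)
        best[event.episode_id] = max(current, event.action)
    return [
        EpisodeOutcome(
            episode_id=e.episode_id,
            actionable=best.get(e.episode_id, Action.NONE) is not Action.NONE,
            action=best.get(e.episode_id, Action.NONE),
        )
        for e in episodes
    ]


def episode_stats(episodes: Sequence[Episode]) -> EpisodeStats:
    """Episode-level workload summary.

    The consolidation factor (alerts in / episodes out) equals the mean
    episode size and measures the reduction in discrete review events.
    """
    if not episodes:
        raise EmptyInput("episode statistics are undefined for zero episodes")
    sizes = [len(e) for e in episodes]
    n_alerts = sum(sizes)
    per_patient: dict[str, int] = defaultdict(int)
    for e in episodes:
        per_patient[e.patient_id] += 1
    counts = sorted(per_patient.values())
    mid = len(counts) // 2
    median = (
        float(counts[mid])
        if len(counts) % 2
        else (counts[mid - 1] + counts[mid]) / 2.0
    )
    return EpisodeStats(
        n_alerts_in=n_alerts,
        n_episodes=len(episodes),
        mean_alerts_per_episode=n_alerts / len(episodes),
        alerts_per_episode_range=(min(sizes), max(sizes)),
        episodes_per_patient_median=median,
        episodes_per_patient_range=(counts[0], counts[-1]),
        consolidation_factor=n_alerts / len(episodes),
    )
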