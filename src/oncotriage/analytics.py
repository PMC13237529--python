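"""Descriptive service metrics: engagement, alert distribution, per-patient
red-alert burden, timeliness of clinical response, escalation breakdowns and
run-chart series.

All analyses are descriptive (counts, proportions, medians, ranges), matching
quality-improvement practice.  Every percentage is emitted together with its
numerator and denominator for auditability, and rendered values are rounded
half-up to one decimal place.  Calendar-day logic (engagement patient-days,
same-day response, run-chart bins) uses the service's local timezone, never
UTC.
"""
from __future__ import annotations

import statistics
from collections import Counter, defaultdict
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyInput, EmptyRoster, ZeroExpectedDays
from .model import (
    Action,
    Alert,
    CheckIn,
    ClinicalResponse,
    EnrollmentWindow,
    EpisodeOutcome,
    Tier,
)
from .policy import MonitoringSchedule

__all__ = [
    "round1",
    "pct",
    "engagement_summary",
    "engagement_from_counts",
    "alert_distribution",
    "distribution_from_counts",
    "red_burden",
    "red_coverage",
    "timeliness",
    "escalation_summary",
    "run_chart",
    "plot_run_chart",
    "cohort_report",
    "render_report_text",
]


def round1(value: float | int | Decimal) -> float:
    """Round half-up to one decimal place (presentation convention)."""
    if not isinstance(value, Decimal):
        value = Decimal(repr(float(value)))
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal place, on exact rationals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return float(
        (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


# ---------------------------------------------------------------------------
# engagement


def engagement_from_counts(completed: int, expected: int) -> dict:
    if expected <= 0:
        raise ZeroExpectedDays("expected patient-days must be positive")
    return {"completed": completed, "expected": expected, "pct": pct(completed, expected)}


def engagement_summary(
    checkins: Iterable[CheckIn],
    windows: Sequence[EnrollmentWindow],
    schedule: MonitoringSchedule | None = None,
) -> dict:
    """Completed check-ins divided by expected patient-days.

    A patient-day counts as completed when at least one check-in falls on
    that local calendar date inside the patient's enrollment window; extra
    same-day submissions do not add to the numerator.
    """
    schedule = schedule or MonitoringSchedule()
    tz = schedule.tzinfo()
    expected = sum(w.expected_days for w in windows)
    if expected <= 0:
        raise ZeroExpectedDays("no expected patient-days in enrollment windows")
    window_by_patient = {w.patient_id: w for w in windows}
    days: set[tuple[str, object]] = set()
    for c in checkins:
        local_date = c.submitted_at.astimezone(tz).date()
        w = window_by_patient.get(c.patient_id)
        if w is not None and w.enrolled_from <= local_date <= w.enrolled_to:
            days.add((c.patient_id, local_date))
    return engagement_from_counts(len(days), expected)


# ---------------------------------------------------------------------------
# alert distribution and burden


def distribution_from_counts(green: int, amber: int, red: int) -> dict:
    total = green + amber + red
    out = {"total": total}
    for label, n in (("green", green), ("amber", amber), ("red", red)):
        out[label] = {"n": n, "pct": pct(n, total) if total else 0.0}
    return out


def alert_distribution(alerts: Iterable[Alert]) -> dict:
    """Per-tier alert counts and percentages of all alerts."""
    counts = Counter(a.tier for a in alerts)
    return distribution_from_counts(
        counts.get(Tier.GREEN, 0), counts.get(Tier.AMBER, 0), counts.get(Tier.RED, 0)
    )


def red_burden(alerts: Iterable[Alert], patient_ids: Sequence[str]) -> dict:
    """Per-patient red-alert burden over the full roster.

    Zero-alert patients count, which is why the roster is a required input.
    Reports the fraction of patients with no red alerts and the fraction
    with >=10 (the concentration the service observed).
    """
    roster = list(dict.fromkeys(patient_ids))
    if not roster:
        raise EmptyRoster("red burden needs a nonempty patient roster")
    counts = {p: 0 for p in roster}
    for a in alerts:
        if a.tier is Tier.RED and a.patient_id in counts:
            counts[a.patient_id] += 1
    values = list(counts.values())
    n_zero = sum(1 for v in values if v == 0)
    n_ge10 = sum(1 for v in values if v >= 10)
    return {
        "per_patient": counts,
        "n_patients": len(roster),
        "zero": {"n": n_zero, "pct": pct(n_zero, len(roster))},
        "ge10": {"n": n_ge10, "pct": pct(n_ge10, len(roster))},
    }


def red_coverage(alerts: Iterable[Alert]) -> dict:
    """Split of red alerts into staffed (in-hours) vs out-of-hours."""
    reds = [a for a in alerts if a.tier is Tier.RED]
    n_in = sum(1 for a in reds if a.in_hours)
    total = len(reds)
    return {
        "total_red": total,
        "in_hours": {"n": n_in, "pct": pct(n_in, total) if total else 0.0},
        "out_of_hours": {
            "n": total - n_in,
            "pct": pct(total - n_in, total) if total else 0.0,
        },
    }


# ---------------------------------------------------------------------------
# timeliness


def timeliness(
    alerts: Iterable[Alert],
    responses: Iterable[ClinicalResponse],
    schedule: MonitoringSchedule | None = None,
) -> dict:
    """Time to first clinical response for in-hours red alerts.

    Uses the first response per alert; same-day means the same local
    calendar date as the alert.  Alerts with no recorded response are
    reported separately as unreviewed, not folded into the delay summary.
    """
    schedule = schedule or MonitoringSchedule()
    tz = schedule.tzinfo()
    first: dict[str, object] = {}
    for r in responses:
        prev = first.get(r.alert_id)
        if prev is None or r.responded_at < prev:
            first[r.alert_id] = r.responded_at
    targets = [a for a in alerts if a.tier is Tier.RED and a.in_hours]
    delays_min: list[float] = []
    same_day = 0
    unreviewed = 0
    for a in targets:
        responded = first.get(a.alert_id)
        if responded is None:
            unreviewed += 1
            continue
        delays_min.append((responded - a.raised_at).total_seconds() / 60.0)
        if responded.astimezone(tz).date() == a.raised_at.astimezone(tz).date():
            same_day += 1
    n = len(targets)
    out = {
        "n_in_hours_red": n,
        "n_responded": len(delays_min),
        "n_unreviewed": unreviewed,
        "same_day": {"n": same_day, "pct": pct(same_day, n) if n else 0.0},
    }
    if delays_min:
        out["delay_minutes"] = {
            "median": round1(statistics.median(delays_min)),
            "min": round1(min(delays_min)),
            "max": round1(max(delays_min)),
        }
    else:
        out["delay_minutes"] = None
    return out


# ---------------------------------------------------------------------------
# escalation


def escalation_summary(outcomes: Sequence[EpisodeOutcome]) -> dict:
    """Actionability and action mix, among actionable and all episodes."""
    n = len(outcomes)
    if n == 0:
        raise EmptyInput("no episode outcomes")
    actionable = [o for o in outcomes if o.actionable]
    n_act = len(actionable)
    action_counts = Counter(o.action for o in actionable)
    actions = {}
    for action in (
        Action.TELEPHONE_ADVICE,
        Action.OHAU_ASSESSMENT,
        Action.ED_REFERRAL,
        Action.ADMISSION,
    ):
        k = action_counts.get(action, 0)
        actions[action.label] = {
            "n": k,
            "pct_of_actionable": pct(k, n_act) if n_act else 0.0,
            "pct_of_all": pct(k, n),
        }
    escalated = sum(
        action_counts.get(a, 0)
        for a in (Action.OHAU_ASSESSMENT, Action.ED_REFERRAL, Action.ADMISSION)
    )
    return {
        "n_episodes": n,
        "actionable": {"n": n_act, "pct": pct(n_act, n)},
        "non_actionable": {"n": n - n_act, "pct": pct(n - n_act, n)},
        "actions": actions,
        "escalated_to_acute_care": {"n": escalated, "pct": pct(escalated, n)},
    }


# ---------------------------------------------------------------------------
# run chart


def run_chart(
    checkins: Iterable[CheckIn], schedule: MonitoringSchedule | None = None
) -> dict:
    """Daily check-in counts across the observed span, plus the median line.

    Days inside the span with no check-ins are zero-filled, as a run chart
    requires an unbroken time axis.
    """
    schedule = schedule or MonitoringSchedule()
    tz = schedule.tzinfo()
    dates = [c.submitted_at.astimezone(tz).date() for c in checkins]
    if not dates:
        raise EmptyInput("run chart needs at least one check-in")
    counts = pd.Series(dates).value_counts()
    span = pd.date_range(min(dates), max(dates), freq="D").date
    series = {d: int(counts.get(d, 0)) for d in span}
    return {
        "dates": [d.isoformat() for d in span],
        "counts": [series[d] for d in span],
        "median": float(statistics.median(series.values())),
    }


def plot_run_chart(chart: Mapping, path) -> None:
    """Render a run chart (daily counts + median line) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dates = pd.to_datetime(chart["dates"])
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.plot(dates, chart["counts"], marker="o", markersize=2.5, lw=1, color="#2b6cb0")
    ax.axhline(chart["median"], color="#c05621", ls="--", lw=1,
               label=f"median {chart['median']:g}")
    ax.set_ylabel("check-ins / day")
    ax.legend(frameon=False, loc="lower right")
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# combined report


def cohort_report(
    checkins: Sequence[CheckIn],
    alerts: Sequence[Alert],
    windows: Sequence[EnrollmentWindow],
    responses: Sequence[ClinicalResponse] = (),
    outcomes: Sequence[EpisodeOutcome] = (),
    episode_summary=None,
    schedule: MonitoringSchedule | None = None,
) -> dict:
    """Assemble the full descriptive service report as one JSON-able dict."""
    schedule = schedule or MonitoringSchedule()
    roster = [w.patient_id for w in windows]
    report = {
        "engagement": engagement_summary(checkins, windows, schedule),
        "alert_distribution": alert_distribution(alerts),
        "red_burden": red_burden(alerts, roster) if roster else None,
        "red_coverage": red_coverage(alerts),
        "timeliness": timeliness(alerts, responses, schedule),
        "run_chart": run_chart(checkins, schedule) if checkins else None,
    }
    if episode_summary is not None:
        report["episodes"] = {
            "n_alerts_in": episode_summary.n_alerts_in,
            "n_episodes": episode_summary.n_episodes,
            "mean_alerts_per_episode": round1(episode_summary.mean_alerts_per_episode),
            "alerts_per_episode_range": list(episode_summary.alerts_per_episode_range),
            "episodes_per_patient_median": episode_summary.episodes_per_patient_median,
            "episodes_per_patient_range": list(
                episode_summary.episodes_per_patient_range
            ),
            "consolidation_factor": round1(episode_summary.consolidation_factor),
        }
    if outcomes:
        report["escalation"] = escalation_summary(outcomes)
    return report


def render_report_text(report: Mapping) -> str:
    """Human-readable rendering of :func:`cohort_report` output."""
    lines: list[str] = ["Service report", "=============="]
    eng = report["engagement"]
    lines.append(
        f"Engagement: {eng['completed']}/{eng['expected']} patient-days "
        f"({eng['pct']}%)"
    )
    dist = report["alert_distribution"]
    lines.append(
        "Alerts: "
        + ", ".join(
            f"{t} {dist[t]['n']} ({dist[t]['pct']}%)" for t in ("green", "amber", "red")
        )
        + f" of {dist['total']}"
    )
    if report.get("red_burden"):
        rb = report["red_burden"]
        lines.append(
            f"Red burden: {rb['zero']['n']}/{rb['n_patients']} patients with no red "
            f"alerts ({rb['zero']['pct']}%); {rb['ge10']['n']} with >=10 "
            f"({rb['ge10']['pct']}%)"
        )
    cov = report["red_coverage"]
    lines.append(
        f"Red coverage: {cov['in_hours']['n']} in-hours ({cov['in_hours']['pct']}%), "
        f"{cov['out_of_hours']['n']} out-of-hours"
    )
    tim = report["timeliness"]
    if tim["delay_minutes"]:
        d = tim["delay_minutes"]
        lines.append(
            f"Timeliness (in-hours red): median {d['median']} min "
            f"(range {d['min']}-{d['max']}); same-day {tim['same_day']['n']}/"
            f"{tim['n_in_hours_red']} ({tim['same_day']['pct']}%)"
        )
    if report.get("episodes"):
        ep = report["episodes"]
        lines.append(
            f"Episodes: {ep['n_alerts_in']} amber/red alerts -> {ep['n_episodes']} "
            f"episodes (mean {ep['mean_alerts_per_episode']} alerts/episode, range "
            f"{ep['alerts_per_episode_range'][0]}-{ep['alerts_per_episode_range'][1]}; "
            f"{ep['consolidation_factor']}-fold consolidation)"
        )
    if report.get("escalation"):
        esc = report["escalation"]
        lines.append(
            f"Actionable episodes: {esc['actionable']['n']}/{esc['n_episodes']} "
            f"({esc['actionable']['pct']}%)"
        )
        for label, row in esc["actions"].items():
            lines.append(
                f"  {label}: {row['n']} ({row['pct_of_actionable']}% of actionable)"
            )
    if report.get("run_chart"):
        lines.append(f"Run chart: median {report['run_chart']['median']:g} check-ins/day")
    return "\n".join(lines) + "\n"
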