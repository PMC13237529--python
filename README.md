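# oncotriage

Digital symptom triage for patients on systemic anticancer therapy (SACT),
built around the UK Oncology Nursing Society (UKONS) red/amber/green model
and episode-based clinician review.

Acute oncology services need early warning of treatment toxicity between
scheduled visits. In the monitored-service model this package implements,
patients submit one daily check-in scoring eleven symptoms (temperature,
dyspnea, nausea/vomiting, diarrhea, constipation, pain, bleeding/bruising,
fatigue, skin rash, peripheral neuropathy, oral mucositis) on a 0–3 ordinal
scale. Each check-in maps to a single acuity tier:

* per-symptom tiers come from a configurable score→tier table
  (default 0,1 → green, 2 → amber, 3 → red);
* the check-in tier is the maximum per-symptom tier, upgraded to red when
  two or more symptoms are individually amber (the UKONS multi-amber
  convention);
* green gives reassurance, amber is batch-reviewed, red demands urgent
  contact, with in-hours status judged against the staffed dashboard window
  (Mon–Fri 09:00–17:00, service-local time, half-open).

Raw alerts over-count clinical work, so amber/red alerts are consolidated
into **episodes**: an alert joins a patient's open episode if it arrives
within 48 h of that episode's most recent alert *and* shares at least one of
nine symptom domains with the episode's cumulative domain set; otherwise it
starts a new episode. Episode review outcomes (none < telephone advice <
OHAU assessment < ED referral < admission), engagement, per-tier alert
distribution, per-patient red-alert burden, response timeliness, and
run-chart series make up the service report. A structured safety
case-finding pass cross-references every acute-care encounter against the
preceding 48 h of check-ins, alerts, and responses, flagging candidates for
human adjudication in four predefined categories (missed deterioration,
delayed escalation, inappropriate reassurance, technical failure).

A seeded synthetic cohort generator reproduces the statistical structure of
a real 32-patient, 10-week deployment, so the whole pipeline is exercisable
and testable without patient data. See `docs/methods.md` for the generative
model and its calibration.

## Worked example

```bash
oncotriage all --seed 3 --out-dir run/
cat run/report.txt
```

produces (default 32-patient cohort, seed 3):

```
Service report
==============
Engagement: 1496/1639 patient-days (91.3%)
Alerts: green 1125 (75.2%), amber 237 (15.8%), red 134 (9.0%) of 1496
Red burden: 17/32 patients with no red alerts (53.1%); 4 with >=10 (12.5%)
Red coverage: 63 in-hours (47.0%), 71 out-of-hours
Timeliness (in-hours red): median 45.4 min (range 17.5-231.1); same-day 63/63 (100.0%)
Episodes: 371 amber/red alerts -> 143 episodes (mean 2.6 alerts/episode, range 1-17; 2.6-fold consolidation)
Actionable episodes: 54/143 (37.8%)
  telephone_advice: 26 (48.1% of actionable)
  ohau_assessment: 19 (35.2% of actionable)
  ed_referral: 7 (13.0% of actionable)
  admission: 2 (3.7% of actionable)
Run chart: median 26 check-ins/day
```

Reading it: 91.3% of expected patient-days produced a check-in; about three
quarters of alerts are green; red alerts concentrate in a minority of
patients (17 patients had none, 4 had ten or more); in-hours red alerts were
first reviewed after a median of ~45 minutes, all on the same calendar day;
and episode grouping cut 371 amber/red alerts to 143 discrete review
events. Cohort-level proportions swing noticeably from seed to seed at
n = 32 — patient frailty makes check-ins cluster — which is itself faithful
to a small single-service deployment. `run/` also contains the full JSON report, episode tables,
the run-chart PNG, and the safety case-finding output (`findings.jsonl`,
`safety.json`).

Every step is also available as a library call (`validate_checkin`,
`triage_checkin`, `build_episodes`, `cohort_report`, `case_find`,
`simulate_cohort`, …) and as individual subcommands
(`simulate`, `triage`, `episodes`, `report`, `safety`).

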