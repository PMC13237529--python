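"""Episode consolidation: 48-hour window, domain continuity, outcomes,
workload statistics."""
from __future__ import annotations

import random
from datetime import timedelta

import pytest

from oncotriage.episodes import attach_outcomes, build_episodes, episode_stats
from oncotriage.errors import EmptyInput, UnknownEpisodeReference
from oncotriage.model import Action, ReviewEvent, SymptomDomain, Tier
from oncotriage.policy import default_policy

from .conftest import T0, hours, make_alert

GI = SymptomDomain.GASTROINTESTINAL
RESP = SymptomDomain.RESPIRATORY


def gi_alert(at, tier=Tier.AMBER, patient_id="P001", checkin_id=None):
    return make_alert(
        tier=tier, domains={GI}, at=at, patient_id=patient_id, checkin_id=checkin_id
    )


def chain_48h_oracle(times):
    """Brute-force chain clustering for a single-domain stream: split
    wherever the gap to the previous alert exceeds 48 hours."""
    sizes = []
    current = 1
    for prev, nxt in zip(times, times[1:]):
        if (nxt - prev) <= timedelta(hours=48):
            current += 1
        else:
            sizes.append(current)
            current = 1
    sizes.append(current)
    return sizes


class TestBuildEpisodes:
    def test_single_amber_initiates_episode(self, policy):
        [ep] = build_episodes([gi_alert(T0)], policy)
        assert len(ep) == 1
        assert ep.domain_set == {GI}
        assert ep.max_tier is Tier.AMBER
        assert ep.started_at == ep.last_alert_at == T0

    def test_window_measured_from_most_recent_alert(self, policy):
        alerts = [gi_alert(T0), gi_alert(T0 + hours(47)), gi_alert(T0 + hours(97))]
        eps = build_episodes(alerts, policy)
        assert [len(e) for e in eps] == [2, 1]

    def test_exact_48h_gap_joins(self, policy):
        eps = build_episodes([gi_alert(T0), gi_alert(T0 + hours(48))], policy)
        assert [len(e) for e in eps] == [2]

    def test_disjoint_domains_open_concurrent_episodes(self, policy):
        alerts = [
            gi_alert(T0),
            make_alert(tier=Tier.RED, domains={RESP}, at=T0 + hours(6)),
        ]
        eps = build_episodes(alerts, policy)
        assert len(eps) == 2
        assert {frozenset(e.domain_set) for e in eps} == {
            frozenset({GI}),
            frozenset({RESP}),
        }

    def test_four_alert_chain_within_windows(self, policy):
        alerts = [gi_alert(T0 + hours(40 * k)) for k in range(4)]
        [ep] = build_episodes(alerts, policy)
        assert len(ep) == 4
        assert ep.max_tier is Tier.AMBER

    def test_green_alerts_ignored(self, policy):
        alerts = [make_alert(tier=Tier.GREEN, domains=set(), at=T0), gi_alert(T0)]
        eps = build_episodes(alerts, policy)
        assert sum(len(e) for e in eps) == 1

    def test_cumulative_domain_set_carries_continuity(self, policy):
        """GI -> GI+pain -> pain-only chains through the cumulative set even
        though the first and last alerts share no domain."""
        alerts = [
            gi_alert(T0),
            make_alert(tier=Tier.AMBER, domains={GI, SymptomDomain.PAIN}, at=T0 + hours(20)),
            make_alert(tier=Tier.AMBER, domains={SymptomDomain.PAIN}, at=T0 + hours(40)),
        ]
        [ep] = build_episodes(alerts, policy)
        assert len(ep) == 3
        assert ep.domain_set == {GI, SymptomDomain.PAIN}

    def test_multi_eligible_alert_joins_most_recent_episode(self, policy):
        a1 = gi_alert(T0, checkin_id="A1")
        a2 = make_alert(
            tier=Tier.AMBER, domains={GI, RESP}, at=T0 + hours(10), checkin_id="A2"
        )
        # two concurrent open episodes: force with disjoint-domain starts
        b1 = make_alert(tier=Tier.AMBER, domains={RESP}, at=T0 + hours(2), checkin_id="B1")
        joiner = make_alert(
            tier=Tier.AMBER, domains={GI, RESP}, at=T0 + hours(12), checkin_id="Z9"
        )
        eps = build_episodes([a1, b1, a2, joiner], policy)
        # a2 (eligible for both) joins the RESP episode? No: both eligible;
        # most recent last_alert_at wins (b1 at +2h over a1 at 0h), then the
        # joiner follows the episode updated at +10h.
        by_size = sorted(eps, key=len)
        assert [len(e) for e in by_size] == [1, 3]
        assert by_size[1].alerts[0].checkin_id == "B1"

    def test_max_tier_is_max_over_members(self, policy):
        alerts = [gi_alert(T0), gi_alert(T0 + hours(5), tier=Tier.RED)]
        [ep] = build_episodes(alerts, policy)
        assert ep.max_tier is Tier.RED

    def test_patients_partition_independently(self, policy):
        alerts = [gi_alert(T0, patient_id="P001"), gi_alert(T0 + hours(1), patient_id="P002")]
        eps = build_episodes(alerts, policy)
        assert len(eps) == 2
        assert {e.patient_id for e in eps} == {"P001", "P002"}

    def test_single_domain_streams_match_brute_force_oracle(self, policy):
        rng = random.Random(7)
        for _ in range(300):
            n = rng.randint(1, 12)
            offsets = sorted(
                rng.choice([rng.uniform(0, 240), 48.0 * rng.randint(0, 4)])
                for _ in range(n)
            )
            alerts = [
                gi_alert(T0 + hours(off), checkin_id=f"K{i:03d}")
                for i, off in enumerate(offsets)
            ]
            eps = build_episodes(alerts, policy)
            got = sorted(len(e) for e in eps)
            expected = sorted(chain_48h_oracle([a.raised_at for a in alerts]))
            assert got == expected

    def test_partition_and_window_invariants_random_streams(self, policy):
        rng = random.Random(11)
        domains = list(SymptomDomain)
        for _ in range(150):
            alerts = []
            for i in range(rng.randint(1, 25)):
                doms = set(rng.sample(domains, rng.randint(1, 3)))
                tier = rng.choice([Tier.AMBER, Tier.AMBER, Tier.RED, Tier.GREEN])
                alerts.append(
                    make_alert(
                        tier=tier,
                        domains=doms if tier > Tier.GREEN else set(),
                        at=T0 + hours(rng.uniform(0, 500)),
                        patient_id=f"P{rng.randint(1, 3)}",
                        checkin_id=f"R{i:03d}",
                    )
                )
            eps = build_episodes(alerts, policy)
            member_ids = [a.alert_id for e in eps for a in e.alerts]
            non_green = [a.alert_id for a in alerts if a.tier > Tier.GREEN]
            assert sorted(member_ids) == sorted(non_green)  # partition, no dupes
            for e in eps:
                ts = [a.raised_at for a in e.alerts]
                assert ts == sorted(ts)
                assert all(
                    (b - a) <= timedelta(hours=48) for a, b in zip(ts, ts[1:])
                )
                assert e.domain_set == frozenset().union(*(a.domains for a in e.alerts))

    def test_permutation_invariance(self, policy):
        rng = random.Random(3)
        alerts = [
            gi_alert(T0 + hours(rng.uniform(0, 300)), checkin_id=f"S{i:02d}")
            for i in range(15)
        ]
        reference = {
            frozenset(a.alert_id for a in e.alerts)
            for e in build_episodes(alerts, policy)
        }
        for _ in range(10):
            shuffled = alerts[:]
            rng.shuffle(shuffled)
            got = {
                frozenset(a.alert_id for a in e.alerts)
                for e in build_episodes(shuffled, policy)
            }
            assert got == reference


class TestOutcomes:
    def _episode(self, policy):
        return build_episodes([gi_alert(T0)], policy)

    def test_single_review_event(self, policy):
        eps = self._episode(policy)
        [outcome] = attach_outcomes(
            eps, [ReviewEvent(eps[0].episode_id, T0 + hours(2), Action.TELEPHONE_ADVICE)]
        )
        assert outcome.actionable and outcome.action is Action.TELEPHONE_ADVICE

    def test_highest_action_wins(self, policy):
        eps = self._episode(policy)
        events = [
            ReviewEvent(eps[0].episode_id, T0 + hours(2), Action.TELEPHONE_ADVICE),
            ReviewEvent(eps[0].episode_id, T0 + hours(5), Action.ADMISSION),
        ]
        [outcome] = attach_outcomes(eps, events)
        assert outcome.action is Action.ADMISSION

    def test_unreviewed_episode_not_actionable(self, policy):
        [outcome] = attach_outcomes(self._episode(policy), [])
        assert not outcome.actionable and outcome.action is Action.NONE

    def test_explicit_none_review_not_actionable(self, policy):
        eps = self._episode(policy)
        [outcome] = attach_outcomes(
            eps, [ReviewEvent(eps[0].episode_id, T0 + hours(2), Action.NONE)]
        )
        assert not outcome.actionable

    def test_unknown_episode_reference(self, policy):
        with pytest.raises(UnknownEpisodeReference):
            attach_outcomes(
                self._episode(policy),
                [ReviewEvent("nope", T0, Action.TELEPHONE_ADVICE)],
            )


class TestEpisodeStats:
    def test_hand_computed_sizes(self, policy):
        alerts = (
            [gi_alert(T0, patient_id="P1")]
            + [gi_alert(T0 + hours(5 * k), patient_id="P2") for k in range(2)]
            + [gi_alert(T0 + hours(5 * k), patient_id="P3") for k in range(3)]
        )
        stats = episode_stats(build_episodes(alerts, policy))
        assert stats.n_episodes == 3
        assert stats.n_alerts_in == 6
        assert stats.mean_alerts_per_episode == pytest.approx(2.0)
        assert stats.alerts_per_episode_range == (1, 3)
        assert stats.consolidation_factor == pytest.approx(2.0)

    def test_singletons_floor_consolidation(self, policy):
        alerts = [gi_alert(T0, patient_id=f"P{i}") for i in range(5)]
        stats = episode_stats(build_episodes(alerts, policy))
        assert stats.mean_alerts_per_episode == pytest.approx(1.0)
        assert stats.consolidation_factor >= 1.0

    def test_empty_input_raises_not_nan(self):
        with pytest.raises(EmptyInput):
            episode_stats([])
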