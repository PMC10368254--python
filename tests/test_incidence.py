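import datetime as dt

import pytest

from ehrepi.cohort_builder import (
    build_all_episodes,
    build_exposure_episodes,
    derive_follow_ups,
)
from ehrepi.incidence_engine import (
    WASH_IN_DAYS,
    annual_incidence,
    choose_scale,
    identify_incident_events,
    patient_person_days,
    person_time_by_year,
)
from ehrepi.registry_model import Chronicity, DiseaseDefinition, ObservationWindow
from ehrepi.synthetic_ehr import SimulationConfig, simulate_registry

from conftest import d, follow_up, make_events, make_patient


def oracle_person_days(year, fu, reg, episodes):
    """Independent day-by-day enumeration of one patient's at-risk days.

    A day counts when the patient is eligible (>= 90 days between
    registration and follow-up end), inside follow-up, past the 90-day
    wash-in, and not inside any exposure episode.
    """
    if (fu.end - reg).days < WASH_IN_DAYS:
        return 0
    wash_end = reg + dt.timedelta(days=WASH_IN_DAYS)
    total = 0
    day = dt.date(year, 1, 1)
    while day.year == year:
        if (
            fu.start <= day <= fu.end
            and day >= wash_end
            and not any(ep.onset <= day <= ep.end for ep in episodes)
        ):
            total += 1
        day += dt.timedelta(days=1)
    return total


class TestIncidentEvents:
    def test_wash_in_boundary_at_day_90(self, lifelong_disease):
        """Day 89 after registration is inside the wash-in; day 90 ('90
        days or more') is incident."""
        fu = follow_up(start="2010-01-01", end="2010-12-31")
        reg = d("2010-01-01")
        assert identify_incident_events(
            lifelong_disease, [d("2010-03-31")], reg, fu
        ) == []
        assert identify_incident_events(
            lifelong_disease, [d("2010-04-01")], reg, fu
        ) == [d("2010-04-01")]

    def test_recurrence_lookback_blocks_within_duration(self, acute_disease):
        """Records at day 0, 20, 60 of a 28-day disease: day 20 falls inside
        the look-back of day 0's record, day 60 starts a new illness."""
        fu = follow_up(start="2009-01-01", end="2010-12-31")
        reg = d("2009-01-01")
        base = d("2010-01-01")
        dates = [base + dt.timedelta(days=o) for o in (0, 20, 60)]
        assert identify_incident_events(acute_disease, dates, reg, fu) == [
            dates[0],
            dates[2],
        ]

    def test_lifelong_first_record_in_washin_blocks_forever(self, lifelong_disease):
        """If the first-ever record lands in the wash-in, the patient never
        becomes incident (later records are not first)."""
        fu = follow_up(start="2005-06-01", end="2015-12-31")
        reg = d("2005-12-01")
        events = [d("2006-01-01"), d("2009-01-01")]
        assert identify_incident_events(lifelong_disease, events, reg, fu) == []

    def test_event_outside_follow_up_not_incident(self, lifelong_disease):
        fu = follow_up(start="2010-01-01", end="2010-12-31")
        assert identify_incident_events(
            lifelong_disease, [d("2011-05-01")], d("2009-01-01"), fu
        ) == []

    def test_lookback_boundary_exactly_duration_blocks(self, acute_disease):
        """A prior record exactly duration days before t is still inside the
        look-back window."""
        fu = follow_up(start="2009-01-01", end="2010-12-31")
        reg = d("2009-01-01")
        t0 = d("2010-01-01")
        dates = [t0, t0 + dt.timedelta(days=28)]
        assert identify_incident_events(acute_disease, dates, reg, fu) == [t0]
        dates = [t0, t0 + dt.timedelta(days=29)]
        assert identify_incident_events(acute_disease, dates, reg, fu) == dates

    def test_larger_washin_never_adds_incident_events(self, monkeypatch, acute_disease):
        """Monotonicity: enlarging the wash-in can only shrink the incident
        set."""
        import ehrepi.incidence_engine as ie

        fu = follow_up(start="2009-01-01", end="2012-12-31")
        reg = d("2009-01-01")
        dates = [reg + dt.timedelta(days=o) for o in (30, 95, 200, 600)]
        baseline = identify_incident_events(acute_disease, dates, reg, fu)
        monkeypatch.setattr(ie, "WASH_IN_DAYS", 365)
        stricter = identify_incident_events(acute_disease, dates, reg, fu)
        assert set(stricter) <= set(baseline)


class TestPersonTime:
    def test_full_year_no_event(self, lifelong_disease):
        fu = follow_up(start="2008-01-01", end="2012-12-31")
        assert patient_person_days(2010, fu, d("2008-01-01"), []) == 365

    def test_leap_year(self, lifelong_disease):
        fu = follow_up(start="2008-01-01", end="2012-12-31")
        assert patient_person_days(2012, fu, d("2008-01-01"), []) == 366

    def test_washin_and_onset_bound_the_contribution(self, lifelong_disease):
        """Registration 1 March 2010, onset 15 August 2010: at-risk time is
        the 77 days from the end of wash-in (30 May) up to onset."""
        fu = follow_up(start="2010-03-01", end="2012-12-31")
        eps = build_exposure_episodes(lifelong_disease, [d("2010-08-15")], fu)
        got = patient_person_days(2010, fu, d("2010-03-01"), eps)
        assert got == 77
        assert got == oracle_person_days(2010, fu, d("2010-03-01"), eps)

    def test_year_after_follow_up_end_contributes_zero(self):
        fu = follow_up(start="2005-01-01", end="2009-12-31")
        assert patient_person_days(2010, fu, d("2005-01-01"), []) == 0

    def test_ineligible_short_registration_contributes_zero(self):
        fu = follow_up(start="2010-01-01", end="2010-03-01")
        assert patient_person_days(2010, fu, d("2010-01-01"), []) == 0

    def test_recurrent_disease_readmits_at_risk_time(self, acute_disease):
        """At-risk time pauses during each episode and resumes when the
        episode's expected duration elapses."""
        fu = follow_up(start="2008-01-01", end="2012-12-31")
        eps = build_exposure_episodes(
            acute_disease, [d("2010-03-01"), d("2010-09-01")], fu
        )
        got = patient_person_days(2010, fu, d("2008-01-01"), eps)
        assert got == 365 - 2 * 28
        assert got == oracle_person_days(2010, fu, d("2008-01-01"), eps)


def _random_registry(chronicity, seed):
    duration = None if chronicity is Chronicity.lifelong else 45
    cfg = SimulationConfig(
        n_patients=220,
        window=ObservationWindow(
            start_date=d("2004-01-01"), end_date=d("2013-12-31")
        ),
        exit_hazard=0.08,
        death_hazard=0.02,
        onset_hazard=0.25 if chronicity is not Chronicity.lifelong else 0.06,
        chronicity=chronicity,
        expected_duration_days=duration,
        recurrence_hazard=0.5 if chronicity is not Chronicity.lifelong else 0.0,
        seed=seed,
        truth_replicates=100,
    )
    patients, events, _ = simulate_registry(cfg)
    d_def = cfg.disease_definition()
    followups, _ = derive_follow_ups(patients, uts_applies=True)
    registrations = {p.patient_id: p.registration_date for p in patients}
    episodes = build_all_episodes(d_def, events, followups)
    return cfg, followups, registrations, episodes


@pytest.mark.parametrize("chronicity", [Chronicity.lifelong, Chronicity.acute])
def test_person_time_matches_day_enumeration_oracle(chronicity):
    """On a randomized 220-patient, 10-year registry the interval-arithmetic
    person-time equals an exhaustive day-by-day count, year by year."""
    cfg, followups, registrations, episodes = _random_registry(chronicity, seed=42)
    for year in cfg.window.years:
        expected = sum(
            oracle_person_days(year, fu, registrations[pid], episodes.get(pid, []))
            for pid, fu in followups.items()
        )
        got = person_time_by_year(year, followups, registrations, episodes)
        assert got == expected, f"{chronicity} year {year}"


def test_lifelong_person_time_conservation():
    """Across all years, a lifelong patient's person-days sum to the length
    of [max(fu.start, reg+90), min(onset, fu.end)] within the window."""
    cfg, followups, registrations, episodes = _random_registry(
        Chronicity.lifelong, seed=7
    )
    for pid, fu in followups.items():
        reg = registrations[pid]
        if (fu.end - reg).days < 90:
            continue
        eps = episodes.get(pid, [])
        a = max(fu.start, reg + dt.timedelta(days=90), cfg.window.start_date)
        b_excl = min(
            fu.end + dt.timedelta(days=1),
            cfg.window.end_date + dt.timedelta(days=1),
            eps[0].onset if eps else dt.date.max,
        )
        expected = max(0, (b_excl - a).days)
        total = sum(
            patient_person_days(y, fu, reg, eps) for y in cfg.window.years
        )
        assert total == expected


class TestAnnualIncidence:
    def test_ten_patient_cohort_denominator(self, lifelong_disease):
        """Ten patients fully followed through 2010, one incident lifelong
        case on 1 July: denominator is (9*365 + 181) at-risk days."""
        patients = [
            make_patient(pid=f"p{i}", reg="2008-01-01", last="2010-12-31")
            for i in range(10)
        ]
        events = make_events("p0", ["2010-07-01"])
        window = ObservationWindow(start_date=d("2010-01-01"), end_date=d("2010-12-31"))
        (est,) = annual_incidence(
            lifelong_disease, patients, events, window, scale=100_000
        )
        assert est.numerator == 1
        expected_py = (9 * 365 + 181) / 365.25
        assert est.denominator == pytest.approx(expected_py)
        assert est.rate == pytest.approx(1 / expected_py * 100_000)

    def test_no_events_means_zero_rates(self, lifelong_disease):
        patients = [make_patient(pid="a", reg="2008-01-01", last="2010-12-31")]
        window = ObservationWindow(start_date=d("2009-01-01"), end_date=d("2010-12-31"))
        ests = annual_incidence(lifelong_disease, patients, [], window, scale=1000)
        assert [e.numerator for e in ests] == [0, 0]
        assert all(e.rate == 0 for e in ests)

    def test_rate_is_linear_in_scale(self, lifelong_disease):
        patients = [
            make_patient(pid=f"p{i}", reg="2008-01-01", last="2010-12-31")
            for i in range(5)
        ]
        events = make_events("p0", ["2010-07-01"])
        window = ObservationWindow(start_date=d("2010-01-01"), end_date=d("2010-12-31"))
        (a,) = annual_incidence(lifelong_disease, patients, events, window, scale=10**5)
        (b,) = annual_incidence(lifelong_disease, patients, events, window, scale=10**6)
        assert b.rate == pytest.approx(10 * a.rate)

    def test_zero_denominator_year_reports_missing(self, lifelong_disease):
        patients = [make_patient(pid="a", reg="2008-01-01", last="2009-12-31")]
        window = ObservationWindow(start_date=d("2010-01-01"), end_date=d("2010-12-31"))
        (est,) = annual_incidence(lifelong_disease, patients, [], window, scale=1000)
        assert est.denominator == 0 and est.rate is None

    def test_auto_scale_picks_smallest_power_reaching_one(self):
        assert choose_scale(1, 50_000) == 10**5
        assert choose_scale(1, 200) == 10**3
        assert choose_scale(30, 100) == 10**2
        assert choose_scale(0, 100) == 10**6
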