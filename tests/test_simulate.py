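"""Trajectory simulator: weekly loop semantics, determinism, exact small-horizon law."""

import numpy as np
import pytest

from mdesim.hazards import (
    AGE_GROUPS,
    RECURRENCE_ROW_LABELS,
    AttributeProfile,
    RecoveryParameters,
    RecurrenceParameters,
    TimeConstants,
    recovery_linear_predictor,
    recovery_probability,
)
from mdesim.simulate import (
    SimulationConfig,
    draw_onset_week,
    simulate_cohort,
    simulate_durations,
    simulate_entity,
)


def _never_recur(params):
    return params.replace(Intercept=float("-inf"))


def test_onset_week_support_and_mean(recurrence_params):
    rng = np.random.default_rng(0)
    draws = np.array([draw_onset_week(rng) for _ in range(10_000)])
    assert draws.min() >= 1 and draws.max() <= 104
    # uniform on 1..104: mean 52.5, sd ~30
    assert abs(draws.mean() - 52.5) < 3 * 30.0 / np.sqrt(draws.size)
    rng2 = np.random.default_rng(0)
    assert draws[0] == draw_onset_week(rng2)


def test_forced_recovery_gives_one_week_episodes(recurrence_params):
    # alpha = 5 makes the weekly recovery probability ~1.
    config = SimulationConfig(
        recovery=RecoveryParameters(alpha=5.0),
        recurrence=recurrence_params,
        n_entities_per_profile=20,
        seed=1,
    )
    for record in simulate_cohort(config):
        for ep in record.episodes:
            assert ep.end_week - ep.start_week == 0


def test_never_recur_sentinel_gives_single_episode(recovery_params, recurrence_params):
    config = SimulationConfig(
        recovery=recovery_params,
        recurrence=_never_recur(recurrence_params),
        n_entities_per_profile=30,
        seed=2,
    )
    for record in simulate_cohort(config):
        assert len(record.episodes) == 1


def test_cohort_size_and_determinism(recovery_params, recurrence_params):
    config = SimulationConfig(recovery_params, recurrence_params, n_entities_per_profile=10, seed=3)
    a = simulate_cohort(config)
    b = simulate_cohort(config)
    assert len(a) == 400
    for ra, rb in zip(a, b):
        assert ra.onset_week == rb.onset_week
        assert np.array_equal(ra.depressed, rb.depressed)


def test_growing_cohort_preserves_existing_entities(recovery_params, recurrence_params):
    # Entity draws depend only on (seed, profile index, entity index).
    small = SimulationConfig(recovery_params, recurrence_params, n_entities_per_profile=5, seed=4)
    large = SimulationConfig(recovery_params, recurrence_params, n_entities_per_profile=9, seed=4)
    a = simulate_cohort(small)
    b = simulate_cohort(large)
    for pidx in range(40):
        for i in range(5):
            ra, rb = a[pidx * 5 + i], b[pidx * 9 + i]
            assert ra.onset_week == rb.onset_week
            assert np.array_equal(ra.depressed, rb.depressed)


def test_different_seeds_agree_within_sampling_error(recovery_params, recurrence_params):
    cfgs = [
        SimulationConfig(recovery_params, recurrence_params, n_entities_per_profile=50, seed=s)
        for s in (5, 6)
    ]
    totals = []
    for cfg in cfgs:
        weeks = np.array([r.cumulative_weeks_depressed for r in simulate_cohort(cfg)])
        totals.append(weeks)
    m1, m2 = totals[0].mean(), totals[1].mean()
    assert not np.array_equal(totals[0], totals[1])
    se = np.sqrt(totals[0].var() / totals[0].size + totals[1].var() / totals[1].size)
    assert abs(m1 - m2) < 4 * se


def test_trajectory_invariants(small_cohort_config):
    horizon = small_cohort_config.time.horizon_weeks
    for r in simulate_cohort(small_cohort_config):
        # no depression before onset
        assert not r.depressed[: r.onset_week - 1].any()
        # conservation of depressed weeks
        assert 0 <= r.cumulative_weeks_depressed <= horizon - r.onset_week + 1
        # episodes exactly tile the depressed weeks, disjoint and ordered
        covered = np.zeros(horizon, dtype=bool)
        last_end = 0
        for ep in r.episodes:
            assert ep.start_week > last_end + 1 or last_end == 0
            covered[ep.start_week - 1 : ep.end_week] = True
            last_end = ep.end_week
            assert ep.censored == (ep.end_week == horizon)
        assert np.array_equal(covered, r.depressed)


def test_mean_duration_increases_with_age(recovery_params):
    # Closed form: E[T] = 1 + sum_t prod_{k<=t}(1 - h_k); the published
    # age coefficients are increasingly negative, so expected episode
    # duration rises monotonically across age groups.
    means = []
    weeks = np.arange(1, 209)
    for age in AGE_GROUPS:
        h = recovery_probability(
            recovery_linear_predictor(AttributeProfile(age), weeks, recovery_params)
        )
        means.append(1.0 + np.cumprod(1.0 - h).sum())
    assert all(a < b for a, b in zip(means, means[1:]))


def test_simulated_survival_matches_closed_form_product():
    # With all attribute coefficients zero, survival past t weeks is
    # prod_{k=1..t}(1 - cloglog^-1(alpha + beta ln k)).
    params = RecoveryParameters(alpha=-1.31, log_time=-0.53)
    n = 30_000
    dur, event = simulate_durations(AttributeProfile("12-18"), n, params, seed=9)
    weeks = np.arange(1, 209)
    h = recovery_probability(params.alpha + params.log_time * np.log(weeks))
    surv = np.cumprod(1.0 - h)
    for t in (1, 2, 4, 8, 16, 32):
        emp = np.mean(dur > t)
        se = np.sqrt(surv[t - 1] * (1 - surv[t - 1]) / n)
        assert abs(emp - surv[t - 1]) < 3 * se + 1e-12


def _enumerate_path_law(horizon, p_rec, p_recur):
    """Exact distribution over weekly depressed patterns, onset at week 1.

    Independent brute-force oracle: recursion over weeks mirroring the
    stated week-end transition semantics (recovery and recurrence never
    in the same week; cumulative episode clock).
    """
    law: dict[tuple, float] = {}

    def go(week, state, clock, pattern, prob):
        if week > horizon:
            law[pattern] = law.get(pattern, 0.0) + prob
            return
        if state == "dep":
            c = clock + 1
            pr = p_rec[c - 1]
            go(week + 1, "rec", c, pattern + (1,), prob * pr)
            go(week + 1, "dep", c, pattern + (1,), prob * (1 - pr))
        else:
            go(week + 1, "dep", clock, pattern + (0,), prob * p_recur)
            go(week + 1, "rec", clock, pattern + (0,), prob * (1 - p_recur))

    go(1, "dep", 0, (), 1.0)
    return law


@pytest.mark.parametrize("horizon", [4, 6])
def test_path_distribution_matches_exact_enumeration(horizon):
    recovery = RecoveryParameters(alpha=-0.3, log_time=-0.4)
    recurrence_coeffs = {k: 0.0 for k in RECURRENCE_ROW_LABELS}
    recurrence_coeffs["Intercept"] = -1.0
    recurrence = RecurrenceParameters(recurrence_coeffs)
    time = TimeConstants(
        horizon_weeks=horizon,
        onset_window_weeks=1,
        interview_weeks=(1, horizon),
        past_year_window_weeks=1,
    )
    n = 40_000
    config = SimulationConfig(
        recovery, recurrence, n_entities_per_profile=n, time=time, seed=13
    )
    profile = AttributeProfile("12-18")
    records = simulate_cohort(config, profiles=[profile])

    weeks = np.arange(1, horizon + 1)
    p_rec = np.asarray(recovery_probability(recovery_linear_predictor(profile, weeks, recovery)))
    p_recur = float(np.exp(-1.0) / (1 + np.exp(-1.0)))
    law = _enumerate_path_law(horizon, p_rec, p_recur)
    assert sum(law.values()) == pytest.approx(1.0)

    counts: dict[tuple, int] = {}
    for r in records:
        key = tuple(int(x) for x in r.depressed)
        counts[key] = counts.get(key, 0) + 1
    # every observed pattern must be possible
    assert set(counts) <= set(law)
    for pattern, p in law.items():
        emp = counts.get(pattern, 0) / n
        se = np.sqrt(p * (1 - p) / n)
        assert abs(emp - p) < 3 * se + 1e-9, pattern


def test_simulate_entity_consistent_with_config(recovery_params, recurrence_params):
    config = SimulationConfig(recovery_params, recurrence_params, n_entities_per_profile=1, seed=8)
    rng = np.random.default_rng(123)
    record = simulate_entity(AttributeProfile("26-45", pain=True), config, rng)
    assert 1 <= record.onset_week <= 104
    assert record.depressed[record.onset_week - 1]


def test_reset_clock_flag_changes_later_episodes(recovery_params, recurrence_params):
    # With a strongly declining hazard, resetting the clock on recurrence
    # makes later episodes shorter on average than under the cumulative
    # clock; at minimum the two readings must produce different cohorts.
    high_recur = recurrence_params.replace(Intercept=-2.0)
    base = dict(recovery=recovery_params, recurrence=high_recur, n_entities_per_profile=80, seed=10)
    cum = simulate_cohort(SimulationConfig(**base, reset_clock_on_recurrence=False))
    reset = simulate_cohort(SimulationConfig(**base, reset_clock_on_recurrence=True))
    w_cum = sum(r.cumulative_weeks_depressed for r in cum)
    w_reset = sum(r.cumulative_weeks_depressed for r in reset)
    assert w_cum != w_reset
    # cumulative clock => lower hazard in later episodes => more depressed weeks
    assert w_cum > w_reset
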