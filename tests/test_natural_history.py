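"""Per-cycle transition operators: examples, conservation, oracle agreement."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcscreen.natural_history import (CohortState, ModelError,
                                      NaturalHistoryParams, apply_clinical_detection,
                                      apply_incidence, apply_mortality,
                                      apply_progression)
from bcscreen.rates import AgeRateSchedule


def make_state(**kw):
    return CohortState(**kw)


class TestIncidence:
    def test_zero_rate_is_identity(self):
        s = make_state(u1=100_000)
        out, tally = apply_incidence(s, 0.0)
        assert out == s
        assert tally.incident_cases == 0

    def test_peak_japanese_rate_yields_146_cases(self):
        s = make_state(u1=100_000)
        out, tally = apply_incidence(s, 0.00146)
        assert tally.incident_cases == pytest.approx(146.0)
        assert out.u2 == pytest.approx(146.0)
        assert out.u1 == pytest.approx(100_000 - 146.0)

    def test_conserves_people(self):
        s = make_state(u1=5000, u2=10, w3=5, du1=100)
        out, _ = apply_incidence(s, 0.3)
        assert out.total == pytest.approx(s.total, rel=1e-12)

    def test_rejects_invalid_rate(self):
        with pytest.raises(ModelError):
            apply_incidence(make_state(u1=1), 1.5)


class TestProgression:
    def test_stage1_to_stage2_at_japanese_rate(self):
        s = make_state(u2=1000)
        out, tally = apply_progression(s, 0.22, 0.06, 0.01)
        assert tally.progressions[0] == pytest.approx(220.0)
        assert out.u3 == pytest.approx(220.0)

    def test_zero_rates_identity(self):
        s = make_state(u2=10, u3=20, u4=30, u5=40)
        out, _ = apply_progression(s, 0, 0, 0)
        assert out == s

    def test_no_double_jump_in_one_cycle(self):
        s = make_state(u2=100, u3=0)
        out, _ = apply_progression(s, 1.0, 1.0, 0.5)
        assert out.u3 == pytest.approx(100.0)
        assert out.u4 == pytest.approx(0.0)

    def test_detected_states_never_move(self):
        s = make_state(u2=10, w2=50, w3=60, w4=70, w5=80)
        out, _ = apply_progression(s, 1.0, 1.0, 1.0)
        assert (out.w2, out.w3, out.w4, out.w5) == (50, 60, 70, 80)


class TestClinicalDetection:
    def test_stage4_outpatient_rate(self):
        s = make_state(u5=100)
        out, tally = apply_clinical_detection(s, 0, 0, 0, 0.40)
        assert out.w5 == pytest.approx(40.0)
        assert tally.clinical_detections == pytest.approx((0, 0, 0, 40.0))

    def test_zero_rates_identity(self):
        s = make_state(u2=10, u3=20)
        out, tally = apply_clinical_detection(s, 0, 0, 0, 0)
        assert out == s
        assert sum(tally.clinical_detections) == 0

    def test_stage_labels_preserved(self):
        s = make_state(u3=100)
        out, tally = apply_clinical_detection(s, 0.5, 0.5, 0.5, 0.5)
        assert out.w3 == pytest.approx(50.0)
        assert out.w2 == 0 and out.w4 == 0 and out.w5 == 0
        assert tally.clinical_detections[1] == pytest.approx(50.0)


class TestMortality:
    def test_detected_stage4_mortality(self):
        s = make_state(w5=100)
        out, tally = apply_mortality(s, 0.0, (0.008, 0.021, 0.062, 0.230), 1.5)
        assert tally.deaths_bc_detected[3] == pytest.approx(23.0)
        assert out.dw4 == pytest.approx(23.0)

    def test_undetected_stage4_uses_multiplied_rate(self):
        s = make_state(u5=100)
        out, tally = apply_mortality(s, 0.0, (0.008, 0.021, 0.062, 0.230), 1.5)
        # delta' = 1.5 * 0.230 = 0.345 (the published table rounds from
        # unrounded delta and prints 0.344)
        assert tally.deaths_bc_undetected[3] == pytest.approx(34.5)
        assert out.du5 == pytest.approx(34.5)

    def test_no_rates_no_deaths(self):
        s = make_state(u1=100, u3=50, w4=20)
        out, tally = apply_mortality(s, 0.0, (0, 0, 0, 0), 1.5)
        assert out == s
        assert tally.deaths_other == 0 and tally.deaths_bc_total == 0

    def test_independent_competing_risks(self):
        mu, delta = 0.1, 0.2
        s = make_state(w2=1000)
        out, tally = apply_mortality(s, mu, (delta, 0, 0, 0), 1.0)
        total_death_p = 1 - (1 - mu) * (1 - delta)
        assert 1000 - out.w2 == pytest.approx(1000 * total_death_p)
        assert tally.deaths_other == pytest.approx(1000 * mu)
        assert tally.deaths_bc_detected[0] == pytest.approx(1000 * (1 - mu) * delta)

    def test_multiplier_one_equalizes_detected_and_undetected(self):
        deltas = (0.01, 0.02, 0.06, 0.2)
        su = make_state(u2=100, u3=100, u4=100, u5=100)
        sw = make_state(w2=100, w3=100, w4=100, w5=100)
        _, tu = apply_mortality(su, 0.05, deltas, 1.0)
        _, tw = apply_mortality(sw, 0.05, deltas, 1.0)
        assert tu.deaths_bc_undetected == pytest.approx(tw.deaths_bc_detected)

    def test_excessive_multiplier_rejected(self):
        with pytest.raises(ModelError):
            apply_mortality(make_state(u5=1), 0.0, (0, 0, 0, 0.5), 2.5)


def brute_force_year(state: dict, h1, h2, h3, h4, f2, f3, f4, f5, mu, deltas, m):
    """Independent single-year oracle: clinical detection, progression,
    incidence, mortality — written directly from the state-flow definitions
    with explicit dictionaries, no shared code with the operators."""
    s = dict(state)
    # clinical detection
    for stage, f in zip((2, 3, 4, 5), (f2, f3, f4, f5)):
        moved = s[f"u{stage}"] * f
        s[f"u{stage}"] -= moved
        s[f"w{stage}"] += moved
    # progression, simultaneous
    m12 = s["u2"] * h2
    m23 = s["u3"] * h3
    m34 = s["u4"] * h4
    s["u2"] -= m12
    s["u3"] += m12 - m23
    s["u4"] += m23 - m34
    s["u5"] += m34
    # incidence
    onset = s["u1"] * h1
    s["u1"] -= onset
    s["u2"] += onset
    # mortality
    s["du1"] += s["u1"] * mu
    s["u1"] *= 1 - mu
    for stage, d in zip((2, 3, 4, 5), deltas):
        p_dead = 1 - (1 - mu) * (1 - m * d)
        s[f"du{stage}"] += s[f"u{stage}"] * (1 - mu) * (m * d)
        s["du1"] += s[f"u{stage}"] * mu
        s[f"u{stage}"] *= 1 - p_dead
    for stage, d in zip((2, 3, 4, 5), deltas):
        s[f"dw{stage - 1}"] += s[f"w{stage}"] * (1 - mu) * d
        s["du1"] += s[f"w{stage}"] * mu
        s[f"w{stage}"] *= (1 - mu) * (1 - d)
    return s


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_operator_chain_matches_brute_force_oracle(seed):
    """One unscreened model year equals the independently coded oracle."""
    rng = np.random.default_rng(seed)
    counts = rng.uniform(0, 1000, size=9)
    state = CohortState(u1=counts[0], u2=counts[1], u3=counts[2], u4=counts[3],
                        u5=counts[4], w2=counts[5], w3=counts[6], w4=counts[7],
                        w5=counts[8])
    h1 = rng.uniform(0, 0.01)
    h = rng.uniform(0, 0.5, size=3)
    f = rng.uniform(0, 0.5, size=4)
    mu = rng.uniform(0, 0.3)
    deltas = rng.uniform(0, 0.3, size=4)
    m = rng.uniform(1.0, 3.0)

    out, _ = apply_clinical_detection(state, *f)
    out, _ = apply_progression(out, *h)
    out, _ = apply_incidence(out, h1)
    out, _ = apply_mortality(out, mu, tuple(deltas), m)

    expected = brute_force_year(
        {fld.name: getattr(state, fld.name) for fld in dataclasses.fields(state)},
        h1, *h, *f, mu, tuple(deltas), m)
    for name in ("u1", "u2", "u3", "u4", "u5", "w2", "w3", "w4", "w5",
                 "du1", "du2", "du3", "du4", "du5", "dw1", "dw2", "dw3", "dw4"):
        assert getattr(out, name) == pytest.approx(expected[name], abs=1e-12, rel=1e-12)
    assert out.total == pytest.approx(state.total, rel=1e-9)


@settings(max_examples=50, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_every_operator_conserves_people(seed):
    """Living plus cumulative dead is invariant under each operator."""
    rng = np.random.default_rng(seed)
    c = rng.uniform(0, 1e5, size=9)
    s = CohortState(u1=c[0], u2=c[1], u3=c[2], u4=c[3], u5=c[4],
                    w2=c[5], w3=c[6], w4=c[7], w5=c[8], du1=rng.uniform(0, 1e4))
    total = s.total
    for out in (
        apply_incidence(s, rng.uniform(0, 1))[0],
        apply_progression(s, *rng.uniform(0, 1, 3))[0],
        apply_clinical_detection(s, *rng.uniform(0, 1, 4))[0],
        apply_mortality(s, rng.uniform(0, 1), tuple(rng.uniform(0, 0.33, 4)),
                        rng.uniform(1, 3))[0],
    ):
        assert out.total == pytest.approx(total, rel=1e-9)
        out.validate(total)


def test_params_validation():
    h1 = AgeRateSchedule.zeros()
    with pytest.raises(ModelError):
        NaturalHistoryParams(h1=h1, mu=h1, h2=1.2, h3=0, h4=0, f2=0, f3=0,
                             f4=0, f5=0, delta1=0, delta2=0, delta3=0, delta4=0)
    with pytest.raises(ModelError):  # m * delta4 > 1
        NaturalHistoryParams(h1=h1, mu=h1, h2=0, h3=0, h4=0, f2=0, f3=0,
                             f4=0, f5=0, delta1=0, delta2=0, delta3=0,
                             delta4=0.5, m=2.5)


def test_delta_prime_derivation_and_cap():
    h1 = AgeRateSchedule.zeros()
    p = NaturalHistoryParams(h1=h1, mu=h1, h2=0, h3=0, h4=0, f2=0, f3=0, f4=0,
                             f5=0, delta1=0.008, delta2=0.021, delta3=0.062,
                             delta4=0.230, m=1.5)
    assert p.deltas_undetected == pytest.approx((0.012, 0.0315, 0.093, 0.345))
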