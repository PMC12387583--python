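import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats as sps

from vergesim.geometry import WorldPoint, hitting_deviation_pd
from vergesim.subject_model import (
    CONVERGENCE,
    DIVERGENCE,
    CohortSpec,
    SyntheticSubject,
    achieved_vergence,
    folded_normal_location,
    residual_demand,
    sample_cohort,
    simulate_hit,
    subject_seed_sequence,
)

from conftest import make_subject


class TestAchievedVergence:
    def test_demand_below_amplitude_fully_met(self):
        s = make_subject(pfv=18.0)
        assert achieved_vergence(s, 10.0, CONVERGENCE) == 10.0

    def test_clamped_at_amplitude(self):
        s = make_subject(nfv=8.0)
        assert achieved_vergence(s, 20.0, DIVERGENCE) == 8.0

    def test_zero_demand(self):
        s = make_subject(nfv=8.0)
        assert achieved_vergence(s, 0.0, DIVERGENCE) == 0.0

    def test_negative_demand_rejected(self):
        with pytest.raises(ValueError):
            achieved_vergence(make_subject(), -1.0, CONVERGENCE)

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            achieved_vergence(make_subject(), 5.0, "sideways")

    def test_soft_saturation_below_hard_clamp(self):
        s = make_subject(pfv=10.0)
        soft = achieved_vergence(s, 10.0, CONVERGENCE, softness=2.0)
        assert 0.0 < soft < 10.0


class TestResidualDemand:
    def test_simple_residual(self):
        assert residual_demand(make_subject(pfv=18.0), 20.0, CONVERGENCE) == 2.0

    def test_table_style_residual(self):
        # amplitude chosen so residual is the NFV-20 style value
        s = make_subject(nfv=10.05)
        assert residual_demand(s, 20.0, DIVERGENCE) == pytest.approx(9.95, abs=1e-12)

    def test_boundary_zero_residual(self):
        assert residual_demand(make_subject(nfv=8.0), 8.0, DIVERGENCE) == 0.0

    def test_zero_iff_demand_within_amplitude(self):
        s = make_subject(nfv=8.0)
        assert residual_demand(s, 7.9, DIVERGENCE) == 0.0
        assert residual_demand(s, 8.1, DIVERGENCE) > 0.0


@given(
    amp=st.floats(min_value=0, max_value=30, allow_nan=False),
    d1=st.floats(min_value=0, max_value=25, allow_nan=False),
    d2=st.floats(min_value=0, max_value=25, allow_nan=False),
)
def test_residual_monotone_in_demand(amp, d1, d2):
    s = make_subject(nfv=amp, bias=0.0, noise=0.0)
    lo, hi = sorted([d1, d2])
    assert residual_demand(s, lo, DIVERGENCE) <= residual_demand(s, hi, DIVERGENCE)


@given(
    a1=st.floats(min_value=0, max_value=30, allow_nan=False),
    a2=st.floats(min_value=0, max_value=30, allow_nan=False),
    demand=st.floats(min_value=0, max_value=25, allow_nan=False),
)
def test_residual_antitone_in_amplitude(a1, a2, demand):
    lo, hi = sorted([a1, a2])
    r_lo = residual_demand(make_subject(nfv=lo, bias=0, noise=0), demand, DIVERGENCE)
    r_hi = residual_demand(make_subject(nfv=hi, bias=0, noise=0), demand, DIVERGENCE)
    assert r_hi <= r_lo


class TestFoldedNormalLocation:
    def test_sd_zero_passthrough(self):
        assert folded_normal_location(0.65, 0.0) == 0.65

    def test_default_calibration_against_quadrature(self):
        # oracle: E|N(mu, sd)| by numerical integration
        mu = folded_normal_location(0.65, 0.25)
        mean_abs, _ = integrate.quad(
            lambda x: abs(x) * sps.norm.pdf(x, loc=mu, scale=0.25), -10, 10
        )
        assert mean_abs == pytest.approx(0.65, abs=1e-9)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            folded_normal_location(0.01, 1.0)

    def test_boundary_target(self):
        sd = 0.25
        floor = sd * np.sqrt(2 / np.pi)
        assert folded_normal_location(floor, sd) == 0.0


class TestSimulateHit:
    def test_perfect_fusion_hits_center(self, center, rng):
        s = make_subject(pfv=18.0, bias=0.0, noise=0.0)
        hit = simulate_hit(s, 10.0, CONVERGENCE, center, rng)
        assert hit == center

    def test_residual_displacement_magnitude(self, center, rng):
        s = make_subject(nfv=10.0, bias=0.0, noise=0.0)
        hit = simulate_hit(s, 20.0, DIVERGENCE, center, rng)
        assert abs(hit.x - center.x) == pytest.approx(0.6, abs=1e-12)
        assert hit.z == center.z and hit.y == center.y

    def test_sign_convention(self, center, rng):
        s = make_subject(nfv=10.0, bias=0.0, noise=0.0)
        left = simulate_hit(s, 20.0, DIVERGENCE, center, rng, sign=-1)
        right = simulate_hit(s, 20.0, DIVERGENCE, center, rng, sign=1)
        assert left.x < center.x < right.x

    def test_determinism(self, center):
        s = make_subject()
        h1 = simulate_hit(s, 20.0, DIVERGENCE, center, np.random.default_rng(7))
        h2 = simulate_hit(s, 20.0, DIVERGENCE, center, np.random.default_rng(7))
        assert h1 == h2

    def test_invalid_rng_rejected(self, center):
        with pytest.raises(TypeError):
            simulate_hit(make_subject(), 10.0, DIVERGENCE, center, rng="not-an-rng")

    def test_invalid_sign_rejected(self, center, rng):
        with pytest.raises(ValueError):
            simulate_hit(make_subject(), 10.0, DIVERGENCE, center, rng, sign=0)


def test_clamp_oracle_grid(center):
    """Zero-noise hit -> deviation equals the brute-force clamp residual."""
    for amplitude in (0.0, 5.0, 8.0, 10.0, 16.0, 25.0):
        for demand in (0.0, 10.0, 20.0):
            expected = demand - min(demand, amplitude)
            s = make_subject(pfv=amplitude, nfv=amplitude, bias=0.0, noise=0.0)
            for direction in (CONVERGENCE, DIVERGENCE):
                hit = simulate_hit(s, demand, direction, center, np.random.default_rng(0))
                dev = hitting_deviation_pd(hit, center)
                assert abs(dev) == pytest.approx(expected, abs=1e-12)


def test_fusion_plateau_matches_control_exactly(center):
    """Demand within amplitude -> deviations identical to zero demand,
    draw for draw, under the same rng stream."""
    s = make_subject(pfv=30.0, nfv=30.0)
    devs = {}
    for label, demand, direction in [
        ("control", 0.0, DIVERGENCE),
        ("fused", 10.0, CONVERGENCE),
    ]:
        rng = np.random.default_rng(99)
        devs[label] = [
            abs(hitting_deviation_pd(simulate_hit(s, demand, direction, center, rng), center))
            for _ in range(50)
        ]
    assert devs["control"] == devs["fused"]


class TestSyntheticSubjectValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"pfv_amplitude": -1.0},
            {"nfv_amplitude": float("nan")},
            {"baseline_bias_mean": -0.1},
            {"motor_noise_sd": float("inf")},
        ],
    )
    def test_invalid_fields(self, kwargs):
        base = dict(subject_id="s", pfv_amplitude=18.0, nfv_amplitude=8.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SyntheticSubject(**base)


class TestSampleCohort:
    def test_degenerate_draw(self):
        spec = CohortSpec(n_subjects=19, pfv_amplitude_sd=0.0, nfv_amplitude_sd=0.0, seed=3)
        cohort = sample_cohort(spec)
        assert len(cohort) == 19
        assert {(s.pfv_amplitude, s.nfv_amplitude) for s in cohort} == {(18.0, 8.0)}

    def test_clt_bound_on_sample_mean(self):
        spec = CohortSpec(
            n_subjects=1000, pfv_amplitude_mean=20.0, pfv_amplitude_sd=3.0, seed=11
        )
        cohort = sample_cohort(spec)
        mean = np.mean([s.pfv_amplitude for s in cohort])
        assert abs(mean - 20.0) < 3 * 3.0 / np.sqrt(1000)

    def test_reproducible_under_seed(self):
        spec = CohortSpec(n_subjects=10, seed=5)
        assert sample_cohort(spec) == sample_cohort(spec)

    def test_nonnegative_amplitudes(self):
        spec = CohortSpec(n_subjects=500, nfv_amplitude_mean=1.0, nfv_amplitude_sd=3.0, seed=2)
        assert all(s.nfv_amplitude >= 0 for s in sample_cohort(spec))

    @pytest.mark.parametrize(
        "kwargs", [{"n_subjects": 0}, {"pfv_amplitude_sd": -1.0}, {"baseline_bias_mean": -1.0}]
    )
    def test_invalid_spec(self, kwargs):
        with pytest.raises(ValueError):
            CohortSpec(**kwargs)


def test_subject_seed_sequence_stable():
    a = subject_seed_sequence(1, "s001")
    b = subject_seed_sequence(1, "s001")
    c = subject_seed_sequence(1, "s002")
    assert np.random.default_rng(a).random() == np.random.default_rng(b).random()
    assert np.random.default_rng(a).random() != np.random.default_rng(c).random()
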