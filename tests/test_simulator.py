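"""Unit and property tests of the gliding-tip Monte-Carlo simulator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fiberglide import (
    FiberGeometry,
    MotilityParams,
    TipState,
    Zone,
    apply_edge_rule,
    simulate_population,
    step_diffusion,
    step_gliding,
)
from fiberglide.simulator import InvalidParameterError, TipEnsemble, _wrap_angle


def make_tip(x=0.0, y=0.0, heading=0.0, zone=Zone.CORE, bundled=False):
    return TipState(position=np.array([x, y]), heading=heading, zone=zone, bundled=bundled)


class TestStepGliding:
    def test_infinite_stiffness_gives_straight_line(self, params, rng):
        stiff = MotilityParams(gliding_speed=500.0, persistence_length=1e9)
        tip = make_tip(heading=0.7)
        for _ in range(50):
            tip = step_gliding(tip, stiff, rng)
        # heading essentially unchanged, path length = 50 steps
        assert tip.heading == pytest.approx(0.7, abs=1e-3)
        assert np.linalg.norm(tip.position) == pytest.approx(50 * stiff.step_length, rel=1e-6)

    def test_zero_speed_freezes_position(self, rng):
        frozen = MotilityParams(gliding_speed=0.0, persistence_length=5.0)
        tip = make_tip(x=3.0, y=-2.0, heading=1.0)
        out = step_gliding(tip, frozen, rng)
        assert np.allclose(out.position, tip.position)

    def test_heading_change_variance_matches_worm_like_chain(self):
        # Var(dtheta) = v_f * dt / L_p = 5e-5 rad^2 at 500 nm/s, 10 ms, 100 µm
        p = MotilityParams(gliding_speed=500.0, persistence_length=100.0, time_step=0.01)
        rng = np.random.default_rng(7)
        tip = make_tip()
        deltas = np.empty(10_000)
        for i in range(deltas.size):
            new = step_gliding(tip, p, rng)
            deltas[i] = new.heading - tip.heading
        expected = 5e-5
        var = deltas.var()
        # chi-squared test on the sample variance at the 1% level
        n = deltas.size
        q = (n - 1) * var / expected
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1)
        assert lo < q < hi

    def test_heading_wrapped_to_half_open_interval(self, rng):
        p = MotilityParams(gliding_speed=500.0, persistence_length=0.001)
        tip = make_tip(heading=3.14)
        for _ in range(200):
            tip = step_gliding(tip, p, rng)
            assert -math.pi < tip.heading <= math.pi

    def test_non_finite_speed_rejected(self):
        with pytest.raises(InvalidParameterError):
            MotilityParams(gliding_speed=float("nan"))
        with pytest.raises(InvalidParameterError):
            MotilityParams(persistence_length=0.0)


@given(theta=st.floats(-50.0, 50.0))
@settings(derandomize=True, max_examples=200)
def test_wrap_angle_lands_in_half_open_interval(theta):
    w = float(_wrap_angle(theta))
    assert -math.pi < w <= math.pi
    # wrapping preserves the angle modulo 2*pi
    assert math.isclose(math.cos(w), math.cos(theta), abs_tol=1e-9)
    assert math.isclose(math.sin(w), math.sin(theta), abs_tol=1e-9)


class TestEdgeRule:
    def out_of_zone_tip(self, geometry, heading=0.0):
        r = geometry.cladding_outer_radius + 0.05
        return make_tip(x=r, y=0.0, heading=heading, zone=Zone.CLADDING)

    def test_certain_detachment(self, geometry, rng):
        p = MotilityParams(detach_probability=1.0)
        for _ in range(100):
            out = apply_edge_rule(self.out_of_zone_tip(geometry), geometry, p, rng)
            assert out.zone is Zone.DIFFUSING
            assert out.radius == pytest.approx(geometry.cladding_outer_radius)

    def test_detachment_fraction_matches_probability(self, geometry):
        # 10^4 independent encounters; binomial 3-sigma band around 0.8
        p = MotilityParams(detach_probability=0.8)
        rng = np.random.default_rng(99)
        n = 10_000
        detached = sum(
            apply_edge_rule(self.out_of_zone_tip(geometry), geometry, p, rng).zone
            is Zone.DIFFUSING
            for _ in range(n)
        )
        sigma3 = 3 * math.sqrt(0.8 * 0.2 / n)
        assert abs(detached / n - 0.8) < sigma3

    def test_steering_turns_radial_heading_to_tangent(self, geometry, rng):
        p = MotilityParams(detach_probability=0.0)
        tip = self.out_of_zone_tip(geometry, heading=0.0)  # moving radially outward
        out = apply_edge_rule(tip, geometry, p, rng)
        assert out.zone is Zone.CLADDING
        assert out.radius == pytest.approx(geometry.cladding_outer_radius)
        # tangent at (R, 0) is vertical; radial tie resolves counter-clockwise (+y)
        assert out.heading == pytest.approx(math.pi / 2)

    def test_steering_keeps_travel_direction(self, geometry, rng):
        p = MotilityParams(detach_probability=0.0)
        tip = self.out_of_zone_tip(geometry, heading=0.3)  # outward, slightly CCW
        out = apply_edge_rule(tip, geometry, p, rng)
        d_in = np.array([math.cos(0.3), math.sin(0.3)])
        d_out = np.array([math.cos(out.heading), math.sin(out.heading)])
        assert float(d_in @ d_out) > 0

    def test_bundled_tip_confined_to_core(self, geometry, rng):
        p = MotilityParams(detach_probability=1.0)
        tip = make_tip(x=geometry.core_radius + 0.02, y=0.0, bundled=True)
        out = apply_edge_rule(tip, geometry, p, rng)
        assert out.zone is Zone.CORE
        assert out.radius == pytest.approx(geometry.core_radius)


class TestStepDiffusion:
    def diffusing_tip(self, x=50.0):
        return make_tip(x=x, zone=Zone.DIFFUSING)

    def test_zero_landing_rate_never_lands(self, geometry):
        p = MotilityParams(landing_rate=0.0, diffusion_coefficient=0.0)
        rng = np.random.default_rng(1)
        tip = self.diffusing_tip()
        for _ in range(1000):
            tip = step_diffusion(tip, geometry, p, rng)
            assert tip.zone is Zone.DIFFUSING

    def test_landing_fraction_matches_bernoulli_closed_form(self, geometry):
        # tip pinned over the motility zone (D = 0) for 100 s; the chance of
        # landing is 1 - (1 - rate*dt)^(100/dt) ~ 0.632 at 0.01 /s
        # gliding_speed 0 so tips stay put once landed (first-landing count)
        p = MotilityParams(
            gliding_speed=0.0, landing_rate=0.01, diffusion_coefficient=0.0, time_step=0.01
        )
        n_steps = int(100 / p.time_step)
        expected = 1.0 - (1.0 - p.landing_rate * p.time_step) ** n_steps
        n_rep = 10_000
        rng = np.random.default_rng(5)
        ens = TipEnsemble.uniform_on_core(n_rep, geometry, p, rng)
        ens.zone[:] = 2  # all diffusing, positions over the core
        for _ in range(n_steps):
            ens.step()
        landed = np.count_nonzero(ens.zone < 2)
        sigma3 = 3 * math.sqrt(expected * (1 - expected) / n_rep)
        assert abs(landed / n_rep - expected) < sigma3

    def test_absorbing_boundary_loses_fast_diffusers(self, rng):
        # escape radius barely beyond the motility zone and steps much larger
        # than the whole disc: nearly every diffusing tip is absorbed fast
        geom = FiberGeometry(core_radius=100.0, cladding_width=10.0, escape_factor=1.001)
        p = MotilityParams(diffusion_coefficient=2e6, landing_rate=0.0)
        lost = 0
        for _ in range(200):
            tip = make_tip(x=geom.cladding_outer_radius, zone=Zone.DIFFUSING)
            for _ in range(20):
                tip = step_diffusion(tip, geom, p, rng)
                if tip.zone is Zone.LOST:
                    lost += 1
                    break
        assert lost >= 195

    def test_lost_zone_is_terminal_in_population(self, geometry):
        p = MotilityParams(gliding_speed=800.0, landing_rate=0.0, diffusion_coefficient=20.0)
        pop = simulate_population(100, geometry, p, duration=200.0, seed=3, record_interval=1.0)
        assert np.all(np.diff(pop.count_lost) >= 0)


class TestSimulatePopulation:
    def test_zero_speed_freezes_counts(self, geometry):
        p = MotilityParams(gliding_speed=0.0)
        pop = simulate_population(100, geometry, p, duration=20.0, seed=2, record_interval=1.0)
        assert np.all(pop.count_core == 100)

    def test_count_conservation_every_record(self, geometry):
        p = MotilityParams(gliding_speed=800.0)
        pop = simulate_population(250, geometry, p, duration=300.0, seed=11, record_interval=0.5)
        total = pop.count_core + pop.count_cladding + pop.count_diffusing + pop.count_lost
        assert np.all(total == 250)

    def test_no_relanding_means_surface_population_non_increasing(self, geometry):
        p = MotilityParams(gliding_speed=800.0, landing_rate=0.0, bundled_fraction=0.0)
        pop = simulate_population(300, geometry, p, duration=400.0, seed=4, record_interval=1.0)
        on_surface = pop.count_core + pop.count_cladding
        assert np.all(np.diff(on_surface) <= 0)

    def test_seed_determinism_is_bit_identical(self, geometry, params):
        a = simulate_population(80, geometry, params, duration=30.0, seed=42, record_interval=0.1)
        b = simulate_population(80, geometry, params, duration=30.0, seed=42, record_interval=0.1)
        for name in ("times", "count_core", "count_cladding", "count_diffusing", "count_lost"):
            assert np.array_equal(getattr(a, name), getattr(b, name))

    def test_core_decay_is_single_exponential_without_relanding(self, geometry):
        from fiberglide import fit_decay

        p = MotilityParams(gliding_speed=800.0, landing_rate=0.0)
        runs = [
            simulate_population(250, geometry, p, duration=600.0, seed=s, record_interval=2.0)
            for s in range(5)
        ]
        mean_core = np.mean([r.count_core for r in runs], axis=0)
        fit = fit_decay((runs[0].times, mean_core / mean_core[0]))
        assert fit.r_squared > 0.95

    def test_lambda_scales_with_speed(self, geometry):
        from fiberglide import fit_decay

        lams = []
        for v, dur in ((400.0, 1200.0), (800.0, 600.0)):
            p = MotilityParams(gliding_speed=v, landing_rate=0.0)
            cores = []
            for s in range(4):
                pop = simulate_population(
                    250, geometry, p, duration=dur, seed=100 + s, record_interval=2.0
                )
                t, c = pop.times, pop.count_core
                cores.append((t, c / c[0]))
            mean = np.mean([c for _, c in cores], axis=0)
            lams.append(fit_decay((cores[0][0], mean)).params.Lambda)
        ratio = lams[1] / lams[0]
        assert ratio == pytest.approx(2.0, abs=0.3)

    def test_bundled_fraction_stays_on_core(self, geometry):
        p = MotilityParams(gliding_speed=800.0, bundled_fraction=1.0)
        pop = simulate_population(150, geometry, p, duration=300.0, seed=8, record_interval=1.0)
        assert np.all(pop.count_core == 150)

    @pytest.mark.parametrize("bad", [{"duration": 0.0}, {"n": 0}])
    def test_invalid_run_parameters_rejected(self, geometry, params, bad):
        kwargs = dict(n_total=bad.get("n", 10), duration=bad.get("duration", 10.0))
        with pytest.raises(InvalidParameterError):
            simulate_population(
                kwargs["n_total"], geometry, params, kwargs["duration"], seed=0
            )


def test_geometry_invariants_enforced():
    with pytest.raises(InvalidParameterError):
        FiberGeometry(core_radius=-1.0)
    with pytest.raises(InvalidParameterError):
        FiberGeometry(cladding_width=0.0)
    g = FiberGeometry(core_radius=100.0, cladding_width=10.0, escape_factor=4.0)
    assert g.core_radius < g.cladding_outer_radius < g.escape_radius
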