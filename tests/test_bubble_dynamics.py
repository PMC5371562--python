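import numpy as np
import pytest

from decobubble import (
    AHSite,
    Bubble,
    BuoyancyModel,
    DiveProfile,
    SimulationConfig,
    activation_interval,
    buoyancy_force,
    grow,
    growth_rate_from_supersaturation,
    run_profile,
    sample_detachment_volume,
    sample_growth_coefficient,
    sample_initiation_time,
    simulate_sites,
    sphere_diameter_mm,
    sphere_volume_mm3,
)
from decobubble.bubble_dynamics import (
    REFERENCE_SUPERSATURATION_KPA,
    initiation_gamma_params,
)


class TestActivation:
    def test_first_interval(self):
        assert activation_interval(1) == pytest.approx(14.95, abs=5e-3)

    def test_limit_is_additive_constant(self):
        assert activation_interval(10**6) == pytest.approx(1.657, abs=1e-12)

    def test_strictly_decreasing(self):
        s = np.arange(1, 100)
        assert np.all(np.diff(activation_interval(s)) < 0)

    def test_sequence_below_one_rejected(self):
        with pytest.raises(ValueError):
            activation_interval(0)


class TestBuoyancy:
    def test_reference_sphere_force(self):
        # 4.2 mm sphere, empirical conversion -> 38e-6 N to rounding
        f = buoyancy_force(sphere_volume_mm3(4.2))
        assert round(f * 1e6) == 38

    def test_unit_volume_empirical(self):
        assert buoyancy_force(1.0) == pytest.approx(9.80e-7)

    def test_unit_volume_physical_mode(self):
        assert buoyancy_force(1.0, BuoyancyModel.physical()) == pytest.approx(
            9.81e-6
        )

    def test_zero_volume_zero_force(self):
        assert buoyancy_force(0.0) == 0.0

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            buoyancy_force(-1.0)

    def test_linearity_against_multiplication_oracle(self, rng):
        volumes = rng.uniform(0.0, 50.0, size=200)
        forces = buoyancy_force(volumes)
        assert forces == pytest.approx(9.80e-7 * volumes, rel=1e-12)


class TestDetachmentSampler:
    def test_mean_diameter_calibrated(self, rng):
        d = sphere_diameter_mm(sample_detachment_volume(rng, size=100_000))
        assert d.mean() == pytest.approx(1.0, abs=0.02)

    def test_minimum_diameter_support(self, rng):
        d = sphere_diameter_mm(sample_detachment_volume(rng, size=100_000))
        assert d.min() >= 0.4

    def test_degenerate_mean_collapses_to_minimum(self, rng):
        d = sphere_diameter_mm(
            sample_detachment_volume(
                rng, size=1000, mean_diameter_mm=0.401, min_diameter_mm=0.4
            )
        )
        assert d.max() < 0.42
        assert d.min() >= 0.4


class TestInitiationSampler:
    def test_gamma_params_reproduce_mode_and_sd(self):
        shape, scale = initiation_gamma_params(45.0, 20.0)
        assert (shape - 1) * scale == pytest.approx(45.0)
        assert np.sqrt(shape) * scale == pytest.approx(20.0)

    def test_histogram_mode_near_45_min(self, rng):
        t = sample_initiation_time(rng, size=100_000)
        counts, edges = np.histogram(t, bins=np.arange(0.0, 200.0, 2.0))
        mode_center = edges[counts.argmax()] + 1.0
        assert abs(mode_center - 45.0) <= 3.0

    def test_mass_beyond_one_hour(self, rng):
        t = sample_initiation_time(rng, size=100_000)
        assert (t > 60.0).mean() > 0.0

    def test_all_draws_positive(self, rng):
        assert sample_initiation_time(rng, size=10_000).min() > 0.0


class TestGrowth:
    def test_no_growth_without_supersaturation(self):
        assert growth_rate_from_supersaturation(-5.0, 1e-4) == 0.0
        assert growth_rate_from_supersaturation(0.0, 1e-4) == 0.0

    def test_rate_linear_in_supersaturation(self):
        r1 = growth_rate_from_supersaturation(100.0, 1e-4)
        r2 = growth_rate_from_supersaturation(200.0, 1e-4)
        assert r2 == pytest.approx(2.0 * r1)

    def test_mean_size_bubble_rates_span_calibrated_range(self, rng):
        """A bubble detaching at the mean 1.0 mm diameter grows at
        0.0375-0.45 mm/min at the reference supersaturation."""
        k = sample_growth_coefficient(rng, 1.0, size=10_000)
        rates = k * REFERENCE_SUPERSATURATION_KPA
        assert rates.min() >= 0.0375 - 1e-9
        assert rates.max() <= 0.45 + 1e-9

    def test_slowest_mean_size_bubble_takes_24_min(self):
        # (1.0 - 0.1) mm at 0.0375 mm/min is 24 min by construction
        assert (1.0 - 0.1) / 0.0375 == pytest.approx(24.0)

    def test_grow_is_linear_and_stateful(self):
        b = Bubble("s", "growing", 0.1, 0.0375, t_init_min=0.0)
        assert grow(b, 0.0).diameter_mm == 0.1
        assert grow(b, 24.0).diameter_mm == pytest.approx(1.0)
        seq = [grow(b, dt).diameter_mm for dt in np.linspace(0.1, 10.0, 20)]
        assert np.all(np.diff(seq) > 0)

    def test_grow_detached_bubble_rejected(self):
        b = Bubble("s", "detached", 1.0, 0.0375, 0.0, 30.0, 0.52)
        with pytest.raises(ValueError):
            grow(b, 1.0)


def _flat_surface_profile():
    return DiveProfile.from_samples([(0.0, 101.325, 0.79), (7200.0, 101.325, 0.79)])


class TestSimulateSites:
    def _methods_setup(self, methods_profile, methods_venous):
        return methods_venous, methods_profile, methods_profile.duration_s / 60.0

    def test_zero_supersaturation_yields_no_records(self):
        profile = _flat_surface_profile()
        venous = run_profile(profile)
        sites = [AHSite("a", "aorta", productivity_per_h=10)]
        records = simulate_sites(
            sites, venous, profile, 120.0, np.random.default_rng(0)
        )
        assert records == []

    def test_empty_site_list_is_not_an_error(self, methods_profile, methods_venous):
        venous, profile, dur = self._methods_setup(methods_profile, methods_venous)
        assert simulate_sites([], venous, profile, dur, np.random.default_rng(0)) == []

    def test_reproducible_record_stream(self, methods_profile, methods_venous):
        venous, profile, dur = self._methods_setup(methods_profile, methods_venous)

        def run():
            sites = [AHSite("a", "aorta", 6), AHSite("b", "vena_cava", 3)]
            return simulate_sites(
                sites, venous, profile, dur, np.random.default_rng(42)
            )

        assert run() == run()

    def test_no_record_precedes_supersaturation_onset(
        self, methods_profile, methods_venous
    ):
        venous, profile, dur = self._methods_setup(methods_profile, methods_venous)
        t_deco_min = profile.times_s[2] / 60.0  # supersaturation starts after this
        sites = [AHSite(f"s{i}", "aorta", 8) for i in range(20)]
        records = simulate_sites(
            sites, venous, profile, dur, np.random.default_rng(3)
        )
        assert records
        assert min(r.t_detach_min for r in records) > t_deco_min

    def test_intervals_follow_activation_curve_without_noise(self):
        # long post-decompression window so the site can fully activate
        from decobubble import make_fixture_profile

        profile = make_fixture_profile("methods_exposure", tail_min=600.0)
        venous = run_profile(profile, water_vapor_kpa=0.0)
        dur = profile.duration_s / 60.0
        config = SimulationConfig(interval_jitter_sd=0.0, stripping_fraction=0.0)
        sites = [AHSite("hot", "aorta", productivity_per_h=40)]
        records = simulate_sites(
            sites, venous, profile, dur, np.random.default_rng(5), config
        )
        times = np.array([r.t_detach_min for r in records])
        intervals = np.diff(times)
        assert len(intervals) >= 8
        expected = activation_interval(np.arange(2, len(times) + 1))
        assert intervals == pytest.approx(expected, rel=1e-9)
        # approaches the 1.657 min floor
        assert intervals[-1] < 2.5

    def test_event_times_strictly_increase_within_site(
        self, methods_profile, methods_venous
    ):
        venous, profile, dur = self._methods_setup(methods_profile, methods_venous)
        sites = [AHSite("a", "aorta", 10)]
        records = simulate_sites(
            sites, venous, profile, dur, np.random.default_rng(11)
        )
        times = [r.t_detach_min for r in records]
        assert np.all(np.diff(times) > 0)
        assert [r.sequence for r in records] == list(range(1, len(records) + 1))

    def test_doubling_sites_roughly_doubles_records(
        self, methods_profile, methods_venous
    ):
        venous, profile, dur = self._methods_setup(methods_profile, methods_venous)

        def count(n, seed):
            sites = [AHSite(f"s{i}", "aorta", 4) for i in range(n)]
            return len(
                simulate_sites(sites, venous, profile, dur,
                               np.random.default_rng(seed))
            )

        a = np.mean([count(10, s) for s in range(5)])
        b = np.mean([count(20, s) for s in range(5)])
        assert b == pytest.approx(2.0 * a, rel=0.3)

    def test_force_is_linear_in_recorded_volume(
        self, methods_profile, methods_venous
    ):
        venous, profile, dur = self._methods_setup(methods_profile, methods_venous)
        sites = [AHSite("a", "aorta", 10)]
        records = simulate_sites(
            sites, venous, profile, dur, np.random.default_rng(2)
        )
        for r in records:
            assert r.force_n == pytest.approx(9.80e-7 * r.volume_mm3, rel=1e-12)
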