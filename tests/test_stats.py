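"""Segmentation, autocorrelation, Radon velocities, events, rotations."""
import numpy as np
import pytest

from cdrwave import PhantomParams, make_kymograph_direct, make_spiral_stack
from cdrwave.containers import CorrelationMap, Kymograph
from cdrwave.stats import (
    autocorrelation_2d,
    average_correlation,
    count_rotations,
    cuts,
    detect_events,
    period_from_cut,
    radon_velocity,
    segment_kymograph,
    terminal_gap,
)


def autocorr_brute_force(values):
    """Direct double-loop oracle: circular in space, unbiased in time."""
    f = values - values.mean()
    var = np.mean(f**2)
    s_n, t_n = f.shape
    out = np.empty((s_n, 2 * t_n - 1))
    for i, ds in enumerate(range(-(s_n // 2), s_n - s_n // 2)):
        for j, dt in enumerate(range(-(t_n - 1), t_n)):
            total = 0.0
            count = 0
            for s in range(s_n):
                for t in range(t_n):
                    t2 = t + dt
                    if 0 <= t2 < t_n:
                        total += f[s, t] * f[(s + ds) % s_n, t2]
                        count += 1
            out[i, j] = total / count / var
    return out


class TestSegmentation:
    def test_otsu_recovers_generating_stripes(self):
        p = PhantomParams(shape=(120, 1, 1), lateral_speed=0.12,
                          frame_interval=20.0)
        kymo, gt = make_kymograph_direct(p, mode="pulses")
        binary = segment_kymograph(kymo).values > 0.5
        # truth: within half front width of the generating pulse position
        s_axis = np.arange(kymo.n_space) * kymo.spacing_um
        truth = np.zeros_like(binary)
        L = kymo.length_um
        for k, snap in enumerate(gt.pulse_positions):
            for s_p in snap:
                d = np.abs(s_axis - s_p)
                truth[np.minimum(d, L - d) <= p.front_width / 2, k] = True
        inter = (binary & truth).sum()
        union = (binary | truth).sum()
        assert inter / union > 0.9

    def test_threshold_below_minimum_gives_all_background(self):
        kymo, _ = make_kymograph_direct(PhantomParams(shape=(30, 1, 1)),
                                        mode="pulses")
        with pytest.warns(UserWarning):
            binary = segment_kymograph(kymo, threshold=-1.0)
        assert not binary.values.any()

    def test_inverted_contrast_with_flag_gives_same_mask(self):
        kymo, _ = make_kymograph_direct(PhantomParams(shape=(30, 1, 1)),
                                        mode="pulses")
        flipped = Kymograph(-kymo.values, kymo.spacing_um, kymo.spacing_s,
                            kymo.periodic)
        b1 = segment_kymograph(kymo, threshold=0.5)
        b2 = segment_kymograph(flipped, threshold=-0.5, invert=True)
        assert np.array_equal(b1.values, b2.values)


class TestAutocorrelation:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        values = (rng.random((17, 13)) < 0.3).astype(float)
        kymo = Kymograph(values, 0.8, 10.0, periodic=True)
        cmap = autocorrelation_2d(kymo)
        ref = autocorr_brute_force(values)
        assert np.abs(cmap.values - ref).max() < 1e-10

    def test_zero_lag_is_exactly_one_and_symmetric(self):
        rng = np.random.default_rng(1)
        kymo = Kymograph(rng.random((32, 40)), 1.0, 5.0, periodic=True)
        cmap = autocorrelation_2d(kymo)
        i0 = np.argmin(np.abs(cmap.lags_um))
        j0 = np.argmin(np.abs(cmap.lags_s))
        assert cmap.values[i0, j0] == pytest.approx(1.0, abs=1e-12)
        assert np.abs(cmap.values).max() <= 1 + 1e-9
        flipped = cmap.values[::-1, ::-1]
        # point symmetry holds on the common sub-grid (even s-axis drops one row)
        assert np.abs(cmap.values[1:] - flipped[:-1]).max() < 1e-10

    def test_temporal_stripes_peak_at_multiples_of_period(self):
        t = np.arange(120)
        values = np.tile(0.5 + 0.5 * np.sign(np.sin(2 * np.pi * t / 24)),
                         (16, 1))
        values[:8] = 1.0  # some spatial structure so variance is finite
        kymo = Kymograph(values, 1.0, 10.0, periodic=True)
        cmap = autocorrelation_2d(kymo)
        (lags_s, c0), _ = cuts(cmap)
        for mult in (1, 2, 3):
            lag = 24 * 10.0 * mult
            j = np.argmin(np.abs(lags_s - lag))
            assert c0[j] > 0.5

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(2)
        kymo = Kymograph(rng.random((100, 120)), 1.0, 1.0, periodic=True)
        cmap = autocorrelation_2d(kymo)
        keep = np.abs(cmap.lags_s) <= 60
        sub = cmap.values[:, keep]
        i0 = np.argmin(np.abs(cmap.lags_um))
        j0 = np.argmin(np.abs(cmap.lags_s[keep]))
        sub = sub.copy()
        sub[i0, j0] = 0.0
        assert np.abs(sub).max() < 0.1

    def test_zero_variance_rejected(self):
        kymo = Kymograph(np.ones((16, 16)), 1.0, 1.0)
        with pytest.raises(ValueError):
            autocorrelation_2d(kymo)


def stripe_kymograph(speed, n_space=128, n_time=121, ds=0.8, dt=20.0,
                     spacing_um=30.0, width=2.0):
    """Ideal periodic diagonal stripes moving at the given speed."""
    s = np.arange(n_space) * ds
    t = np.arange(n_time) * dt
    ss, tt = np.meshgrid(s, t, indexing="ij")
    L = n_space * ds
    phase = (ss - speed * tt) % spacing_um
    d = np.minimum(phase, spacing_um - phase)
    return Kymograph(1.0 - 0.8 * np.exp(-d**2 / (2 * width**2)), ds, dt,
                     periodic=True)


class TestRadonVelocity:
    def test_recovers_stripe_speed(self):
        kymo = stripe_kymograph(0.12)
        cmap = autocorrelation_2d(segment_kymograph(kymo))
        res = radon_velocity(cmap)
        assert res.velocities.size >= 1
        assert res.speed == pytest.approx(0.12, abs=0.01)

    def test_static_stripes_give_zero_velocity(self):
        kymo = stripe_kymograph(0.0)
        cmap = autocorrelation_2d(segment_kymograph(kymo))
        res = radon_velocity(cmap)
        assert res.speed == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("speed", [0.05, 0.1, 0.2, 0.4])
    def test_unbiased_across_speeds(self, speed):
        # frame interval chosen to resolve the motion (~2 px advance/frame)
        kymo = stripe_kymograph(speed, dt=2 * 0.8 / speed)
        cmap = autocorrelation_2d(segment_kymograph(kymo))
        res = radon_velocity(cmap)
        assert res.speed == pytest.approx(speed, rel=0.08)

    def test_isotropic_map_yields_no_velocity(self):
        rng = np.random.default_rng(3)
        kymo = Kymograph(rng.random((64, 64)), 1.0, 10.0, periodic=True)
        cmap = autocorrelation_2d(kymo)
        res = radon_velocity(cmap)
        assert res.velocities.size == 0
        assert np.isnan(res.speed)


class TestAverageAndCuts:
    def test_average_of_identical_maps_is_the_map(self):
        kymo = stripe_kymograph(0.1)
        cmap = autocorrelation_2d(segment_kymograph(kymo))
        avg = average_correlation([cmap, cmap, cmap])
        assert np.allclose(avg.values, cmap.values)

    def test_period_of_six_minutes_from_cut(self):
        p = PhantomParams(shape=(240, 1, 1), lateral_speed=0.12,
                          firing_period=360.0, frame_interval=20.0)
        kymo, _ = make_kymograph_direct(p, mode="stripes")
        cmap = autocorrelation_2d(segment_kymograph(kymo))
        (lags_s, c0), _ = cuts(cmap)
        period = period_from_cut(lags_s, c0)
        assert period == pytest.approx(360.0, abs=cmap.spacing_s)

    def test_four_equally_spaced_sites_give_four_spatial_maxima(self):
        # four sites on a periodic axis of 128 px: c(Δs, 0) repeats at L/4
        n_s, n_t = 128, 60
        values = np.ones((n_s, n_t))
        s = np.arange(n_s)
        for site in (0, 32, 64, 96):
            d = np.abs(s - site)
            d = np.minimum(d, n_s - d)
            values[d <= 2, :] = 0.0
        kymo = Kymograph(values, 1.0, 10.0, periodic=True)
        cmap = autocorrelation_2d(segment_kymograph(kymo, threshold=0.5))
        _, (lags_um, cs0) = cuts(cmap)
        prev = np.roll(cs0, 1)
        nxt = np.roll(cs0, -1)
        peaks = (cs0 > 0.5) & (cs0 >= prev) & (cs0 >= nxt)
        assert peaks.sum() == 4


class TestPeriodFromCut:
    def test_cosine_cut_returns_its_period(self):
        lags = np.arange(-200, 201) * 10.0
        c0 = np.cos(2 * np.pi * lags / 600.0)
        assert period_from_cut(lags, c0) == pytest.approx(600.0, abs=10.0)

    def test_monotone_decay_returns_none(self):
        lags = np.arange(-50, 51) * 10.0
        c0 = np.exp(-np.abs(lags) / 100.0)
        assert period_from_cut(lags, c0) is None

    def test_noisy_periodic_cut_within_one_bin(self):
        rng = np.random.default_rng(4)
        lags = np.arange(-200, 201) * 10.0
        c0 = np.cos(2 * np.pi * lags / 600.0)
        c0 = c0 + rng.normal(0, np.std(c0) / 5, size=c0.size)  # SNR ~ 5
        assert period_from_cut(lags, c0) == pytest.approx(600.0, abs=10.0)


class TestEvents:
    def test_single_firing_site_initiation_located(self):
        p = PhantomParams(shape=(60, 1, 1), lateral_speed=0.12,
                          firing_period=1e9, frame_interval=10.0)
        kymo, gt = make_kymograph_direct(p, mode="stripes")
        ev = detect_events(segment_kymograph(kymo))
        init = ev[ev.type == "initiation"]
        assert len(init) >= 1
        true = gt.events.query("type == 'initiation'").iloc[0]
        d = abs(init.iloc[0].s_um - true.s_um) % kymo.length_um
        assert min(d, kymo.length_um - d) <= 2 * kymo.spacing_um
        assert abs(init.iloc[0].t_s - true.t_s) <= 2 * kymo.spacing_s

    def test_annihilate_collision_classified_mutual(self):
        p = PhantomParams(shape=(80, 1, 1), collision_mode="annihilate",
                          terminal_gap=12.0, frame_interval=10.0)
        kymo, _ = make_kymograph_direct(p, mode="collision")
        ev = detect_events(segment_kymograph(kymo))
        coll = ev[ev.type == "collision"]
        assert len(coll) == 1
        assert coll.iloc[0].collision_class == "mutual"

    def test_cross_collision_classified_one_survives(self):
        p = PhantomParams(shape=(80, 1, 1), collision_mode="cross",
                          frame_interval=10.0)
        kymo, _ = make_kymograph_direct(p, mode="collision")
        ev = detect_events(segment_kymograph(kymo))
        coll = ev[ev.type == "collision"]
        assert len(coll) >= 1
        assert (coll.collision_class == "one_survives").all()

    def test_empty_segmentation_gives_empty_table(self):
        kymo = Kymograph(np.zeros((40, 40)), 1.0, 10.0, periodic=True)
        assert len(detect_events(kymo)) == 0


class TestTerminalGap:
    @pytest.mark.parametrize("gap", [12.0, 5.0, 0.0])
    def test_gap_recovered_within_one_pixel(self, gap):
        p = PhantomParams(shape=(90, 1, 1), collision_mode="annihilate",
                          terminal_gap=gap, frame_interval=10.0)
        kymo, _ = make_kymograph_direct(p, mode="collision")
        ev = detect_events(segment_kymograph(kymo))
        coll = ev[(ev.type == "collision") & (ev.collision_class == "mutual")]
        assert len(coll) >= 1
        measured = terminal_gap(kymo, coll.iloc[0])
        assert measured == pytest.approx(gap, abs=kymo.spacing_um)


@pytest.fixture(scope="module")
def spiral():
    p = PhantomParams(shape=(85, 64, 64), rotation_period=525.0,
                      frame_interval=50.0, cell_radius=20.0,
                      pixel_size=0.8)
    stack, gt = make_spiral_stack(p)
    return p, stack, gt


class TestRotations:
    def test_eight_rotations_in_70_minutes(self, spiral):
        p, stack, gt = spiral
        n = count_rotations(stack, p.frame_center_um(), 0.7 * p.cell_radius)
        assert n == 8 == gt.rotation_count

    def test_static_pattern_counts_zero(self, spiral):
        from cdrwave import ImageStack

        p, stack, _ = spiral
        static = ImageStack(np.repeat(stack.data[:1], 20, axis=0),
                            stack.pixel_size, stack.frame_interval)
        assert count_rotations(static, p.frame_center_um(),
                               0.7 * p.cell_radius) == 0

    def test_half_duration_counts_four(self, spiral):
        from cdrwave import ImageStack

        p, stack, _ = spiral
        half = ImageStack(stack.data[:43], stack.pixel_size,
                          stack.frame_interval)
        assert count_rotations(half, p.frame_center_um(),
                               0.7 * p.cell_radius) == 4
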