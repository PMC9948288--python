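"""Encapsulation statistics, assay signal generation, and the rolling sorter."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from dropdel import (
    AssayModel,
    ScreenConfig,
    droplet_concentration,
    encapsulate,
    expected_outlier_rate,
    finite_window_outlier_rate,
    generate_signals,
    rolling_sorter,
    sample_aliquot,
)
from dropdel.library import LibraryDesign


def _uniform_design(n):
    return LibraryDesign.from_lists([[f"b{i}" for i in range(n)]])


class TestDropletConcentration:
    @pytest.mark.parametrize(
        "loading,volume,release,expected",
        [(100, 100, 1.0, 1.0), (100, 100, 0.0, 0.0), (50, 100, 1.0, 0.5)],
    )
    def test_fmol_per_pl_is_mM(self, loading, volume, release, expected):
        assert droplet_concentration(loading, volume, release) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            droplet_concentration(100, 0.0)

    @given(
        loading=st.floats(1, 1000),
        volume=st.floats(1, 1000),
        release=st.floats(0, 1),
        a=st.floats(0.1, 10),
    )
    def test_linear_in_loading_inverse_in_volume(self, loading, volume, release, a):
        base = droplet_concentration(loading, volume, release)
        assert droplet_concentration(a * loading, volume, release) == pytest.approx(a * base)
        assert droplet_concentration(loading, a * volume, release) == pytest.approx(base / a)


class TestEncapsulate:
    def test_zero_occupancy_gives_empty_droplets(self):
        aliquot = sample_aliquot(_uniform_design(100), 2.0, seed=0)
        stream = encapsulate(aliquot, ScreenConfig(bead_occupancy=0.0), 500, seed=1)
        assert stream.bead_counts.sum() == 0

    def test_occupancy_histogram_is_poisson(self):
        n = 100_000
        aliquot = sample_aliquot(_uniform_design(100_000), 3.0, seed=2)
        stream = encapsulate(aliquot, ScreenConfig(bead_occupancy=1.0), n, seed=3)
        counts = np.bincount(stream.bead_counts, minlength=7)
        kmax = 6
        observed = np.append(counts[:kmax], counts[kmax:].sum())
        probs = stats.poisson.pmf(np.arange(kmax), 1.0)
        probs = np.append(probs, 1 - probs.sum())
        _, pvalue = stats.chisquare(observed, n * probs)
        assert pvalue > 0.01

    def test_beads_drawn_without_replacement(self):
        design = _uniform_design(50)
        aliquot = sample_aliquot(design, 2.0, seed=4)
        stream = encapsulate(aliquot, ScreenConfig(bead_occupancy=0.5), 150, seed=5)
        for member, used in zip(*np.unique(stream.bead_members, return_counts=True)):
            assert used <= aliquot.count(int(member))

    def test_exhaustion_leaves_later_droplets_beadless_with_warning(self):
        aliquot = sample_aliquot(_uniform_design(20), 1.0, seed=6)
        with pytest.warns(UserWarning, match="exhausted"):
            stream = encapsulate(aliquot, ScreenConfig(bead_occupancy=2.0), 1000, seed=7)
        assert stream.bead_counts.sum() == aliquot.total_beads
        assert stream.bead_counts[-1] == 0

    def test_reproducible_given_seed(self):
        aliquot = sample_aliquot(_uniform_design(100), 1.0, seed=8)
        a = encapsulate(aliquot, ScreenConfig(), 1000, seed=9)
        b = encapsulate(aliquot, ScreenConfig(), 1000, seed=9)
        assert np.array_equal(a.bead_members, b.bead_members)
        assert np.array_equal(a.bead_offsets, b.bead_offsets)


class TestGenerateSignals:
    def test_null_stream_matches_baseline_gaussian(self):
        n = 50_000
        aliquot = sample_aliquot(_uniform_design(100), 0.0, seed=0)
        stream = encapsulate(aliquot, ScreenConfig(bead_occupancy=0.0), n, seed=1)
        assay = AssayModel(mu_neg=100.0, sigma_neg=10.0)
        stream = generate_signals(stream, assay, ScreenConfig(), seed=2)
        assert abs(stream.signals.mean() - 100.0) <= 3 * 10.0 / math.sqrt(n)

    def test_full_inhibition_zeroes_active_droplets(self):
        design = _uniform_design(10)
        aliquot = sample_aliquot(design, 50.0, seed=3)
        config = ScreenConfig(bead_occupancy=0.5)
        stream = encapsulate(aliquot, config, 800, seed=4)
        assay = AssayModel(
            mu_neg=100.0, sigma_neg=5.0, active_members=frozenset(range(10)), effect=1.0
        )
        stream = generate_signals(stream, assay, config, seed=5)
        with_bead = stream.bead_counts > 0
        assert np.allclose(stream.signals[with_bead], 0.0)
        assert not np.allclose(stream.signals[~with_bead], 0.0)

    def test_half_maximal_concentration_gives_half_effect(self):
        assay = AssayModel(mu_neg=1, sigma_neg=1, ic50_mM=1.0, effect=1.0)
        assert assay.inhibition(1.0) == pytest.approx(0.5)
        assert assay.inhibition(0.0) == 0.0

    def test_additive_noise_mode_shifts_mean_only(self):
        design = _uniform_design(5)
        aliquot = sample_aliquot(design, 40.0, seed=6)
        config = ScreenConfig(bead_occupancy=0.3, noise_mode="additive")
        stream = encapsulate(aliquot, config, 500, seed=7)
        assay = AssayModel(
            mu_neg=100.0, sigma_neg=2.0, active_members=frozenset(range(5)), effect=0.5
        )
        out = generate_signals(stream, assay, config, seed=8)
        one_bead = stream.bead_counts == 1
        assert abs(out.signals[one_bead].mean() - 50.0) < 3 * 2.0 / math.sqrt(one_bead.sum())


class TestRollingSorter:
    def test_constant_stream_has_no_hits(self):
        res = rolling_sorter(np.full(5000, 7.0), ScreenConfig(window=1000))
        assert res.n_hits == 0

    def test_stream_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            rolling_sorter(np.zeros(10), ScreenConfig(window=1000))

    def test_burn_in_droplets_never_sorted(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(0, 1, 3000)
        sig[:1000] = -100.0  # extreme but inside burn-in
        res = rolling_sorter(sig, ScreenConfig(window=1000))
        assert (res.hit_indices >= 1000).all()

    def test_spiked_outliers_all_sorted(self):
        rng = np.random.default_rng(1)
        n = 50_000
        sig = rng.normal(100, 10, n)
        spikes = rng.choice(np.arange(1000, n), 100, replace=False)
        sig[spikes] = 100 - 10 * 10  # 10 sigma below the mean
        res = rolling_sorter(sig, ScreenConfig(window=1000, z_threshold=4.0))
        assert set(spikes) <= set(res.hit_indices)
        false_hits = len(set(res.hit_indices) - set(spikes))
        expected = n * finite_window_outlier_rate(4.0, 1000)
        assert false_hits <= expected + 3 * math.sqrt(expected) + 3

    def test_high_signal_direction(self):
        rng = np.random.default_rng(2)
        sig = rng.normal(0, 1, 20_000)
        sig[5000] = 50.0
        res = rolling_sorter(sig, ScreenConfig(window=1000, hit_direction="high"))
        assert 5000 in res.hit_indices

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        sig = rng.normal(0, 1, 20_000)
        config = ScreenConfig(window=500)
        base = rolling_sorter(sig, config).hit_indices
        scaled = rolling_sorter(3.5 * sig + 11.0, config).hit_indices
        assert np.array_equal(base, scaled)

    def test_fully_inhibiting_actives_always_sorted(self, design2000, strong_assay):
        # device-fidelity assumption: every droplet with >= 1 active bead is
        # sorted when the effect is ~10 sigma and the droplet is past burn-in
        config = ScreenConfig(bead_occupancy=0.05, window=1000)
        aliquot = sample_aliquot(design2000, 3.0, seed=10)
        stream = encapsulate(aliquot, config, 100_000, seed=11)
        stream = generate_signals(stream, strong_assay, config, seed=12)
        res = rolling_sorter(stream, config)
        active = np.isin(stream.bead_members, np.arange(5))
        droplet_ids = stream.bead_droplet_ids()
        active_droplets = np.unique(droplet_ids[active])
        active_droplets = active_droplets[active_droplets >= config.window]
        assert set(active_droplets) <= set(res.hit_indices)


class TestOutlierRate:
    def test_four_sigma_is_32_ppm(self):
        assert round(expected_outlier_rate(4.0) * 1e6) == 32

    def test_zero_threshold_is_half(self):
        assert expected_outlier_rate(0.0) == pytest.approx(0.5)

    def test_matches_quantile_oracle(self):
        assert expected_outlier_rate(1.959964) == pytest.approx(0.0250, abs=5e-5)

    def test_matches_numerical_integration(self):
        for z in (0.5, 1.0, 2.0, 3.0, 4.0):
            numeric, _ = integrate.quad(stats.norm.pdf, -np.inf, -z)
            assert abs(expected_outlier_rate(z) - numeric) < 1e-10

    @given(z=st.floats(0, 6))
    def test_strictly_decreasing(self, z):
        assert expected_outlier_rate(z + 0.1) < expected_outlier_rate(z)

    def test_finite_window_rate_converges_to_asymptotic(self):
        assert finite_window_outlier_rate(4.0, 10**6) == pytest.approx(
            expected_outlier_rate(4.0), rel=1e-2
        )
        assert finite_window_outlier_rate(4.0, 1000) > expected_outlier_rate(4.0)
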