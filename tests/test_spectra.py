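import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dft_oracle import one_sided_amplitude_phase
from rrmkit.encoding import NumericalSeries
from rrmkit.errors import DomainError, ValidationError
from rrmkit.simulate import synth_group
from rrmkit.spectra import (
    ConsensusSpectrum,
    amplitude_spectrum,
    cross_spectrum,
    find_consensus_peak,
    is_opposite_phase,
    phase_difference,
    signal_to_noise,
)


def series(values, source_id="s"):
    return NumericalSeries(values=np.asarray(values, float), source_id=source_id)


def make_consensus(amplitudes, n_points=None):
    amplitudes = np.asarray(amplitudes, float)
    n = n_points or 2 * (len(amplitudes) - 1)
    return ConsensusSpectrum(
        frequencies=np.arange(len(amplitudes)) / n,
        amplitudes=amplitudes,
        member_count=2,
    )


class TestAmplitudeSpectrum:
    def test_constant_series_all_zero(self):
        sp = amplitude_spectrum(series([3.0] * 16), n_points=16)
        assert np.allclose(sp.amplitudes, 0.0, atol=1e-12)

    def test_pure_on_grid_cosine_single_bin(self):
        N, k = 32, 5
        j = np.arange(N)
        sp = amplitude_spectrum(series(np.cos(2 * np.pi * k / N * j)), n_points=N)
        nonzero = np.flatnonzero(sp.amplitudes > 1e-9)
        assert nonzero.tolist() == [k]
        assert sp.frequencies[k] == k / N

    def test_matches_direct_dft_oracle(self, rng):
        values = rng.normal(size=32)
        sp = amplitude_spectrum(series(values), n_points=64)
        amp, phase = one_sided_amplitude_phase(values, 64)
        amp[0] = 0.0
        assert np.allclose(sp.amplitudes, amp, rtol=1e-9, atol=1e-9)
        mask = amp > 1e-9  # phase only meaningful off the noise floor
        assert np.allclose(sp.phases[mask], phase[mask], atol=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            amplitude_spectrum(series([1.0, 2.0, 3.0]))

    def test_n_points_smaller_than_series_rejected(self):
        with pytest.raises(ValidationError):
            amplitude_spectrum(series(np.arange(16.0)), n_points=8)

    def test_grid_tops_out_at_nyquist(self):
        sp = amplitude_spectrum(series(np.arange(8.0)), n_points=16)
        assert sp.frequencies[-1] == 0.5
        assert sp.frequencies[0] == 0.0

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(min_value=4, max_value=64).flatmap(
            lambda n: st.tuples(
                st.just(n),
                st.lists(
                    st.floats(-10, 10, allow_nan=False), min_size=n, max_size=n
                ),
            )
        )
    )
    def test_oracle_equivalence_property(self, n_and_values):
        n, values = n_and_values
        n_points = 64
        sp = amplitude_spectrum(series(values), n_points=n_points)
        amp, _ = one_sided_amplitude_phase(values, n_points)
        amp[0] = 0.0
        scale = max(amp.max(), 1.0)
        assert np.allclose(sp.amplitudes, amp, rtol=1e-9, atol=1e-9 * scale)

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=4, max_size=48))
    def test_parseval_identity(self, values):
        n_points = 64
        x = np.asarray(values) - np.mean(values)
        transform = np.fft.fft(x, n_points)
        lhs = float(np.sum(np.abs(transform) ** 2))
        rhs = n_points * float(np.sum(x**2))
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)


class TestCrossSpectrum:
    def test_identical_members_power(self, rng):
        sp = amplitude_spectrum(series(rng.normal(size=16)), n_points=32)
        consensus = cross_spectrum([sp, sp, sp])
        assert np.allclose(consensus.amplitudes, sp.amplitudes**3)

    def test_zero_member_absorbs(self, rng):
        sp = amplitude_spectrum(series(rng.normal(size=16)), n_points=32)
        zero = amplitude_spectrum(series([1.0] * 16), n_points=32)
        consensus = cross_spectrum([sp, zero])
        assert np.all(consensus.amplitudes == 0.0)

    def test_recovers_shared_frequency(self):
        n_points = 512
        fixture = synth_group(0.25, n=5, lengths=128, seed=7)
        spectra = [amplitude_spectrum(m, n_points) for m in fixture.series]
        consensus = cross_spectrum(spectra)
        peak = find_consensus_peak(consensus, min_snr=1.0)
        assert abs(peak.frequency - 0.25) <= 1 / n_points + 1e-12

    def test_mismatched_grids_rejected(self, rng):
        a = amplitude_spectrum(series(rng.normal(size=16)), n_points=32)
        b = amplitude_spectrum(series(rng.normal(size=16)), n_points=64)
        with pytest.raises(ValidationError, match="grid"):
            cross_spectrum([a, b])

    def test_fewer_than_two_members_rejected(self, rng):
        sp = amplitude_spectrum(series(rng.normal(size=16)), n_points=32)
        with pytest.raises(ValidationError):
            cross_spectrum([sp])

    def test_member_ids_propagate(self, rng):
        a = amplitude_spectrum(series(rng.normal(size=16), "a"), n_points=32)
        b = amplitude_spectrum(series(rng.normal(size=16), "b"), n_points=32)
        assert cross_spectrum([a, b]).member_ids == ("a", "b")


class TestSignalToNoise:
    def test_single_nonzero_bin_gives_bin_count(self):
        amplitudes = np.zeros(17)
        amplitudes[4] = 2.5
        consensus = make_consensus(amplitudes, n_points=32)
        # mean over the 16 nonzero-frequency bins is A/16, so S/N = 16
        assert signal_to_noise(consensus, 4 / 32) == pytest.approx(16.0)

    def test_flat_consensus_snr_one_everywhere(self):
        consensus = make_consensus(np.full(17, 3.0), n_points=32)
        for k in range(1, 17):
            assert signal_to_noise(consensus, k / 32) == pytest.approx(1.0)

    def test_peak_snr_dominates_fixture(self):
        n_points = 512
        fixture = synth_group(0.25, n=5, lengths=128, seed=7)
        consensus = cross_spectrum(
            [amplitude_spectrum(m, n_points) for m in fixture.series]
        )
        peak = find_consensus_peak(consensus, min_snr=1.0)
        snrs = [
            signal_to_noise(consensus, k / n_points)
            for k in range(1, n_points // 2 + 1)
        ]
        assert peak.snr == pytest.approx(max(snrs))

    def test_all_zero_consensus_raises(self):
        consensus = make_consensus(np.zeros(17), n_points=32)
        with pytest.raises(DomainError):
            signal_to_noise(consensus, 4 / 32)

    def test_off_grid_frequency_rejected(self):
        consensus = make_consensus(np.ones(17), n_points=32)
        with pytest.raises(DomainError):
            signal_to_noise(consensus, 0.1001)


class TestFindConsensusPeak:
    def test_single_nonzero_bin_called(self):
        amplitudes = np.zeros(17)
        amplitudes[4] = 1.0
        peak = find_consensus_peak(make_consensus(amplitudes, 32), min_snr=1.0)
        assert peak.frequency == 4 / 32

    def test_flat_consensus_below_threshold_returns_none(self):
        assert find_consensus_peak(make_consensus(np.ones(17), 32), min_snr=2.0) is None

    def test_tie_breaks_to_lower_frequency(self):
        n_points = 40
        amplitudes = np.zeros(n_points // 2 + 1)
        amplitudes[int(0.10 * n_points)] = 5.0
        amplitudes[int(0.30 * n_points)] = 5.0
        peak = find_consensus_peak(make_consensus(amplitudes, n_points), min_snr=1.0)
        assert peak.frequency == pytest.approx(0.10)

    def test_zero_frequency_never_called(self):
        amplitudes = np.zeros(17)
        amplitudes[0] = 99.0
        assert find_consensus_peak(make_consensus(amplitudes, 32), min_snr=0.0) is None

    def test_consensus_monotonicity_ranking(self, rng):
        # a member that is weak at f_a but maximal at f_b cannot leave f_a
        # ranked above f_b in the product
        n_points = 32
        base = np.zeros(n_points // 2 + 1)
        base[3] = 4.0  # f_a strong in the base group
        base[8] = 2.0  # f_b present but weaker
        group = make_consensus(base, n_points)
        extra = np.full(n_points // 2 + 1, 0.1)
        extra[8] = 5.0  # new member maximal at f_b, below its mean at f_a
        extra[3] = 0.01
        combined = group.amplitudes * extra
        assert combined[8] > combined[3]


class TestPhaseDifference:
    def test_negation_flips_phase_to_pi(self, rng):
        values = rng.normal(size=32)
        a, b = series(values), series(-values)
        sp = amplitude_spectrum(a, 64)
        k = int(np.argmax(sp.amplitudes))
        assert phase_difference(a, b, k / 64, 64) == pytest.approx(np.pi)

    def test_identical_series_phase_zero(self, rng):
        values = rng.normal(size=32)
        a = series(values)
        sp = amplitude_spectrum(a, 64)
        k = int(np.argmax(sp.amplitudes))
        assert phase_difference(a, a, k / 64, 64) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_half_period_shift(self):
        N, f0 = 64, 0.25
        j = np.arange(N)
        a = series(np.cos(2 * np.pi * f0 * j))
        b = series(np.cos(2 * np.pi * f0 * j + np.pi))
        assert phase_difference(a, b, f0, N) == pytest.approx(np.pi)
        assert is_opposite_phase(a, b, f0, N)

    def test_zero_amplitude_is_error(self):
        a = series([1.0] * 16)  # constant: zero everywhere after mean removal
        b = series(np.cos(2 * np.pi * 0.25 * np.arange(16)))
        with pytest.raises(DomainError):
            phase_difference(a, b, 0.25, 16)

    def test_result_in_closed_interval(self, rng):
        a = series(rng.normal(size=32))
        b = series(rng.normal(size=32))
        sp = amplitude_spectrum(a, 64)
        k = int(np.argmax(sp.amplitudes))
        value = phase_difference(a, b, k / 64, 64)
        assert 0.0 <= value <= np.pi
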