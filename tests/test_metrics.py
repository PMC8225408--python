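"""Phase-amplitude binning, modulation index, surrogates, phase max."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pacpipe as pp
from pacpipe.metrics import BIN_CENTERS_DEG, N_BINS, PhaseAmpDistribution


def direct_mi(p):
    """Independent oracle: direct evaluation of sum p ln(18 p) / ln 18."""
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    terms = np.where(p > 0, p * np.log(N_BINS * np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum() / np.log(N_BINS)


class TestBinning:
    def test_constant_amplitude_uniform_bins(self):
        phase = np.linspace(-180, 179.9, 3600)
        dist = pp.bin_amplitude_by_phase(phase, np.full_like(phase, 3.5))
        assert np.allclose(dist.mean_amp, 3.5)

    def test_cosine_modulator_argmax_bin(self):
        # analytic integration of 1 + cos(phase - 90) puts the peak in [80, 100)
        phase = np.linspace(-180, 179.99, 36000)
        amp = 1 + np.cos(np.deg2rad(phase - 90.0))
        dist = pp.bin_amplitude_by_phase(phase, amp)
        assert BIN_CENTERS_DEG[int(np.argmax(dist.mean_amp))] == 90.0

    def test_degenerate_single_bin_flags_missing(self):
        dist = pp.bin_amplitude_by_phase(np.full(10, 5.0), np.ones(10))
        assert dist.missing_bins.sum() == 17

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pp.bin_amplitude_by_phase(np.zeros(3), np.zeros(4))


class TestAverageDistributions:
    def test_identity_and_mean(self):
        a = PhaseAmpDistribution(np.full(N_BINS, 1.0))
        b = PhaseAmpDistribution(np.full(N_BINS, 3.0))
        assert np.allclose(pp.average_distributions([a, a]).mean_amp, 1.0)
        assert np.allclose(pp.average_distributions([a, b]).mean_amp, 2.0)

    def test_bin_missing_everywhere_errors(self):
        amp = np.ones(N_BINS)
        amp[4] = np.nan
        with pytest.raises(ValueError):
            pp.average_distributions([PhaseAmpDistribution(amp)] * 3)

    def test_averaging_shrinks_noise_like_sqrt_n(self):
        rng = np.random.default_rng(0)
        single_sds, mean_sds = [], []
        for _ in range(200):
            draws = 1.0 + 0.2 * rng.standard_normal((30, N_BINS))
            dists = [PhaseAmpDistribution(np.abs(d)) for d in draws]
            mean_sds.append(pp.average_distributions(dists).mean_amp.std())
            single_sds.append(dists[0].mean_amp.std())
        ratio = np.mean(single_sds) / np.mean(mean_sds)
        assert 0.8 * np.sqrt(30) < ratio < 1.2 * np.sqrt(30)


class TestModulationIndex:
    def test_uniform_is_zero(self):
        assert pp.modulation_index(np.full(N_BINS, 2.0)) == pytest.approx(0.0, abs=1e-15)

    def test_single_bin_is_one(self):
        amp = np.zeros(N_BINS)
        amp[7] = 5.0
        assert pp.modulation_index(amp) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # one bin holds 2/19 of the mass, seventeen hold 1/19 each
        amp = np.ones(N_BINS)
        amp[0] = 2.0
        assert pp.modulation_index(amp) == pytest.approx(6.5374e-3, rel=1e-3)

    def test_matches_direct_oracle_on_random_distributions(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            p = rng.dirichlet(np.full(N_BINS, rng.uniform(0.2, 5.0)))
            assert pp.modulation_index(p) == pytest.approx(direct_mi(p), abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        amp = rng.uniform(0.1, 2.0, N_BINS)
        assert pp.modulation_index(amp) == pytest.approx(
            pp.modulation_index(100 * amp), abs=1e-14
        )

    def test_strictly_increases_as_mass_concentrates(self):
        # one-parameter family: uniform -> single bin
        lams = np.linspace(0, 1, 20)
        spike = np.zeros(N_BINS)
        spike[3] = 1.0
        mis = [
            pp.modulation_index((1 - lam) * np.full(N_BINS, 1 / N_BINS) + lam * spike)
            for lam in lams
        ]
        assert np.all(np.diff(mis) > 0)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            pp.modulation_index(np.zeros(N_BINS))


class TestNormalizeMi:
    def test_equal_to_surrogate_mean_gives_zero(self):
        _, _, z = pp.normalize_mi(0.2, np.full(10, 0.2) + np.linspace(-0.01, 0.01, 10))
        assert z == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_z(self):
        surr = np.array([0.1] * 100 + [0.3] * 100)
        mean, sd, z = pp.normalize_mi(0.4, surr)
        assert mean == pytest.approx(0.2)
        assert sd == pytest.approx(0.10025, rel=1e-3)  # sample SD, n-1
        assert z == pytest.approx(1.995, rel=1e-3)

    def test_translation_invariance(self):
        surr = np.random.default_rng(0).uniform(0.1, 0.2, 50)
        _, _, z1 = pp.normalize_mi(0.25, surr)
        _, _, z2 = pp.normalize_mi(0.25 + 5.0, surr + 5.0)
        assert z1 == pytest.approx(z2, rel=1e-12)

    def test_zero_spread_errors(self):
        with pytest.raises(ValueError):
            pp.normalize_mi(0.3, np.full(10, 0.1))


class TestPhaseMax:
    def test_peak_bin_center(self):
        amp = np.ones(N_BINS)
        amp[13] = 2.0  # bin [80, 100)
        deg, tie = pp.phase_max(PhaseAmpDistribution(amp))
        assert deg == 90.0 and not tie

    def test_uniform_ties_to_smallest_center_with_flag(self):
        deg, tie = pp.phase_max(PhaseAmpDistribution(np.ones(N_BINS)))
        assert deg == -170.0 and tie

    def test_recovers_simulated_negative_90(self, single_pair_bank):
        params = pp.SimSignalParams(
            lf_hz=8.0, hf_hz=64.0, phase_pref_deg=-90.0, coupling_depth=0.8,
            duration_s=60.0, noise_scale=1.0, seed=7,
        )
        seg = pp.segment_recording(pp.simulate_coupled_signal(params))
        pac = pp.compute_pac_map(seg, single_pair_bank, n_surr=0)
        assert pac.cell("Cz", 8.0, 64.0).phase_max_deg == -90.0


class TestSurrogates:
    def test_exactly_n_surrogate_values(self, coupled_segments, single_pair_bank):
        phase, amp = pp.extract_phase_amp(coupled_segments, "Cz", (8.0, 64.0), single_pair_bank)
        surr = pp.surrogate_mi(phase, amp, fs_hz=250.0, n_surr=200, seed=0)
        assert surr.shape == (200,)

    def test_shifts_destroy_true_coupling(self, noiseless_coupled_segments, single_pair_bank):
        phase, amp = pp.extract_phase_amp(
            noiseless_coupled_segments, "Cz", (8.0, 64.0), single_pair_bank
        )
        core = slice(103, -103)
        dists = [pp.bin_amplitude_by_phase(p[core], a[core]) for p, a in zip(phase, amp)]
        mi_raw = pp.modulation_index(pp.average_distributions(dists))
        surr = pp.surrogate_mi(phase, amp, 250.0, n_surr=200, seed=1, edge_trim=103)
        assert surr.max() < mi_raw

    def test_invalid_shift_range(self, coupled_segments, single_pair_bank):
        phase, amp = pp.extract_phase_amp(coupled_segments, "Cz", (8.0, 64.0), single_pair_bank)
        with pytest.raises(ValueError):
            pp.surrogate_mi(phase, amp, 250.0, shift_range_s=(0.0, 3.0))

    def test_reproducible_with_seed(self, coupled_segments, single_pair_bank):
        phase, amp = pp.extract_phase_amp(coupled_segments, "Cz", (8.0, 64.0), single_pair_bank)
        a = pp.surrogate_mi(phase, amp, 250.0, n_surr=20, seed=3)
        b = pp.surrogate_mi(phase, amp, 250.0, n_surr=20, seed=3)
        assert np.array_equal(a, b)

    def test_fast_and_slow_paths_agree(self):
        # slow path handles empty bins; on full-coverage input both must match
        rng = np.random.default_rng(0)
        n_seg, n = 4, 500
        phase = np.stack(
            [(np.rad2deg(2 * np.pi * 8 * np.arange(n) / 250) + 180) % 360 - 180]
            * n_seg
        )
        amp = rng.uniform(0.5, 1.5, (n_seg, n))
        from pacpipe.metrics import _surrogate_mi_slow, phase_bin_indices

        fast = pp.surrogate_mi(phase, amp, 250.0, n_surr=10, seed=5, edge_trim=50)
        shifts = np.random.default_rng(5).integers(25, 476, size=(10, n_seg))
        core = slice(50, n - 50)
        slow = _surrogate_mi_slow(phase_bin_indices(phase[:, core]), amp, shifts, core)
        assert np.allclose(fast, slow, atol=1e-12)


class TestComputePacMap:
    def test_strong_coupling_detected(self, coupled_segments, single_pair_bank):
        seg = pp.select_segments(coupled_segments, 30, seed=0)
        pac = pp.compute_pac_map(seg, single_pair_bank, n_surr=200, seed=1)
        cell = pac.cell("Cz", 8.0, 64.0)
        assert cell.mi_norm > 1.96
        assert cell.mi_norm == pytest.approx(
            (cell.mi_raw - cell.surr_mean) / cell.surr_sd
        )

    def test_cells_exist_only_for_valid_pairs(self):
        spec = pp.build_filterbank(lf_centers=[8.0, 20.0], hf_centers=[40.0, 64.0])
        params = pp.SimSignalParams(duration_s=10.0, seed=0)
        seg = pp.segment_recording(pp.simulate_coupled_signal(params))
        pac = pp.compute_pac_map(seg, spec, n_surr=10, seed=0)
        frame = pac.to_frame()
        assert len(frame) == spec.valid_pair_mask.sum()
        assert np.isnan(pac.mi_raw[0][~spec.valid_pair_mask]).all()
        with pytest.raises(KeyError):
            pac.cell("Cz", 20.0, 40.0)

    def test_deterministic_for_seed(self, coupled_segments, single_pair_bank):
        seg = pp.select_segments(coupled_segments, 30, seed=0)
        a = pp.compute_pac_map(seg, single_pair_bank, n_surr=50, seed=7)
        b = pp.compute_pac_map(seg, single_pair_bank, n_surr=50, seed=7)
        assert np.array_equal(a.mi_norm, b.mi_norm)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    weights=st.lists(st.floats(0.01, 10.0), min_size=N_BINS, max_size=N_BINS),
    scale=st.floats(0.1, 100.0),
)
def test_mi_scale_invariance_property(weights, scale):
    amp = np.asarray(weights)
    assert pp.modulation_index(amp * scale) == pytest.approx(
        pp.modulation_index(amp), abs=1e-10
    )
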