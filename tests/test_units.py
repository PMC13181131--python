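"""MUA extraction, waveform classes, responsiveness, receptive fields and
pairwise phase consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from seqssvep import synthgen
from seqssvep.units import (
    ApSegment,
    Psth,
    SpikePhaseSet,
    UnitWaveform,
    classify_waveform,
    compute_psth,
    extract_mua,
    is_responsive,
    isi_violation_fraction,
    ppc,
    retinotopic_coverage,
    spike_phases,
    sta_receptive_field,
)

FS_AP = 30000.0


def ppc_bruteforce(phases_cycles):
    """O(N^2) double-loop oracle for the pairwise phase consistency."""
    th = 2 * np.pi * np.asarray(phases_cycles)
    n = th.size
    acc = 0.0
    for j in range(n - 1):
        for k in range(j + 1, n):
            acc += (np.cos(th[j]) * np.cos(th[k])
                    + np.sin(th[j]) * np.sin(th[k]))
    return 2.0 * acc / (n * (n - 1))


class TestExtractMua:
    def test_gaussian_noise_crossing_rate_matches_rice_oracle(self, rng):
        dur = 20.0
        x = rng.standard_normal((1, int(dur * FS_AP)))
        with pytest.warns(UserWarning, match="single-channel"):
            events = extract_mua(ApSegment(x, FS_AP), threshold_sd=4.0)
        # Rice rate of the band-passed Gaussian, from the filter's PSD moments
        sos = sps.butter(2, [300.0, 3000.0], btype="bandpass", fs=FS_AP,
                         output="sos")
        f, h = sps.sosfreqz(sos, worN=8192, fs=FS_AP)
        psd = np.abs(h) ** 4  # filtfilt: |H|^2 in amplitude
        m0 = np.trapezoid(psd, f)
        m2 = np.trapezoid((2 * np.pi * f) ** 2 * psd, f)
        up_rate = np.sqrt(m2 / m0) / (2 * np.pi) * np.exp(-16.0 / 2)
        expected = 2 * up_rate * dur  # both polarities
        observed = events[0].size
        assert expected / 2 < observed < expected * 2

    def test_injected_template_detected_at_injected_times(self, rng):
        n = int(5 * FS_AP)
        x = rng.standard_normal((4, n))
        tpl = -6.0 * sps.windows.gaussian(30, 4) + np.roll(
            3.0 * sps.windows.gaussian(30, 6), 10)
        true_times = np.array([0.5, 1.2, 2.0, 3.3, 4.4])
        for t0 in true_times:
            i = int(t0 * FS_AP)
            x[2, i : i + 30] += tpl * x[2].std() * 1.5
        events = extract_mua(ApSegment(x, FS_AP))
        for t0 in true_times:
            assert np.min(np.abs(events[2] - t0)) < 0.2e-3 + 30 / FS_AP

    def test_common_mode_artifact_removed_by_median(self):
        n = int(2 * FS_AP)
        artifact = 50.0 * np.sin(2 * np.pi * 1000.0 * np.arange(n) / FS_AP)
        x = np.tile(artifact, (8, 1))
        events = extract_mua(ApSegment(x, FS_AP))
        assert all(e.size == 0 for e in events)


class TestClassifyWaveform:
    @staticmethod
    def _template(trough_to_peak_ms, fs=100000.0):
        n = int(0.003 * fs)
        t = np.arange(n) / fs * 1000.0
        w = (-1.0 * np.exp(-0.5 * ((t - 1.0) / 0.08) ** 2)
             + 0.5 * np.exp(-0.5 * ((t - 1.0 - trough_to_peak_ms) / 0.15) ** 2))
        return UnitWaveform(w, fs)

    @pytest.mark.parametrize("ptt, expected", [(0.30, "narrow"), (0.60, "broad")])
    def test_classes_either_side_of_boundary(self, ptt, expected):
        w = classify_waveform(self._template(ptt))
        assert w.cls == expected
        assert w.peak_to_trough_ms == pytest.approx(ptt, abs=0.02)

    def test_boundary_exactly_043_is_broad(self):
        # at fs = 100 kHz, 0.43 ms is exactly 43 samples
        w = classify_waveform(self._template(0.43))
        assert w.peak_to_trough_ms == pytest.approx(0.43, abs=1e-9)
        assert w.cls == "broad"

    def test_monotone_template_rejected(self):
        with pytest.raises(ValueError, match="unclassifiable"):
            classify_waveform(UnitWaveform(np.linspace(1, -1, 50), FS_AP))

    def test_round_trip_on_generated_templates(self):
        cfg = synthgen.SyntheticConfig(n_channels=4, hf_span_channels=(0, 1),
                                       n_units=30, rng_seed=5)
        units = synthgen.generate_waveforms(cfg)
        for u in units:
            w = classify_waveform(UnitWaveform(u.template, cfg.fs_ap))
            assert w.cls == u.cls
            assert w.peak_to_trough_ms == pytest.approx(u.peak_to_trough_ms)


class TestIsiViolations:
    def test_regular_train_clean(self):
        frac, qc = isi_violation_fraction(np.arange(0, 100, 0.1))
        assert frac == 0.0 and qc is True

    def test_single_violation_counted(self):
        st_ = np.arange(1000) * 1.0
        st_[500] = st_[499] + 0.0005
        frac, _ = isi_violation_fraction(np.sort(st_), refractory_ms=2.0)
        assert frac == pytest.approx(1 / 999)

    def test_poisson_rate_matches_exponential_cdf(self, rng):
        rate = 50.0
        st_ = np.cumsum(rng.exponential(1 / rate, size=200_000))
        frac, qc = isi_violation_fraction(st_, refractory_ms=2.0)
        assert frac == pytest.approx(1 - np.exp(-rate * 0.002), rel=0.05)
        assert qc is False

    def test_too_few_spikes_flagged(self):
        frac, qc = isi_violation_fraction(np.array([1.0]))
        assert frac == 0.0 and qc is None

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            isi_violation_fraction(np.array([2.0, 1.0]))


class TestResponsiveness:
    @staticmethod
    def _psth(baseline, evoked):
        edges = np.arange(-0.5, 2.0 + 1e-9, 0.025)
        centers = (edges[:-1] + edges[1:]) / 2
        rate = np.zeros(centers.size)
        rate[centers < 0] = baseline
        rate[centers >= 0.5] = evoked
        return Psth(rate, edges)

    def test_flat_psth_not_responsive(self):
        edges = np.arange(-0.5, 2.0 + 1e-9, 0.025)
        assert not is_responsive(Psth(np.full(edges.size - 1, 3.0), edges))

    def test_threshold_arithmetic(self):
        # baseline mean 2, SD 1 -> gate at 2 + 7.5 = 9.5
        edges = np.arange(-0.5, 2.0 + 1e-9, 0.025)
        centers = (edges[:-1] + edges[1:]) / 2
        base = np.where(np.arange((centers < 0).sum()) % 2 == 0, 1.0, 3.0)
        for peak, expected in [(12.0, True), (9.0, False)]:
            rate = np.zeros(centers.size)
            rate[centers < 0] = base
            rate[centers >= 0.5] = peak
            assert is_responsive(Psth(rate, edges)) is expected

    def test_degenerate_zero_baseline(self):
        with pytest.warns(UserWarning, match="zero baseline"):
            assert is_responsive(self._psth(0.0, 1.0))

    def test_psth_rates_from_counts(self):
        spikes = np.concatenate([np.array([0.6, 0.7]), np.array([4.6, 4.7])])
        psth = compute_psth(spikes, [0.0, 4.0], bin_ms=100.0)
        centers = (psth.bin_edges_s[:-1] + psth.bin_edges_s[1:]) / 2
        # 1 spike per trial in the 0.6-0.7 s bin, 2 trials, 0.1 s bins -> 10 sp/s
        assert psth.rate[np.argmin(np.abs(centers - 0.65))] == pytest.approx(10.0)


@pytest.fixture(scope="module")
def sparse_session():
    cfg = synthgen.SyntheticConfig(n_channels=4, hf_span_channels=(0, 1),
                                   rng_seed=11)
    centers = [(0.0, 0.0), (30.0, 0.0), (0.0, 30.0), (-45.0, -15.0)]
    frames, units = synthgen.generate_sparse_noise_responses(
        cfg, centers_deg=centers, repeats_per_position=10)
    return frames, units


class TestReceptiveFields:
    def test_center_recovery_within_one_grid_square(self, sparse_session):
        frames, units = sparse_session
        for u in units:
            rf = sta_receptive_field(u.spike_times_s, frames)
            err = np.hypot(rf.center_deg[0] - u.rf_center_deg[0],
                           rf.center_deg[1] - u.rf_center_deg[1])
            assert err < 15.0

    def test_untuned_unit_fails_snr_gate(self, sparse_session, rng):
        frames, _ = sparse_session
        t_end = frames["onset_s"].max()
        st_ = np.sort(rng.uniform(0, t_end, 400))
        rf = sta_receptive_field(st_, frames)
        assert rf.snr < 15.0

    def test_pairwise_center_distance(self, sparse_session):
        frames, units = sparse_session
        rfs = [sta_receptive_field(u.spike_times_s, frames) for u in units[:2]]
        d = np.hypot(rfs[0].center_deg[0] - rfs[1].center_deg[0],
                     rfs[0].center_deg[1] - rfs[1].center_deg[1])
        assert d == pytest.approx(30.0, abs=15.0)

    def test_zero_spikes_rejected(self, sparse_session):
        frames, _ = sparse_session
        with pytest.raises(ValueError, match="no spikes"):
            sta_receptive_field(np.empty(0), frames)

    def test_coverage_spans_layout(self, sparse_session):
        frames, units = sparse_session
        rfs = [sta_receptive_field(u.spike_times_s, frames) for u in units]
        cov = retinotopic_coverage(rfs)
        true_cov = 0.0
        for a in units:
            for b in units:
                true_cov = max(true_cov, np.hypot(
                    a.rf_center_deg[0] - b.rf_center_deg[0],
                    a.rf_center_deg[1] - b.rf_center_deg[1]))
        assert cov == pytest.approx(true_cov, abs=15.0)


class TestRetinotopicCoverage:
    @staticmethod
    def _rf(center, snr=20.0):
        from seqssvep.units import ReceptiveField
        return ReceptiveField(np.zeros((4, 4)), center, 10.0, snr)

    def test_identical_centers(self):
        assert retinotopic_coverage([self._rf((5, 5)), self._rf((5, 5))]) == 0.0

    def test_three_four_five(self):
        assert retinotopic_coverage(
            [self._rf((0, 0)), self._rf((30, 40))]) == pytest.approx(50.0)

    def test_gate_enforced(self):
        with pytest.raises(ValueError, match="SNR gate"):
            retinotopic_coverage([self._rf((0, 0)), self._rf((1, 1), snr=2.0)])


class TestSpikePhases:
    WINDOWS = np.array([[2.0, 4.0]])

    def test_anchor_and_half_cycle(self):
        ph = spike_phases(np.array([2.0, 2.15]), 10.0, self.WINDOWS)
        assert ph.phases[0] == 0.0
        assert ph.phases[1] == pytest.approx(0.5)  # 1.5 cycles -> phase 0.5

    def test_period_multiples_all_zero(self):
        st_ = 2.0 + np.arange(10) / 10.0
        ph = spike_phases(st_, 10.0, self.WINDOWS)
        assert np.allclose(np.minimum(ph.phases, 1 - ph.phases), 0.0, atol=1e-9)

    def test_spikes_outside_windows_excluded(self):
        ph = spike_phases(np.array([0.5, 2.5, 5.0]), 10.0, self.WINDOWS)
        assert ph.phases.size == 1

    def test_rejects_nonpositive_frequency(self):
        with pytest.raises(ValueError):
            spike_phases(np.array([1.0]), 0.0, self.WINDOWS)


class TestPpc:
    def test_identical_phases_give_one(self):
        assert ppc(SpikePhaseSet(np.full(50, 0.3), 10.0)).ppc == pytest.approx(1.0)

    def test_two_antiphase_spikes_give_minus_one(self):
        assert ppc(SpikePhaseSet(np.array([0.1, 0.6]), 10.0)).ppc == pytest.approx(
            -1.0)

    def test_undefined_below_two_spikes(self):
        assert ppc(SpikePhaseSet(np.array([0.2]), 10.0)).ppc is None

    def test_uniform_phases_unbiased_around_zero(self):
        vals = []
        for rep in range(20):
            r = np.random.default_rng(1000 + rep)
            vals.append(ppc(SpikePhaseSet(r.uniform(0, 1, 10_000), 10.0)).ppc)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-12

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 60))
    def test_matches_double_loop_oracle(self, seed, n):
        r = np.random.default_rng(seed)
        phases = r.uniform(0, 1, n)
        assert ppc(SpikePhaseSet(phases, 10.0)).ppc == pytest.approx(
            ppc_bruteforce(phases), abs=1e-10)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000),
           shift=st.floats(0, 1, allow_nan=False))
    def test_invariant_under_global_phase_shift(self, seed, shift):
        r = np.random.default_rng(seed)
        phases = r.uniform(0, 1, 40)
        a = ppc(SpikePhaseSet(phases, 10.0)).ppc
        b = ppc(SpikePhaseSet(np.mod(phases + shift, 1.0), 10.0)).ppc
        assert a == pytest.approx(b, abs=1e-9)

    def test_locking_weakens_with_repeat_frequency_at_fixed_jitter_ms(self):
        # spikes jittered by a fixed 8 ms SD around cycle anchors lock tightly
        # at 10 Hz but poorly at 40 Hz, mirroring the fall-off of phase
        # consistency with increasing repeat frequency
        r = np.random.default_rng(7)
        windows = np.array([[0.0, 100.0]])
        prev = np.inf
        for f_rep in (10.0, 24.0, 40.0):
            anchors = np.arange(0.0, 100.0, 1 / f_rep)
            st_ = np.sort(anchors + r.normal(0, 0.008, anchors.size))
            val = ppc(spike_phases(st_, f_rep, windows)).ppc
            assert val < prev
            prev = val
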