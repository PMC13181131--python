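"""Unit-level analysis: MUA extraction, waveform classes, responsiveness,
spike-triggered-average receptive fields, ISI quality, and pairwise phase
consistency against the stimulus repeat frequency.

Phase locking is quantified with the pairwise phase consistency (PPC), the
mean over spike pairs of cos(theta_j - theta_k), an estimator of the squared
resultant length that is free of the sample-size bias of vector strength.
Spike phases are measured against a fixed sinusoid at the stimulus repeat
frequency anchored at stimulus onset, stored in cycles in [0, 1) and converted
to radians for trigonometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal

__all__ = [
    "ApSegment",
    "UnitWaveform",
    "SpikePhaseSet",
    "PPCResult",
    "ReceptiveField",
    "Psth",
    "extract_mua",
    "classify_waveform",
    "isi_violation_fraction",
    "compute_psth",
    "is_responsive",
    "sta_receptive_field",
    "retinotopic_coverage",
    "spike_phases",
    "ppc",
    "units_table",
]

WAVEFORM_BOUNDARY_MS = 0.43
RESPONSIVENESS_SNR = 7.5
RF_SNR_GATE_AU = 15.0
ISI_QC_FRACTION = 0.0005


@dataclass
class ApSegment:
    """Action-potential-band segment, channels x samples (uV) at 30 kHz."""

    data: np.ndarray
    fs: float = 30000.0


@dataclass
class UnitWaveform:
    """Mean spike template with its peak-to-trough class."""

    template: np.ndarray
    fs: float
    peak_to_trough_ms: float | None = None
    cls: str | None = None


@dataclass
class SpikePhaseSet:
    """Per-spike phases, in cycles in [0, 1), of one unit at one repeat frequency."""

    phases: np.ndarray
    f_rep: float
    unit_id: int = 0


@dataclass
class PPCResult:
    ppc: float | None
    n_spikes: int
    unit_id: int = 0


@dataclass
class ReceptiveField:
    """STA receptive field on the sparse-noise grid, interpolated to find the peak."""

    map: np.ndarray  # nx x ny STA values on the stimulus grid
    center_deg: tuple[float, float]
    size_deg: float
    snr: float
    azimuth_deg: np.ndarray | None = None
    elevation_deg: np.ndarray | None = None


@dataclass
class Psth:
    """Peri-stimulus time histogram; rate in spikes/s per bin."""

    rate: np.ndarray
    bin_edges_s: np.ndarray
    baseline_window_s: tuple[float, float] = (-0.5, -0.005)
    evoked_window_s: tuple[float, float] = (0.5, 2.0)


# ---------------------------------------------------------------------------
# MUA

def extract_mua(
    ap: ApSegment,
    threshold_sd: float = 4.0,
    dead_time_ms: float = 1.0,
) -> list[np.ndarray]:
    """Threshold-crossing event times per channel.

    The common median across channels is subtracted per sample, the result is
    band-passed 0.3-3 kHz (Butterworth order 2, zero-phase), and events are
    kept where |signal| exceeds ``threshold_sd`` times the per-channel SD;
    events closer than ``dead_time_ms`` on one channel are merged.
    """
    data = np.asarray(ap.data, dtype=np.float64)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[0] > 1:
        data = data - np.median(data, axis=0, keepdims=True)
    else:
        warnings.warn("single-channel segment: median subtraction skipped")
    sos = signal.butter(2, [300.0, 3000.0], btype="bandpass", fs=ap.fs, output="sos")
    filt = signal.sosfiltfilt(sos, data, axis=1)
    dead = int(round(dead_time_ms / 1000.0 * ap.fs))
    out = []
    for ch in range(filt.shape[0]):
        x = filt[ch]
        thr = threshold_sd * x.std()
        above = np.abs(x) > thr
        # onsets of supra-threshold excursions
        onsets = np.nonzero(above & ~np.r_[False, above[:-1]])[0]
        if onsets.size:
            keep = [onsets[0]]
            for i in onsets[1:]:
                if i - keep[-1] >= dead:
                    keep.append(i)
            onsets = np.asarray(keep)
        out.append(onsets / ap.fs)
    return out


# ---------------------------------------------------------------------------
# waveforms

def classify_waveform(w: UnitWaveform) -> UnitWaveform:
    """Assign broad/narrow class from the trough-to-peak duration.

    Duration = time of the post-trough maximum minus time of the minimum;
    narrow if strictly below 0.43 ms, broad otherwise (the boundary itself is
    assigned to broad).
    """
    tpl = np.asarray(w.template, dtype=float)
    trough = int(np.argmin(tpl))
    if trough >= tpl.size - 1:
        raise ValueError("template has no post-trough peak; unclassifiable")
    peak = trough + int(np.argmax(tpl[trough:]))
    if peak == trough or np.all(np.diff(tpl) >= 0) or np.all(np.diff(tpl) <= 0):
        raise ValueError("monotone template; unclassifiable")
    ptt = (peak - trough) / w.fs * 1000.0
    w.peak_to_trough_ms = ptt
    w.cls = "narrow" if ptt < WAVEFORM_BOUNDARY_MS else "broad"
    return w


# ---------------------------------------------------------------------------
# quality and responsiveness

def isi_violation_fraction(spike_times_s: np.ndarray, refractory_ms: float = 2.0):
    """Fraction of inter-spike intervals shorter than the refractory period.

    Returns ``(fraction, passes_qc)``; QC passes when the fraction is below
    0.05%.  Fewer than 2 spikes give fraction 0 with QC flagged as
    indeterminate (None).
    """
    st = np.asarray(spike_times_s, dtype=float)
    if np.any(np.diff(st) < 0):
        raise ValueError("spike times must be sorted ascending")
    if st.size < 2:
        return 0.0, None
    isi = np.diff(st)
    frac = float((isi < refractory_ms / 1000.0).mean())
    return frac, frac < ISI_QC_FRACTION


def compute_psth(
    spike_times_s: np.ndarray,
    event_times_s: np.ndarray,
    window_s: tuple[float, float] = (-0.5, 2.0),
    bin_ms: float = 25.0,
) -> Psth:
    """Trial-averaged peri-stimulus time histogram, rate in spikes/s."""
    events = np.atleast_1d(np.asarray(event_times_s, dtype=float))
    edges = np.arange(window_s[0], window_s[1] + 1e-9, bin_ms / 1000.0)
    counts = np.zeros(edges.size - 1)
    for t0 in events:
        rel = np.asarray(spike_times_s) - t0
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / events.size / (bin_ms / 1000.0)
    return Psth(rate, edges)


def is_responsive(psth: Psth, snr: float = RESPONSIVENESS_SNR) -> bool:
    """Visual responsiveness gate: evoked peak reaches baseline mean + 7.5 SD.

    Baseline statistics are taken across the pre-stimulus bins (-500 to -5 ms);
    the evoked window is 500-2000 ms.  A silent, zero-variance baseline
    degenerates to "any evoked spike counts" (logged via warning).
    """
    centers = (psth.bin_edges_s[:-1] + psth.bin_edges_s[1:]) / 2
    b = psth.rate[(centers >= psth.baseline_window_s[0])
                  & (centers <= psth.baseline_window_s[1])]
    e = psth.rate[(centers >= psth.evoked_window_s[0])
                  & (centers <= psth.evoked_window_s[1])]
    if b.size == 0 or e.size == 0:
        raise ValueError("PSTH does not cover the baseline/evoked windows")
    if b.std() == 0:
        # zero-variance baseline: the SNR gate degenerates, so require strict
        # exceedance of the baseline level (any evoked spike if also silent)
        if b.mean() == 0:
            warnings.warn("zero baseline; responsiveness degenerates to any "
                          "evoked spike")
        return bool(e.max() > b.mean())
    return bool(e.max() >= b.mean() + snr * b.std())


# ---------------------------------------------------------------------------
# receptive fields

def sta_receptive_field(
    spike_times_s: np.ndarray,
    sparse_frames: pd.DataFrame,
    latency_s: float = 0.0,
    upsample: int = 4,
) -> ReceptiveField:
    """Spike-triggered-average receptive field from a sparse-noise session.

    Each spike is attributed to the frame on screen ``latency_s`` earlier; the
    STA map counts how often each grid square was a target at spike time,
    normalised by its presentation count.  The map is upsampled with 2-D cubic
    spline interpolation; the centre is the interpolated peak (degrees), the
    size the mean width at half the peak amplitude along azimuth and
    elevation, and the SNR the peak deviation from the map mean over the SD of
    the outermost ring of grid squares.
    """
    st = np.asarray(spike_times_s, dtype=float)
    if st.size == 0:
        raise ValueError("no spikes; STA undefined")
    nx, ny = sparse_frames.attrs["grid_shape"]
    square = sparse_frames.attrs["square_deg"]
    frame_s = sparse_frames.attrs["frame_ms"] / 1000.0

    onset = sparse_frames["onset_s"].to_numpy()
    ix = sparse_frames["ix"].to_numpy()
    iy = sparse_frames["iy"].to_numpy()
    n_frames = int(sparse_frames["frame"].max()) + 1

    frame_of_spike = np.floor((st - latency_s) / frame_s).astype(int)
    frame_of_spike = frame_of_spike[(frame_of_spike >= 0) & (frame_of_spike < n_frames)]
    spike_counts = np.bincount(frame_of_spike, minlength=n_frames)

    frame_idx = sparse_frames["frame"].to_numpy()
    sta = np.zeros((nx, ny))
    shown = np.zeros((nx, ny))
    np.add.at(sta, (ix, iy), spike_counts[frame_idx])
    np.add.at(shown, (ix, iy), 1.0)
    shown[shown == 0] = 1.0
    sta = sta / shown

    az = (np.arange(nx) - (nx - 1) / 2.0) * square
    el = (np.arange(ny) - (ny - 1) / 2.0) * square
    spline = interpolate.RectBivariateSpline(az, el, sta, kx=3, ky=3)
    az_f = np.linspace(az[0], az[-1], nx * upsample)
    el_f = np.linspace(el[0], el[-1], ny * upsample)
    fine = spline(az_f, el_f)
    pi, pj = np.unravel_index(np.argmax(fine), fine.shape)
    center = (float(az_f[pi]), float(el_f[pj]))

    half = fine.mean() + (fine[pi, pj] - fine.mean()) / 2.0
    wa = (fine[:, pj] >= half).sum() * (az_f[1] - az_f[0])
    we = (fine[pi, :] >= half).sum() * (el_f[1] - el_f[0])
    size = float((wa + we) / 2.0)

    ring = np.concatenate([sta[0, :], sta[-1, :], sta[1:-1, 0], sta[1:-1, -1]])
    ring_sd = ring.std()
    snr = float(np.abs(fine[pi, pj] - sta.mean()) / ring_sd) if ring_sd > 0 else np.inf
    return ReceptiveField(sta, center, size, snr, az, el)


def retinotopic_coverage(rfs: list[ReceptiveField],
                         snr_gate: float = RF_SNR_GATE_AU) -> float:
    """Maximal pairwise Euclidean distance between gated RF centres, degrees."""
    gated = [rf for rf in rfs if rf.snr >= snr_gate]
    if len(gated) < 2:
        raise ValueError("fewer than 2 receptive fields pass the SNR gate")
    centers = np.array([rf.center_deg for rf in gated])
    d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
    return float(d.max())


# ---------------------------------------------------------------------------
# phase locking

def spike_phases(
    spike_times_s: np.ndarray,
    f_rep: float,
    stim_windows_s: np.ndarray,
    unit_id: int = 0,
) -> SpikePhaseSet:
    """Phases of spikes against a fixed sinusoid at the repeat frequency.

    For a spike at t inside a stimulus window starting at t0, the phase is
    frac((t - t0) * f_rep), a unit-less position in the cycle in [0, 1).
    Spikes outside stimulus windows are excluded.
    """
    if f_rep <= 0:
        raise ValueError("f_rep must be positive")
    st = np.asarray(spike_times_s, dtype=float)
    windows = np.atleast_2d(np.asarray(stim_windows_s, dtype=float))
    phases = []
    for on, off in windows:
        sel = st[(st >= on) & (st < off)]
        phases.append(np.mod((sel - on) * f_rep, 1.0))
    return SpikePhaseSet(np.concatenate(phases) if phases else np.empty(0),
                         f_rep, unit_id)


def ppc(phase_set: SpikePhaseSet) -> PPCResult:
    """Pairwise phase consistency of one unit's spike phases.

    PPC = 2 / (N (N-1)) * sum_{j<k} cos(theta_j - theta_k), the mean over
    spike pairs of the cosine of their phase difference, computed through the
    resultant-length identity (|sum e^{i theta}|^2 - N) / (N (N-1)).  Phases
    are stored in cycles and converted to radians here.  Undefined (None) for
    fewer than 2 spikes.
    """
    n = int(phase_set.phases.size)
    if n < 2:
        return PPCResult(None, n, phase_set.unit_id)
    theta = 2 * np.pi * np.asarray(phase_set.phases, dtype=float)
    resultant = np.exp(1j * theta).sum()
    val = (np.abs(resultant) ** 2 - n) / (n * (n - 1))
    return PPCResult(float(val), n, phase_set.unit_id)


def units_table(results: list[dict]) -> pd.DataFrame:
    """Assemble per-unit analysis rows into the standard output table."""
    return pd.DataFrame(results)
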