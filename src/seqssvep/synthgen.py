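"""Synthetic Neuropixels-like recordings with known ground truth.

The generator emulates the geometry and statistics of an awake-mouse V1
recording just closely enough to exercise every downstream stage with a known
answer: 384-channel LFP at 2.5 kHz with 1/f^alpha Gaussian background, a
stimulus-locked SSVEP harmonic series at the repeat frequency (with a
retinotopic phase progression across channels), an injectable narrow-band
high-frequency power increase over a contiguous channel span during stimulus
windows, inhomogeneous-Poisson spike trains with von Mises phase locking to
the repeat frequency, biphasic waveform templates in two peak-to-trough
classes, and sparse-noise responses with Gaussian spatial tuning around known
receptive-field centres.  Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, special

from .stimgen import FrameSchedule, StimulusSpec, repeat_frequency

__all__ = [
    "SyntheticConfig",
    "SyntheticUnit",
    "SyntheticRecording",
    "generate_background",
    "generate_lfp",
    "generate_spikes",
    "generate_waveforms",
    "generate_sparse_noise_responses",
    "save_recording",
    "load_recording",
]

WAVEFORM_BOUNDARY_MS = 0.43


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic recording; defaults follow the emulated setup.

    384 channels at 2.5 kHz LFP / 30 kHz AP band, 10 um per sorted channel,
    1/f background (alpha = 1).  ``hf_span_channels`` is the inclusive channel
    interval that receives extra band-limited power (``hf_band``) during
    stimulus windows, with band power multiplied by ``hf_gain``.
    ``locking_kappa`` is the von Mises concentration of spike phases relative
    to the repeat-frequency sinusoid; ``modulation_depth`` optionally adds a
    sinusoidal rate modulation instead.
    """

    n_channels: int = 384
    fs_lfp: float = 2500.0
    fs_ap: float = 30000.0
    channel_pitch_um: float = 10.0
    noise_exponent: float = 1.0
    noise_rms_uv: float = 25.0
    ssvep_amplitude_uv: float = 40.0
    ssvep_harmonics: int = 3
    hf_band: tuple[float, float] = (100.0, 190.0)
    hf_span_channels: tuple[int, int] = (100, 149)
    hf_gain: float = 1.0
    baseline_rate_hz: float = 5.0
    locking_kappa: float = 0.0
    preferred_phase: float = 0.0
    modulation_depth: float = 0.0
    n_units: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.hf_band[0] < self.hf_band[1]):
            raise ValueError("hf_band must satisfy 0 < low < high")
        if self.hf_band[1] >= self.fs_lfp / 2:
            raise ValueError("hf_band must lie below the LFP Nyquist frequency")
        lo, hi = self.hf_span_channels
        if not (0 <= lo <= hi < self.n_channels):
            raise ValueError("hf_span_channels must lie within [0, n_channels)")
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline_rate_hz must be non-negative")
        if self.locking_kappa < 0:
            raise ValueError("locking_kappa must be non-negative")
        if self.hf_gain < 0 or self.ssvep_amplitude_uv < 0 or self.noise_rms_uv < 0:
            raise ValueError("gains and amplitudes must be non-negative")


@dataclass
class SyntheticUnit:
    """Ground truth for one synthetic unit."""

    unit_id: int
    spike_times_s: np.ndarray
    cls: str  # "broad" or "narrow"
    locking_kappa: float
    preferred_phase: float
    template: np.ndarray | None = None
    peak_to_trough_ms: float | None = None
    rf_center_deg: tuple[float, float] | None = None


@dataclass
class SyntheticRecording:
    """LFP + spikes + trial events + the ground truth that produced them."""

    lfp: np.ndarray  # channels x samples, float32 uV
    fs_lfp: float
    events: pd.DataFrame  # trial, onset_s, label
    units: list[SyntheticUnit] = field(default_factory=list)
    truth: dict = field(default_factory=dict)
    config: SyntheticConfig | None = None

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.fs_lfp


# ---------------------------------------------------------------------------
# LFP

def generate_background(
    n_channels: int, n_samples: int, fs: float, exponent: float,
    rms_uv: float, rng: np.random.Generator,
) -> np.ndarray:
    """1/f^alpha Gaussian background, synthesized in the frequency domain.

    Amplitudes scale as f^(-alpha/2) (power ~ 1/f^alpha) with random phases,
    normalised per channel to the requested RMS.
    """
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    out = np.empty((n_channels, n_samples), dtype=np.float32)
    for ch in range(n_channels):
        spec = amp * (rng.standard_normal(freqs.size)
                      + 1j * rng.standard_normal(freqs.size))
        x = np.fft.irfft(spec, n=n_samples)
        sd = x.std()
        out[ch] = (x * (rms_uv / sd if sd > 0 else 0.0)).astype(np.float32)
    return out


def _stim_mask(schedule: FrameSchedule, n_samples: int, fs: float,
               ramp_s: float = 0.01) -> np.ndarray:
    """Soft 0/1 gate over stimulus windows with short cosine ramps."""
    t = np.arange(n_samples) / fs
    gate = np.zeros(n_samples)
    for on, off in schedule.stim_windows():
        m = (t >= on) & (t < off)
        gate[m] = 1.0
        rise = (t >= on) & (t < on + ramp_s)
        gate[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - on) / ramp_s))
        fall = (t >= off - ramp_s) & (t < off)
        gate[fall] = 0.5 * (1 - np.cos(np.pi * (off - t[fall]) / ramp_s))
    return gate


def generate_lfp(config: SyntheticConfig, schedule: FrameSchedule) -> SyntheticRecording:
    """Generate the LFP part of a synthetic recording.

    LFP = 1/f^alpha background
        + (stimulus windows) SSVEP harmonic series at the repeat frequency,
          phase-shifted across channels to mimic the retinotopic progression
        + (stimulus windows, hf_span channels) band-limited Gaussian noise in
          ``hf_band`` scaled so band power rises by the factor ``hf_gain``.
    """
    rng = np.random.default_rng(config.rng_seed)
    fs = config.fs_lfp
    n_samples = int(np.round(schedule.duration_s * fs))
    lfp = generate_background(config.n_channels, n_samples, fs,
                              config.noise_exponent, config.noise_rms_uv, rng)

    f_rep = repeat_frequency(schedule.spec)
    t = np.arange(n_samples) / fs

    # stimulus-locked SSVEP, identical across trials (anchored at trial onset)
    if config.ssvep_amplitude_uv > 0:
        chan_phase = 2 * np.pi * np.arange(config.n_channels) / config.n_channels
        for on, off in schedule.stim_windows():
            s0 = int(np.round(on * fs))
            s1 = min(int(np.round(off * fs)), n_samples)
            tt = t[s0:s1] - on
            # sin(h w t + h phi_ch) expanded so each harmonic is two outer
            # products instead of a per-channel loop
            block = np.zeros((config.n_channels, s1 - s0))
            for h in range(1, config.ssvep_harmonics + 1):
                s_h = np.sin(2 * np.pi * h * f_rep * tt)
                c_h = np.cos(2 * np.pi * h * f_rep * tt)
                block += (np.cos(h * chan_phase)[:, None] * s_h[None, :]
                          + np.sin(h * chan_phase)[:, None] * c_h[None, :]) / h
            lfp[:, s0:s1] += (config.ssvep_amplitude_uv * block).astype(np.float32)

    # high-frequency injection
    if config.hf_gain != 1.0:
        sos = signal.butter(4, config.hf_band, btype="bandpass", fs=fs, output="sos")
        gate = _stim_mask(schedule, n_samples, fs).astype(np.float32)
        lo, hi = config.hf_span_channels
        for ch in range(lo, hi + 1):
            bg_band = signal.sosfiltfilt(sos, lfp[ch].astype(np.float64))
            p_band = bg_band.var()
            extra = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
            extra *= np.sqrt(max(config.hf_gain - 1.0, 0.0) * p_band / extra.var())
            lfp[ch] += (extra * gate).astype(np.float32)

    events = pd.DataFrame(
        {
            "trial": np.arange(schedule.spec.n_trials),
            "onset_s": schedule.trial_onsets_s,
            "label": schedule.spec.kind,
        }
    )
    truth = {
        "hf_span_channels": list(config.hf_span_channels),
        "hf_gain": config.hf_gain,
        "hf_band": list(config.hf_band),
        "repeat_frequency_hz": f_rep,
    }
    return SyntheticRecording(lfp, fs, events, [], truth, config)


# ---------------------------------------------------------------------------
# spikes

def generate_spikes(
    config: SyntheticConfig,
    schedule: FrameSchedule,
    n_units: int | None = None,
) -> list[SyntheticUnit]:
    """Spike trains phase-locked to the repeat-frequency sinusoid.

    Spikes are an inhomogeneous Poisson process with rate

        lambda(t) = r0 * exp(kappa * cos(phi(t) - mu)) / I0(kappa)

    inside stimulus windows (phi the phase of the repeat-frequency sinusoid
    anchored at trial onset), so spike phases are exactly von Mises(mu, kappa)
    and the mean rate stays r0; kappa = 0 reduces to a homogeneous Poisson
    process.  Outside stimulus windows the rate is the homogeneous r0.
    Simulated by thinning; deterministic given ``config.rng_seed``.
    """
    if config.baseline_rate_hz < 0:
        raise ValueError("negative rate")
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    n_units = config.n_units if n_units is None else n_units
    f_rep = repeat_frequency(schedule.spec)
    r0 = config.baseline_rate_hz
    kappa = config.locking_kappa
    mu = config.preferred_phase
    depth = config.modulation_depth
    i0k = special.i0(kappa) if np.isfinite(kappa) else np.inf

    units: list[SyntheticUnit] = []
    windows = schedule.stim_windows()
    duration = schedule.duration_s
    for u in range(n_units):
        spikes = []
        # homogeneous spikes in gray periods
        if r0 > 0:
            n_bg = rng.poisson(r0 * duration)
            bg = np.sort(rng.uniform(0.0, duration, n_bg))
            in_stim = np.zeros(bg.size, dtype=bool)
            for on, off in windows:
                in_stim |= (bg >= on) & (bg < off)
            spikes.append(bg[~in_stim])
        if not np.isfinite(kappa):
            # perfect locking: one spike per cycle, exactly at the preferred phase
            period = 1.0 / f_rep
            for on, off in windows:
                n_cyc = int(np.floor((off - on) * f_rep))
                spikes.append(on + (np.arange(n_cyc) + mu / (2 * np.pi)) * period)
            st = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
            units.append(SyntheticUnit(u, st, "broad" if u % 2 == 0 else "narrow",
                                       kappa, mu))
            continue
        # modulated spikes inside stimulus windows (thinning)
        lam_max = r0 * np.exp(kappa) / i0k * (1.0 + abs(depth))
        if lam_max > 0:
            for on, off in windows:
                span = off - on
                n_cand = rng.poisson(lam_max * span)
                cand = rng.uniform(0.0, span, n_cand)
                phase = 2 * np.pi * f_rep * cand
                lam = r0 * np.exp(kappa * np.cos(phase - mu)) / i0k
                if depth:
                    lam = lam * (1.0 + depth * np.cos(phase - mu))
                keep = rng.uniform(0.0, lam_max, n_cand) < lam
                spikes.append(np.sort(cand[keep]) + on)
        st = np.sort(np.concatenate(spikes)) if spikes else np.empty(0)
        units.append(
            SyntheticUnit(
                unit_id=u,
                spike_times_s=st,
                cls="broad" if u % 2 == 0 else "narrow",
                locking_kappa=kappa,
                preferred_phase=mu,
            )
        )
    return units


# ---------------------------------------------------------------------------
# waveforms

def generate_waveforms(
    config: SyntheticConfig,
    n_units: int | None = None,
    n_samples: int = 90,
    boundary_margin_ms: float = 0.02,
) -> list[SyntheticUnit]:
    """Biphasic spike templates in two peak-to-trough classes.

    Half the units are narrow (trough-to-peak below the 0.43 ms class
    boundary), half broad (above), with durations kept at least
    ``boundary_margin_ms`` away from the boundary so class labels are
    unambiguous.  Templates are a negative Gaussian trough followed by a
    smaller positive Gaussian peak, sampled at ``config.fs_ap``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    n_units = config.n_units if n_units is None else n_units
    fs = config.fs_ap
    t = np.arange(n_samples) / fs * 1000.0  # ms
    trough_ms = 0.8
    units = []
    for u in range(n_units):
        narrow = u % 2 == 1
        if narrow:
            d = rng.uniform(0.15, WAVEFORM_BOUNDARY_MS - boundary_margin_ms)
        else:
            d = rng.uniform(WAVEFORM_BOUNDARY_MS + boundary_margin_ms, 0.85)
        d = round(d * fs / 1000.0) / fs * 1000.0  # snap to the sample grid
        w = (-100.0 * np.exp(-0.5 * ((t - trough_ms) / 0.1) ** 2)
             + 45.0 * np.exp(-0.5 * ((t - trough_ms - d) / (0.12 + 0.25 * d)) ** 2))
        trough_i = int(np.argmin(w))
        peak_i = trough_i + int(np.argmax(w[trough_i:]))
        units.append(
            SyntheticUnit(
                unit_id=u,
                spike_times_s=np.empty(0),
                cls="narrow" if narrow else "broad",
                locking_kappa=0.0,
                preferred_phase=0.0,
                template=w,
                peak_to_trough_ms=(peak_i - trough_i) / fs * 1000.0,
            )
        )
    return units


# ---------------------------------------------------------------------------
# sparse-noise responses

def generate_sparse_noise_responses(
    config: SyntheticConfig,
    centers_deg: list[tuple[float, float]] | None = None,
    grid_shape: tuple[int, int] = (36, 22),
    square_deg: float = 15.0,
    frame_ms: float = 100.0,
    repeats_per_position: int = 20,
    tuning_sigma_deg: float = 10.0,
    peak_rate_hz: float = 60.0,
    base_rate_hz: float = 1.0,
    targets_per_frame: int = 2,
):
    """Sparse-noise mapping session with Gaussian spatially tuned units.

    Builds a pseudo-random target sequence (``targets_per_frame`` squares per
    100 ms frame, each grid position shown ``repeats_per_position`` times) and
    draws, for each unit, Poisson spike counts per frame with rate

        base + peak * sum_targets exp(-||target - center||^2 / (2 sigma^2)).

    Returns ``(frames, units)`` where frames is a DataFrame with columns
    onset_s, ix, iy (one row per target) and units carry ground-truth centres.
    Grid positions are spaced ``square_deg`` apart, centred on (0, 0).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    nx, ny = grid_shape
    if centers_deg is None:
        centers_deg = [(0.0, 0.0)]

    n_target_slots = nx * ny * repeats_per_position
    n_frames = n_target_slots // targets_per_frame
    slots = np.tile(np.arange(nx * ny), repeats_per_position)
    rng.shuffle(slots)
    slots = slots[: n_frames * targets_per_frame].reshape(n_frames, targets_per_frame)

    az = (np.arange(nx) - (nx - 1) / 2.0) * square_deg
    el = (np.arange(ny) - (ny - 1) / 2.0) * square_deg
    ix = slots % nx
    iy = slots // nx
    onset = np.arange(n_frames) * frame_ms / 1000.0

    frames = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(n_frames), targets_per_frame),
            "onset_s": np.repeat(onset, targets_per_frame),
            "ix": ix.ravel(),
            "iy": iy.ravel(),
        }
    )

    units = []
    dt = frame_ms / 1000.0
    for u, (cx, cy) in enumerate(centers_deg):
        d2 = (az[ix] - cx) ** 2 + (el[iy] - cy) ** 2
        lam = base_rate_hz + peak_rate_hz * np.exp(-d2 / (2 * tuning_sigma_deg**2)).sum(axis=1)
        counts = rng.poisson(lam * dt)
        times = []
        for k in np.nonzero(counts)[0]:
            times.append(onset[k] + rng.uniform(0, dt, counts[k]))
        st = np.sort(np.concatenate(times)) if times else np.empty(0)
        units.append(
            SyntheticUnit(
                unit_id=u,
                spike_times_s=st,
                cls="broad",
                locking_kappa=0.0,
                preferred_phase=0.0,
                rf_center_deg=(cx, cy),
            )
        )
    frames.attrs.update(
        grid_shape=grid_shape, square_deg=square_deg, frame_ms=frame_ms,
        targets_per_frame=targets_per_frame,
    )
    return frames, units


# ---------------------------------------------------------------------------
# on-disk format: flat binary int16 + JSON sidecar, CSV tables

def save_recording(rec: SyntheticRecording, outdir) -> None:
    """Write flat-binary little-endian int16 LFP + JSON sidecar + CSV tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gain = max(np.abs(rec.lfp).max() / 32000.0, 1e-6)
    ints = np.round(rec.lfp / gain).astype("<i2")
    # channels interleaved per sample (sample-major, Neuropixels convention)
    ints.T.tofile(out / "lfp.bin")
    sidecar = {
        "n_channels": int(rec.lfp.shape[0]),
        "fs": float(rec.fs_lfp),
        "gain_uV_per_bit": float(gain),
        "pitch_um": float(rec.config.channel_pitch_um if rec.config else 10.0),
        "dtype": "int16-le",
        "order": "sample_major",
    }
    (out / "lfp.json").write_text(json.dumps(sidecar, indent=2))
    rec.events.to_csv(out / "events.csv", index=False)
    if rec.units:
        rows = [
            {"unit_id": u.unit_id, "time_s": t, "cls": u.cls}
            for u in rec.units
            for t in u.spike_times_s
        ]
        pd.DataFrame(rows, columns=["unit_id", "time_s", "cls"]).to_csv(
            out / "spikes.csv", index=False
        )
    truth = dict(rec.truth)
    if rec.config is not None:
        truth["config"] = asdict(rec.config)
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=list))


def load_recording(indir) -> SyntheticRecording:
    """Read a recording written by :func:`save_recording`."""
    ind = Path(indir)
    sidecar = json.loads((ind / "lfp.json").read_text())
    raw = np.fromfile(ind / "lfp.bin", dtype="<i2")
    lfp = (raw.reshape(-1, sidecar["n_channels"]).T.astype(np.float32)
           * sidecar["gain_uV_per_bit"])
    events = pd.read_csv(ind / "events.csv")
    units: list[SyntheticUnit] = []
    spikes_path = ind / "spikes.csv"
    if spikes_path.exists():
        tbl = pd.read_csv(spikes_path)
        for uid, grp in tbl.groupby("unit_id"):
            units.append(
                SyntheticUnit(
                    unit_id=int(uid),
                    spike_times_s=np.sort(grp["time_s"].to_numpy()),
                    cls=str(grp["cls"].iloc[0]),
                    locking_kappa=float("nan"),
                    preferred_phase=float("nan"),
                )
            )
    truth_path = ind / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticRecording(lfp, sidecar["fs"], events, units, truth, None)
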