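"""Stimulus schedules for sequential-flicker and standard visual stimulation.

A *sequential* stimulus splits the screen into ``n_sections`` checkerboard
sections (wedges or bars) and exposes exactly one section per screen refresh
cycle, cycling 0, 1, ..., N-1, 0, ... for the whole 2 s trial.  Each section is
therefore re-exposed at the *repeat frequency* ``refresh_hz / n_sections`` while
neighbouring sections are offset by one frame (``1000 / refresh_hz`` ms).
Schedules are abstract (a section index per frame), never rendered images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "SEQUENTIAL_KINDS",
    "STANDARD_KINDS",
    "StimulusSpec",
    "FrameSchedule",
    "build_sequential_schedule",
    "repeat_frequency",
    "section_phase_shift",
    "visual_angle_deg",
    "build_chirp_trace",
    "enumerate_stimulus_set",
    "round_reported",
    "schedule_to_frame",
    "schedule_to_csv",
    "spec_to_json",
    "spec_from_json",
]

SEQUENTIAL_KINDS = frozenset(
    {"wedge_top", "wedge_bottom", "horizontal_bars", "vertical_bars"}
)
STANDARD_KINDS = frozenset(
    {"checker", "chirp", "moving_bar", "sparse_noise", "gray"}
)

#: canonical section counts per sequential kind (wedges split the screen into 6,
#: bar stimuli into 7 or 14 strips)
_CANONICAL_SECTIONS = {
    "wedge_top": 6,
    "wedge_bottom": 6,
    "horizontal_bars": 7,
    "vertical_bars": 14,
}

#: screen refresh rates used for sequential stimulation
SEQUENTIAL_REFRESH_HZ = (144.0, 180.0, 240.0)


def round_reported(x: float, ndigits: int = 1) -> float:
    """Round half-up to ``ndigits`` decimals, as used for reported frequencies.

    Reported repeat frequencies are quoted to one decimal (10.3 / 12.9 / 17.1 Hz
    etc.); raw rational values are kept internally and only rounded for display.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StimulusSpec:
    """Parametric description of one visual stimulus condition.

    Parameters
    ----------
    kind:
        One of the sequential kinds (``wedge_top``, ``wedge_bottom``,
        ``horizontal_bars``, ``vertical_bars``) or a standard kind
        (``checker``, ``chirp``, ``moving_bar``, ``sparse_noise``, ``gray``).
    n_sections:
        Number of screen sections for sequential kinds (6, 7 or 14
        canonically); 1 for full-field stimuli.
    refresh_hz:
        Screen refresh rate; 144/180/240 Hz for sequential kinds, 120 Hz for
        the standard comparison stimuli.
    trial_duration_s, n_trials, iti_duration_s:
        Trial structure: 2 s stimulus alternated with 2 s gray, 50 trials.
    extra:
        Kind-specific parameters (moving-bar direction/width, checker square
        size, sparse-noise grid geometry, ...).
    """

    kind: str
    n_sections: int = 1
    refresh_hz: float = 120.0
    trial_duration_s: float = 2.0
    n_trials: int = 50
    iti_duration_s: float = 2.0
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in SEQUENTIAL_KINDS | STANDARD_KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.n_sections < 1:
            raise ValueError("n_sections must be a positive integer")
        if self.refresh_hz <= 0:
            raise ValueError("refresh_hz must be positive")
        if self.trial_duration_s <= 0 or self.iti_duration_s < 0:
            raise ValueError("trial/ITI durations must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be at least 1")

    @property
    def is_sequential(self) -> bool:
        return self.kind in SEQUENTIAL_KINDS

    @property
    def frame_duration_ms(self) -> float:
        return 1000.0 / self.refresh_hz


@dataclass(frozen=True)
class FrameSchedule:
    """Frame-accurate exposure timeline for one stimulus condition.

    ``frame_times_s`` are monotone frame onsets covering stimulus and gray
    (inter-trial) frames; ``active_section`` holds the exposed section index
    per frame (-1 during gray); ``trial_index`` maps each frame to the trial it
    belongs to (gray frames carry the index of the preceding trial, the leading
    gray carries -1).  Within a trial, section ``k`` is active on frames where
    ``frame_index_within_trial % n_sections == k`` and each trial restarts at
    section 0.
    """

    spec: StimulusSpec
    frame_times_s: np.ndarray
    active_section: np.ndarray
    trial_index: np.ndarray
    trial_onsets_s: np.ndarray
    section_polarity: np.ndarray  # 0 = black-leading checkerboard, 1 = white-leading

    @property
    def frame_duration_ms(self) -> float:
        return self.spec.frame_duration_ms

    @property
    def duration_s(self) -> float:
        return float(self.frame_times_s[-1] + self.spec.frame_duration_ms / 1000.0)

    @property
    def frames_per_trial(self) -> int:
        return int(np.floor(self.spec.trial_duration_s * self.spec.refresh_hz))

    def stim_windows(self) -> np.ndarray:
        """(n_trials, 2) array of [onset, offset] times of the stimulus epochs."""
        on = self.trial_onsets_s
        return np.column_stack([on, on + self.spec.trial_duration_s])


def build_sequential_schedule(spec: StimulusSpec) -> FrameSchedule:
    """Construct the frame schedule of a sequential stimulus.

    The schedule starts with one gray inter-trial period (so that every trial,
    including the first, has a defined pre-stimulus baseline), then alternates
    ``trial_duration_s`` of sequential exposure with ``iti_duration_s`` of gray
    for ``n_trials`` trials.  Sections alternate black/white checkerboard
    polarity, starting black.  A trial need not contain an integer number of
    section cycles; the partial last cycle is presented and the next trial
    restarts at section 0, making all trials identical.
    """
    if not spec.is_sequential:
        raise ValueError(
            f"stimulus kind {spec.kind!r} is not a sequential kind; expected one "
            f"of {sorted(SEQUENTIAL_KINDS)}"
        )
    dt = 1.0 / spec.refresh_hz
    n_stim = int(np.floor(spec.trial_duration_s * spec.refresh_hz))
    n_gray = int(np.round(spec.iti_duration_s * spec.refresh_hz))
    period_frames = n_stim + n_gray

    frames_per_block = n_gray + period_frames * spec.n_trials
    idx = np.arange(frames_per_block)
    times = idx * dt

    section = np.full(frames_per_block, -1, dtype=int)
    trial = np.full(frames_per_block, -1, dtype=int)
    onsets = np.empty(spec.n_trials)
    for t in range(spec.n_trials):
        start = n_gray + t * period_frames
        within = np.arange(n_stim)
        section[start : start + n_stim] = within % spec.n_sections
        trial[start : start + n_stim + n_gray] = t
        onsets[t] = times[start]

    polarity = np.arange(spec.n_sections) % 2  # black-leading first
    return FrameSchedule(
        spec=spec,
        frame_times_s=times,
        active_section=section,
        trial_index=trial,
        trial_onsets_s=onsets,
        section_polarity=polarity,
    )


def repeat_frequency(spec: StimulusSpec) -> float:
    """Rate at which one section is re-exposed: ``refresh_hz / n_sections`` Hz.

    Returns the exact rational value; use :func:`round_reported` (one decimal,
    half-up) when quoting it.
    """
    if not spec.is_sequential and spec.n_sections != 1:
        raise ValueError("repeat_frequency is defined for sequential stimuli")
    if spec.n_sections == 0:
        raise ValueError("n_sections must be non-zero")
    return spec.refresh_hz / spec.n_sections


def section_phase_shift(spec: StimulusSpec) -> float:
    """Exposure delay between neighbouring sections, in ms (one frame)."""
    if spec.refresh_hz <= 0:
        raise ValueError("refresh_hz must be positive")
    return 1000.0 / spec.refresh_hz


def visual_angle_deg(extent_cm: float, distance_cm: float) -> float:
    """Visual angle subtended by ``extent_cm`` at ``distance_cm`` from the eye.

    ``2 * arctan(extent / (2 * distance))`` in degrees; e.g. 2.6 cm at the
    15 cm viewing distance subtends ~10 degrees at screen centre.
    """
    if extent_cm < 0 or distance_cm <= 0:
        raise ValueError("extent must be >= 0 and distance > 0")
    return float(np.degrees(2.0 * np.arctan2(extent_cm / 2.0, distance_cm)))


# chirp segment layout: (duration_s, kind, params)
_CHIRP_SEGMENTS = (
    (2.2, "step", 0.0),     # black
    (3.3, "step", 1.0),     # white
    (3.3, "step", 0.0),     # black
    (2.2, "step", 0.5),     # gray
    (8.75, "fsweep", (0.5, 11.0)),   # full-contrast frequency sweep
    (8.75, "csweep", 0.4),           # 0..100% contrast sweep at 0.4 Hz
    (2.2, "step", 0.5),     # gray
)

CHIRP_TOTAL_S = float(sum(d for d, _, _ in _CHIRP_SEGMENTS))


def build_chirp_trace(refresh_hz: float) -> tuple[np.ndarray, np.ndarray]:
    """Full-field chirp intensity trace, sampled once per screen frame.

    Starting from gray, luminance steps (2.2 s black, 3.3 s white, 3.3 s black,
    2.2 s gray) are followed by a full-contrast frequency sweep 0.5 -> 11 Hz
    (8.75 s), a 0 -> 100% contrast sweep at 0.4 Hz (8.75 s), and 2.2 s gray.
    Intensity is in [0, 1] with gray = 0.5.

    Returns ``(times_s, intensity)``.
    """
    if refresh_hz <= 0:
        raise ValueError("refresh_hz must be positive")
    dt = 1.0 / refresh_hz
    n = int(np.floor(CHIRP_TOTAL_S * refresh_hz))
    t = np.arange(n) * dt
    y = np.full(n, 0.5)
    t0 = 0.0
    for dur, kind, par in _CHIRP_SEGMENTS:
        m = (t >= t0) & (t < t0 + dur)
        tt = t[m] - t0
        if kind == "step":
            y[m] = par
        elif kind == "fsweep":
            f0, f1 = par
            # linear chirp: instantaneous frequency f0 + (f1-f0) * tt / dur
            phase = 2 * np.pi * (f0 * tt + 0.5 * (f1 - f0) * tt**2 / dur)
            y[m] = 0.5 + 0.5 * np.sin(phase)
        elif kind == "csweep":
            contrast = tt / dur
            y[m] = 0.5 + 0.5 * contrast * np.sin(2 * np.pi * par * tt)
        t0 += dur
    return t, y


def enumerate_stimulus_set(
    include_standard: bool = True,
    n_trials: int = 50,
) -> list[StimulusSpec]:
    """The full stimulus battery: 12 sequential conditions plus standards.

    Sequential conditions are the 4 kinds x 3 refresh rates (144/180/240 Hz)
    with their canonical section counts; across them the repeat frequencies
    take exactly 9 distinct values, from ~10.29 Hz (14 sections at 144 Hz) to
    40 Hz (6 sections at 240 Hz) — both wedge kinds share one repeat frequency
    at each refresh rate.
    """
    specs: list[StimulusSpec] = []
    for kind in ("wedge_top", "wedge_bottom", "horizontal_bars", "vertical_bars"):
        for refresh in SEQUENTIAL_REFRESH_HZ:
            specs.append(
                StimulusSpec(
                    kind=kind,
                    n_sections=_CANONICAL_SECTIONS[kind],
                    refresh_hz=refresh,
                    n_trials=n_trials,
                )
            )
    if include_standard:
        specs.append(StimulusSpec("checker", refresh_hz=120.0, n_trials=n_trials,
                                  extra={"square_size_deg": 10.0}))
        specs.append(StimulusSpec("chirp", refresh_hz=120.0, n_trials=n_trials))
        for k, direction in enumerate(range(0, 360, 30)):
            specs.append(
                StimulusSpec(
                    "moving_bar",
                    refresh_hz=120.0,
                    n_trials=n_trials,
                    extra={"direction_deg": direction, "width_deg": 10.0,
                           "speed_deg_s": 90.0},
                )
            )
        specs.append(
            StimulusSpec(
                "sparse_noise",
                refresh_hz=120.0,
                n_trials=n_trials,
                extra={"grid_shape": (36, 22), "square_deg": 15.0,
                       "targets_per_frame": 2, "frame_ms": 100.0,
                       "repeats_per_position": 20},
            )
        )
    return specs


# ---------------------------------------------------------------------------
# serialisation

def schedule_to_frame(schedule: FrameSchedule) -> pd.DataFrame:
    """Schedule as a tidy table: frame_index, onset_s, section_index, trial_index."""
    return pd.DataFrame(
        {
            "frame_index": np.arange(len(schedule.frame_times_s)),
            "onset_s": schedule.frame_times_s,
            "section_index": schedule.active_section,
            "trial_index": schedule.trial_index,
        }
    )


def schedule_to_csv(schedule: FrameSchedule, path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def spec_to_json(spec: StimulusSpec, path=None) -> str:
    payload = json.dumps(asdict(spec), indent=2)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(payload)
    return payload


def spec_from_json(source: str) -> StimulusSpec:
    data = json.loads(source)
    return StimulusSpec(**data)
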