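"""Build the sequential stimulus battery and print its timing arithmetic.

A sequential stimulus splits the screen into N checkerboard sections, exposing
one section per screen refresh cycle.  Each section therefore repeats at
refresh_hz / N, and neighbouring sections are offset by one frame.
"""

from seqssvep.stimgen import (
    StimulusSpec,
    build_sequential_schedule,
    enumerate_stimulus_set,
    repeat_frequency,
    round_reported,
    section_phase_shift,
)

spec = StimulusSpec("vertical_bars", n_sections=14, refresh_hz=144.0, n_trials=50)
sched = build_sequential_schedule(spec)

print(f"{spec.kind}: {spec.n_sections} sections at {spec.refresh_hz:g} Hz refresh")
print(f"  repeat frequency : {round_reported(repeat_frequency(spec))} Hz "
      "(rate at which one section is re-exposed)")
print(f"  section phase shift: {round_reported(section_phase_shift(spec), 2)} ms "
      "(delay between neighbouring sections)")
print(f"  frames per 2 s trial: {sched.frames_per_trial}")
print(f"  schedule: {len(sched.frame_times_s)} frames over "
      f"{sched.duration_s:.0f} s ({spec.n_trials} trials + gray ITIs)")

seq = [s for s in enumerate_stimulus_set() if s.is_sequential]
freqs = sorted({round_reported(repeat_frequency(s)) for s in seq})
print(f"\nfull battery: {len(seq)} sequential conditions, "
      f"{len(freqs)} distinct repeat frequencies: {freqs} Hz")
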