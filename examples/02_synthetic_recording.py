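"""Generate a small synthetic Neuropixels-like recording with ground truth.

The generator produces 1/f-background LFP with a stimulus-locked SSVEP, an
injected high-frequency power increase on a known channel span, and phase-
locked spike trains — everything downstream analyses should later recover.
"""

import numpy as np

from seqssvep.stimgen import StimulusSpec, build_sequential_schedule
from seqssvep.synthgen import SyntheticConfig, generate_lfp, generate_spikes

spec = StimulusSpec("vertical_bars", n_sections=14, refresh_hz=144.0, n_trials=10)
schedule = build_sequential_schedule(spec)

config = SyntheticConfig(
    n_channels=32,
    hf_span_channels=(8, 23),  # 16 channels carry extra 100-190 Hz power
    hf_gain=4.0,               # band power x4 during stimulation
    locking_kappa=1.0,         # von Mises concentration of spike phases
    baseline_rate_hz=8.0,
    rng_seed=42,
)

rec = generate_lfp(config, schedule)
rec.units = generate_spikes(config, schedule, n_units=6)

print(f"LFP: {rec.lfp.shape[0]} channels x {rec.lfp.shape[1]} samples "
      f"at {rec.fs_lfp:g} Hz ({rec.duration_s:.0f} s)")
print(f"trials: {len(rec.events)} ({rec.events['label'].iloc[0]})")
print(f"truth: HF gain {rec.truth['hf_gain']} on channels "
      f"{rec.truth['hf_span_channels']}, band {rec.truth['hf_band']} Hz")
rates = [u.spike_times_s.size / rec.duration_s for u in rec.units]
print(f"units: {len(rec.units)}, mean rate {np.mean(rates):.1f} sp/s, "
      f"locking kappa {config.locking_kappa}")
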