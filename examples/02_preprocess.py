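"""Condition a drifting, noisy channel with the HRF low-pass + DCT detrend.

Builds one channel = slow half-cosine drift + band-limited oscillation +
white noise, applies the two-step conditioning chain, and reports how much
of the drift variance the detrend removes while the oscillation survives.
"""

import numpy as np

import nirsnet as nn

config = nn.CohortConfig(
    n_subjects=2,
    fs=13.33,
    duration=600.0,
    channel_labels=("CH01",),
    oscillators=(nn.OscillatorSpec(0.05, 0.5, 1.0),),
    noise_sd=0.5,
    drift_amplitude=3.0,
    seed=2,
)
rec = nn.generate_recording(config, 0, "near")

t = rec.times()
drift = 3.0 * np.cos(np.pi * t / 600.0)

clean = nn.preprocess(rec)  # HRF low-pass, then DCT detrend (128 s cutoff)

print(f"raw channel variance        : {rec.samples[0].var():.3f}")
print(f"drift variance (planted)    : {drift.var():.3f}")
print(f"conditioned channel variance: {clean.samples[0].var():.3f}")

# the drift itself is almost annihilated by the same chain
drift_only = rec.with_samples(drift[None, :])
residual = nn.preprocess(drift_only).samples[0]
print(f"drift surviving the chain   : {100 * residual.var() / drift.var():.3f}% of its variance")
print("\nThe detrend projects out DCT components slower than 128 s (drift), "
      "while the 0.05 Hz oscillation passes through nearly untouched.")
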