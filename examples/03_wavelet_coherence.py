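"""Wavelet phase coherence with AAFT surrogate validation on one pair.

Generates a 3-channel recording where CH01-CH02 share a strongly coupled
in-band source while CH03 is independent, then computes band WPCO over
0.01-0.1 Hz for every pair with a 50-surrogate significance test.
"""

import nirsnet as nn

config = nn.CohortConfig(
    n_subjects=2,
    fs=4.0,
    duration=600.0,
    channel_labels=("CH01", "CH02", "CH03"),
    oscillators=(nn.OscillatorSpec(0.05, 0.6, 1.0),),
    couplings={
        "near": (nn.CouplingSpec(("CH01", "CH02"), strength=0.9,
                                 phase_lag=0.5, band=(0.02, 0.08)),),
    },
    noise_sd=0.4,
    drift_amplitude=0.0,
    seed=21,
)
rec = nn.generate_recording(config, 0, "near")

pairs = nn.pair_matrix(rec, m=50, seed=0)

print("pair        band WPCO   surrogate mean+2SD   margin    valid")
for p in pairs:
    thresh = p.surrogate_mean + 2 * p.surrogate_sd
    print(f"{p.channels[0]}-{p.channels[1]}   {p.band_wpco:9.3f}   "
          f"{thresh:18.3f}   {p.margin:+7.3f}   {p.valid}")

print("\nOnly the planted CH01-CH02 coupling beats its surrogate threshold: "
      "raw low-frequency WPCO is inflated for *any* pair (few cycles in a "
      "finite segment), and the AAFT ensemble calibrates that away.")
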