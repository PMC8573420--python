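"""Synthetic cohorts with known connectivity and behavioral structure.

Real resting-state ΔHbO recordings superpose band-limited physiological
rhythms (cardiac, respiratory, myogenic, neurogenic, endothelial), slow
drift and broadband noise; some channel pairs share an oscillatory source
and are therefore phase-coherent. The generator emulates exactly this:

* each oscillator is white noise band-pass limited (by spectral masking)
  to ``center ± fractional_bandwidth * center``, giving realistic
  non-sinusoidal rhythms whose spectral mass lies entirely in the target
  interval;
* a coupling mixes a *shared* in-band source (phase-shifted by a fixed
  lag for the second channel) with weight ``kappa`` against *independent*
  in-band sources with weight ``1 - kappa``, so expected phase coherence
  grows monotonically with ``kappa``;
* drift is a half-cosine with period longer than the recording (exercising
  DCT detrending), noise is i.i.d. Gaussian;
* behavioral transfer performance is linear in the subject's coupling
  strength, ``perf = intercept + slope * kappa + N(0, residual_sd)``, so
  the planted population correlation with kappa is
  ``slope * sd(kappa) / sd(perf)``.

All randomness is drawn from named counter-based substreams of one root
seed keyed by (stream, subject, condition, channel, ...), so every
recording is reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import CONDITIONS, DEFAULT_CHANNELS, Recording
from .wavelet import ANALYSIS_BAND, PHYSIOLOGICAL_BANDS

__all__ = [
    "OscillatorSpec",
    "CouplingSpec",
    "BehavioralModel",
    "CohortConfig",
    "BehavioralRecord",
    "CohortResult",
    "default_oscillators",
    "generate_recording",
    "generate_cohort",
]

# Substream tags (SeedSequence entropy words).
_STREAM = {"noise": 1, "osc": 2, "shared": 3, "kappa": 4, "behav": 5, "prior": 6}
_COND_CODE = {c: i for i, c in enumerate(CONDITIONS)}


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


@dataclass(frozen=True)
class OscillatorSpec:
    """One band-limited physiological rhythm.

    ``center_frequency`` in Hz, ``fractional_bandwidth`` in (0, 1] so the
    realized band is ``center * (1 ± fractional_bandwidth)``, ``amplitude``
    is the target RMS in signal units. ``interval`` optionally names the
    physiological interval (I–VI) the rhythm belongs to, in which case the
    center must lie inside it.
    """

    center_frequency: float
    fractional_bandwidth: float = 0.3
    amplitude: float = 1.0
    interval: str | None = None

    def __post_init__(self) -> None:
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if not 0 < self.fractional_bandwidth <= 1:
            raise ValueError("fractional_bandwidth must lie in (0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.interval is not None:
            lo, hi = PHYSIOLOGICAL_BANDS[self.interval]
            if not lo <= self.center_frequency <= hi:
                raise ValueError(
                    f"center {self.center_frequency} Hz outside interval "
                    f"{self.interval} ({lo}-{hi} Hz)"
                )

    @property
    def band(self) -> tuple[float, float]:
        half = self.fractional_bandwidth * self.center_frequency
        return (self.center_frequency - half, self.center_frequency + half)


@dataclass(frozen=True)
class CouplingSpec:
    """Planted phase coupling between one channel pair in one band."""

    channel_pair: tuple[str, str]
    strength: float  # kappa in [0, 1]
    phase_lag: float = 0.0  # radians
    band: tuple[float, float] = (0.02, 0.08)

    def __post_init__(self) -> None:
        a, b = self.channel_pair
        if a == b:
            raise ValueError("coupling requires two distinct channels")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")
        lo, hi = self.band
        if not (ANALYSIS_BAND[0] <= lo < hi <= ANALYSIS_BAND[1]):
            raise ValueError(
                f"coupling band {self.band} must sit inside the analysis band "
                f"{ANALYSIS_BAND}"
            )


@dataclass(frozen=True)
class BehavioralModel:
    """Linear link from coupling strength to transfer performance."""

    intercept: float = 50.0
    slope: float = 30.0
    residual_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")


def default_oscillators() -> tuple[OscillatorSpec, ...]:
    """One rhythm per physiological interval.

    Center frequencies sit near the middle of each interval; amplitudes
    follow the usual hemodynamic profile where low-frequency (myogenic to
    endothelial) oscillations dominate cardiac and respiratory pulsations
    in ΔHbO.
    """
    return (
        OscillatorSpec(1.1, 0.2, 0.4, interval="I"),  # cardiac
        OscillatorSpec(0.25, 0.3, 0.3, interval="II"),  # respiration
        OscillatorSpec(0.09, 0.3, 0.8, interval="III"),  # myogenic
        OscillatorSpec(0.032, 0.4, 1.0, interval="IV"),  # neurogenic
        OscillatorSpec(0.014, 0.3, 0.7, interval="V"),  # endothelial metabolic
        OscillatorSpec(0.005, 0.5, 0.6, interval="VI"),  # endothelial
    )


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the reference acquisition: 31 subjects, 13.33 Hz
    sampling, 10-minute resting segments, 22 channels.
    """

    n_subjects: int = 31
    fs: float = 13.33
    duration: float = 600.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    oscillators: tuple[OscillatorSpec, ...] = field(default_factory=default_oscillators)
    couplings: dict[str, tuple[CouplingSpec, ...]] = field(default_factory=dict)
    drift_amplitude: float = 2.0
    noise_sd: float = 0.5
    behavioral: BehavioralModel = field(default_factory=BehavioralModel)
    kappa_range: tuple[float, float] = (0.2, 1.0)
    conditions: tuple[str, ...] = ("near", "far")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        for cond in self.couplings:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in couplings")
        for cond in self.conditions:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        lo, hi = self.kappa_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("kappa_range must satisfy 0 <= lo <= hi <= 1")
        centers = [o.center_frequency for o in self.oscillators]
        for cs in self.couplings.values():
            centers.extend((c.band[0] + c.band[1]) / 2 for c in cs)
        if centers and self.duration < 2.0 / min(centers):
            raise ValueError(
                f"duration {self.duration:g} s holds fewer than 2 cycles of the "
                f"slowest rhythm ({min(centers):g} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass(frozen=True)
class BehavioralRecord:
    """Per-subject behavioral scores."""

    subject_id: str
    prior_score: float
    performance_near: float
    performance_far: float

    def __post_init__(self) -> None:
        for v in (self.prior_score, self.performance_near, self.performance_far):
            if not np.isfinite(v):
                raise ValueError("behavioral scores must be finite")


def _band_spectrum(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Random complex half-spectrum supported on ``band`` (DC excluded)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not mask.any():
        raise ValueError(f"band {band} contains no Fourier bin at n={n}, fs={fs}")
    c = np.zeros(freqs.size, dtype=complex)
    k = int(mask.sum())
    c[mask] = rng.standard_normal(k) + 1j * rng.standard_normal(k)
    return c


def _realize(c: np.ndarray, n: int, phase_lag: float = 0.0) -> np.ndarray:
    """Real series from a half-spectrum, all components shifted by the lag."""
    x = np.fft.irfft(c * np.exp(-1j * phase_lag), n)
    rms = x.std()
    return x / rms if rms > 0 else x


def generate_recording(
    config: CohortConfig,
    subject_index: int,
    condition: str,
    kappa_scale: float = 1.0,
) -> Recording:
    """One subject's recording under one condition.

    Each channel is the sum of the configured oscillators, Gaussian noise
    and slow drift. For channels named in a coupling whose band overlaps an
    oscillator's band, that oscillator is realized as the
    ``kappa``-weighted mix of the shared pair source and an independent
    source; ``kappa_scale`` (the per-subject coupling modulation drawn by
    :func:`generate_cohort`) multiplies the spec's strength.

    Deterministic given ``(config.seed, subject_index, condition)``.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if not 0 <= subject_index < config.n_subjects:
        raise ValueError("subject_index out of range")
    n = config.n_samples
    t = np.arange(n) / config.fs
    cond = _COND_CODE[condition]
    couplings = config.couplings.get(condition, ())
    drift = config.drift_amplitude * np.cos(np.pi * t / config.duration)

    # Pre-realize shared sources, one per coupling: (plain, lagged) copies.
    shared: list[tuple[np.ndarray, np.ndarray]] = []
    for ci, cp in enumerate(couplings):
        rng = _rng(config.seed, _STREAM["shared"], subject_index, cond, ci)
        c = _band_spectrum(rng, n, config.fs, cp.band)
        shared.append((_realize(c, n), _realize(c, n, cp.phase_lag)))

    samples = np.empty((len(config.channel_labels), n))
    for ch_idx, label in enumerate(config.channel_labels):
        rng_noise = _rng(config.seed, _STREAM["noise"], subject_index, cond, ch_idx)
        x = (
            rng_noise.standard_normal(n) * config.noise_sd
            if config.noise_sd > 0
            else np.zeros(n)
        )
        x = x + drift
        for oi, osc in enumerate(config.oscillators):
            if osc.amplitude == 0:
                continue
            rng_o = _rng(
                config.seed, _STREAM["osc"], subject_index, cond, ch_idx, oi
            )
            lo_o, hi_o = osc.band
            coupling = next(
                (
                    (ci, cp)
                    for ci, cp in enumerate(couplings)
                    if label in cp.channel_pair
                    and cp.band[0] < hi_o
                    and cp.band[1] > lo_o
                ),
                None,
            )
            if coupling is None:
                comp = _realize(_band_spectrum(rng_o, n, config.fs, osc.band), n)
            else:
                ci, cp = coupling
                kappa = float(np.clip(cp.strength * kappa_scale, 0.0, 1.0))
                side = cp.channel_pair.index(label)
                s_shared = shared[ci][side]
                s_own = _realize(_band_spectrum(rng_o, n, config.fs, cp.band), n)
                comp = kappa * s_shared + (1.0 - kappa) * s_own
                rms = comp.std()
                if rms > 0:
                    comp = comp / rms
            x = x + osc.amplitude * comp
        samples[ch_idx] = x

    return Recording(
        subject_id=f"S{subject_index + 1:02d}",
        condition=condition,
        fs=config.fs,
        channel_labels=config.channel_labels,
        samples=samples,
        meta={"kappa_scale": kappa_scale},
    )


@dataclass
class CohortResult:
    """Recordings per condition, behavioral table and ground-truth kappas."""

    recordings: dict[str, list[Recording]]
    behavior: pd.DataFrame
    kappas: pd.DataFrame


def subject_kappas(config: CohortConfig) -> pd.DataFrame:
    """Per-(subject, condition) coupling modulation, reproducible from seed."""
    lo, hi = config.kappa_range
    rows = []
    for s in range(config.n_subjects):
        for cond in config.conditions:
            rng = _rng(config.seed, _STREAM["kappa"], s, _COND_CODE[cond])
            rows.append(
                {
                    "subject_id": f"S{s + 1:02d}",
                    "condition": cond,
                    "kappa": float(rng.uniform(lo, hi)),
                }
            )
    return pd.DataFrame(rows)


def generate_behavior(config: CohortConfig) -> pd.DataFrame:
    """Behavioral table: prior score plus per-condition transfer performance.

    Performance is ``intercept + slope * kappa + N(0, residual_sd)`` with
    the subject's condition-specific kappa; the prior score is a standard
    normal draw (the concept-sorting composite is not modeled further).
    """
    kap = subject_kappas(config).set_index(["subject_id", "condition"])["kappa"]
    model = config.behavioral
    rows = []
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        perf = {"near": model.intercept, "far": model.intercept}
        for cond in ("near", "far"):
            if cond in config.conditions:
                rng = _rng(config.seed, _STREAM["behav"], s, _COND_CODE[cond])
                perf[cond] = (
                    model.intercept
                    + model.slope * kap[(sid, cond)]
                    + rng.standard_normal() * model.residual_sd
                )
        prior_rng = _rng(config.seed, _STREAM["prior"], s)
        rec = BehavioralRecord(
            subject_id=sid,
            prior_score=float(prior_rng.standard_normal()),
            performance_near=float(perf["near"]),
            performance_far=float(perf["far"]),
        )
        rows.append(rec.__dict__)
    return pd.DataFrame(rows)


def generate_cohort(
    config: CohortConfig, include_recordings: bool = True
) -> CohortResult:
    """Generate the full cohort: recordings, behavior, ground-truth kappas."""
    kappas = subject_kappas(config)
    behavior = generate_behavior(config)
    recordings: dict[str, list[Recording]] = {}
    if include_recordings:
        kap = kappas.set_index(["subject_id", "condition"])["kappa"]
        for cond in config.conditions:
            recordings[cond] = [
                generate_recording(
                    config, s, cond, kappa_scale=float(kap[(f"S{s + 1:02d}", cond)])
                )
                for s in range(config.n_subjects)
            ]
    return CohortResult(recordings=recordings, behavior=behavior, kappas=kappas)
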