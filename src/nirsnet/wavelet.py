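"""Complex Morlet continuous wavelet transform and band bookkeeping.

The decomposition writes each channel as complex coefficients
``x(w_k, t_n) = a + ib`` on a log-spaced frequency grid. From those the
instantaneous phase is the four-quadrant angle of ``a + ib`` and the wavelet
amplitude at a frequency is the time average of the modulus
``(1/T) sum_n sqrt(a^2 + b^2)``.

The mother wavelet is the complex Morlet with dimensionless bandwidth
parameter ``B = 2`` and center-frequency parameter ``fc = 0.5``:

    psi(t) = (pi B)^(-1/2) exp(2 pi i fc t) exp(-t^2 / B)

An analysis frequency ``f`` (Hz) maps to scale ``s = fc * fs / f`` samples
(the standard center-frequency relation). The transform is evaluated by FFT
convolution with L1 normalization, i.e. the kernel's frequency response
peaks at exactly 1, so a unit complex exponential at a grid frequency yields
unit-modulus coefficients and amplitudes are comparable across scales (a
real sinusoid of amplitude A yields modulus A/2, since the analytic wavelet
responds only to the positive-frequency half).

Hemodynamic oscillations are conventionally partitioned into six
physiological intervals spanning 0.0005–2 Hz (cardiac, respiratory,
myogenic, neurogenic, endothelial-metabolic, endothelial); connectivity
analysis focuses on the 0.01–0.1 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import next_fast_len

__all__ = [
    "WaveletSpec",
    "Decomposition",
    "BandSet",
    "PHYSIOLOGICAL_BANDS",
    "ANALYSIS_BAND",
    "cwt_morlet",
    "phase",
    "amplitude",
    "band_average",
    "coi_mask",
    "export_modulus",
]

#: Six physiological frequency intervals (Hz) of spontaneous hemodynamic
#: oscillations, highest first: cardiac, respiratory, myogenic, neurogenic,
#: endothelial metabolic, endothelial.
PHYSIOLOGICAL_BANDS: dict[str, tuple[float, float]] = {
    "I": (0.6, 2.0),
    "II": (0.145, 0.6),
    "III": (0.052, 0.145),
    "IV": (0.021, 0.052),
    "V": (0.0095, 0.021),
    "VI": (0.0005, 0.0095),
}

BAND_ACTIVITY: dict[str, str] = {
    "I": "cardiac",
    "II": "respiration",
    "III": "myogenic",
    "IV": "neurogenic",
    "V": "endothelial metabolic",
    "VI": "endothelial",
}

#: Band used for connectivity analysis (covers neurogenic activity and the
#: stimulus presentation frequencies).
ANALYSIS_BAND: tuple[float, float] = (0.01, 0.1)


@dataclass(frozen=True)
class BandSet:
    """The named physiological intervals plus the analysis band."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PHYSIOLOGICAL_BANDS)
    )
    analysis_band: tuple[float, float] = ANALYSIS_BAND

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not 0 <= lo < hi:
                raise ValueError(f"band {name}: invalid interval ({lo}, {hi})")
        lo, hi = self.analysis_band
        if not (0.0005 <= lo < hi <= 2.0):
            raise ValueError("analysis band must sit inside 0.0005-2 Hz")

    def contiguous(self) -> bool:
        """True when the named intervals tile their range without gaps."""
        edges = sorted(self.bands.values())
        return all(
            np.isclose(edges[i][1], edges[i + 1][0]) for i in range(len(edges) - 1)
        )


@dataclass(frozen=True)
class WaveletSpec:
    """Complex Morlet shape parameters and the analysis frequency grid.

    ``bandwidth`` and ``center`` are the dimensionless Morlet shape
    parameters (2 and 0.5 by default). The grid is log-spaced from ``fmin``
    to ``fmax`` with ``voices_per_octave`` points per frequency doubling,
    which gives uniform relative resolution across all six physiological
    intervals.
    """

    bandwidth: float = 2.0
    center: float = 0.5
    fmin: float = 0.005
    fmax: float = 2.0
    voices_per_octave: int = 12

    def __post_init__(self) -> None:
        if self.bandwidth <= 0 or self.center <= 0:
            raise ValueError("bandwidth and center parameters must be positive")
        if not 0 < self.fmin < self.fmax:
            raise ValueError("need 0 < fmin < fmax")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")

    def frequencies(self) -> np.ndarray:
        """Strictly increasing log-spaced grid from fmin to fmax (Hz)."""
        n_oct = np.log2(self.fmax / self.fmin)
        k = np.arange(int(np.floor(n_oct * self.voices_per_octave)) + 1)
        grid = self.fmin * 2.0 ** (k / self.voices_per_octave)
        if grid[-1] < self.fmax * (1 - 1e-12):
            grid = np.append(grid, self.fmax)
        return grid

    def restrict(self, band: tuple[float, float]) -> "WaveletSpec":
        """Spec whose grid keeps only frequencies strictly inside ``band``."""
        lo, hi = band
        grid = self.frequencies()
        inside = grid[(grid > lo) & (grid < hi)]
        if inside.size == 0:
            raise ValueError(f"no grid frequency strictly inside band {band}")
        return replace(self, fmin=float(inside[0]), fmax=float(inside[-1]))


@dataclass
class Decomposition:
    """Complex wavelet coefficients of one channel on (frequency x time)."""

    coefficients: np.ndarray  # complex, shape (n_freqs, n_samples)
    frequencies: np.ndarray  # Hz, strictly increasing
    fs: float

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.coefficients.shape[0] != self.frequencies.size:
            raise ValueError("coefficient rows must match the frequency grid")
        if not np.isfinite(self.coefficients).all():
            raise ValueError("coefficients must be finite")


def _morlet_kernel_ft(
    omega: np.ndarray, scales: np.ndarray, bandwidth: float, center: float
) -> np.ndarray:
    """Frequency response of the L1-normalized Morlet bank.

    ``omega`` is angular frequency in rad/sample; rows are scales. The
    response of the mother wavelet is ``exp(-B (w - w0)^2 / 4)`` with
    ``w0 = 2 pi fc``; at scale ``s`` the argument is ``s * omega``.
    """
    w0 = 2.0 * np.pi * center
    arg = scales[:, None] * omega[None, :] - w0
    return np.exp(-bandwidth * arg**2 / 4.0)


def cwt_morlet(
    signal: np.ndarray,
    spec: WaveletSpec | None = None,
    fs: float = 13.33,
    frequencies: np.ndarray | None = None,
    boundary: str = "periodic",
) -> Decomposition:
    """Continuous wavelet transform of a 1-D series.

    Parameters
    ----------
    signal
        Real (or complex) 1-D series.
    spec
        Morlet shape and default grid; defaults to :class:`WaveletSpec`.
    fs
        Sampling rate in Hz.
    frequencies
        Optional explicit grid (Hz) overriding ``spec``'s.
    boundary
        ``"periodic"`` (default) evaluates the convolution circularly on
        the series' own FFT grid: coefficients near the edges mix the two
        ends, but a phase relation between two channels is preserved
        exactly (no spectral leakage across frequency zero). ``"zero"``
        pads past both edges instead, attenuating edge coefficients.

    Returns
    -------
    Decomposition
        Coefficients of shape ``(len(frequencies), len(signal))``. The
        transform is linear in the input; edge (cone-of-influence) samples
        are retained either way.

    Raises
    ------
    ValueError
        If a grid frequency is at or above Nyquist, or the signal holds
        fewer than two cycles of the lowest grid frequency.
    """
    spec = spec or WaveletSpec()
    x = np.asarray(signal)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    n = x.size
    freqs = spec.frequencies() if frequencies is None else np.asarray(frequencies, float)
    if not (np.diff(freqs) > 0).all():
        raise ValueError("frequency grid must be strictly increasing")
    if freqs[-1] >= fs / 2:
        raise ValueError(
            f"grid frequency {freqs[-1]:g} Hz >= Nyquist ({fs / 2:g} Hz)"
        )
    if freqs[0] <= 0:
        raise ValueError("grid frequencies must be positive")
    if n / fs < 2.0 / freqs[0]:
        raise ValueError(
            f"signal holds {n / fs * freqs[0]:.2f} cycles of {freqs[0]:g} Hz; "
            "need at least 2"
        )

    scales = spec.center * fs / freqs  # samples
    if boundary == "periodic":
        nfft = n
    elif boundary == "zero":
        # Pad past the widest wavelet (4 sigma each side) to kill wrap-around.
        sigma_max = scales.max() * np.sqrt(spec.bandwidth / 2.0)
        nfft = next_fast_len(n + int(np.ceil(8.0 * sigma_max)))
    else:
        raise ValueError("boundary must be 'periodic' or 'zero'")
    X = np.fft.fft(x, nfft)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft)
    H = _morlet_kernel_ft(omega, scales, spec.bandwidth, spec.center)
    coeff = np.fft.ifft(X[None, :] * H, axis=1)[:, :n]
    return Decomposition(coefficients=coeff, frequencies=freqs, fs=fs)


def phase(d: Decomposition) -> np.ndarray:
    """Instantaneous phase in (-pi, pi], the four-quadrant angle of a + ib.

    Cells with zero modulus have undefined phase and are flagged NaN.
    """
    ph = np.angle(d.coefficients)
    ph = np.where(np.abs(d.coefficients) == 0, np.nan, ph)
    return ph


def coi_mask(d: Decomposition) -> np.ndarray:
    """Cone-of-influence mask, True where a coefficient is edge-affected.

    A sample is inside the cone when it lies within one Gaussian-envelope
    e-folding time ``s * sqrt(B)`` of either series edge (wider at lower
    frequencies).
    """
    spec = WaveletSpec()
    scales = spec.center * d.fs / d.frequencies
    radius = scales * np.sqrt(spec.bandwidth)
    n = d.coefficients.shape[1]
    t = np.arange(n)
    dist = np.minimum(t, n - 1 - t)
    return dist[None, :] < radius[:, None]


def amplitude(d: Decomposition, exclude_coi: bool = False) -> np.ndarray:
    """Time-averaged wavelet amplitude per frequency.

    ``|x_k| = (1/T) sum_n sqrt(a_{k,n}^2 + b_{k,n}^2)`` with T the number of
    samples — the mean instantaneous modulus, nonnegative by construction.
    Edge (cone-of-influence) samples are included by default; with
    ``exclude_coi`` the average runs over interior samples only.
    """
    if d.coefficients.shape[1] == 0:
        raise ValueError("empty series has no amplitude")
    mod = np.abs(d.coefficients)
    if not exclude_coi:
        return mod.mean(axis=1)
    inside = ~coi_mask(d)
    counts = inside.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("cone of influence covers the whole series at some scale")
    return (mod * inside).sum(axis=1) / counts


def export_modulus(d: Decomposition, path) -> None:
    """Write the (frequency x time) modulus as a compressed array container
    with a JSON header alongside (grid and sampling rate)."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(path, modulus=np.abs(d.coefficients))
    header = {"frequencies_hz": d.frequencies.tolist(), "fs_hz": d.fs}
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def band_average(
    values: np.ndarray, frequencies: np.ndarray, band: tuple[float, float]
) -> float:
    """Arithmetic mean of per-frequency values strictly inside ``band``."""
    values = np.asarray(values)
    frequencies = np.asarray(frequencies, dtype=float)
    lo, hi = band
    mask = (frequencies > lo) & (frequencies < hi)
    if not mask.any():
        raise ValueError(f"no grid frequency strictly inside band ({lo}, {hi})")
    return float(values[..., mask].mean(axis=-1))
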