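"""Signal conditioning for ΔHbO recordings.

Two steps, composable in either order (default: low-pass first):

* :func:`hrf_lowpass` — convolution with a canonical double-gamma
  hemodynamic response function sampled at the recording rate and
  normalized to unit sum, which smooths measurement noise while preserving
  the DC level exactly.
* :func:`dct_detrend` — a high-pass projection that removes the DCT-II
  basis functions whose period exceeds a cutoff (128 s by default,
  including the constant term), the standard discrete-cosine detrending
  used for slow drift in hemodynamic time series.

Both operations preserve channel count, labels and sampling rate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dct, idct
from scipy.signal import fftconvolve
from scipy.stats import gamma as gamma_dist

from .recording import Recording

__all__ = [
    "PreprocessConfig",
    "hrf_kernel",
    "hrf_lowpass",
    "dct_detrend",
    "preprocess",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the conditioning chain.

    ``order`` lists the steps to apply, in order. ``dct_cutoff_s`` is the
    detrending cutoff period in seconds.
    """

    order: tuple[str, ...] = ("lowpass", "detrend")
    dct_cutoff_s: float = 128.0
    apply_hrf: bool = True

    def __post_init__(self) -> None:
        bad = set(self.order) - {"lowpass", "detrend"}
        if bad:
            raise ValueError(f"unknown preprocessing steps: {sorted(bad)}")


def hrf_kernel(
    fs: float,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    ratio: float = 6.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``fs``, normalized to unit sum.

    The conventional shape: a gamma response peaking at 6 s minus a gamma
    undershoot peaking at 16 s scaled by 1/6, with 32 s of support. Unit
    dispersion, so the gamma shape parameters equal the peak times.
    """
    t = np.arange(int(round(length_s * fs))) / fs
    h = gamma_dist.pdf(t, a=peak_s) - gamma_dist.pdf(t, a=undershoot_s) / ratio
    return h / h.sum()


def hrf_lowpass(rec: Recording, **kernel_kwargs) -> Recording:
    """Smooth each channel by convolution with the canonical HRF kernel.

    The convolution is one-sided (output at t mixes samples at and before
    t, like the hemodynamic system itself); the left edge is reflection-
    padded by one kernel length so there is no startup transient. A unit
    impulse maps to the normalized kernel starting at the impulse location,
    and a constant channel is returned unchanged (unit-sum kernel).
    """
    k = hrf_kernel(rec.fs, **kernel_kwargs)
    L = k.size
    if rec.n_samples < L:
        raise ValueError(
            f"recording ({rec.n_samples} samples) shorter than HRF kernel ({L})"
        )
    padded = np.pad(rec.samples, ((0, 0), (L, 0)), mode="reflect")
    full = fftconvolve(padded, k[None, :], mode="full", axes=1)
    out = full[:, L : L + rec.n_samples]
    logger.debug("hrf_lowpass: kernel %d taps at fs=%g", L, rec.fs)
    return rec.with_samples(out)


def dct_detrend(rec: Recording, cutoff_period: float = 128.0) -> Recording:
    """Project out slow DCT-II components (period > ``cutoff_period``).

    DCT basis function ``k`` over ``N`` samples has period ``2N/(k fs)``
    seconds; every component with period strictly greater than the cutoff,
    including the constant term ``k = 0``, is removed. The result is a
    linear idempotent projection and each output channel is zero-mean.

    If the cutoff exceeds the recording length only the mean is removed and
    a warning is emitted.
    """
    if not cutoff_period > 2.0 / rec.fs:
        raise ValueError("cutoff_period must exceed two samples (2/fs)")
    n = rec.n_samples
    coeff = dct(rec.samples, type=2, norm="ortho", axis=1)
    if cutoff_period > rec.duration:
        warnings.warn(
            f"DCT cutoff ({cutoff_period:g} s) exceeds recording length "
            f"({rec.duration:g} s); removing only the mean",
            stacklevel=2,
        )
        remove = np.zeros(n, dtype=bool)
        remove[0] = True
    else:
        k = np.arange(n)
        period = np.divide(2.0 * n, k * rec.fs, out=np.full(n, np.inf), where=k > 0)
        remove = period > cutoff_period
        remove[0] = True
    coeff[:, remove] = 0.0
    out = idct(coeff, type=2, norm="ortho", axis=1)
    logger.debug(
        "dct_detrend: removed %d/%d DCT components (cutoff %g s)",
        int(remove.sum()),
        n,
        cutoff_period,
    )
    return rec.with_samples(out)


def preprocess(rec: Recording, config: PreprocessConfig | None = None) -> Recording:
    """Apply the conditioning chain (HRF low-pass, DCT detrend) to ``rec``."""
    config = config or PreprocessConfig()
    out = rec
    for step in config.order:
        if step == "lowpass":
            if config.apply_hrf:
                out = hrf_lowpass(out)
                logger.info("applied HRF low-pass to %s/%s", rec.subject_id, rec.condition)
        else:
            out = dct_detrend(out, cutoff_period=config.dct_cutoff_s)
            logger.info(
                "applied DCT detrend (cutoff %g s) to %s/%s",
                config.dct_cutoff_s,
                rec.subject_id,
                rec.condition,
            )
    return out
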