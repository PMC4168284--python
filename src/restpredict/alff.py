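"""Amplitude of low-frequency fluctuation (ALFF).

ALFF summarises the strength of a voxel's spontaneous slow activity: the
series is taken to the frequency domain with an FFT, the square-root power
spectrum is averaged over the low-frequency band (0.01-0.08 Hz by default),
and each voxel's value is finally divided by the global mean so that maps are
comparable across subjects.

Scaling convention: the one-sided power at bin k is

    P_k = c_k |X_k|^2 / T,   c_k = 2 except for DC and (even T) Nyquist,

with ``X = rfft(x)``.  Under this convention ``sum_k P_k`` equals the
time-domain energy ``sum_t x_t^2`` (Parseval), and ALFF is the mean of
``sqrt(P_k)`` over the bins whose frequency lies inside the band, both edges
inclusive.  The global-mean normalisation cancels any constant rescaling of
the spectrum, so downstream results do not depend on this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class ALFFMap:
    """Per-voxel ALFF values for one subject/session.

    Attributes
    ----------
    values : ndarray, shape (V,)
        Non-negative amplitudes.
    normalized : bool
        Whether the map has been divided by its global mean.
    band : tuple of float
        Frequency band (Hz) the amplitudes were averaged over.
    """

    values: np.ndarray
    normalized: bool
    band: tuple[float, float]


def band_bins(n_timepoints: int, band: tuple[float, float], tr_seconds: float) -> np.ndarray:
    """Indices of rFFT bins whose frequency lies in [low, high], inclusive."""
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    low, high = band
    return np.flatnonzero((freqs >= low - 1e-12) & (freqs <= high + 1e-12))


def compute_alff(
    ts: np.ndarray, band: tuple[float, float] = (0.01, 0.08), tr_seconds: float = 2.0
) -> ALFFMap:
    """Unnormalised ALFF of every column of ``ts``.

    Parameters
    ----------
    ts : ndarray, shape (T, V)
    band : (low_hz, high_hz)
        Band edges, inclusive on both sides.
    tr_seconds : float
        Sampling interval.

    Raises
    ------
    ValueError
        If no FFT bin falls inside the band (the message names the minimum
        run length that would place a bin there).
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    n_t = ts.shape[0]
    if n_t < 2:
        raise ValueError("need at least 2 time points")
    low, high = band
    nyq = 0.5 / tr_seconds
    if not (0.0 < low < high <= nyq + 1e-12):
        raise ValueError(f"band {band} invalid for Nyquist {nyq} Hz")
    bins = band_bins(n_t, band, tr_seconds)
    if bins.size == 0:
        t_min = int(np.ceil(1.0 / (high * tr_seconds)))
        raise ValueError(
            f"no FFT bin inside [{low}, {high}] Hz for T={n_t}, TR={tr_seconds}s; "
            f"need T >= {t_min} for the first in-band bin"
        )
    spec = np.fft.rfft(ts, axis=0)
    scale = np.full(spec.shape[0], 2.0)
    scale[0] = 1.0
    if n_t % 2 == 0:
        scale[-1] = 1.0
    power = scale[:, None] * np.abs(spec) ** 2 / n_t
    values = np.sqrt(power[bins]).mean(axis=0)
    return ALFFMap(values=values, normalized=False, band=(low, high))


def normalize_global(alff_map: ALFFMap, mask: np.ndarray | None = None) -> ALFFMap:
    """Divide by the global (or in-mask) mean ALFF, giving mean 1 over the mask."""
    values = alff_map.values
    pool = values if mask is None else values[np.asarray(mask)]
    mean = pool.mean()
    if not mean > 0:
        raise ValueError("global mean ALFF is zero; cannot normalise an all-zero map")
    return replace(alff_map, values=values / mean, normalized=True)
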