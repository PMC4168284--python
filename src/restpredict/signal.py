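"""Temporal conditioning of BOLD-like time series.

Resting-state pipelines condition every voxel (and nuisance) series the same
way before feature extraction: remove the linear scanner drift, then restrict
the series to the low-frequency band (0.01-0.08 Hz by default) where
spontaneous BOLD fluctuations live.  Filtering is done with a zero-phase
Chebyshev type-I band-pass so that the temporal alignment of the series is
preserved (forward-backward application squares the magnitude response and
cancels the phase response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal


class FilterDesignError(ValueError):
    """Raised when the requested band-pass filter cannot be realised."""


@dataclass(frozen=True)
class BandpassSpec:
    """Chebyshev type-I band-pass specification.

    Parameters
    ----------
    low_hz, high_hz : float
        Pass-band edges in Hz; must satisfy 0 < low < high < Nyquist.
    order : int
        Design order of the analogue prototype.  The effective order is
        doubled by the zero-phase forward-backward application.
    ripple_db : float
        Maximum pass-band ripple in dB.
    tr_seconds : float
        Sampling interval (fMRI repetition time) in seconds.
    """

    low_hz: float = 0.01
    high_hz: float = 0.08
    order: int = 4
    ripple_db: float = 0.5
    tr_seconds: float = 2.0

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds

    def validate(self) -> None:
        if self.tr_seconds <= 0:
            raise FilterDesignError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if not (0.0 < self.low_hz < self.high_hz < self.nyquist_hz):
            raise FilterDesignError(
                "band must satisfy 0 < low < high < Nyquist "
                f"(got low={self.low_hz}, high={self.high_hz}, "
                f"Nyquist={self.nyquist_hz})"
            )
        if self.order < 1:
            raise FilterDesignError(f"order must be >= 1, got {self.order}")


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove the per-column least-squares linear trend (slope and intercept).

    Parameters
    ----------
    ts : ndarray, shape (T,) or (T, V)
        Time series in columns.

    Returns
    -------
    ndarray of the same shape whose columns are orthogonal to both the
    constant and the linear ramp.
    """
    ts = np.asarray(ts, dtype=float)
    n_t = ts.shape[0]
    if n_t < 3:
        raise ValueError(f"detrend_linear needs at least 3 time points, got {n_t}")
    return scipy.signal.detrend(ts, axis=0, type="linear")


def design_bandpass(spec: BandpassSpec) -> np.ndarray:
    """Return second-order sections for the Chebyshev type-I band-pass."""
    spec.validate()
    wn = np.array([spec.low_hz, spec.high_hz]) / spec.nyquist_hz
    sos = scipy.signal.cheby1(spec.order, spec.ripple_db, wn, btype="bandpass", output="sos")
    # stability guard: all poles strictly inside the unit circle
    _, poles, _ = scipy.signal.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0 - 1e-12):
        raise FilterDesignError(
            f"Chebyshev design of order {spec.order} is numerically unstable for "
            f"band [{spec.low_hz}, {spec.high_hz}] Hz at TR={spec.tr_seconds}s; "
            "try a lower order"
        )
    return sos


def bandpass(ts: np.ndarray, spec: BandpassSpec) -> np.ndarray:
    """Zero-phase Chebyshev type-I band-pass filter, column-wise.

    Applied forward and backward (``sosfiltfilt``) so the output has zero
    phase shift; the magnitude response is the square of the single-pass
    design.
    """
    sos = design_bandpass(spec)
    ts = np.asarray(ts, dtype=float)
    min_len = 3 * (sos.shape[0] * 2 + 1)
    if ts.shape[0] <= min_len:
        raise ValueError(
            f"time series too short to filter: need more than {min_len} samples, "
            f"got {ts.shape[0]} (lower the filter order or provide a longer run)"
        )
    return scipy.signal.sosfiltfilt(sos, ts, axis=0)


def condition(ts: np.ndarray, spec: BandpassSpec) -> np.ndarray:
    """Detrend then band-pass — the standard conditioning order."""
    return bandpass(detrend_linear(ts), spec)
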