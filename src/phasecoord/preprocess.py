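"""Run-level signal conditioning and instantaneous-phase extraction.

The fixed conditioning order is: global-signal regression, zero-phase
band-pass (0.0025-0.05 Hz Butterworth, forward-backward) plus an FFT notch
at 0.03 Hz, per-ROI z-scoring, then the analytic signal (Hilbert transform)
whose angle gives each region's instantaneous phase.  The first and last
volumes are dropped after the transform because the Hilbert boundary
distorts them.

With a 2.4 s TR the Nyquist frequency is ~0.208 Hz, so the 0.0025-0.05 Hz
band keeps the slow hemodynamic fluctuations whose phase is meaningful and
the narrowband assumption behind the analytic-signal decomposition
x(t) = A(t) cos(phi(t)) holds.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import butter, freqz, hilbert

from .containers import PhaseRun, RoiTimeSeriesRun

__all__ = [
    "regress_global_signal",
    "temporal_filter",
    "zscore_run",
    "analytic_phase",
    "condition_run",
    "wrap_phase",
    "RunTooShortError",
]

DEFAULT_LOW_CUT_HZ = 0.0025
DEFAULT_HIGH_CUT_HZ = 0.05
DEFAULT_NOTCH_HZ = 0.03
DEFAULT_NOTCH_HALF_WIDTH_HZ = 0.002
FILTER_ORDER = 2


class RunTooShortError(ValueError):
    """Raised when a run has too few volumes for a stable operation."""


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles into the half-open interval [-pi, pi)."""
    return np.mod(np.asarray(phi) + np.pi, 2 * np.pi) - np.pi


def regress_global_signal(run: RoiTimeSeriesRun) -> RoiTimeSeriesRun:
    """Remove the mean-across-ROIs signal from every ROI by OLS.

    Each ROI row is replaced by its residual after regression on an
    intercept plus the global (ROI-mean) signal; residuals are therefore
    exactly orthogonal to the global regressor.  If the global signal has
    zero variance there is nothing to regress: the run is returned unchanged
    (de-meaned rows only) with a warning.
    """
    x = run.values
    global_sig = x.mean(axis=0)
    centered = x - x.mean(axis=1, keepdims=True)
    g = global_sig - global_sig.mean()
    denom = g @ g
    if denom == 0.0:
        warnings.warn(
            f"run {run.meta.run_id}: global signal has zero variance; "
            "skipping global-signal regression",
            stacklevel=2,
        )
        return run.with_values(centered)
    beta = centered @ g / denom  # per-ROI slope on the centered global signal
    residuals = centered - np.outer(beta, g)
    return run.with_values(residuals)


def _min_length_for_filter(low_cut: float, high_cut: float, tr_seconds: float) -> int:
    # the run must be long enough for the FFT to resolve the passband with
    # at least 3 frequency bins
    return int(np.ceil(3.0 / ((high_cut - low_cut) * tr_seconds)))


def _fft_notch(x: np.ndarray, fs: float, notch_hz: float, half_width_hz: float) -> np.ndarray:
    """Zero-phase frequency-domain notch: zero all FFT bins within
    +/- half_width_hz of notch_hz (conjugate-symmetric bins included)."""
    t = x.shape[-1]
    freqs = np.fft.rfftfreq(t, d=1.0 / fs)
    spec = np.fft.rfft(x, axis=-1)
    kill = np.abs(freqs - notch_hz) <= half_width_hz
    spec[..., kill] = 0.0
    return np.fft.irfft(spec, n=t, axis=-1)


def temporal_filter(
    run: RoiTimeSeriesRun,
    low_cut: float = DEFAULT_LOW_CUT_HZ,
    high_cut: float = DEFAULT_HIGH_CUT_HZ,
    notch: float | None = DEFAULT_NOTCH_HZ,
    notch_half_width: float = DEFAULT_NOTCH_HALF_WIDTH_HZ,
    order: int = FILTER_ORDER,
) -> RoiTimeSeriesRun:
    """Zero-phase band-pass plus optional FFT notch.

    The band-pass applies the squared magnitude response |H(f)|^2 of a
    Butterworth filter of the given order to the run's FFT — the steady-state
    frequency response of a forward-backward (zero-phase) pass, without the
    edge transients a time-domain pass would leave on runs much shorter than
    the 0.0025 Hz high-pass settling time.  The realization is exactly
    zero-phase, removes DC exactly, and commutes exactly with time reversal.
    The notch zeroes the FFT bins within ``notch_half_width`` of ``notch``.
    """
    nyquist = 0.5 / run.tr_seconds
    if not (0 < low_cut < high_cut < nyquist):
        raise ValueError(
            f"need 0 < low_cut < high_cut < Nyquist={nyquist:.4g} Hz; "
            f"got low_cut={low_cut}, high_cut={high_cut}"
        )
    if notch is not None and not (low_cut < notch < high_cut):
        raise ValueError(f"notch {notch} Hz must lie inside ({low_cut}, {high_cut}) Hz")
    min_t = _min_length_for_filter(low_cut, high_cut, run.tr_seconds)
    if run.n_volumes < min_t:
        raise RunTooShortError(
            f"run {run.meta.run_id}: {run.n_volumes} volumes < minimum {min_t} "
            "required to resolve the passband"
        )
    fs = 1.0 / run.tr_seconds
    t = run.n_volumes
    freqs = np.fft.rfftfreq(t, d=run.tr_seconds)
    b, a = butter(order, [low_cut, high_cut], btype="bandpass", fs=fs)
    _, h = freqz(b, a, worN=freqs, fs=fs)
    gain = np.abs(h) ** 2  # forward-backward: squared magnitude, zero phase
    gain[0] = 0.0  # exact DC removal
    spec = np.fft.rfft(run.values, axis=-1) * gain[None, :]
    filtered = np.fft.irfft(spec, n=t, axis=-1)
    if notch is not None:
        filtered = _fft_notch(filtered, fs, notch, notch_half_width)
    return run.with_values(filtered)


def zscore_run(run: RoiTimeSeriesRun) -> RoiTimeSeriesRun:
    """Z-score each ROI row (mean 0, sample SD 1, ddof=1)."""
    x = run.values
    sd = x.std(axis=1, ddof=1)
    zero_var = np.flatnonzero(sd == 0)
    if zero_var.size:
        names = [run.roi_names[i] for i in zero_var]
        raise ValueError(f"zero-variance ROI rows cannot be z-scored: {names}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    return run.with_values(z)


def analytic_phase(run: RoiTimeSeriesRun) -> PhaseRun:
    """Instantaneous amplitude and phase from the analytic signal.

    For each ROI the analytic signal x + i H[x] is formed via the Hilbert
    transform; its modulus is the instantaneous amplitude A(t) and its angle
    the instantaneous phase phi(t), wrapped to [-pi, pi).  The first and
    last volumes are excluded, so the output has T - 2 columns, and the
    retained samples satisfy x(t) = A(t) cos(phi(t)) up to rounding.
    """
    if run.n_volumes < 3:
        raise RunTooShortError("need at least 3 volumes for phase extraction")
    analytic = hilbert(run.values, axis=-1)
    amplitudes = np.abs(analytic)[:, 1:-1]
    phases = wrap_phase(np.angle(analytic)[:, 1:-1])
    return PhaseRun(
        phases=phases,
        amplitudes=amplitudes,
        roi_names=list(run.roi_names),
        tr_seconds=run.tr_seconds,
        meta=run.meta,
    )


def condition_run(
    run: RoiTimeSeriesRun,
    low_cut: float = DEFAULT_LOW_CUT_HZ,
    high_cut: float = DEFAULT_HIGH_CUT_HZ,
    notch: float | None = DEFAULT_NOTCH_HZ,
    gsr: bool = True,
) -> PhaseRun:
    """Full conditioning chain: GSR -> filters -> z-score -> analytic phase."""
    if gsr:
        run = regress_global_signal(run)
    run = temporal_filter(run, low_cut=low_cut, high_cut=high_cut, notch=notch)
    run = zscore_run(run)
    return analytic_phase(run)
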