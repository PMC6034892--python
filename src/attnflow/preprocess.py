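"""Time-series conditioning and block-amplitude extraction.

Implements the standard conditioning chain for blocked-design BOLD data:
linear trend removal, high-pass filtering at 0.015 Hz, session grand-mean
scaling to 100, and per-block response-amplitude extraction using a 2-s
pre-onset baseline and a [5, 16] s post-onset response window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import BlockDesign, TimeSeriesSet

__all__ = [
    "remove_linear_trend",
    "highpass",
    "grand_mean_scale",
    "extract_block_amplitude",
]

log = logging.getLogger(__name__)


def remove_linear_trend(ts: TimeSeriesSet) -> TimeSeriesSet:
    """Subtract the per-region least-squares line (intercept and slope).

    The output is mean-zero per region; the removed intercept is not
    re-added.
    """
    if ts.n_time < 3:
        raise ValueError("need at least 3 time points to remove a linear trend")
    t = ts.times
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    resid = ts.data - (X @ beta).T
    return ts.copy_with(resid, detrended=True)


def _dct_basis(n: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Orthonormal DCT-II regressors (incl. constant) with frequency < cutoff.

    Basis function k has frequency k / (2 n tr); the constant (k = 0)
    is always included so the filter removes DC exactly.
    """
    freqs = np.arange(n) / (2.0 * n * tr)
    k_max = int(np.searchsorted(freqs, cutoff_hz))  # components strictly below cutoff
    k_max = max(k_max, 1)
    t = np.arange(n)
    ks = np.arange(k_max)
    basis = np.cos(np.pi * np.outer(t + 0.5, ks) / n)
    basis /= np.linalg.norm(basis, axis=0, keepdims=True)
    return basis


def highpass(
    ts: TimeSeriesSet, cutoff_hz: float = 0.015, method: str = "dct"
) -> TimeSeriesSet:
    """High-pass filter each region's series.

    The default realization projects out a discrete-cosine set of
    regressors with frequencies below ``cutoff_hz`` (the common fMRI
    drift model), which removes DC exactly and leaves the passband
    untouched.  ``method="butterworth"`` applies a zero-phase 2nd-order
    Butterworth filter instead.
    """
    nyquist = 0.5 / ts.tr
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    if method == "dct":
        basis = _dct_basis(ts.n_time, ts.tr, cutoff_hz)
        coef = basis.T @ ts.data.T
        filtered = ts.data - (basis @ coef).T
    elif method == "butterworth":
        from scipy.signal import butter, filtfilt

        b, a = butter(2, cutoff_hz / nyquist, btype="highpass")
        filtered = filtfilt(b, a, ts.data, axis=1)
    else:
        raise ValueError(f"unknown highpass method {method!r}")
    return ts.copy_with(filtered, highpass_hz=cutoff_hz, highpass_method=method)


def grand_mean_scale(ts: TimeSeriesSet, target: float = 100.0) -> TimeSeriesSet:
    """Scale so the grand mean over all regions and times equals ``target``.

    Mirrors session-specific grand-mean scaling where the mean signal
    over space and time is set to 100.  Idempotent.
    """
    gm = float(np.mean(ts.data))
    if gm == 0.0:
        raise ValueError("grand mean is zero; cannot scale")
    return ts.copy_with(ts.data * (target / gm), grand_mean_target=target)


def extract_block_amplitude(
    ts: TimeSeriesSet,
    design: BlockDesign,
    baseline_window: float = 2.0,
    response_window: tuple[float, float] = (5.0, 16.0),
    percent: bool = True,
    subject: str | int | None = None,
) -> pd.DataFrame:
    """Per-block response amplitudes relative to the pre-onset baseline.

    For each stimulus block, the ``baseline_window`` seconds preceding
    the onset serve as baseline (samples in [onset - w, onset), one TR
    sample at -2 s in the standard design) and the mean signal in the
    closed window [onset + 5, onset + 16] s is the response measure.
    A sample at start-of-TR time t belongs to a closed window [a, b]
    iff a <= t <= b.

    Amplitude is ``mean(response) - mean(baseline)``, expressed in % of
    the baseline level when ``percent`` is true (requires a positive
    baseline, e.g. after grand-mean scaling) and in raw signal units
    otherwise.  Blocks whose windows fall outside the run are skipped
    with a logged warning.

    Returns a tidy frame with columns subject, region, condition,
    block_index, amplitude.
    """
    lo, hi = response_window
    if baseline_window <= 0 or hi <= lo:
        raise ValueError("windows must have positive extent")
    t = ts.times
    rows = []
    for block_index, (cond, onset, _dur) in enumerate(design.blocks()):
        base_mask = (t >= onset - baseline_window - 1e-9) & (t < onset - 1e-9)
        resp_mask = (t >= onset + lo - 1e-9) & (t <= onset + hi + 1e-9)
        if not base_mask.any() or not resp_mask.any() or onset + hi > ts.times[-1] + 1e-9:
            log.warning(
                "block %d (%s, onset %.1f s): window outside run; skipped",
                block_index, cond, onset,
            )
            continue
        base = ts.data[:, base_mask].mean(axis=1)
        resp = ts.data[:, resp_mask].mean(axis=1)
        amp = resp - base
        if percent:
            if np.any(base <= 0):
                raise ValueError(
                    "non-positive baseline level; percent conversion undefined "
                    "(grand-mean scale the series first or pass percent=False)"
                )
            amp = amp / base * 100.0
        for r, label in enumerate(ts.region_labels):
            rows.append(
                {
                    "subject": subject if subject is not None else ts.meta.get("subject", 0),
                    "region": label,
                    "condition": cond,
                    "block_index": block_index,
                    "amplitude": amp[r],
                }
            )
    df = pd.DataFrame(rows, columns=["subject", "region", "condition", "block_index", "amplitude"])
    df.attrs["baseline_window"] = baseline_window
    df.attrs["response_window"] = response_window
    df.attrs["percent"] = percent
    return df


def mean_condition_amplitudes(amplitudes: pd.DataFrame) -> pd.DataFrame:
    """Mean amplitude per subject × region × condition (wide by condition)."""
    return (
        amplitudes.groupby(["subject", "region", "condition"])["amplitude"]
        .mean()
        .unstack("condition")
        .reset_index()
    )
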