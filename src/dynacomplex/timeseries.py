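"""Autocorrelation utilities shared by the chain-dynamics and trajectory modules."""
from __future__ import annotations

import numpy as np


def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Normalized autocorrelation of a scalar series (FFT-based).

    C(0) = 1; the mean is subtracted. Uses the biased estimator
    (divide by n) which keeps the integrated time well behaved.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    dx = x - x.mean()
    var = np.mean(dx * dx)
    if var == 0:
        raise ValueError("constant series: correlation time undefined")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(dx, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n] / n / var
    if max_lag is not None:
        acf = acf[:max_lag + 1]
    return acf


def integrated_correlation_time(x: np.ndarray, dt: float,
                                cutoff: float = 0.01,
                                tail_fit_upper: float = 0.1) -> float:
    """Integrated correlation time of a scalar series.

    The normalized autocorrelation is integrated (trapezoid) up to the
    first lag where it drops below ``cutoff``; an exponential tail
    correction C(t_c) * tau_loc is added, with tau_loc estimated by a
    log-linear fit over the region where C is between ``cutoff`` and
    ``tail_fit_upper``. Returned in the units of ``dt``.
    """
    acf = autocorrelation(x)
    below = np.nonzero(acf < cutoff)[0]
    i_c = int(below[0]) if below.size else len(acf) - 1
    tau = np.trapezoid(acf[:i_c + 1], dx=dt)
    # exponential tail correction from the local decay rate near the cutoff
    sel = np.nonzero((acf[:i_c + 1] > cutoff) & (acf[:i_c + 1] < tail_fit_upper))[0]
    if sel.size >= 3:
        t = sel * dt
        slope = np.polyfit(t, np.log(acf[sel]), 1)[0]
        if slope < 0:
            tau += max(acf[i_c], 0.0) * (-1.0 / slope)
    return float(tau)


def block_correlation_time(x: np.ndarray, dt: float, n_blocks: int = 10,
                           **kwargs) -> tuple[float, float]:
    """Correlation time with a block-resampled standard error of the mean."""
    x = np.asarray(x, dtype=float)
    m = len(x) // n_blocks
    if m < 10:
        raise ValueError("blocks too short for correlation analysis")
    taus = np.array([integrated_correlation_time(x[i * m:(i + 1) * m], dt, **kwargs)
                     for i in range(n_blocks)])
    return float(taus.mean()), float(taus.std(ddof=0) / np.sqrt(n_blocks))
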