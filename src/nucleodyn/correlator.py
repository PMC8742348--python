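"""Autocorrelation estimators for binned photon-count traces.

Two schemes compute the normalized fluctuation autocorrelation
G(tau) = <dF(t) dF(t+tau)> / <F>^2:

* ``direct`` — every integer-bin lag up to a maximum, at full time
  resolution (O(n log n) via FFT).
* ``multi_tau`` — the community-standard correlator design: m linearly
  spaced lag channels per stage, trace coarsened by the bin ratio between
  stages, so the lag grid is geometric overall and spans many decades at
  fixed cost.

Both use the symmetric (time-matched) normalization: at lag k the raw
product average is divided by the means of the leading and trailing
sub-traces, which removes the finite-length bias of normalizing by the
global mean. The zero-lag channel is never reported — it is dominated by
shot noise and excluded from fitting.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .types import CorrelationCurve, IntensityTrace

__all__ = ["autocorrelate", "average_curves"]


def _check_trace(trace: IntensityTrace) -> np.ndarray:
    x = np.asarray(trace.counts, dtype=float)
    if x.mean() <= 0:
        raise ValueError("degenerate trace: zero mean, normalization undefined")
    if x.var() == 0:
        raise ValueError("degenerate trace: zero variance")
    return x


def _raw_products(x: np.ndarray, max_lag: int) -> np.ndarray:
    """sum_t x[t] * x[t+k] for k = 0..max_lag, via FFT convolution."""
    n = x.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[: max_lag + 1]
    return acov


def _direct_g(x: np.ndarray, lags_bins: np.ndarray) -> np.ndarray:
    """Symmetric-normalized G at the given integer-bin lags of trace x."""
    n = x.size
    csum = np.concatenate(([0.0], np.cumsum(x)))
    raw = _raw_products(x, int(lags_bins.max()))
    g = np.empty(lags_bins.size)
    for i, k in enumerate(lags_bins):
        m = n - k
        mean_left = (csum[m] - csum[0]) / m
        mean_right = (csum[n] - csum[k]) / m
        g[i] = (raw[k] / m) / (mean_left * mean_right) - 1.0
    return g


def _multi_tau_lags(n: int, m: int, ratio: int) -> List[Tuple[int, np.ndarray]]:
    """Per-stage (coarsening factor, integer lags in coarse bins)."""
    stages = []
    factor = 1
    # stage 0: lags 1..m at full resolution
    lags0 = np.arange(1, m + 1)
    stages.append((factor, lags0))
    while True:
        factor *= ratio
        n_coarse = n // factor
        # subsequent stages only add lags beyond those already covered
        lo = m // ratio + 1
        lags = np.arange(lo, m + 1)
        lags = lags[lags < n_coarse]  # need at least one product pair
        if lags.size == 0:
            break
        stages.append((factor, lags))
        if n_coarse // ratio <= m // ratio + 1:
            break
    return stages


def autocorrelate(
    trace: IntensityTrace,
    scheme: str = "multi_tau",
    m: int = 16,
    ratio: int = 2,
    max_lag: Optional[int] = None,
) -> CorrelationCurve:
    """Normalized autocorrelation of a photon-count trace.

    Parameters
    ----------
    trace : IntensityTrace
        Binned counts; mean and variance must be positive.
    scheme : {"multi_tau", "direct"}
        "direct" evaluates every integer-bin lag 1..max_lag;
        "multi_tau" uses geometrically coarsened lag registers.
    m : int
        Channels per multi-tau stage (default 16).
    ratio : int
        Coarsening factor between stages (default 2).
    max_lag : int, optional
        Direct scheme only; defaults to n // 4 bins.

    Returns
    -------
    CorrelationCurve
        Lags in seconds (tau > 0 only) and G values.
    """
    x = _check_trace(trace)
    n = x.size
    if scheme == "direct":
        if max_lag is None:
            max_lag = max(n // 4, 1)
        max_lag = min(max_lag, n - 1)
        lag_bins = np.arange(1, max_lag + 1)
        g = _direct_g(x, lag_bins)
        lags = lag_bins * trace.bin_width
    elif scheme == "multi_tau":
        if m < ratio or m % ratio:
            raise ValueError("m must be a positive multiple of the ratio")
        lag_list, g_list = [], []
        for factor, lag_bins in _multi_tau_lags(n, m, ratio):
            n_coarse = (n // factor) * factor
            coarse = x[:n_coarse].reshape(-1, factor).mean(axis=1)
            g_list.append(_direct_g(coarse, lag_bins))
            lag_list.append(lag_bins * factor * trace.bin_width)
        lags = np.concatenate(lag_list)
        g = np.concatenate(g_list)
        order = np.argsort(lags)
        lags, g = lags[order], g[order]
    else:
        raise ValueError(f"unknown scheme: {scheme!r}")
    return CorrelationCurve(
        lags=lags,
        g=g,
        n_traces_averaged=1,
        label=trace.label,
        condition=trace.condition,
    )


def average_curves(
    curves: List[CorrelationCurve],
    normalize: bool = False,
    norm_lags: int = 3,
) -> CorrelationCurve:
    """Per-lag mean (and SD) of correlation curves on a shared lag grid.

    Parameters
    ----------
    curves : list of CorrelationCurve
        All curves must share an identical lag grid.
    normalize : bool
        If True, divide the averaged curve by its mean G over the first
        ``norm_lags`` lags — display convention only; fitting always uses
        unnormalized curves.
    norm_lags : int
        Number of leading lags defining the display normalization.
    """
    if not curves:
        raise ValueError("empty curve list")
    lag0 = curves[0].lags
    for c in curves[1:]:
        if c.lags.size != lag0.size or not np.allclose(c.lags, lag0):
            raise ValueError("curves must share an identical lag grid")
    gmat = np.vstack([c.g for c in curves])
    g = gmat.mean(axis=0)
    sd = gmat.std(axis=0, ddof=0)
    if normalize:
        scale = g[:norm_lags].mean()
        if scale == 0:
            raise ValueError("cannot normalize: zero mean over leading lags")
        g = g / scale
        sd = sd / abs(scale)
    return CorrelationCurve(
        lags=lag0.copy(),
        g=g,
        sd=sd,
        n_traces_averaged=len(curves),
        condition=curves[0].condition,
    )
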