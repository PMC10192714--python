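"""Autocorrelation estimators for binned photon-count traces.

Two paths are provided: a direct linear-lag estimator that serves as the
in-repo oracle, and a multi-tau estimator (linear lags within each octave,
bin width doubling between octaves) that covers millisecond-to-minute lags
at a cost roughly linear in the trace length.

Both use the symmetric normalization

    G(k) = <F_t F_{t+k}> / (<F_t> <F_{t+k}>) - 1

with the means taken over the overlapping head/tail segments at each lag,
which suppresses the bias from slow drifts.  Lag 0 (shot-noise dominated)
is never reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateTraceError, InputError
from .model import ACFCurve

__all__ = ["IntensityTrace", "direct_acf", "multitau_acf", "segment_acf"]


@dataclass
class IntensityTrace:
    """Photon counts per sampling bin.

    ``bin_width`` is the sampling interval in seconds (1/rate); e.g. 2e-5 s
    for a 50 kHz acquisition.
    """

    counts: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise InputError("counts must be a 1-D array")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise InputError("counts must be numeric")
        if np.any(self.counts < 0):
            raise InputError("counts must be non-negative")
        if not (np.isfinite(self.bin_width) and self.bin_width > 0):
            raise InputError("bin_width must be finite and > 0")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.counts.size * self.bin_width

    @property
    def rate_hz(self) -> float:
        return 1.0 / self.bin_width


def _check_signal(x: np.ndarray) -> None:
    if float(x.mean()) <= 0:
        raise DegenerateTraceError("trace mean is zero; the normalized ACF is undefined")


def _acf_at_lags(
    x: np.ndarray, lag_bins: np.ndarray, norm_mean: float | None = None
) -> np.ndarray:
    """Normalized ACF of a float signal at integer bin lags.

    With ``norm_mean=None`` the symmetric normalization is used (separate
    means of the overlapping head/tail segments at each lag).  When a
    ``norm_mean`` is supplied the products are normalized by that external
    mean instead; :func:`segment_acf` uses this with the whole-trace mean so
    that correlations slower than one segment are not subtracted away.
    """
    n = x.size
    out = np.empty(lag_bins.size, dtype=float)
    for i, k in enumerate(lag_bins):
        k = int(k)
        head = x[: n - k]
        tail = x[k:]
        if norm_mean is None:
            m1 = head.mean()
            m2 = tail.mean()
        else:
            m1 = m2 = norm_mean
        if m1 <= 0 or m2 <= 0:
            out[i] = 0.0
            continue
        out[i] = float(np.dot(head, tail)) / ((n - k) * m1 * m2) - 1.0
    return out


def direct_acf(trace: IntensityTrace, max_lag_bins: int) -> ACFCurve:
    """Direct linear-lag ACF estimate, lags 1..max_lag_bins.

    O(n * max_lag_bins); intended as the oracle for small lag ranges.
    """
    if max_lag_bins < 1:
        raise InputError("max_lag_bins must be >= 1")
    x = np.asarray(trace.counts, dtype=float)
    if x.size <= 2 * max_lag_bins:
        raise InputError("trace length must exceed 2 * max_lag_bins")
    _check_signal(x)
    lag_bins = np.arange(1, max_lag_bins + 1)
    g = _acf_at_lags(x, lag_bins)
    return ACFCurve(lags=lag_bins * trace.bin_width, g=g, bin_width=trace.bin_width)


def _multitau_ladder(n: int, points_per_octave: int) -> list[tuple[int, np.ndarray]]:
    """Levels of the multi-tau scheme as (rebin factor, lag indices at that level).

    Level 0 carries lags 1..m at full resolution; each deeper level halves the
    time resolution and carries lags m/2+1..m in rebinned units.
    """
    m = points_per_octave
    levels = [(1, np.arange(1, m + 1))]
    factor = 2
    deep = np.arange(m // 2 + 1, m + 1)
    # Descend while the rebinned signal still overlaps the deepest lag by at
    # least half an octave: reaching lags of ~T/3 anchors slow exponential
    # tails that would otherwise be unconstrained by the fit window.
    while n // factor >= (3 * m) // 2:
        levels.append((factor, deep))
        factor *= 2
    return levels


def multitau_acf(
    trace: IntensityTrace,
    points_per_octave: int = 16,
    norm_mean: float | None = None,
) -> ACFCurve:
    """Quasi-logarithmic (multi-tau) ACF estimate.

    Lags within the first octave reproduce :func:`direct_acf` exactly (same
    estimator on the raw signal); deeper octaves correlate progressively
    rebinned copies of the signal.  ``norm_mean`` optionally replaces the
    symmetric per-lag normalization by an externally supplied mean (rebinning
    by pair averaging leaves the mean unchanged, so one value serves every
    level).
    """
    if points_per_octave < 2 or points_per_octave % 2:
        raise InputError("points_per_octave must be an even integer >= 2")
    x = np.asarray(trace.counts, dtype=float)
    if x.size < 3 * points_per_octave:
        raise InputError("trace too short for the requested lag ladder")
    _check_signal(x)

    lags: list[np.ndarray] = []
    gs: list[np.ndarray] = []
    signal = x
    factor_done = 1
    for factor, lag_idx in _multitau_ladder(x.size, points_per_octave):
        while factor_done < factor:  # rebin by averaging consecutive pairs
            usable = signal.size - (signal.size % 2)
            signal = signal[:usable].reshape(-1, 2).mean(axis=1)
            factor_done *= 2
        lags.append(lag_idx * factor * trace.bin_width)
        gs.append(_acf_at_lags(signal, lag_idx, norm_mean=norm_mean))
    return ACFCurve(
        lags=np.concatenate(lags), g=np.concatenate(gs), bin_width=trace.bin_width
    )


def segment_acf(
    trace: IntensityTrace, n_segments: int, points_per_octave: int = 16
) -> ACFCurve:
    """Mean +/- SEM of multi-tau ACFs over equal contiguous trace segments.

    The per-lag SEM feeds weighted fitting.  Each segment must be long enough
    to support the lag ladder (>= 3 * points_per_octave bins).

    Per-segment curves are normalized by the whole-trace mean rather than by
    each segment's own mean: subtracting segment-local means would also
    subtract any correlation component slower than a fraction of the segment
    length, biasing long residence times low.  Segmentation here only
    provides the per-lag sampling error.
    """
    if n_segments < 2:
        raise InputError("n_segments must be >= 2")
    x = trace.counts
    seg_len = x.size // n_segments
    if seg_len < 3 * points_per_octave:
        raise InputError("segments too short for the requested lag ladder")
    _check_signal(np.asarray(x, dtype=float))
    global_mean = float(np.asarray(x, dtype=float).mean())
    curves = []
    for i in range(n_segments):
        seg = IntensityTrace(x[i * seg_len : (i + 1) * seg_len], trace.bin_width)
        curves.append(
            multitau_acf(seg, points_per_octave=points_per_octave, norm_mean=global_mean)
        )
    g = np.vstack([c.g for c in curves])
    sem = g.std(axis=0, ddof=1) / np.sqrt(n_segments)
    return ACFCurve(
        lags=curves[0].lags, g=g.mean(axis=0), sem=sem, bin_width=trace.bin_width
    )
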