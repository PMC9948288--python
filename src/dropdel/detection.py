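"""Detector-side signal utilities: trace reduction and fluorescence polarization.

A raw detector trace is a uniformly sampled time series in which each droplet
transit appears as a contiguous segment above the inter-droplet baseline.
:func:`reduce_trace` smooths the trace with a moving average, segments it at
the baseline, and reduces each sufficiently wide segment to one scalar (its
peak height), yielding the per-droplet signals the sorter consumes.

:func:`fp_polarization` converts a pair of polarized emission intensities to
the standard polarization ratio ``(I_par - I_perp) / (I_par + I_perp)``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fp_polarization", "reduce_trace"]


def fp_polarization(parallel_intensity, perpendicular_intensity):
    """Fluorescence polarization from the two emission channels, in [-1, 1].

    0 for fully depolarized emission (equal channels), 1 for fully polarized.
    Accepts scalars or arrays; raises if any intensity pair is (0, 0) or
    either channel is negative.
    """
    par = np.asarray(parallel_intensity, dtype=float)
    perp = np.asarray(perpendicular_intensity, dtype=float)
    if np.any(par < 0) or np.any(perp < 0):
        raise ValueError("intensities must be nonnegative")
    total = par + perp
    if np.any(total == 0):
        raise ValueError("polarization undefined when both intensities are zero")
    out = (par - perp) / total
    if np.isscalar(parallel_intensity) and np.isscalar(perpendicular_intensity):
        return float(out)
    return out


def reduce_trace(
    trace,
    min_width: int = 3,
    baseline: float = 0.0,
    smooth_window: int = 5,
) -> np.ndarray:
    """Reduce a sampled signal trace to one scalar per droplet transit.

    The trace is smoothed with a centered moving average of ``smooth_window``
    samples, segmented into contiguous runs strictly above ``baseline``, and
    each run of at least ``min_width`` samples contributes its peak height.
    A flat trace at (or below) the baseline yields an empty result.
    """
    y = np.asarray(trace, dtype=float)
    if y.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    if y.size == 0:
        return np.empty(0)
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(y, kernel, mode="same")
    above = smoothed > baseline
    # run-length segmentation of the boolean mask
    edges = np.diff(above.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [y.size]])
    heights = [
        float(smoothed[s:e].max()) for s, e in zip(starts, ends) if e - s >= min_width
    ]
    return np.asarray(heights)
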