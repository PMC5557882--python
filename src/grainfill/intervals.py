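"""Splitting the elution-time axis into contiguous modelling intervals."""

from __future__ import annotations

import numpy as np

__all__ = ["split_time_axis"]


def split_time_axis(n_timepoints: int, n_intervals: int) -> list[tuple[int, int]]:
    """Partition ``[0, n_timepoints)`` into ``n_intervals`` half-open ranges.

    Ranges are contiguous, non-overlapping, cover the axis completely and
    their lengths differ by at most one (longer intervals first).
    """
    if n_intervals <= 0:
        raise ValueError("n_intervals must be positive")
    if n_intervals > n_timepoints:
        raise ValueError("cannot split into more intervals than time points")
    base, extra = divmod(n_timepoints, n_intervals)
    bounds = []
    start = 0
    for i in range(n_intervals):
        length = base + (1 if i < extra else 0)
        bounds.append((start, start + length))
        start += length
    assert start == n_timepoints
    return bounds
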