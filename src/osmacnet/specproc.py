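"""GNPS-style per-spectrum peak filtering applied before similarity scoring.

Two filters, in the fixed order the networking workflow applies them:

1. delete every fragment within +/-17 Da of the precursor m/z (residual
   precursor removal, inclusive boundary);
2. keep a fragment only if it ranks among the 6 most intense peaks within
   +/-50 Da of its own m/z (window anchored on the peak itself, ties broken
   toward lower m/z so the result is deterministic).

Both filters are idempotent.  Intensity ranking uses raw intensities, before
any cosine weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from osmacnet.msio import Spectrum


@dataclass(frozen=True)
class FilterParams:
    """Peak-filter settings (defaults are the networking workflow's)."""

    precursor_window_da: float = 17.0
    window_top_k: int = 6
    window_half_width_da: float = 50.0

    def __post_init__(self) -> None:
        if self.precursor_window_da <= 0 or self.window_half_width_da <= 0:
            raise ValueError("windows must be strictly positive")
        if self.window_top_k < 1:
            raise ValueError("window_top_k must be >= 1")


def remove_precursor_window(spectrum: Spectrum, precursor_window_da: float = 17.0) -> Spectrum:
    """Delete all peaks with |mz - precursor_mz| <= ``precursor_window_da``."""
    mask = np.abs(spectrum.mz - spectrum.precursor_mz) > precursor_window_da
    if mask.all():
        return spectrum
    return spectrum.with_peaks(spectrum.mz[mask], spectrum.intensity[mask])


def window_top_k(spectrum: Spectrum, k: int = 6, half_width: float = 50.0) -> Spectrum:
    """Keep a peak iff it is among the ``k`` most intense within +/-``half_width`` of itself.

    A competing peak outranks peak *i* when it is strictly more intense, or
    equally intense at lower m/z.  Peak *i* survives when fewer than ``k``
    peaks (itself included) rank at or above it in its own window.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    n = len(spectrum)
    if n <= k:
        return spectrum
    mz, inten = spectrum.mz, spectrum.intensity
    keep = np.zeros(n, dtype=bool)
    # windows over a sorted mz array are contiguous slices
    lo = np.searchsorted(mz, mz - half_width, side="left")
    hi = np.searchsorted(mz, mz + half_width, side="right")
    for i in range(n):
        wi, wj = lo[i], hi[i]
        win_int = inten[wi:wj]
        win_mz = mz[wi:wj]
        better = np.count_nonzero(
            (win_int > inten[i]) | ((win_int == inten[i]) & (win_mz < mz[i]))
        )
        keep[i] = better < k
    if keep.all():
        return spectrum
    return spectrum.with_peaks(mz[keep], inten[keep])


def preprocess(spectrum: Spectrum, params: FilterParams = FilterParams()) -> Spectrum:
    """Apply precursor-window removal then windowed top-k, in that order."""
    s = remove_precursor_window(spectrum, params.precursor_window_da)
    return window_top_k(s, params.window_top_k, params.window_half_width_da)
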