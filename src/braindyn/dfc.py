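"""Band-pass filtering and sliding-window dynamic functional connectivity.

The resting-state band of interest is 0.01-0.08 Hz; filtering is zero-phase
(forward-backward Butterworth) applied per region before windowing.
Dynamic connectivity is the ordered stack of Pearson correlation matrices
over overlapping rectangular windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_core import ParcellatedTimeSeries


@dataclass
class WindowedConnectivity:
    """Stack of per-window region x region correlation matrices."""

    matrices: np.ndarray  # (n_windows, n, n)
    window_length: int
    step: int
    window_starts: np.ndarray
    region_ids: list[str]

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]


def bandpass_filter(
    series: ParcellatedTimeSeries,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
) -> ParcellatedTimeSeries:
    """Zero-phase Butterworth band-pass, independently per region.

    Output length equals input length (``filtfilt`` with default padding).
    The band must fit strictly inside (0, Nyquist).
    """
    nyquist = 0.5 / series.tr_seconds
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must lie strictly inside "
            f"(0, {nyquist}) Hz for TR = {series.tr_seconds} s"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / series.tr_seconds,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, series.values, axis=0)
    return ParcellatedTimeSeries(
        values=filtered, tr_seconds=series.tr_seconds, region_ids=series.region_ids
    )


def window_count(n_timepoints: int, window_length: int, step: int) -> int:
    return (n_timepoints - window_length) // step + 1


def sliding_window_dfc(
    series: ParcellatedTimeSeries, window_length: int = 22, step: int = 1
) -> WindowedConnectivity:
    """Pearson correlation within each overlapping window.

    Window ``w`` covers time points ``[w*step, w*step + window_length)``.
    A zero-variance region inside any window is rejected (its correlation is
    undefined) with the window and region named.
    """
    t, n = series.values.shape
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if t < window_length:
        raise ValueError(f"series has {t} time points < window length {window_length}")
    n_win = window_count(t, window_length, step)
    starts = np.arange(n_win) * step
    mats = np.empty((n_win, n, n))
    for w, s in enumerate(starts):
        block = series.values[s : s + window_length]
        sd = block.std(axis=0)
        if np.any(sd == 0):
            bad = [series.region_ids[i] for i in np.nonzero(sd == 0)[0]]
            raise ValueError(
                f"zero-variance region(s) {bad} in window {w} "
                f"(time points {s}..{s + window_length - 1})"
            )
        c = np.corrcoef(block, rowvar=False)
        c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(c, 1.0)
        mats[w] = c
    return WindowedConnectivity(
        matrices=mats,
        window_length=window_length,
        step=step,
        window_starts=starts,
        region_ids=list(series.region_ids),
    )
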