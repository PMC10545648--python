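"""Epoch containers and trial-level ERP amplitude measures.

The two outcome measures of the analysis are window means of
baseline-corrected single-trial epochs:

* VAN-relevant amplitude — mean over 180-280 ms at occipital/parieto-
  occipital electrodes (O1, O2, PO3, PO4, PO7, PO8);
* LP-relevant amplitude — mean over 350-550 ms at centro-parietal
  electrodes (Pz, P1, P2, CPz, CP1, CP2).

Epochs span -100..800 ms around stimulus onset; the 100 ms before onset
serve as the baseline.  A deterministic artifact flagger replaces manual
inspection: epochs whose 30-Hz-low-passed peak-to-peak range exceeds a
per-subject median + k*MAD threshold are marked bad.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["Epoch", "EpochArray", "WindowSpec", "VAN_WINDOW", "LP_WINDOW",
           "baseline_correct", "mean_amplitude", "flag_artifacts", "downsample"]

VAN_ELECTRODES = ("O1", "O2", "PO3", "PO4", "PO7", "PO8")
LP_ELECTRODES = ("Pz", "P1", "P2", "CPz", "CP1", "CP2")


@dataclass(frozen=True)
class WindowSpec:
    """Analysis window: a time interval (ms, inclusive on both ends at the
    sample grid) and the set of electrodes averaged over."""

    t_start: float
    t_end: float
    electrodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must precede t_end")
        if not self.electrodes:
            raise ValueError("electrode set must be non-empty")


VAN_WINDOW = WindowSpec(180.0, 280.0, VAN_ELECTRODES)
LP_WINDOW = WindowSpec(350.0, 550.0, LP_ELECTRODES)


@dataclass
class EpochArray:
    """Stack of epochs: ``data`` is (n_epochs, n_channels, n_times) in uV,
    ``times_ms`` relative to stimulus onset."""

    data: np.ndarray
    channels: tuple[str, ...]
    times_ms: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, times)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel count mismatch")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("time axis mismatch")

    def channel_indices(self, names) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.channels)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise ValueError(f"channels not present: {missing}")
        return np.array([lookup[n] for n in names])


# a single Epoch is an EpochArray with one epoch; alias kept for readability
Epoch = EpochArray


def baseline_correct(epochs: EpochArray, baseline=(-100.0, 0.0)) -> EpochArray:
    """Subtract the per-channel mean of the pre-stimulus baseline interval.

    The baseline is ``[t0, t1)`` in ms; the epoch must cover it.  Returns a
    new :class:`EpochArray` whose baseline mean is zero per channel.
    """
    t0, t1 = baseline
    mask = (epochs.times_ms >= t0) & (epochs.times_ms < t1)
    if not mask.any():
        raise ValueError(f"epoch does not cover baseline [{t0}, {t1}) ms")
    base = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochArray(epochs.data - base, epochs.channels,
                      epochs.times_ms.copy(), epochs.sample_rate)


def mean_amplitude(epochs: EpochArray, window: WindowSpec) -> np.ndarray:
    """Mean amplitude (uV) over the window's samples and electrodes.

    Endpoints are inclusive on the sample grid.  Returns one value per
    epoch.
    """
    tmask = (epochs.times_ms >= window.t_start) & (epochs.times_ms <= window.t_end)
    if not tmask.any():
        raise ValueError("no samples fall inside the analysis window")
    ch = epochs.channel_indices(window.electrodes)
    return epochs.data[:, ch][:, :, tmask].mean(axis=(1, 2))


def _lowpass(data: np.ndarray, sample_rate: float, cutoff_hz: float) -> np.ndarray:
    sos = signal.butter(4, cutoff_hz, btype="low", fs=sample_rate, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def flag_artifacts(epochs: EpochArray, k: float = 8.0,
                   range_floor_uv: float = 25.0,
                   lowpass_hz: float = 30.0) -> np.ndarray:
    """Deterministic per-subject artifact flagging.

    Each epoch's maximum peak-to-peak range across channels is computed
    after a 30-Hz low-pass.  Epochs whose range exceeds
    ``median + max(k * MAD, range_floor_uv)`` are flagged; the absolute
    floor guards the zero-MAD case of (near-)identical epochs.  Returns a
    boolean array, one entry per epoch.
    """
    if epochs.data.shape[0] == 0:
        return np.zeros(0, dtype=bool)
    filtered = _lowpass(epochs.data, epochs.sample_rate, lowpass_hz)
    ranges = (filtered.max(axis=2) - filtered.min(axis=2)).max(axis=1)
    med = np.median(ranges)
    mad = np.median(np.abs(ranges - med))
    threshold = med + max(k * mad, range_floor_uv)
    return ranges > threshold


def downsample(epochs: EpochArray, factor: int) -> EpochArray:
    """Decimate the time axis by an integer factor after anti-alias
    filtering (zero-phase FIR).  Window means of band-limited signals are
    preserved to within filter tolerance."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return epochs
    data = signal.decimate(epochs.data, factor, axis=-1, ftype="fir",
                           zero_phase=True)
    return EpochArray(data, epochs.channels, epochs.times_ms[::factor],
                      epochs.sample_rate / factor)
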