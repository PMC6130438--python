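"""Time-indexed gamma-band cross-power connectivity networks.

Each electrode is a node; the edge weight between electrodes ``i`` and
``j`` in a given time window is the band-restricted cross-power

    A_ij = sum over DFT bins f in [f_lo, f_hi] of P_i(f) * P_j(f) * df,

where ``P_i`` is the DFT magnitude of channel ``i`` within the window and
``df`` the bin width — a discrete quadrature of the cross-power integral
over the gamma band (30-90 Hz by default).  Matrices are symmetric and
nonnegative by construction; the diagonal (self-power) is zeroed since it
carries no inter-electrode information.

Windows slide over the analysis clip (2.5 s length, 1 s hop by default),
so a network is emitted roughly once per second.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError, DataError
from .preprocess import Recording

#: Gamma band in Hz; the band with the strongest ictal power modulation.
DEFAULT_BAND = (30.0, 90.0)
DEFAULT_WINDOW_S = 2.5
DEFAULT_HOP_S = 1.0

_CHUNK = 32  # windows FFT'd per batch, bounds peak memory


@dataclass
class AdjacencySequence:
    """Ordered sliding-window connectivity matrices for one clip.

    ``matrices`` has shape ``(T, N, N)``; ``window_times`` holds each
    window's center time in seconds from the clip start.
    """

    matrices: np.ndarray
    window_times: np.ndarray
    channel_labels: list[str]
    band: tuple[float, float]
    window_len_s: float
    hop_s: float

    def __len__(self) -> int:
        return self.matrices.shape[0]

    def save(self, path: str | Path) -> None:
        """Persist to a single ``.npz`` container with metadata."""
        np.savez_compressed(
            path,
            matrices=self.matrices,
            window_times=self.window_times,
            channel_labels=np.array(self.channel_labels),
            band=np.array(self.band),
            window_len_s=self.window_len_s,
            hop_s=self.hop_s,
        )

    @classmethod
    def load(cls, path: str | Path) -> "AdjacencySequence":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                matrices=data["matrices"],
                window_times=data["window_times"],
                channel_labels=[str(c) for c in data["channel_labels"]],
                band=tuple(data["band"]),
                window_len_s=float(data["window_len_s"]),
                hop_s=float(data["hop_s"]),
            )


def _check_band(band: tuple[float, float], fs: float) -> tuple[float, float]:
    lo, hi = float(band[0]), float(band[1])
    if not 0 < lo < hi < fs / 2:
        raise ConfigurationError(
            f"band {band} must lie strictly inside (0, {fs / 2}) Hz"
        )
    return lo, hi


def window_adjacency(segment: np.ndarray, fs: float,
                     band: tuple[float, float] = DEFAULT_BAND,
                     zero_diagonal: bool = True) -> np.ndarray:
    """Band-restricted cross-power adjacency of one window.

    Parameters
    ----------
    segment
        Channels x samples matrix (rectangular window, no taper).
    fs
        Sampling rate in Hz.
    band
        Inclusive frequency band (Hz) over which cross-power is summed.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2 or segment.shape[0] < 2:
        raise ConfigurationError("segment must be 2-D with >= 2 channels")
    lo, hi = _check_band(band, fs)
    n = segment.shape[1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= lo) & (freqs <= hi)
    power = np.abs(np.fft.rfft(segment, axis=1))[:, mask]
    df = fs / n
    adjacency = (power @ power.T) * df
    if zero_diagonal:
        np.fill_diagonal(adjacency, 0.0)
    return adjacency


def sliding_adjacency(rec: Recording,
                      band: tuple[float, float] = DEFAULT_BAND,
                      window_len_s: float = DEFAULT_WINDOW_S,
                      hop_s: float = DEFAULT_HOP_S,
                      zero_diagonal: bool = True) -> AdjacencySequence:
    """Adjacency matrices over a sliding window covering the whole clip.

    Windows are anchored at the clip start; incomplete trailing windows
    are dropped.  Bad channels are excluded.  The input is expected to be
    the preprocessed analysis clip (onset - 60 s to offset + 60 s).
    """
    data = rec.retained_samples()
    labels = rec.retained_labels
    if len(labels) < 2:
        raise ConfigurationError("need >= 2 retained channels")
    lo, hi = _check_band(band, rec.fs)
    wlen = int(round(window_len_s * rec.fs))
    hop = int(round(hop_s * rec.fs))
    if wlen < 2 or hop < 1:
        raise ConfigurationError("window/hop too small for sampling rate")
    n_samples = data.shape[1]
    if n_samples < wlen:
        raise DataError(
            f"clip of {n_samples / rec.fs:.2f} s shorter than one "
            f"{window_len_s} s window"
        )
    n_win = (n_samples - wlen) // hop + 1

    freqs = np.fft.rfftfreq(wlen, 1.0 / rec.fs)
    mask = (freqs >= lo) & (freqs <= hi)
    df = rec.fs / wlen
    n_ch = data.shape[0]
    matrices = np.empty((n_win, n_ch, n_ch))
    for start in range(0, n_win, _CHUNK):
        stop = min(start + _CHUNK, n_win)
        idx = (np.arange(start, stop)[:, None] * hop
               + np.arange(wlen)[None, :])
        windows = data[:, idx]                      # (ch, chunk, wlen)
        power = np.abs(np.fft.rfft(windows, axis=2))[:, :, mask]
        matrices[start:stop] = np.einsum(
            "iwf,jwf->wij", power, power
        ) * df
    if zero_diagonal:
        matrices[:, np.arange(n_ch), np.arange(n_ch)] = 0.0
    window_times = np.arange(n_win) * hop_s + window_len_s / 2.0
    return AdjacencySequence(
        matrices=matrices,
        window_times=window_times,
        channel_labels=labels,
        band=(lo, hi),
        window_len_s=window_len_s,
        hop_s=hop_s,
    )
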