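"""Normalized rank-centrality signatures and decile feature vectors.

Rank trajectories from different patients differ in length (seizure
duration) and amplitude (electrode count N).  Three normalizations make
them comparable:

1. time: resample every trajectory to 500 points on a normalized time
   axis t in [0, 1] (linear interpolation when stretching, uniform
   index-decimation when shrinking);
2. amplitude: divide ranks by N so values lie in (0, 1];
3. area: divide by the trapezoid area under the curve so each signal
   becomes a probability-density-like signature integrating to 1.

The feature vector of a signature is its ten decile locations: the
normalized times at which the cumulative integral reaches 0.1, 0.2, ...,
1.0.  Mass concentrated mid-clip (the ictal "arch") pulls interior
deciles toward the center, which is what separates epileptogenic-zone
electrodes in feature space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from .centrality import CentralityTimeSeries
from .exceptions import DataError

#: Common length of every time-normalized signature.
SIGNATURE_LENGTH = 500

#: Number of decile features per signature.
N_FEATURES = 10

#: Normalized time grid shared by all signatures.
TIME_GRID = np.linspace(0.0, 1.0, SIGNATURE_LENGTH)


@dataclass
class RankSignature:
    """Density-normalized rank-centrality curve of one electrode.

    ``density`` integrates to 1 over normalized time [0, 1] (trapezoid
    rule); ``features`` are the ten nondecreasing decile locations.
    ``onset_frac``/``offset_frac`` mark where the seizure sits on the
    normalized axis.
    """

    density: np.ndarray
    features: np.ndarray
    channel: str
    seizure_id: str = ""
    onset_frac: float = 0.0
    offset_frac: float = 1.0


def time_normalize(series: np.ndarray,
                   n_points: int = SIGNATURE_LENGTH) -> np.ndarray:
    """Resample a trajectory to a fixed number of points.

    Shorter signals are stretched by linear interpolation; longer ones are
    shrunk by uniform index-decimation (no anti-aliasing); a signal already
    at the target length passes through unchanged.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise DataError("need a 1-D series of length >= 2")
    T = series.size
    if T == n_points:
        return series.copy()
    if T < n_points:
        return np.interp(
            np.linspace(0.0, T - 1.0, n_points), np.arange(T), series
        )
    idx = np.round(np.linspace(0.0, T - 1.0, n_points)).astype(int)
    return series[idx]


def scale_ranks(rank_series: np.ndarray, n_electrodes: int) -> np.ndarray:
    """Scale ranks into (0, 1] by dividing by the electrode count."""
    if n_electrodes <= 0:
        raise ValueError("electrode count must be positive")
    return np.asarray(rank_series, dtype=float) / n_electrodes


def density_normalize(scaled: np.ndarray) -> np.ndarray:
    """Divide by the area under the curve so the signal integrates to 1.

    Integration uses the trapezoid rule on the uniform grid over [0, 1];
    the result is invariant to any positive rescaling of the input.
    """
    scaled = np.asarray(scaled, dtype=float)
    t = np.linspace(0.0, 1.0, scaled.size)
    area = trapezoid(scaled, t)
    if area <= 0:
        raise DataError("signal has nonpositive area under the curve")
    return scaled / area


def extract_deciles(density: np.ndarray) -> np.ndarray:
    """Decile locations of a normalized signature.

    Feature ``k`` (k = 1..10) is the smallest normalized time at which the
    cumulative trapezoid integral reaches k/10, interpolated linearly
    within a grid cell; the last feature is 1 by construction.
    """
    density = np.asarray(density, dtype=float)
    t = np.linspace(0.0, 1.0, density.size)
    cum = cumulative_trapezoid(density, t, initial=0.0)
    if abs(cum[-1] - 1.0) > 1e-6:
        raise ValueError(
            f"density integrates to {cum[-1]:.6f}, not 1; normalize first"
        )
    features = np.empty(N_FEATURES)
    for k in range(1, N_FEATURES + 1):
        target = k / N_FEATURES
        if target >= cum[-1]:
            features[k - 1] = 1.0
            continue
        i = int(np.searchsorted(cum, target, side="left"))
        if cum[i] == target or i == 0:
            features[k - 1] = t[i]
        else:
            frac = (target - cum[i - 1]) / (cum[i] - cum[i - 1])
            features[k - 1] = t[i - 1] + frac * (t[i] - t[i - 1])
    return features


def rank_signature(rank_series: np.ndarray, n_electrodes: int,
                   channel: str = "", seizure_id: str = "",
                   onset_frac: float = 0.0,
                   offset_frac: float = 1.0) -> RankSignature:
    """Full normalization chain: time -> amplitude -> area -> deciles."""
    resampled = time_normalize(rank_series)
    density = density_normalize(scale_ranks(resampled, n_electrodes))
    return RankSignature(
        density=density,
        features=extract_deciles(density),
        channel=channel,
        seizure_id=seizure_id,
        onset_frac=onset_frac,
        offset_frac=offset_frac,
    )


def compute_signatures(cts: CentralityTimeSeries,
                       onset_time: float, offset_time: float,
                       mode: str = "full",
                       seizure_id: str = "") -> list[RankSignature]:
    """Per-electrode signatures from a rank-centrality time series.

    Parameters
    ----------
    cts
        Window-by-channel centrality ranks.
    onset_time, offset_time
        Seizure onset/offset in the same time base as ``cts.window_times``
        (seconds from clip start).
    mode
        ``"full"`` (default) normalizes the whole clip, recording the
        seizure position via ``onset_frac``/``offset_frac``; ``"ictal"``
        restricts to windows within the seizure.  Training and inference
        must use the same mode.
    """
    if mode not in ("full", "ictal"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    times = cts.window_times
    ranks = cts.ranks
    if mode == "ictal":
        keep = (times >= onset_time) & (times <= offset_time)
        if keep.sum() < 2:
            raise DataError("fewer than 2 windows inside the ictal period")
        ranks = ranks[keep]
        onset_frac, offset_frac = 0.0, 1.0
    else:
        span = times[-1] - times[0]
        if span <= 0:
            raise DataError("need at least 2 windows for a signature")
        onset_frac = float(np.clip((onset_time - times[0]) / span, 0.0, 1.0))
        offset_frac = float(np.clip((offset_time - times[0]) / span, 0.0, 1.0))
    n_electrodes = ranks.shape[1]
    return [
        rank_signature(
            ranks[:, i], n_electrodes,
            channel=cts.channel_labels[i], seizure_id=seizure_id,
            onset_frac=onset_frac, offset_frac=offset_frac,
        )
        for i in range(n_electrodes)
    ]


def feature_matrix(signatures: list[RankSignature]) -> tuple[np.ndarray, list[str]]:
    """Stack signature feature vectors into an (n_channels, 10) matrix."""
    feats = np.array([s.features for s in signatures])
    labels = [s.channel for s in signatures]
    return feats, labels
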