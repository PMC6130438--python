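"""Eigenvector centrality of connectivity networks and its rank dynamics.

The eigenvector centrality (EVC) of a node is proportional to the sum of
the centralities of its neighbours weighted by edge strength: the leading
eigenvector of the (symmetric, nonnegative) adjacency matrix.  By the
Perron-Frobenius theorem this vector can be chosen elementwise nonnegative.

Per window the EVC vector is converted to ranks 1..N (1 = least central,
N = most central), which makes centrality trajectories comparable across
windows, electrodes and patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import AdjacencySequence

_SYMMETRY_RTOL = 1e-8
_RESIDUAL_RTOL = 1e-8


@dataclass
class CentralityTimeSeries:
    """Window-by-channel EVC values and their within-window ranks.

    ``evc`` rows are unit-L2, nonnegative; each ``ranks`` row is a
    permutation of 1..N.
    """

    evc: np.ndarray
    ranks: np.ndarray
    window_times: np.ndarray
    channel_labels: list[str]


def eigenvector_centrality(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector (unit L2, nonnegative) and eigenvalue of ``A``.

    ``A`` must be symmetric with nonnegative entries.  A flat all-zero
    matrix carries no information and maps to the uniform vector with
    eigenvalue 0.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    scale = np.abs(A).max()
    if scale == 0.0:
        n = A.shape[0]
        return np.full(n, 1.0 / np.sqrt(n)), 0.0
    if not np.allclose(A, A.T, rtol=_SYMMETRY_RTOL, atol=_SYMMETRY_RTOL * scale):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -_SYMMETRY_RTOL * scale:
        raise ValueError("adjacency must be nonnegative")
    eigvals, eigvecs = np.linalg.eigh(A)
    lam = float(eigvals[-1])
    v = eigvecs[:, -1]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    # Perron vector of a nonnegative matrix; clip eigensolver noise
    v = np.clip(v, 0.0, None)
    v /= np.linalg.norm(v)
    if np.linalg.norm(A @ v - lam * v) > _RESIDUAL_RTOL * max(lam, scale):
        raise ValueError("eigenvector residual above tolerance")
    return v, lam


def rank_centrality(evc: np.ndarray) -> np.ndarray:
    """Convert centrality values to ranks 1..N, 1 = smallest.

    Ties are broken by ascending channel index (stable), so the output is
    always a permutation of 1..N.
    """
    evc = np.asarray(evc, dtype=float)
    if evc.ndim != 1 or evc.size < 1:
        raise ValueError("evc must be a nonempty 1-D vector")
    return stats.rankdata(evc, method="ordinal").astype(int)


def centrality_time_series(adj: AdjacencySequence) -> CentralityTimeSeries:
    """EVC and rank trajectories for every window of an adjacency sequence."""
    n_win = len(adj)
    n_ch = adj.matrices.shape[1]
    evc = np.empty((n_win, n_ch))
    ranks = np.empty((n_win, n_ch), dtype=int)
    for t in range(n_win):
        v, _ = eigenvector_centrality(adj.matrices[t])
        evc[t] = v
        ranks[t] = rank_centrality(v)
    return CentralityTimeSeries(
        evc=evc,
        ranks=ranks,
        window_times=adj.window_times,
        channel_labels=adj.channel_labels,
    )
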