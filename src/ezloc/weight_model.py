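"""Quadrant-Gaussian electrode weighting in 2D principal-component space.

Decile feature vectors of all training electrodes are projected onto
their first two principal components.  Electrodes whose signatures show
the epileptogenic "arch" (low rank before the seizure, high during, low
after) cluster in a distinct region of this plane.  A weighting surface

    w(x, y) = exp(-alpha_q * (p - mu)^T Sigma_q^{-1} (p - mu)),

with ``q`` the quadrant of point ``p = (x, y)`` relative to the origin
``mu``, assigns every electrode a likelihood in (0, 1] of belonging to
the epileptogenic zone: 1 at the origin, decaying with the per-quadrant
Mahalanobis distance.

The origin is trained by grid search over a 100 x 100 partition of the
training scores' bounding box, maximizing the mean held-out degree of
agreement with clinical annotations under leave-one-patient-out folds.
Per-quadrant covariances are the sample covariances of the training
points falling in each quadrant (pooled-covariance fallback for sparse
quadrants, plus a small ridge against singularity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.decomposition import PCA

from .exceptions import TrainingError
from .signatures import N_FEATURES, RankSignature

DEFAULT_ALPHA_THRESHOLD = 0.9
DEFAULT_GRID_SHAPE = (100, 100)
DEFAULT_GRID_EXPAND = 0.10
DEFAULT_DECAY = 1.0
_MIN_QUADRANT_POINTS = 3
_RIDGE_SCALE = 1e-6


# ---------------------------------------------------------------------------
# Principal-component basis
# ---------------------------------------------------------------------------

@dataclass
class PCBasis:
    """Centering vector and the first two principal directions.

    Features share the common [0, 1] decile scale, so the basis centers
    but does not variance-scale.
    """

    mean: np.ndarray            # (10,)
    loadings: np.ndarray        # (10, 2), orthonormal columns
    explained_variance: np.ndarray = field(
        default_factory=lambda: np.zeros(2)
    )

    def project(self, features: np.ndarray) -> np.ndarray:
        """Project (M, 10) feature rows to (M, 2) PC scores."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != N_FEATURES:
            raise ValueError(
                f"expected {N_FEATURES}-dimensional features, "
                f"got {features.shape[1]}"
            )
        return (features - self.mean) @ self.loadings


def fit_pc_basis(features: np.ndarray) -> PCBasis:
    """Fit a centered 2-component PC basis to (M, 10) feature rows.

    Sign convention: within each component the loading of largest
    magnitude is made positive, so the basis is deterministic.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 3:
        raise TrainingError("need at least 3 feature observations")
    if features.shape[1] != N_FEATURES:
        raise TrainingError(f"features must be {N_FEATURES}-dimensional")
    if np.allclose(features, features[0]):
        raise TrainingError("all feature rows identical; no variance to fit")
    pca = PCA(n_components=2, svd_solver="full")
    pca.fit(features)
    loadings = pca.components_.T.copy()  # (10, 2)
    for k in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, k])), k] < 0:
            loadings[:, k] = -loadings[:, k]
    return PCBasis(
        mean=pca.mean_.copy(),
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
    )


# ---------------------------------------------------------------------------
# Quadrant geometry and Gaussian surface
# ---------------------------------------------------------------------------

def quadrant_of(points: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Quadrant index (0..3) of each point relative to the origin.

    Quadrants are numbered counterclockwise from the upper-right.  Points
    on a boundary belong to the smallest-index matching quadrant
    (Heaviside convention Theta(0) = 1), so the partition covers the
    plane with no overlap.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    dx = pts[:, 0] - origin[0]
    dy = pts[:, 1] - origin[1]
    q = np.full(pts.shape[0], 3, dtype=int)           # lower-right default
    q[(dx <= 0) & (dy <= 0)] = 2                       # lower-left
    q[(dx <= 0) & (dy >= 0)] = 1                       # upper-left
    q[(dx >= 0) & (dy >= 0)] = 0                       # upper-right
    return q


def fit_quadrant_covariances(points: np.ndarray,
                             origin: np.ndarray) -> np.ndarray:
    """Per-quadrant sample covariances of (M, 2) training scores.

    Quadrants holding fewer than 3 points fall back to the pooled sample
    covariance; a ridge of 1e-6 x mean variance guards against
    singularity.  Returns a (4, 2, 2) stack of SPD matrices.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < _MIN_QUADRANT_POINTS:
        raise TrainingError("need at least 3 points to fit covariances")
    pooled = np.cov(points.T)
    covs = np.empty((4, 2, 2))
    q = quadrant_of(points, np.asarray(origin, dtype=float))
    for i in range(4):
        sel = points[q == i]
        covs[i] = np.cov(sel.T) if sel.shape[0] >= _MIN_QUADRANT_POINTS \
            else pooled
    return _regularize(covs)


def _regularize(covs: np.ndarray) -> np.ndarray:
    covs = 0.5 * (covs + np.swapaxes(covs, 1, 2))
    mean_var = float(np.trace(covs.mean(axis=0)) / 2.0)
    if mean_var <= 0:
        mean_var = 1.0
    base_ridge = _RIDGE_SCALE * mean_var
    for i in range(covs.shape[0]):
        ridge = base_ridge
        while np.linalg.eigvalsh(covs[i])[0] <= ridge:
            covs[i] += ridge * np.eye(2)
            ridge *= 10
    return covs


def _inv_quadrant_covs(points: np.ndarray, origin: np.ndarray,
                       pooled: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form inverses of per-quadrant 2x2 covariances (search fast
    path; same fitting rules as :func:`fit_quadrant_covariances`)."""
    q = quadrant_of(points, origin)
    a = np.empty(4)
    b = np.empty(4)
    c = np.empty(4)
    for i in range(4):
        sel = points[q == i]
        if sel.shape[0] >= _MIN_QUADRANT_POINTS:
            d = sel - sel.mean(axis=0)
            n1 = sel.shape[0] - 1
            a[i] = d[:, 0] @ d[:, 0] / n1
            b[i] = d[:, 0] @ d[:, 1] / n1
            c[i] = d[:, 1] @ d[:, 1] / n1
        else:
            a[i], b[i], c[i] = pooled[0, 0], pooled[0, 1], pooled[1, 1]
    base_ridge = _RIDGE_SCALE * (a.mean() + c.mean()) / 2.0
    if base_ridge <= 0:
        base_ridge = _RIDGE_SCALE
    for i in range(4):
        ridge = base_ridge
        while (a[i] + c[i]
               - np.sqrt((a[i] - c[i]) ** 2 + 4 * b[i] ** 2)) / 2 <= ridge:
            a[i] += ridge
            c[i] += ridge
            ridge *= 10
    det = a * c - b * b
    return c / det, -b / det, a / det


@dataclass
class WeightModel:
    """Trained localization model: PC basis + quadrant-Gaussian surface."""

    basis: PCBasis
    origin: np.ndarray                 # (2,)
    covariances: np.ndarray            # (4, 2, 2)
    decay: np.ndarray = field(
        default_factory=lambda: np.full(4, DEFAULT_DECAY)
    )
    grid: dict = field(default_factory=dict)
    mode: str = "full"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(2)
        self.covariances = np.asarray(self.covariances, dtype=float)
        self.decay = np.asarray(self.decay, dtype=float).reshape(4)
        if self.covariances.shape != (4, 2, 2):
            raise ValueError("expected four 2x2 covariance matrices")
        if np.any(self.decay <= 0):
            raise ValueError("decay factors must be positive")
        self._inv = np.linalg.inv(self.covariances)

    def weight(self, points: np.ndarray) -> np.ndarray:
        """Evaluate the weighting surface at (M, 2) PC-space points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return _surface(pts, self.origin, self._inv, self.decay)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps({
            "basis": {
                "mean": self.basis.mean.tolist(),
                "loadings": self.basis.loadings.tolist(),
                "explained_variance": self.basis.explained_variance.tolist(),
            },
            "origin": self.origin.tolist(),
            "covariances": self.covariances.tolist(),
            "decay": self.decay.tolist(),
            "grid": self.grid,
            "mode": self.mode,
        }, indent=1)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source: str | Path) -> "WeightModel":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        doc = json.loads(source)
        return cls(
            basis=PCBasis(
                mean=np.array(doc["basis"]["mean"]),
                loadings=np.array(doc["basis"]["loadings"]),
                explained_variance=np.array(
                    doc["basis"]["explained_variance"]
                ),
            ),
            origin=np.array(doc["origin"]),
            covariances=np.array(doc["covariances"]),
            decay=np.array(doc["decay"]),
            grid=doc.get("grid", {}),
            mode=doc.get("mode", "full"),
        )


def _surface(pts: np.ndarray, origin: np.ndarray, inv: np.ndarray,
             decay: np.ndarray) -> np.ndarray:
    q = quadrant_of(pts, origin)
    d = pts - origin
    quad_form = np.einsum("mi,mij,mj->m", d, inv[q], d)
    return np.exp(-decay[q] * quad_form)


def evaluate_weight(model: WeightModel, point: Sequence[float]) -> float:
    """Weighting-surface value at a single PC-space point (in (0, 1])."""
    return float(model.weight(np.asarray(point, dtype=float))[0])


def electrode_likelihoods(model: WeightModel,
                          signatures: Iterable[RankSignature]) -> dict[str, float]:
    """Per-channel EZ likelihood for one seizure's signatures."""
    sigs = list(signatures)
    feats = np.array([s.features for s in sigs])
    values = model.weight(model.basis.project(feats))
    return {s.channel: float(v) for s, v in zip(sigs, values)}


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class SeizureFeatures:
    """Decile features of every analyzed electrode for one seizure."""

    seizure_id: str
    channel_labels: list[str]
    features: np.ndarray               # (n_channels, 10)


@dataclass
class PatientFeatures:
    """Feature data and clinical labels for one training/test patient."""

    patient_id: str
    seizures: list[SeizureFeatures]
    cez: frozenset[str]
    outcome: str
    center_id: str = ""

    def stacked_features(self) -> np.ndarray:
        return np.vstack([s.features for s in self.seizures])


@dataclass
class OriginSearch:
    """Grid-search diagnostics: candidate origins and their objectives."""

    origins: np.ndarray                # (n_candidates, 2), row-major order
    objectives: np.ndarray             # (n_candidates,)
    best_index: int


def _candidate_grid(scores: np.ndarray, grid_shape: tuple[int, int],
                    expand: float) -> tuple[np.ndarray, dict]:
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    lo = lo - expand * span
    hi = hi + expand * span
    nx, ny = grid_shape
    cx = lo[0] + (np.arange(nx) + 0.5) * (hi[0] - lo[0]) / nx
    cy = lo[1] + (np.arange(ny) + 0.5) * (hi[1] - lo[1]) / ny
    origins = np.stack(
        [np.repeat(cx, ny), np.tile(cy, nx)], axis=1
    )  # row-major: PC1 cell varies slowest
    meta = {"extent": [lo.tolist(), hi.tolist()],
            "shape": [int(nx), int(ny)]}
    return origins, meta


def train_origin(cohort: Sequence[PatientFeatures],
                 alpha: float = DEFAULT_ALPHA_THRESHOLD,
                 grid_shape: tuple[int, int] = DEFAULT_GRID_SHAPE,
                 grid_expand: float = DEFAULT_GRID_EXPAND,
                 decay: float | Sequence[float] = DEFAULT_DECAY,
                 mode: str = "full",
                 return_search: bool = False):
    """Train the weighting surface on an annotated patient cohort.

    For each candidate origin (the centers of a ``grid_shape`` partition
    of the training PC scores' bounding box, expanded by ``grid_expand``),
    quadrant covariances are re-fit on the training fold and the mean
    degree of agreement of held-out seizures at threshold ``alpha`` is
    measured under leave-one-patient-out cross-validation.  The candidate
    maximizing the objective wins; ties keep the first candidate in
    row-major grid order.  Returns the :class:`WeightModel` refit on the
    full cohort at the winning origin (and the search diagnostics when
    ``return_search`` is true).
    """
    if len(cohort) < 2:
        raise TrainingError("need at least 2 training patients")
    if all(len(p.cez) == 0 for p in cohort):
        raise TrainingError("no patient has an annotated CEZ set")
    decay = np.broadcast_to(np.asarray(decay, dtype=float), (4,)).copy()

    basis = fit_pc_basis(np.vstack([p.stacked_features() for p in cohort]))
    patient_scores = [
        [basis.project(s.features) for s in p.seizures] for p in cohort
    ]
    all_scores = np.vstack([np.vstack(ps) for ps in patient_scores])
    origins, grid_meta = _candidate_grid(all_scores, grid_shape, grid_expand)

    # Pre-assemble leave-one-patient-out folds.
    folds = []
    for held in range(len(cohort)):
        train_pts = np.vstack([
            np.vstack(patient_scores[i])
            for i in range(len(cohort)) if i != held
        ])
        heldout = []
        patient = cohort[held]
        if not patient.cez:
            continue
        for seiz, scores in zip(patient.seizures, patient_scores[held]):
            channels = set(seiz.channel_labels)
            cez = patient.cez & channels
            if not cez or cez == channels:
                continue  # agreement undefined for this seizure
            cez_mask = np.array(
                [c in cez for c in seiz.channel_labels], dtype=bool
            )
            heldout.append((scores, cez_mask))
        if heldout:
            folds.append((train_pts, heldout))
    if not folds:
        raise TrainingError("no fold has a scorable held-out seizure")

    # qf < -ln(alpha)/decay  <=>  exp(-decay * qf) > alpha
    with np.errstate(divide="ignore"):
        qf_threshold = -np.log(alpha) / decay if alpha > 0 \
            else np.full(4, np.inf)
    pooled_by_fold = [np.cov(train_pts.T) for train_pts, _ in folds]
    objectives = np.empty(origins.shape[0])
    for c, origin in enumerate(origins):
        doas = []
        for (train_pts, heldout), pooled in zip(folds, pooled_by_fold):
            ia, ib, ic = _inv_quadrant_covs(train_pts, origin, pooled)
            for scores, cez_mask in heldout:
                q = quadrant_of(scores, origin)
                d0 = scores[:, 0] - origin[0]
                d1 = scores[:, 1] - origin[1]
                qf = ia[q] * d0 * d0 + 2 * ib[q] * d0 * d1 + ic[q] * d1 * d1
                in_aez = qf < qf_threshold[q]
                # DOA = sensitivity minus false-positive rate
                doas.append(
                    in_aez[cez_mask].mean() - in_aez[~cez_mask].mean()
                )
        objectives[c] = float(np.mean(doas))
    best = int(np.argmax(objectives))  # argmax keeps first maximum

    model = WeightModel(
        basis=basis,
        origin=origins[best],
        covariances=fit_quadrant_covariances(all_scores, origins[best]),
        decay=decay,
        grid=grid_meta,
        mode=mode,
    )
    if return_search:
        return model, OriginSearch(
            origins=origins, objectives=objectives, best_index=best
        )
    return model
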