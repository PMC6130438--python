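"""End-to-end orchestration: recording -> features -> localization.

Chains the stages in the order the method runs: mains notch and common
average reference, clipping to onset - 60 s .. offset + 60 s, sliding
gamma-band cross-power networks, eigenvector-centrality ranks,
normalized decile signatures, and (given a trained weight model)
per-electrode likelihoods thresholded into a predicted EZ set scored
against the clinical annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from . import connectivity, preprocess
from .centrality import centrality_time_series
from .evaluation import LocalizationResult, score_localization
from .preprocess import Recording
from .signatures import RankSignature, compute_signatures, feature_matrix
from .synthetic_data import SyntheticCohort
from .weight_model import (
    PatientFeatures,
    SeizureFeatures,
    WeightModel,
    electrode_likelihoods,
    train_origin,
)


@dataclass
class PipelineConfig:
    """Stage parameters shared by training and inference."""

    band: tuple[float, float] = connectivity.DEFAULT_BAND
    window_len_s: float = connectivity.DEFAULT_WINDOW_S
    hop_s: float = connectivity.DEFAULT_HOP_S
    clip_pad_s: float = preprocess.DEFAULT_CLIP_PAD_S
    stop_band: tuple[float, float] = preprocess.DEFAULT_STOP_BAND
    apply_notch: bool = True
    apply_car: bool = True
    mode: str = "full"


def preprocess_recording(rec: Recording,
                         config: PipelineConfig | None = None) -> Recording:
    """Notch, re-reference and clip a raw recording (filter first)."""
    config = config or PipelineConfig()
    if config.apply_notch:
        rec = preprocess.notch_filter(rec, stop_band=config.stop_band)
    if config.apply_car:
        rec = preprocess.common_average_reference(rec)
    return preprocess.extract_clip(rec, pad_s=config.clip_pad_s)


def rank_signatures(rec: Recording, config: PipelineConfig | None = None,
                    seizure_id: str = "",
                    preprocessed: bool = False) -> list[RankSignature]:
    """Per-electrode rank signatures of one recording."""
    config = config or PipelineConfig()
    clip = rec if preprocessed else preprocess_recording(rec, config)
    adj = connectivity.sliding_adjacency(
        clip, band=config.band, window_len_s=config.window_len_s,
        hop_s=config.hop_s,
    )
    cts = centrality_time_series(adj)
    return compute_signatures(
        cts,
        onset_time=clip.onset_index / clip.fs,
        offset_time=clip.offset_index / clip.fs,
        mode=config.mode,
        seizure_id=seizure_id,
    )


def seizure_features(rec: Recording, config: PipelineConfig | None = None,
                     seizure_id: str = "") -> SeizureFeatures:
    """Decile feature matrix of one seizure recording."""
    sigs = rank_signatures(rec, config, seizure_id=seizure_id)
    feats, labels = feature_matrix(sigs)
    return SeizureFeatures(
        seizure_id=seizure_id, channel_labels=labels, features=feats
    )


def localize(rec: Recording, model: WeightModel, alpha: float,
             config: PipelineConfig | None = None,
             patient_id: str = "", seizure_id: str = "") -> LocalizationResult:
    """Run the full localization chain on one recording and score it."""
    config = config or PipelineConfig()
    if config.mode != model.mode:
        raise ValueError(
            f"pipeline mode {config.mode!r} differs from the mode the "
            f"model was trained with ({model.mode!r})"
        )
    sigs = rank_signatures(rec, config, seizure_id=seizure_id)
    likelihoods = electrode_likelihoods(model, sigs)
    return score_localization(
        likelihoods, alpha, rec.cez & frozenset(likelihoods),
        seizure_id=seizure_id, patient_id=patient_id,
        center_id=rec.center_id, outcome=rec.outcome,
    )


def cohort_features(cohort: SyntheticCohort,
                    config: PipelineConfig | None = None
                    ) -> list[PatientFeatures]:
    """Feature tables for every patient of a synthetic cohort.

    Recordings are materialized one at a time and discarded after
    feature extraction, keeping memory flat.
    """
    config = config or PipelineConfig()
    by_patient: dict[str, PatientFeatures] = {}
    for patient_id, seizure_id, rec, _planted in cohort.recordings():
        feats = seizure_features(rec, config, seizure_id=seizure_id)
        if patient_id not in by_patient:
            by_patient[patient_id] = PatientFeatures(
                patient_id=patient_id, seizures=[], cez=rec.cez,
                outcome=rec.outcome, center_id=rec.center_id,
            )
        by_patient[patient_id].seizures.append(feats)
    return list(by_patient.values())


@dataclass
class HoldoutExperiment:
    """Outcome of a train/test split on a synthetic cohort."""

    model: WeightModel
    train_patients: list[PatientFeatures]
    test_patients: list[PatientFeatures]
    results: list[LocalizationResult]

    def doas_by_outcome(self) -> tuple[list[float], list[float]]:
        success = [r.doa for r in self.results if r.outcome == "success"]
        failure = [r.doa for r in self.results if r.outcome == "failure"]
        return success, failure


def holdout_experiment(cohort: SyntheticCohort, n_train: int,
                       alpha: float = 0.9,
                       config: PipelineConfig | None = None,
                       grid_shape: tuple[int, int] = (100, 100),
                       features: Sequence[PatientFeatures] | None = None,
                       ) -> HoldoutExperiment:
    """Train on the first ``n_train`` patients, evaluate on the rest.

    Training patients are interleaved across outcomes (the cohort lists
    successes first), so both the training and held-out halves contain
    both outcome groups.  Pre-computed ``features`` (from
    :func:`cohort_features`) may be supplied to avoid reprocessing.
    """
    config = config or PipelineConfig()
    feats = list(features) if features is not None \
        else cohort_features(cohort, config)
    if not 0 < n_train < len(feats):
        raise ValueError("n_train must split the cohort in two")
    order = _interleaved_order(feats)
    train = [feats[i] for i in order[:n_train]]
    test = [feats[i] for i in order[n_train:]]

    model = train_origin(train, alpha=alpha, grid_shape=grid_shape,
                         mode=config.mode)

    results = []
    for patient in test:
        for seiz in patient.seizures:
            likelihoods = {
                c: float(v) for c, v in zip(
                    seiz.channel_labels,
                    model.weight(model.basis.project(seiz.features)),
                )
            }
            results.append(score_localization(
                likelihoods, alpha, patient.cez,
                seizure_id=seiz.seizure_id, patient_id=patient.patient_id,
                center_id=patient.center_id, outcome=patient.outcome,
            ))
    return HoldoutExperiment(
        model=model, train_patients=train, test_patients=test,
        results=results,
    )


def _interleaved_order(feats: Sequence[PatientFeatures]) -> list[int]:
    success = [i for i, p in enumerate(feats) if p.outcome == "success"]
    failure = [i for i, p in enumerate(feats) if p.outcome != "success"]
    order: list[int] = []
    for pair in zip(success, failure):
        order.extend(pair)
    longer = success if len(success) > len(failure) else failure
    order.extend(longer[min(len(success), len(failure)):])
    return order
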