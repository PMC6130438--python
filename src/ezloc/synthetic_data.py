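"""Synthetic multichannel iEEG cohorts with planted epileptogenic zones.

Each synthetic recording emulates a clinical seizure clip: 60 s of
pre-ictal data, an ictal segment, and 60 s of post-ictal data sampled at
1 kHz from ~80 electrodes.  Channels carry independent 1/f background
noise whose gamma-band power is comparable across channels, so
pre-ictal centrality ranks are exchangeable.  A shared narrowband
gamma (30-90 Hz) source is injected into a planted EZ channel subset
with a smooth raised-cosine gain envelope — zero before onset, peaking
mid-ictal, back to zero by offset — which produces the rank "arch":
planted channels become the network's most central nodes during the
seizure and recede afterwards.  Non-EZ channels receive the same source
at a smaller recruitment gain during the ictal period only.

Outcome modes control how the clinical annotation relates to the
planted truth:

* ``success`` — the annotated CEZ is the planted set (correct resection);
* ``failure`` — the CEZ is a random channel set disjoint from the
  planted source (mislocalization);
* ``no_coverage`` — no source is planted at all and the CEZ is a random
  set (the EZ was never covered by the implant); labeled ``failure``.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .exceptions import ConfigurationError
from .preprocess import Recording

GAMMA_BAND = (30.0, 90.0)


@dataclass
class SynthConfig:
    """Parameters of one synthetic seizure recording.

    ``coupling_gain`` is the peak amplitude of the shared gamma source
    injected into EZ channels, in units of the per-channel background
    noise RMS; ``recruit_gain`` is the (smaller) ictal gain into non-EZ
    channels.  ``noise_exponent`` is the spectral slope of the 1/f^a
    background.  A zero ``coupling_gain`` is the null control: no source
    is injected into any channel.
    """

    n_channels: int = 80
    fs: float = 1000.0
    pre_s: float = 60.0
    ictal_s: float = 120.0
    post_s: float = 60.0
    ez_size: int = 8
    coupling_gain: float = 6.0
    recruit_gain: float = 0.5
    noise_exponent: float = 1.0
    seed: int = 0
    outcome_mode: str = "success"
    center_id: str = "SYN"
    ez_channels: tuple[int, ...] | None = None
    cez_channels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.ez_size < self.n_channels:
            raise ConfigurationError("require 0 < ez_size < n_channels")
        if self.coupling_gain < 0 or self.recruit_gain < 0:
            raise ConfigurationError("gains must be nonnegative")
        if self.fs <= 2 * GAMMA_BAND[1]:
            raise ConfigurationError(
                f"fs must exceed {2 * GAMMA_BAND[1]} Hz to carry the "
                "gamma band"
            )
        if min(self.pre_s, self.ictal_s, self.post_s) <= 0:
            raise ConfigurationError("segment durations must be positive")
        if self.outcome_mode not in ("success", "failure", "no_coverage"):
            raise ConfigurationError(
                f"unknown outcome_mode {self.outcome_mode!r}"
            )


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float) -> np.ndarray:
    """Independent 1/f^a noise per channel, unit RMS."""
    white = rng.standard_normal((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=1) * shaping, n=n_samples,
                          axis=1)
    return shaped / shaped.std(axis=1, keepdims=True)


def _gamma_source(rng: np.random.Generator, n_samples: int,
                  fs: float) -> np.ndarray:
    """Shared narrowband gamma source, unit RMS."""
    sos = sp_signal.butter(4, GAMMA_BAND, btype="bandpass", fs=fs,
                           output="sos")
    src = sp_signal.sosfilt(sos, rng.standard_normal(n_samples))
    return src / src.std()


def _envelope(cfg: SynthConfig, n_samples: int) -> np.ndarray:
    """Raised-cosine gain envelope: 0 outside the seizure, 1 mid-ictal."""
    t = np.arange(n_samples) / cfg.fs
    onset, offset = cfg.pre_s, cfg.pre_s + cfg.ictal_s
    env = np.zeros(n_samples)
    ictal = (t >= onset) & (t < offset)
    phase = (t[ictal] - onset) / cfg.ictal_s
    env[ictal] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    return env


def generate_recording(cfg: SynthConfig) -> tuple[Recording, frozenset[str]]:
    """Generate one synthetic seizure clip.

    Returns the :class:`Recording` and the planted EZ channel labels
    (empty for ``no_coverage``).  The recording's ``cez`` annotation
    follows ``outcome_mode``; its ``outcome`` is ``"success"`` only for
    the success mode.
    """
    rng = np.random.default_rng(cfg.seed)
    n_samples = int(round((cfg.pre_s + cfg.ictal_s + cfg.post_s) * cfg.fs))
    labels = [f"CH{i + 1:03d}" for i in range(cfg.n_channels)]

    samples = _pink_noise(rng, cfg.n_channels, n_samples, cfg.noise_exponent)
    source = _gamma_source(rng, n_samples, cfg.fs)
    env = _envelope(cfg, n_samples)

    if cfg.ez_channels is not None:
        planted_idx = np.array(cfg.ez_channels, dtype=int)
    else:
        planted_idx = rng.choice(cfg.n_channels, size=cfg.ez_size,
                                 replace=False)
    planted_idx = np.sort(planted_idx)

    if cfg.outcome_mode == "no_coverage":
        planted = frozenset()
    else:
        # a zero coupling gain is the null control: no source anywhere,
        # but the designated EZ channels keep their identity
        if cfg.coupling_gain > 0:
            gains = np.full(cfg.n_channels, cfg.recruit_gain)
            gains[planted_idx] = cfg.coupling_gain
            # per-channel jitter keeps planted channels from identical
            gains = gains * rng.uniform(0.8, 1.2, cfg.n_channels)
            samples += gains[:, None] * env[None, :] * source[None, :]
        planted = frozenset(labels[i] for i in planted_idx)

    if cfg.outcome_mode == "success":
        cez = frozenset(labels[i] for i in planted_idx)
        outcome = "success"
    else:
        if cfg.cez_channels is not None:
            cez_idx = np.array(cfg.cez_channels, dtype=int)
        else:
            pool = np.setdiff1d(np.arange(cfg.n_channels), planted_idx)
            cez_idx = rng.choice(pool, size=cfg.ez_size, replace=False)
        cez = frozenset(labels[i] for i in np.sort(cez_idx))
        outcome = "failure"

    rec = Recording(
        samples=samples,
        fs=cfg.fs,
        channel_labels=labels,
        onset_index=int(round(cfg.pre_s * cfg.fs)),
        offset_index=int(round((cfg.pre_s + cfg.ictal_s) * cfg.fs)),
        cez=cez,
        outcome=outcome,
        center_id=cfg.center_id,
    )
    return rec, planted


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SynthPatient:
    """One synthetic patient: shared planted/annotated sets, >= 1 seizure."""

    patient_id: str
    seizure_configs: list[SynthConfig]
    outcome: str

    def seizure_ids(self) -> list[str]:
        return [f"{self.patient_id}_sz{k + 1}"
                for k in range(len(self.seizure_configs))]


@dataclass
class SyntheticCohort:
    """A labeled cohort; recordings are materialized on demand.

    Holding a full 16-patient, 80-channel cohort in memory would take
    gigabytes, so members store their generation configs and
    :meth:`recordings` regenerates each clip deterministically when
    iterated.
    """

    patients: list[SynthPatient]
    seed: int

    def recordings(self) -> Iterator[tuple[str, str, Recording, frozenset[str]]]:
        """Yield (patient_id, seizure_id, recording, planted_labels)."""
        for patient in self.patients:
            for sid, cfg in zip(patient.seizure_ids(),
                                patient.seizure_configs):
                rec, planted = generate_recording(cfg)
                yield patient.patient_id, sid, rec, planted

    def manifest(self) -> pd.DataFrame:
        rows = []
        for patient in self.patients:
            for sid, cfg in zip(patient.seizure_ids(),
                                patient.seizure_configs):
                rows.append({
                    "patient_id": patient.patient_id,
                    "seizure_id": sid,
                    "outcome": patient.outcome,
                    "outcome_mode": cfg.outcome_mode,
                    "n_channels": cfg.n_channels,
                    "ez_size": cfg.ez_size,
                    "seed": cfg.seed,
                    "fs": cfg.fs,
                    "pre_s": cfg.pre_s,
                    "ictal_s": cfg.ictal_s,
                    "post_s": cfg.post_s,
                    "center_id": cfg.center_id,
                })
        return pd.DataFrame(rows)

    def manifest_hash(self) -> str:
        csv = self.manifest().to_csv(index=False)
        return hashlib.sha256(csv.encode()).hexdigest()


def generate_cohort(n_patients: int, seed: int,
                    success_fraction: float = 0.5,
                    n_seizures: int = 2,
                    n_channels_range: tuple[int, int] = (76, 92),
                    ez_size_range: tuple[int, int] = (5, 12),
                    base_config: SynthConfig | None = None) -> SyntheticCohort:
    """Generate a reproducible labeled cohort.

    Channel counts and EZ sizes are drawn per patient from the given
    ranges (inclusive); ``round(n_patients * success_fraction)`` patients
    are success cases and the rest failures.  A patient's planted EZ and
    annotated CEZ are fixed across their seizures; only the noise seed
    varies between seizures.
    """
    if n_patients < 2:
        raise ConfigurationError("need at least 2 patients")
    if not 0 <= success_fraction <= 1:
        raise ConfigurationError("success_fraction must be in [0, 1]")
    base = base_config if base_config is not None else SynthConfig()
    rng = np.random.default_rng(seed)
    n_success = int(round(n_patients * success_fraction))
    patients = []
    for p in range(n_patients):
        outcome_mode = "success" if p < n_success else "failure"
        n_channels = int(rng.integers(n_channels_range[0],
                                      n_channels_range[1] + 1))
        ez_size = int(rng.integers(ez_size_range[0], ez_size_range[1] + 1))
        planted = np.sort(rng.choice(n_channels, size=ez_size,
                                     replace=False))
        pool = np.setdiff1d(np.arange(n_channels), planted)
        cez = planted if outcome_mode == "success" else np.sort(
            rng.choice(pool, size=ez_size, replace=False)
        )
        configs = [
            replace(
                base,
                n_channels=n_channels,
                ez_size=ez_size,
                seed=int(rng.integers(2 ** 31)),
                outcome_mode=outcome_mode,
                ez_channels=tuple(int(i) for i in planted),
                cez_channels=(None if outcome_mode == "success"
                              else tuple(int(i) for i in cez)),
            )
            for _ in range(n_seizures)
        ]
        patients.append(SynthPatient(
            patient_id=f"pt{p + 1:02d}",
            seizure_configs=configs,
            outcome="success" if outcome_mode == "success" else "failure",
        ))
    return SyntheticCohort(patients=patients, seed=seed)
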