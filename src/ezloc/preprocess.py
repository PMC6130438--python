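"""Loading, cleaning and referencing of multichannel iEEG seizure clips.

A :class:`Recording` bundles a channels-by-time voltage matrix with its
sampling rate, channel labels, electrographic seizure onset/offset, the
clinician-flagged bad channels, the clinically annotated epileptogenic-zone
(CEZ) electrode set and the surgical outcome label.

Two on-disk representations are supported:

* EDF (European Data Format) for the signals, read through :mod:`mne`.  A
  minimal plain-EDF writer is provided so synthetic cohorts can be persisted
  in the field's standard container.
* a plain numeric matrix: a CSV file whose header row holds the channel
  labels and whose rows are samples (one column per channel).

Either way, annotations travel in a JSON sidecar::

    {"fs": 1000.0, "onset_sec": 60.0, "offset_sec": 180.0,
     "bad_channels": [], "cez": ["CH001"], "outcome": "success",
     "center_id": "SYN"}

``fs`` is required for the CSV format and ignored for EDF (the EDF header
wins).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import AnnotationError, ConfigurationError, FormatError

#: Default mains stop band (Hz).  US data; set (49.5, 50.5) for 50 Hz mains.
DEFAULT_STOP_BAND = (59.5, 60.5)

#: Seconds of pre-onset / post-offset context kept around each seizure.
DEFAULT_CLIP_PAD_S = 60.0


@dataclass
class Recording:
    """An annotated multichannel iEEG clip.

    Attributes
    ----------
    samples
        Voltages, shape ``(n_channels, n_samples)``, arbitrary units.
    fs
        Sampling rate in Hz.
    channel_labels
        Unique channel names, one per row of ``samples``.
    onset_index, offset_index
        Sample indices of electrographic seizure onset and offset.
    bad_channels
        Clinician-flagged artifact channels; retained in ``samples`` but
        excluded from referencing and all downstream analysis.
    cez
        Clinically annotated epileptogenic-zone electrode labels.
    outcome
        ``"success"`` or ``"failure"`` surgical outcome, if known.
    center_id
        Identifier of the recording center.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    onset_index: int
    offset_index: int
    bad_channels: frozenset[str] = frozenset()
    cez: frozenset[str] = frozenset()
    outcome: str | None = None
    center_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 2-D channels x time matrix")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise FormatError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channel rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise FormatError("channel labels must be unique")
        if not self.fs > 0:
            raise FormatError("sampling rate must be positive")
        self.bad_channels = frozenset(self.bad_channels)
        self.cez = frozenset(self.cez)
        labelset = set(self.channel_labels)
        if not self.bad_channels <= labelset:
            raise AnnotationError("bad_channels not a subset of channel labels")
        if not self.cez <= labelset:
            raise AnnotationError("cez not a subset of channel labels")
        if not 0 <= self.onset_index < self.offset_index:
            raise AnnotationError(
                f"require 0 <= onset < offset, got "
                f"({self.onset_index}, {self.offset_index})"
            )
        if self.offset_index >= self.n_samples:
            raise AnnotationError("seizure offset beyond end of recording")
        if self.outcome is not None and self.outcome not in ("success", "failure"):
            raise AnnotationError(f"unknown outcome label {self.outcome!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def retained_labels(self) -> list[str]:
        """Channel labels that survive bad-channel exclusion, in row order."""
        return [c for c in self.channel_labels if c not in self.bad_channels]

    @property
    def retained_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.channel_labels)
             if c not in self.bad_channels],
            dtype=int,
        )

    def retained_samples(self) -> np.ndarray:
        """Samples of the non-bad channels, shape (n_retained, n_samples)."""
        return self.samples[self.retained_indices]


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _load_annotations(annotations: Mapping | str | Path) -> dict:
    if isinstance(annotations, (str, Path)):
        with open(annotations) as fh:
            annotations = json.load(fh)
    ann = dict(annotations)
    for key in ("onset_sec", "offset_sec"):
        if key not in ann:
            raise AnnotationError(f"annotation sidecar missing {key!r}")
    return ann


def read_recording(path: str | Path, annotations: Mapping | str | Path) -> Recording:
    """Load a recording from EDF or plain CSV plus its annotation sidecar.

    Parameters
    ----------
    path
        ``.edf`` file or CSV matrix (header = channel labels, rows = samples).
    annotations
        JSON sidecar path or an equivalent mapping; see module docstring.
    """
    path = Path(path)
    ann = _load_annotations(annotations)
    if path.suffix.lower() == ".edf":
        samples, fs, labels = _read_edf(path)
    else:
        with open(path) as fh:
            header = fh.readline().strip()
        labels = [c.strip() for c in header.split(",")]
        if len(set(labels)) != len(labels):
            raise FormatError("duplicate channel labels in matrix header")
        frame = pd.read_csv(path)
        samples = frame.to_numpy(dtype=float).T
        if "fs" not in ann:
            raise AnnotationError("CSV matrix format requires 'fs' in sidecar")
        fs = float(ann["fs"])
    onset = int(round(float(ann["onset_sec"]) * fs))
    offset = int(round(float(ann["offset_sec"]) * fs))
    if onset >= offset:
        raise AnnotationError(
            f"onset_sec must precede offset_sec "
            f"({ann['onset_sec']} >= {ann['offset_sec']})"
        )
    return Recording(
        samples=samples,
        fs=fs,
        channel_labels=labels,
        onset_index=onset,
        offset_index=offset,
        bad_channels=frozenset(ann.get("bad_channels", ())),
        cez=frozenset(ann.get("cez", ())),
        outcome=ann.get("outcome"),
        center_id=ann.get("center_id", ""),
    )


def write_recording(rec: Recording, path: str | Path,
                    annot_path: str | Path | None = None) -> None:
    """Persist a recording as EDF (``.edf``) or CSV matrix, plus sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        write_edf(path, rec.samples, rec.fs, rec.channel_labels)
    else:
        pd.DataFrame(rec.samples.T, columns=rec.channel_labels).to_csv(
            path, index=False
        )
    if annot_path is not None:
        sidecar = {
            "fs": rec.fs,
            "onset_sec": rec.onset_index / rec.fs,
            "offset_sec": rec.offset_index / rec.fs,
            "bad_channels": sorted(rec.bad_channels),
            "cez": sorted(rec.cez),
            "outcome": rec.outcome,
            "center_id": rec.center_id,
        }
        with open(annot_path, "w") as fh:
            json.dump(sidecar, fh, indent=1)


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = [str(c) for c in raw.ch_names]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate channel labels in EDF header")
    # MNE rescales EEG channels from the EDF physical unit (uV) to volts.
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), labels


def _edf_field(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        text = text[:width]
    return text.ljust(width).encode("ascii")


def _edf_number(x: float, width: int = 8) -> str:
    """Shortest decimal representation of x that fits the EDF field."""
    for prec in range(7, 0, -1):
        text = f"{x:.{prec}g}"
        if len(text) <= width:
            return text
    raise FormatError(f"cannot represent {x} in a {width}-char EDF field")


def write_edf(path: str | Path, samples: np.ndarray, fs: float,
              channel_labels: Sequence[str]) -> None:
    """Write a continuous plain-EDF file (16-bit, 1-second data records).

    The sampling rate must be a positive integer and the signal is
    zero-padded to a whole number of seconds.  Amplitudes are quantized to
    the 16-bit digital range of the per-channel physical extremum, the
    usual EDF precision loss.
    """
    samples = np.asarray(samples, dtype=float)
    n_channels, n_samples = samples.shape
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record, per signal
    n_records = int(np.ceil(n_samples / spr))
    padded = np.zeros((n_channels, n_records * spr))
    padded[:, :n_samples] = samples

    # quantize against the value as written in the header, not the exact one
    phys_max = np.array([
        float(_edf_number(m))
        for m in np.maximum(np.max(np.abs(padded), axis=1) * (1 + 1e-6), 1e-6)
    ])
    dig_max = 32767
    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate 01-JAN-2000 X X X", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (n_channels + 1), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(n_channels, 4),
    ])
    labels = [str(c) for c in channel_labels]
    per_signal = b"".join([
        b"".join(_edf_field(lab, 16) for lab in labels),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field("uV", 8) for _ in labels),
        b"".join(_edf_field(_edf_number(-m), 8) for m in phys_max),
        b"".join(_edf_field(_edf_number(m), 8) for m in phys_max),
        b"".join(_edf_field(-dig_max, 8) for _ in labels),
        b"".join(_edf_field(dig_max, 8) for _ in labels),
        b"".join(_edf_field("", 80) for _ in labels),
        b"".join(_edf_field(spr, 8) for _ in labels),
        b"".join(_edf_field("", 32) for _ in labels),
    ])
    # digital value d maps to physical d / dig_max * phys_max
    digital = np.clip(
        np.round(padded / phys_max[:, None] * dig_max), -dig_max, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# Filtering and referencing
# ---------------------------------------------------------------------------

def notch_filter(rec: Recording, stop_band: tuple[float, float] = DEFAULT_STOP_BAND,
                 order: int = 4) -> Recording:
    """Zero-phase Butterworth band-stop filter around the mains frequency.

    An order-4 Butterworth band-stop prototype is applied forward and
    backward (``sosfiltfilt``), cancelling phase distortion and squaring
    the magnitude response.
    """
    lo, hi = stop_band
    if not 0 < lo < hi:
        raise ConfigurationError(f"invalid stop band {stop_band}")
    if rec.fs <= 2 * hi:
        raise ConfigurationError(
            f"sampling rate {rec.fs} Hz too low for stop band up to {hi} Hz"
        )
    sos = signal.butter(order, stop_band, btype="bandstop", fs=rec.fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    return replace(rec, samples=filtered)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous mean over retained channels.

    The reference is computed over non-bad channels only and subtracted
    from those channels; bad channels are carried through untouched (they
    stay flagged and are dropped from downstream analysis).
    """
    idx = rec.retained_indices
    if idx.size < 2:
        raise ConfigurationError(
            "common average reference needs at least 2 retained channels"
        )
    out = rec.samples.copy()
    ref = out[idx].mean(axis=0)
    out[idx] -= ref
    return replace(rec, samples=out)


def extract_clip(rec: Recording, pad_s: float = DEFAULT_CLIP_PAD_S) -> Recording:
    """Clip the recording to [onset - pad, offset + pad].

    Truncated at the record boundaries with a warning, since some clinical
    clips start less than ``pad_s`` seconds before onset.
    """
    pad = int(round(pad_s * rec.fs))
    start = rec.onset_index - pad
    stop = rec.offset_index + pad
    if start < 0 or stop > rec.n_samples:
        warnings.warn(
            "analysis clip truncated at record boundary "
            f"(wanted [{start}, {stop}) of {rec.n_samples} samples)",
            stacklevel=2,
        )
    start = max(start, 0)
    stop = min(stop, rec.n_samples)
    return replace(
        rec,
        samples=rec.samples[:, start:stop],
        onset_index=rec.onset_index - start,
        offset_index=rec.offset_index - start,
    )
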