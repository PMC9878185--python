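"""EDF ingestion and fixed-length epoching.

Recordings are loaded through MNE's EDF reader, mapped onto the canonical
19-lead montage (reference leads and extras dropped), and cut into
contiguous non-overlapping epochs — 6 s by default, so a 20-min recording
yields 200 epochs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .montage import CHANNELS, N_CHANNELS, normalize_label

__all__ = ["EEGRecording", "EpochSet", "read_edf", "segment_epochs"]


@dataclass
class EEGRecording:
    """A multichannel scalp EEG in the canonical montage.

    data is [19 x samples] in microvolts; channel order is fixed to
    :data:`epicog.montage.CHANNELS`.
    """

    subject_id: str
    sampling_rate_hz: float
    data: np.ndarray
    channel_labels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data must be [{len(self.channel_labels)} x samples], got {self.data.shape}"
            )
        if tuple(self.channel_labels) != CHANNELS:
            raise ValueError("channel_labels must be the canonical montage order")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class EpochSet:
    """Contiguous fixed-length epochs cut from one recording.

    epochs is [n_epochs x 19 x epoch_samples]; n_epochs is the N of the
    across-epoch phase-locking estimator downstream.
    """

    subject_id: str
    sampling_rate_hz: float
    epoch_length_s: float
    epochs: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3 or self.epochs.shape[1] != N_CHANNELS:
            raise ValueError(f"epochs must be [n x {N_CHANNELS} x samples], got {self.epochs.shape}")
        expected = int(round(self.epoch_length_s * self.sampling_rate_hz))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epochs.shape[2]} samples != "
                f"{self.epoch_length_s} s at {self.sampling_rate_hz} Hz ({expected})"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def save(self, path: str | Path) -> None:
        """Export as a .npy array plus a JSON sidecar with the metadata."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.epochs)
        sidecar = {
            "subject_id": self.subject_id,
            "sampling_rate_hz": self.sampling_rate_hz,
            "epoch_length_s": self.epoch_length_s,
            "n_epochs": self.n_epochs,
            "channels": list(CHANNELS),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_edf(
    path: str | Path,
    montage_map: dict[str, str] | None = None,
    subject_id: str | None = None,
    max_duration_s: float | None = None,
) -> EEGRecording:
    """Read an EDF/EDF+ file into the canonical 19-channel montage.

    Channel labels are resolved through :func:`epicog.montage.normalize_label`
    (optionally extended by ``montage_map``); reference leads (A1/A2) and any
    channel that maps to no canonical lead are dropped, and the survivors are
    reordered into canonical order. Data are returned in microvolts.

    Parameters
    ----------
    montage_map
        Optional raw-label -> canonical-name aliases for vendor dialects.
    max_duration_s
        If given, keep only the first ``max_duration_s`` seconds (e.g. 1200
        to truncate long sessions to 20 min).
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    canonical_to_raw: dict[str, str] = {}
    for lbl in raw.ch_names:
        canon = normalize_label(lbl, montage_map)
        if canon is not None and canon not in canonical_to_raw:
            canonical_to_raw[canon] = lbl
    missing = [ch for ch in CHANNELS if ch not in canonical_to_raw]
    if missing:
        raise ValueError(f"EDF file {path.name} is missing canonical channel(s): {', '.join(missing)}")

    sfreqs = {float(raw.info["sfreq"])}
    if len(sfreqs) != 1:
        raise ValueError(f"inconsistent sampling rates in {path.name}: {sorted(sfreqs)}")
    rate = sfreqs.pop()

    order = [canonical_to_raw[ch] for ch in CHANNELS]
    data = raw.get_data(picks=order) * 1e6  # MNE returns volts for EEG
    if max_duration_s is not None:
        data = data[:, : int(round(max_duration_s * rate))]
    return EEGRecording(subject_id=subject_id or path.stem, sampling_rate_hz=rate, data=data)


def segment_epochs(rec: EEGRecording, epoch_length_s: float = 6.0) -> EpochSet:
    """Cut a recording into contiguous non-overlapping epochs.

    Epoch k covers samples [k*L, (k+1)*L) with L = epoch_length_s * rate;
    the trailing remainder shorter than one epoch is discarded.
    """
    if epoch_length_s <= 0:
        raise ValueError("epoch_length_s must be positive")
    L = int(round(epoch_length_s * rec.sampling_rate_hz))
    n = rec.n_samples // L
    if n < 1:
        raise ValueError(
            f"recording of {rec.duration_s:.2f} s is shorter than one {epoch_length_s} s epoch"
        )
    trimmed = rec.data[:, : n * L]
    epochs = trimmed.reshape(N_CHANNELS, n, L).transpose(1, 0, 2).copy()
    return EpochSet(
        subject_id=rec.subject_id,
        sampling_rate_hz=rec.sampling_rate_hz,
        epoch_length_s=epoch_length_s,
        epochs=epochs,
    )
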