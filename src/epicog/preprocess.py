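"""Broadband filtering, amplitude-based epoch rejection, and band splitting.

All filters are 4th-order Butterworth band-passes applied forward-backward
(zero-phase), so downstream instantaneous-phase estimates are not biased by
filter delay. The four analysis bands follow the clinical convention
delta 1-4 Hz, theta 4-7 Hz, alpha 8-13 Hz, beta 14-30 Hz; the 7-8 Hz gap is
kept deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import EEGRecording, EpochSet

__all__ = [
    "BandDefinition",
    "BandEpochSet",
    "DEFAULT_BANDS",
    "broadband_filter",
    "reject_epochs",
    "band_decompose",
]

FILTER_ORDER = 4


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [low_hz, high_hz]."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band edges {self.low_hz}-{self.high_hz} Hz")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 14.0, 30.0),
)

BAND_NAMES = tuple(b.name for b in DEFAULT_BANDS)


@dataclass
class BandEpochSet:
    """Epochs of one subject restricted to one narrow band."""

    subject_id: str
    band: BandDefinition
    sampling_rate_hz: float
    epoch_length_s: float
    epochs: np.ndarray  # [n_epochs x 19 x samples], narrowband

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def _bandpass_sos(low_hz: float, high_hz: float, rate_hz: float) -> np.ndarray:
    nyq = rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"band {low_hz}-{high_hz} Hz invalid for sampling rate {rate_hz} Hz (Nyquist {nyq})"
        )
    return signal.butter(FILTER_ORDER, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")


def zero_phase_bandpass(data: np.ndarray, low_hz: float, high_hz: float, rate_hz: float) -> np.ndarray:
    """Forward-backward Butterworth band-pass along the last axis."""
    sos = _bandpass_sos(low_hz, high_hz, rate_hz)
    return signal.sosfiltfilt(sos, data, axis=-1)


def broadband_filter(rec: EEGRecording, low_hz: float = 0.5, high_hz: float = 30.0) -> EEGRecording:
    """Zero-phase band-pass of the continuous recording (default 0.5-30 Hz)."""
    filtered = zero_phase_bandpass(rec.data, low_hz, high_hz, rec.sampling_rate_hz)
    return EEGRecording(
        subject_id=rec.subject_id, sampling_rate_hz=rec.sampling_rate_hz, data=filtered
    )


def reject_epochs(es: EpochSet, abs_amp_threshold_uv: float) -> EpochSet:
    """Drop epochs whose peak absolute amplitude on any channel exceeds the threshold.

    A crude artifact gate for gross movement/electrode transients; order of
    surviving epochs is preserved.
    """
    if not abs_amp_threshold_uv > 0:
        raise ValueError("abs_amp_threshold_uv must be positive")
    peak = np.abs(es.epochs).max(axis=(1, 2))
    keep = peak <= abs_amp_threshold_uv
    if not keep.any():
        raise ValueError(
            f"all {es.n_epochs} epochs exceed {abs_amp_threshold_uv} uV; "
            "review the rejection threshold"
        )
    return EpochSet(
        subject_id=es.subject_id,
        sampling_rate_hz=es.sampling_rate_hz,
        epoch_length_s=es.epoch_length_s,
        epochs=es.epochs[keep],
    )


def band_decompose(
    es: EpochSet, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> dict[str, BandEpochSet]:
    """Zero-phase band-pass each epoch into every requested band.

    Returns a dict keyed by band name; epoch counts and shapes are preserved.
    """
    out: dict[str, BandEpochSet] = {}
    for band in bands:
        narrow = zero_phase_bandpass(es.epochs, band.low_hz, band.high_hz, es.sampling_rate_hz)
        out[band.name] = BandEpochSet(
            subject_id=es.subject_id,
            band=band,
            sampling_rate_hz=es.sampling_rate_hz,
            epoch_length_s=es.epoch_length_s,
            epochs=narrow,
        )
    return out
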