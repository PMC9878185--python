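"""Hilbert-phase extraction and phase-locking-value (PLV) connectivity.

For a channel pair, the PLV at time point t pools the phase difference
Delta-theta(t, n) across the N epochs:

    PLV(t) = (1/N) | sum_{n=1..N} exp(i * Delta-theta(t, n)) |

so PLV = 1 means the phase difference is identical in every epoch
(perfect locking) and PLV = 0 means it is uniformly spread on the unit
circle. The scalar feature per pair is the mean of PLV(t) over the epoch
interior; the first and last ``edge_trim_s`` seconds are excluded because
the Hilbert transform distorts phase near epoch edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .montage import CHANNELS, CHANNEL_PAIRS, N_CHANNELS, N_PAIRS
from .preprocess import BAND_NAMES, BandEpochSet

__all__ = [
    "PhaseEpochSet",
    "PLVMatrix",
    "PLVFeatureSet",
    "instantaneous_phase",
    "plv_pair",
    "plv_matrix",
    "vectorize",
    "plv_feature_names",
]

DEFAULT_EDGE_TRIM_S = 0.5


@dataclass
class PhaseEpochSet:
    """Instantaneous phase of one band's epochs, wrapped to (-pi, pi]."""

    subject_id: str
    band_name: str
    sampling_rate_hz: float
    phases: np.ndarray  # [n_epochs x 19 x samples], radians

    @property
    def n_epochs(self) -> int:
        return self.phases.shape[0]


@dataclass
class PLVMatrix:
    """Symmetric 19x19 PLV matrix for one subject and band; diagonal is 1."""

    subject_id: str
    band_name: str
    values: np.ndarray
    n_epochs_used: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_CHANNELS, N_CHANNELS):
            raise ValueError(f"PLV matrix must be {N_CHANNELS}x{N_CHANNELS}, got {v.shape}")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=CHANNELS, columns=CHANNELS)


@dataclass
class PLVFeatureSet:
    """Per-band PLV matrices plus their 684-long named vectorization."""

    subject_id: str
    matrices: dict[str, PLVMatrix]
    vector: pd.Series  # 4 bands x 171 pairs, canonical names "theta_T5-T6"


def plv_feature_names(bands: tuple[str, ...] = BAND_NAMES) -> list[str]:
    """Canonical feature names: band prefix + channel pair, 171 per band."""
    return [f"{band}_{a}-{b}" for band in bands for a, b in CHANNEL_PAIRS]


def instantaneous_phase(bes: BandEpochSet) -> PhaseEpochSet:
    """Angle of the analytic signal per channel per epoch.

    Valid as a phase estimator only because the input is narrowband.
    """
    analytic = hilbert(bes.epochs, axis=-1)
    return PhaseEpochSet(
        subject_id=bes.subject_id,
        band_name=bes.band.name,
        sampling_rate_hz=bes.sampling_rate_hz,
        phases=np.angle(analytic),
    )


def _trim_slice(n_samples: int, rate_hz: float, edge_trim_s: float) -> slice:
    k = int(round(edge_trim_s * rate_hz))
    if 2 * k >= n_samples:
        raise ValueError(
            f"edge_trim_s={edge_trim_s} removes all {n_samples} samples of the epoch"
        )
    return slice(k, n_samples - k)


def plv_pair(
    phase_a: np.ndarray,
    phase_b: np.ndarray,
    rate_hz: float,
    edge_trim_s: float = DEFAULT_EDGE_TRIM_S,
) -> float:
    """PLV between two per-epoch phase series, each [n_epochs x samples].

    Computes PLV(t) across epochs at every retained time point and returns
    its mean over the epoch interior. Result lies in [0, 1].
    """
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape or phase_a.ndim != 2:
        raise ValueError(f"phase series shapes differ: {phase_a.shape} vs {phase_b.shape}")
    sl = _trim_slice(phase_a.shape[1], rate_hz, edge_trim_s) if edge_trim_s > 0 else slice(None)
    dphi = phase_a[:, sl] - phase_b[:, sl]
    plv_t = np.abs(np.exp(1j * dphi).mean(axis=0))  # across epochs, per t
    return float(plv_t.mean())


def plv_matrix(
    pes: PhaseEpochSet,
    edge_trim_s: float = DEFAULT_EDGE_TRIM_S,
    max_epochs: int | None = None,
) -> PLVMatrix:
    """All 171 pairwise PLVs as a symmetric matrix with unit diagonal.

    ``max_epochs`` deterministically keeps the first k epochs only (the
    80-segment analysis variant); default uses every epoch.
    """
    phases = pes.phases
    if max_epochs is not None:
        phases = phases[:max_epochs]
    n_epochs = phases.shape[0]
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    sl = _trim_slice(phases.shape[2], pes.sampling_rate_hz, edge_trim_s) if edge_trim_s > 0 else slice(None)
    phasors = np.exp(1j * phases[:, :, sl])  # [n x 19 x t]
    values = np.eye(N_CHANNELS)
    for i in range(N_CHANNELS):
        # mean over epochs of the cross phasor, magnitude per t, mean over t
        cross = (phasors[:, i + 1 :, :] * np.conj(phasors[:, [i], :])).mean(axis=0)
        values[i, i + 1 :] = np.abs(cross).mean(axis=-1)
    values = np.maximum(values, values.T)
    return PLVMatrix(
        subject_id=pes.subject_id,
        band_name=pes.band_name,
        values=values,
        n_epochs_used=n_epochs,
    )


def vectorize(matrices: dict[str, PLVMatrix], subject_id: str | None = None) -> PLVFeatureSet:
    """Flatten the four band matrices' upper triangles into one named vector.

    171 entries per band in canonical pair order, 684 total.
    """
    missing = [b for b in BAND_NAMES if b not in matrices]
    if missing:
        raise ValueError(f"missing band matrix/matrices: {missing}")
    iu = np.triu_indices(N_CHANNELS, k=1)
    values = np.concatenate([matrices[b].values[iu] for b in BAND_NAMES])
    names = plv_feature_names()
    assert len(values) == 4 * N_PAIRS == len(names)
    sid = subject_id or next(iter(matrices.values())).subject_id
    return PLVFeatureSet(
        subject_id=sid,
        matrices=dict(matrices),
        vector=pd.Series(values, index=names, name=sid),
    )
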