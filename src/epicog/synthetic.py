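"""Synthetic two-group cohorts: phase-coupled EEG plus clinical tables.

The generator emulates the study conditions end to end with known ground
truth. Each subject's EEG is a sum of a 1/f background, independent
narrowband oscillations per channel and band, and — for each configured
coupling — a shared narrowband carrier injected into one channel pair.
The first channel of a coupled pair receives a von Mises(kappa) phase
offset redrawn once per 6-s epoch, so the across-epoch phase difference of
the pair is exactly von Mises distributed and the expected PLV equals the
mean resultant length I1(kappa)/I0(kappa) — the calibration law every
pipeline stage is tested against.

Two generation levels share this probabilistic model:

* :func:`generate_eeg` synthesizes full 19-channel waveforms (used to
  exercise filtering, Hilbert phase and the PLV estimator);
* :func:`simulate_plv_features` draws the per-epoch phase differences
  directly and applies the PLV estimator, skipping waveform synthesis —
  cheap enough for cohort-scale classification experiments.

Clinical tables are drawn per group from configurable category
frequencies and continuous moments whose defaults follow a 55 (CON) / 76
(CI) epilepsy cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import i0, i1

from .clinical import ClinicalRecord
from .connectivity import plv_feature_names
from .io import EEGRecording
from .montage import CHANNELS, N_CHANNELS, channel_index, pair_name
from .preprocess import DEFAULT_BANDS, BandDefinition

__all__ = [
    "CouplingSpec",
    "CohortConfig",
    "DEFAULT_COUPLINGS",
    "expected_plv",
    "generate_eeg",
    "generate_clinical",
    "simulate_plv_features",
    "write_fixture_edf",
]

_BANDS = {b.name: b for b in DEFAULT_BANDS}

EPOCH_LENGTH_S = 6.0


def expected_plv(kappa: float) -> float:
    """Mean resultant length of a von Mises(kappa): I1(kappa)/I0(kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    if kappa > 500:  # asymptotic form; i0 overflows
        return 1.0 - 1.0 / (2 * kappa) - 1.0 / (8 * kappa**2)
    return float(i1(kappa) / i0(kappa))


@dataclass(frozen=True)
class CouplingSpec:
    """A pairwise phase coupling implanted in one band.

    kappa_con / kappa_ci are von Mises concentrations of the pair's phase
    difference for the two groups; expected group PLV is I1(k)/I0(k).
    """

    band: str
    pair: tuple[str, str]
    kappa_con: float
    kappa_ci: float

    def __post_init__(self) -> None:
        if self.band not in _BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        a, b = self.pair
        if channel_index(a) == channel_index(b):
            raise ValueError("coupling channels must be distinct")
        if self.kappa_con < 0 or self.kappa_ci < 0:
            raise ValueError("kappa must be non-negative")

    @property
    def feature_name(self) -> str:
        return f"{self.band}_{pair_name(*self.pair)}"

    def kappa(self, label: str) -> float:
        return self.kappa_con if label == "CON" else self.kappa_ci


#: Default implanted contrast: five disjoint theta-band pairs with a
#: moderate concentration gap between groups.
DEFAULT_COUPLINGS: tuple[CouplingSpec, ...] = tuple(
    CouplingSpec("theta", pair, kappa_con=4.0, kappa_ci=1.0)
    for pair in (("Fp1", "Fz"), ("T5", "T6"), ("P3", "F4"), ("Fp2", "T4"), ("C3", "Pz"))
)

#: Per-group clinical distributions: category probabilities as observed
#: frequencies in a 55/76 two-group epilepsy cohort; continuous features
#: as (mean, SD) in years.
DEFAULT_CLINICAL_SPEC: dict[str, dict] = {
    "age_first_onset_y": {"kind": "continuous", "CON": (18.76, 11.02), "CI": (20.71, 14.74)},
    "years_since_onset": {"kind": "continuous", "CON": (7.44, 7.79), "CI": (10.63, 8.14)},
    "gender": {"kind": "binary", "CON": 24 / 55, "CI": 39 / 76, "values": ("M", "F")},
    "family_history": {"kind": "binary", "CON": 2 / 55, "CI": 5 / 76},
    "head_surgery_trauma": {"kind": "binary", "CON": 6 / 55, "CI": 17 / 76},
    "cns_infection": {"kind": "binary", "CON": 8 / 55, "CI": 18 / 76},
    "perinatal_injury": {"kind": "binary", "CON": 4 / 55, "CI": 8 / 76},
    "tle": {"kind": "binary", "CON": 27 / 55, "CI": 48 / 76},
    "mri_abnormal": {"kind": "binary", "CON": 28 / 55, "CI": 51 / 76},
    "hippocampal_atrophy_sclerosis": {"kind": "binary", "CON": 14 / 55, "CI": 37 / 76},
    "seizure_type": {
        "kind": "categorical",
        "categories": ("generalized", "focal", "both"),
        "CON": (13 / 55, 7 / 55, 35 / 55),
        "CI": (21 / 76, 9 / 76, 46 / 76),
    },
    "status_epilepticus": {"kind": "binary", "CON": 4 / 55, "CI": 15 / 76},
    "gtcs": {"kind": "binary", "CON": 45 / 55, "CI": 67 / 76},
    "seizure_frequency": {
        "kind": "categorical",
        "categories": ("rare", "occasional", "frequent"),
        "CON": (17 / 55, 15 / 55, 23 / 55),
        "CI": (12 / 76, 11 / 76, 53 / 76),
    },
    "asm_class_ge2": {"kind": "binary", "CON": 18 / 55, "CI": 41 / 76},
    "vpa": {"kind": "binary", "CON": 17 / 55, "CI": 40 / 76},
    "pht": {"kind": "binary", "CON": 1 / 55, "CI": 2 / 76},
    "tpm": {"kind": "binary", "CON": 3 / 55, "CI": 4 / 76},
    "aura": {"kind": "binary", "CON": 22 / 55, "CI": 24 / 76},
    "anxiety": {
        "kind": "categorical",
        "categories": ("none", "possible", "definitely", "definitely_obvious"),
        "CON": (14 / 55, 13 / 55, 25 / 55, 3 / 55),
        "CI": (12 / 76, 21 / 76, 35 / 76, 8 / 76),
    },
    "depression": {
        "kind": "categorical",
        "categories": ("none", "possible", "definitely"),
        "CON": (23 / 55, 31 / 55, 1 / 55),
        "CI": (25 / 76, 48 / 76, 3 / 76),
    },
    "education": {
        "kind": "categorical",
        "categories": ("<=6y", "7-9y", "10-12y", ">=13y"),
        "CON": (1 / 55, 11 / 55, 15 / 55, 28 / 55),
        "CI": (23 / 76, 18 / 76, 19 / 76, 16 / 76),
    },
}


@dataclass
class CohortConfig:
    """Everything needed to draw one reproducible synthetic cohort."""

    seed: int
    n_con: int = 55
    n_ci: int = 76
    duration_s: float = 1200.0
    rate_hz: float = 256.0
    couplings: tuple[CouplingSpec, ...] = DEFAULT_COUPLINGS
    kappa_spread: float = 0.0  # lognormal sigma on kappa per subject & coupling
    background_rms_uv: float = 10.0
    noise_exponent: float = 1.0
    band_rms_uv: dict[str, float] = field(
        default_factory=lambda: {"delta": 8.0, "theta": 6.0, "alpha": 8.0, "beta": 5.0}
    )
    coupling_amp_uv: float = 80.0
    clinical_spec: dict[str, dict] = field(default_factory=lambda: dict(DEFAULT_CLINICAL_SPEC))

    def __post_init__(self) -> None:
        if self.n_con <= 0 or self.n_ci <= 0:
            raise ValueError("group sizes must be positive")
        for spec in self.couplings:
            for ch in spec.pair:
                channel_index(ch)  # raises on unknown channel
        for name, entry in self.clinical_spec.items():
            if entry["kind"] == "categorical":
                for g in ("CON", "CI"):
                    if abs(sum(entry[g]) - 1.0) > 1e-9:
                        raise ValueError(f"probabilities for {name!r}/{g} do not sum to 1")

    @property
    def n_subjects(self) -> int:
        return self.n_con + self.n_ci

    @property
    def n_epochs(self) -> int:
        return int(self.duration_s // EPOCH_LENGTH_S)

    def label_of(self, subject_index: int) -> str:
        if not 0 <= subject_index < self.n_subjects:
            raise ValueError(f"subject_index {subject_index} out of range")
        return "CON" if subject_index < self.n_con else "CI"

    def subject_id(self, subject_index: int) -> str:
        return f"S{subject_index:03d}"

    def subject_rng(self, subject_index: int, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, subject_index])


def _one_over_f_noise(rng: np.random.Generator, n: int, rate: float,
                      exponent: float, rms: float) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ~ f^(-exponent/2) on 0.3-45 Hz."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    amp = np.zeros_like(freqs)
    band = (freqs >= 0.3) & (freqs <= 45.0)
    amp[band] = freqs[band] ** (-exponent / 2.0)
    spectrum = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _narrowband_noise(rng: np.random.Generator, n: int, rate: float,
                      band: BandDefinition, rms: float) -> np.ndarray:
    from .preprocess import zero_phase_bandpass

    x = zero_phase_bandpass(rng.standard_normal(n), band.low_hz, band.high_hz, rate)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _wandering_phase(rng: np.random.Generator, n: int, rate: float,
                     band: BandDefinition) -> np.ndarray:
    """Carrier phase with slow frequency modulation kept inside the band."""
    fc = 0.5 * (band.low_hz + band.high_hz)
    half = 0.5 * (band.high_hz - band.low_hz)
    sos = signal.butter(2, 0.2 / (rate / 2.0), btype="lowpass", output="sos")
    s = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = s.std()
    s = np.clip(s / sd, -2.0, 2.0) if sd > 0 else s
    inst_freq = fc + 0.25 * half * s
    return 2 * np.pi * np.cumsum(inst_freq) / rate


def _subject_kappa(spec: CouplingSpec, label: str, spread: float,
                   rng: np.random.Generator) -> float:
    k = spec.kappa(label)
    if spread > 0:
        k *= float(np.exp(spread * rng.standard_normal()))
    return k


def generate_eeg(cfg: CohortConfig, subject_index: int) -> EEGRecording:
    """Synthesize one subject's 19-channel recording (microvolts).

    Coupled channels carry the shared carrier in the coupled band instead
    of an independent oscillation there; every other (channel, band)
    combination gets its own independent narrowband process, so all
    non-implanted pairs are phase-independent by construction.
    """
    label = cfg.label_of(subject_index)
    rng = cfg.subject_rng(subject_index, stream=0)
    rate = cfg.rate_hz
    n = int(round(cfg.duration_s * rate))
    epoch_len = int(round(EPOCH_LENGTH_S * rate))
    n_epochs = n // epoch_len

    coupled_slots = {(ch, spec.band) for spec in cfg.couplings for ch in spec.pair}
    data = np.zeros((N_CHANNELS, n))
    for c, ch in enumerate(CHANNELS):
        x = _one_over_f_noise(rng, n, rate, cfg.noise_exponent, cfg.background_rms_uv)
        for band in DEFAULT_BANDS:
            if (ch, band.name) in coupled_slots:
                continue
            x += _narrowband_noise(rng, n, rate, band, cfg.band_rms_uv[band.name])
        data[c] = x

    for spec in cfg.couplings:
        band = _BANDS[spec.band]
        phi = _wandering_phase(rng, n, rate, band)
        kappa = _subject_kappa(spec, label, cfg.kappa_spread, rng)
        jitter_per_epoch = rng.vonmises(0.0, kappa, size=n_epochs) if kappa > 0 else \
            rng.uniform(-np.pi, np.pi, size=n_epochs)
        jitter = np.repeat(jitter_per_epoch, epoch_len)
        if len(jitter) < n:  # tail shorter than one epoch keeps the last offset
            jitter = np.concatenate([jitter, np.full(n - len(jitter), jitter_per_epoch[-1])])
        ia, ib = channel_index(spec.pair[0]), channel_index(spec.pair[1])
        data[ia] += cfg.coupling_amp_uv * np.cos(phi + jitter)
        data[ib] += cfg.coupling_amp_uv * np.cos(phi)

    return EEGRecording(
        subject_id=cfg.subject_id(subject_index), sampling_rate_hz=rate, data=data
    )


def _draw_continuous(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 0.0, None))


def generate_clinical(cfg: CohortConfig) -> list[ClinicalRecord]:
    """Draw the cohort's clinical table; reproducible from cfg.seed."""
    records = []
    for idx in range(cfg.n_subjects):
        label = cfg.label_of(idx)
        rng = cfg.subject_rng(idx, stream=1)
        row: dict[str, object] = {}
        for name, entry in cfg.clinical_spec.items():
            if entry["kind"] == "continuous":
                row[name] = _draw_continuous(rng, *entry[label])
            elif entry["kind"] == "binary":
                p = entry[label]
                values = entry.get("values", ("N", "Y"))
                row[name] = values[int(rng.random() < p)]
            else:
                cats = entry["categories"]
                row[name] = str(rng.choice(cats, p=np.asarray(entry[label])))
        onset = float(row.pop("age_first_onset_y"))
        duration = float(row.pop("years_since_onset"))
        records.append(
            ClinicalRecord(
                subject_id=cfg.subject_id(idx),
                label=label,
                age_y=onset + duration,
                age_first_onset_y=onset,
                years_since_onset=duration,
                **row,
            )
        )
    return records


def simulate_plv_features(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Phase-level cohort simulation: the 684-column PLV feature table.

    For every subject and feature the per-epoch phase differences are drawn
    directly (uniform for uncoupled pairs, von Mises(kappa) for implanted
    ones) and reduced by the across-epoch PLV estimator — the same model as
    :func:`generate_eeg` without waveform synthesis.

    Returns (features [n_subjects x 684], labels 0=CON/1=CI, ground truth).
    """
    names = plv_feature_names()
    col_of = {nm: i for i, nm in enumerate(names)}
    coupled_cols = {col_of[s.feature_name]: s for s in cfg.couplings}
    N = cfg.n_epochs
    rows = np.empty((cfg.n_subjects, len(names)))
    for idx in range(cfg.n_subjects):
        label = cfg.label_of(idx)
        rng = cfg.subject_rng(idx, stream=2)
        angles = rng.uniform(-np.pi, np.pi, size=(len(names), N))
        for col, spec in coupled_cols.items():
            kappa = _subject_kappa(spec, label, cfg.kappa_spread, rng)
            if kappa > 0:
                angles[col] = rng.vonmises(0.0, kappa, size=N)
        rows[idx] = np.abs(np.exp(1j * angles).mean(axis=1))
    index = [cfg.subject_id(i) for i in range(cfg.n_subjects)]
    features = pd.DataFrame(rows, index=index, columns=names)
    labels = pd.Series(
        [0 if i < cfg.n_con else 1 for i in range(cfg.n_subjects)], index=index, name="group"
    )
    truth = {
        "seed": cfg.seed,
        "n_epochs": N,
        "couplings": [
            {
                "feature": s.feature_name,
                "band": s.band,
                "pair": list(s.pair),
                "kappa_con": s.kappa_con,
                "kappa_ci": s.kappa_ci,
                "expected_plv_con": expected_plv(s.kappa_con),
                "expected_plv_ci": expected_plv(s.kappa_ci),
            }
            for s in cfg.couplings
        ],
    }
    return features, labels, truth


# ----------------------------------------------------------------------
# EDF fixture writer (16-bit EDF, 1-s data records)

_PHYS_MIN, _PHYS_MAX = -3276.8, 3276.7
_DIG_MIN, _DIG_MAX = -32768, 32767
QUANT_STEP_UV = (_PHYS_MAX - _PHYS_MIN) / (_DIG_MAX - _DIG_MIN)  # exactly 0.1 uV


def _pad(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field too long: {s!r} > {width}")
    return s.ljust(width).encode("ascii")


def write_fixture_edf(
    rec: EEGRecording,
    path: str | Path,
    channel_order: list[str] | None = None,
    include_reference: bool = False,
    label_fmt: str = "{name}",
) -> Path:
    """Write a recording as a minimal EDF file readable by :func:`read_edf`.

    The fixed physical range (±3276.8 µV) gives a quantization step of
    exactly 0.1 µV. ``channel_order`` permutes the written channel order,
    ``include_reference`` appends zeroed A1/A2 leads, and ``label_fmt``
    (e.g. ``"EEG {name}-REF"``) emulates vendor label dialects — all for
    round-trip testing of the reader.
    """
    path = Path(path)
    rate = rec.sampling_rate_hz
    spr = int(round(rate))  # samples per 1-s record
    if abs(rate - spr) > 1e-9:
        raise ValueError("EDF writer needs an integer sampling rate")
    order = list(channel_order) if channel_order is not None else list(CHANNELS)
    if sorted(order) != sorted(CHANNELS):
        raise ValueError("channel_order must be a permutation of the canonical montage")
    labels = [label_fmt.format(name=ch) for ch in order]
    chans = [rec.data[channel_index(ch)] for ch in order]
    if include_reference:
        labels += ["A1", "A2"]
        chans += [np.zeros(rec.n_samples), np.zeros(rec.n_samples)]
    ns = len(labels)
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s EDF record")

    header = b"".join(
        [
            _pad("0", 8),
            _pad(rec.subject_id, 80),
            _pad("synthetic fixture", 80),
            _pad("01.01.20", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_pad(lbl, 16) for lbl in labels),
            b"".join(_pad("synthetic", 80) for _ in labels),
            b"".join(_pad("uV", 8) for _ in labels),
            b"".join(_pad(f"{_PHYS_MIN}", 8) for _ in labels),
            b"".join(_pad(f"{_PHYS_MAX}", 8) for _ in labels),
            b"".join(_pad(str(_DIG_MIN), 8) for _ in labels),
            b"".join(_pad(str(_DIG_MAX), 8) for _ in labels),
            b"".join(_pad("", 80) for _ in labels),
            b"".join(_pad(str(spr), 8) for _ in labels),
            b"".join(_pad("", 32) for _ in labels),
        ]
    )
    digital = np.stack(
        [
            np.clip(np.round(np.asarray(c[: n_records * spr]) / QUANT_STEP_UV), _DIG_MIN, _DIG_MAX)
            for c in chans
        ]
    ).astype("<i2")
    # records: [record][signal][sample]
    body = digital.reshape(ns, n_records, spr).transpose(1, 0, 2).tobytes()
    path.write_bytes(header + per_signal + body)
    return path


def write_cohort(cfg: CohortConfig, out_dir: str | Path) -> dict:
    """Materialize a cohort on disk: EDFs, clinical CSV, ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = generate_clinical(cfg)
    rows = []
    for rec in records:
        d = {"subject_id": rec.subject_id, "group": rec.label}
        for f in (
            "age_y age_first_onset_y years_since_onset gender family_history "
            "head_surgery_trauma cns_infection perinatal_injury tle mri_abnormal "
            "hippocampal_atrophy_sclerosis seizure_type status_epilepticus gtcs "
            "seizure_frequency asm_class_ge2 vpa pht tpm aura anxiety depression education"
        ).split():
            d[f] = getattr(rec, f)
        rows.append(d)
    pd.DataFrame(rows).to_csv(out_dir / "clinical.csv", index=False)
    for idx in range(cfg.n_subjects):
        eeg = generate_eeg(cfg, idx)
        write_fixture_edf(eeg, out_dir / f"{eeg.subject_id}.edf")
    truth = simulate_plv_features(replace(cfg, duration_s=EPOCH_LENGTH_S))[2]
    truth["n_epochs"] = cfg.n_epochs
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return truth
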