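"""Clinical feature encoding and assembly of the subject-level feature table.

The 23 clinical items cover demographics, epilepsy history, imaging,
seizure semiology, medication and psychometric screens. Binary items are
encoded 0/1, multi-level categories as 0-based ordinals in their clinical
order (e.g. education <=6y -> 0, ..., >=13y -> 3), continuous items pass
through. Missing values are an input error — no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalRecord",
    "CLINICAL_FEATURES",
    "LABELS",
    "encode_clinical",
    "encode_clinical_frame",
    "decode_clinical",
    "assemble_table",
    "read_clinical_csv",
]

LABELS = ("CON", "CI")  # cognitively normal / cognitively impaired

#: Ordinal vocabularies, category order as used clinically (0-based codes).
ORDINAL_VOCAB: dict[str, tuple[str, ...]] = {
    "seizure_type": ("generalized", "focal", "both"),
    "seizure_frequency": ("rare", "occasional", "frequent"),
    "anxiety": ("none", "possible", "definitely", "definitely_obvious"),
    "depression": ("none", "possible", "definitely"),
    "education": ("<=6y", "7-9y", "10-12y", ">=13y"),
}

CONTINUOUS_FEATURES = ("age_y", "age_first_onset_y", "years_since_onset")

BINARY_FEATURES = (
    "gender",  # 1 = female
    "family_history",
    "head_surgery_trauma",
    "cns_infection",
    "perinatal_injury",
    "tle",
    "mri_abnormal",
    "hippocampal_atrophy_sclerosis",
    "status_epilepticus",
    "gtcs",
    "asm_class_ge2",
    "vpa",
    "pht",
    "tpm",
    "aura",
)

#: The 23 clinical features, in their standard reporting order.
CLINICAL_FEATURES: tuple[str, ...] = (
    "age_y",
    "age_first_onset_y",
    "years_since_onset",
    "gender",
    "family_history",
    "head_surgery_trauma",
    "cns_infection",
    "perinatal_injury",
    "tle",
    "mri_abnormal",
    "hippocampal_atrophy_sclerosis",
    "seizure_type",
    "status_epilepticus",
    "gtcs",
    "seizure_frequency",
    "asm_class_ge2",
    "vpa",
    "pht",
    "tpm",
    "aura",
    "anxiety",
    "depression",
    "education",
)

_BINARY_TRUE = {"y", "yes", "1", "true", "t"}
_BINARY_FALSE = {"n", "no", "0", "false", "f"}
_FEMALE = {"f", "female", "1"}
_MALE = {"m", "male", "0"}


@dataclass
class ClinicalRecord:
    subject_id: str
    label: str  # CON or CI
    age_y: float
    age_first_onset_y: float
    years_since_onset: float
    gender: str
    family_history: str
    head_surgery_trauma: str
    cns_infection: str
    perinatal_injury: str
    tle: str
    mri_abnormal: str
    hippocampal_atrophy_sclerosis: str
    seizure_type: str
    status_epilepticus: str
    gtcs: str
    seizure_frequency: str
    asm_class_ge2: str
    vpa: str
    pht: str
    tpm: str
    aura: str
    anxiety: str
    depression: str
    education: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        for f in CONTINUOUS_FEATURES:
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        if self.years_since_onset > self.age_y:
            raise ValueError("years_since_onset cannot exceed age_y")


def _encode_binary(name: str, value) -> int:
    s = str(value).strip().lower()
    if name == "gender":
        if s in _FEMALE:
            return 1
        if s in _MALE:
            return 0
    if s in _BINARY_TRUE:
        return 1
    if s in _BINARY_FALSE:
        return 0
    raise ValueError(f"out-of-vocabulary value {value!r} for binary feature {name!r}")


def _encode_ordinal(name: str, value) -> int:
    vocab = ORDINAL_VOCAB[name]
    s = str(value).strip().lower().replace(" ", "_")
    # accept the code itself, e.g. "2"
    if s.isdigit() and int(s) < len(vocab):
        return int(s)
    for code, cat in enumerate(vocab):
        if s == cat or s == cat.replace("_", " "):
            return code
    raise ValueError(f"out-of-vocabulary value {value!r} for {name!r}; expected one of {vocab}")


def encode_clinical(rec: ClinicalRecord) -> pd.Series:
    """Numeric encoding of one record: a 23-long named vector."""
    out: dict[str, float] = {}
    for name in CLINICAL_FEATURES:
        value = getattr(rec, name)
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"missing value for {name!r} in subject {rec.subject_id}")
        if name in CONTINUOUS_FEATURES:
            out[name] = float(value)
        elif name in BINARY_FEATURES:
            out[name] = _encode_binary(name, value)
        else:
            out[name] = _encode_ordinal(name, value)
    return pd.Series(out, name=rec.subject_id)


def decode_clinical(encoded: pd.Series) -> dict[str, object]:
    """Invert the categorical part of :func:`encode_clinical` (round-trip check)."""
    out: dict[str, object] = {}
    for name, v in encoded.items():
        if name in CONTINUOUS_FEATURES:
            out[name] = float(v)
        elif name in BINARY_FEATURES:
            out[name] = "F" if (name == "gender" and int(v) == 1) else (
                "M" if name == "gender" else ("Y" if int(v) == 1 else "N")
            )
        else:
            out[name] = ORDINAL_VOCAB[name][int(v)]
    return out


def encode_clinical_frame(records: list[ClinicalRecord]) -> tuple[pd.DataFrame, pd.Series]:
    """Encode many records; returns (23-column frame, label series 0=CON/1=CI)."""
    rows = [encode_clinical(r) for r in records]
    frame = pd.DataFrame(rows)
    labels = pd.Series(
        [LABELS.index(r.label) for r in records],
        index=[r.subject_id for r in records],
        name="group",
    )
    return frame, labels


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical table CSV with one column per feature plus subject_id, group."""
    df = pd.read_csv(path, dtype=str)
    needed = {"subject_id", "group", *CLINICAL_FEATURES}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"clinical CSV missing column(s): {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        kwargs = {f: row[f] for f in CLINICAL_FEATURES}
        for f in CONTINUOUS_FEATURES:
            kwargs[f] = float(kwargs[f])
        records.append(ClinicalRecord(subject_id=row["subject_id"], label=row["group"], **kwargs))
    return records


def assemble_table(
    clinical: pd.DataFrame,
    labels: pd.Series,
    plv_features: pd.DataFrame | None = None,
    view: str = "combined",
) -> tuple[pd.DataFrame, pd.Series]:
    """Join clinical and PLV feature blocks into one subject table.

    view: 'clinical' (23 columns), 'plv' (684) or 'combined' (707).
    Subject id sets must match exactly when PLV features are involved.
    """
    if view not in {"clinical", "plv", "combined"}:
        raise ValueError(f"unknown view {view!r}")
    if view == "clinical":
        table = clinical.copy()
    else:
        if plv_features is None:
            raise ValueError(f"view {view!r} needs PLV features")
        only_clin = set(clinical.index) - set(plv_features.index)
        only_plv = set(plv_features.index) - set(clinical.index)
        if only_clin or only_plv:
            raise ValueError(
                "subject mismatch between clinical and PLV blocks: "
                f"missing PLV for {sorted(only_clin)}, missing clinical for {sorted(only_plv)}"
            )
        plv = plv_features.loc[clinical.index]
        table = plv if view == "plv" else pd.concat([clinical, plv], axis=1)
    if table.isna().any().any():
        bad = table.columns[table.isna().any()].tolist()
        raise ValueError(f"missing values in feature column(s): {bad}")
    return table, labels.loc[table.index]
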