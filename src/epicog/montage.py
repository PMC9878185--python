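"""Canonical 19-lead 10-20 scalp montage used throughout the package.

The channel order below is part of the public contract: PLV matrices are
indexed by it and feature names are derived from it, so it must never be
reordered.
"""

from __future__ import annotations

from itertools import combinations

#: Canonical 10-20 recording leads, in the fixed order used for all
#: matrices and feature vectors.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "Cz", "Pz", "C3", "C4", "T3", "T4", "T5",
    "T6", "F3", "F4", "F7", "F8", "O1", "O2", "P3", "P4",
)

#: Reference leads that are dropped on read when present.
REFERENCE_CHANNELS: tuple[str, ...] = ("A1", "A2")

N_CHANNELS = len(CHANNELS)

#: All unordered channel pairs (i < j in canonical order): 171 of them.
CHANNEL_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(CHANNELS, 2))

N_PAIRS = len(CHANNEL_PAIRS)  # C(19, 2) = 171

_INDEX = {name: i for i, name in enumerate(CHANNELS)}
_INDEX_CI = {name.lower(): i for i, name in enumerate(CHANNELS)}


def channel_index(name: str) -> int:
    """Index of a canonical channel name (case-insensitive)."""
    try:
        return _INDEX_CI[name.strip().lower()]
    except KeyError:
        raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}") from None


def pair_name(a: str, b: str) -> str:
    """Canonical 'A-B' pair label with members in montage order."""
    ia, ib = channel_index(a), channel_index(b)
    if ia == ib:
        raise ValueError(f"pair channels must differ, got {a!r} twice")
    if ia > ib:
        ia, ib = ib, ia
    return f"{CHANNELS[ia]}-{CHANNELS[ib]}"


def normalize_label(raw_label: str, aliases: dict[str, str] | None = None) -> str | None:
    """Map a vendor EDF label onto a canonical channel name.

    Strips the common ``EEG `` prefix and reference suffixes (``-A1``,
    ``-A2``, ``-REF``, ``-LE``, ``-AVG``), then matches case-insensitively.
    An explicit ``aliases`` table (raw label -> canonical name) wins over
    the heuristics. Returns None when the label maps to no canonical lead.
    """
    if aliases:
        ci = {k.strip().lower(): v for k, v in aliases.items()}
        hit = ci.get(raw_label.strip().lower())
        if hit is not None:
            return CHANNELS[channel_index(hit)]
    s = raw_label.strip()
    if s.lower().startswith("eeg"):
        s = s[3:].lstrip(" :")
    for suffix in ("-a1", "-a2", "-ref", "-le", "-avg"):
        if s.lower().endswith(suffix):
            s = s[: -len(suffix)]
            break
    s = s.strip()
    idx = _INDEX_CI.get(s.lower())
    return CHANNELS[idx] if idx is not None else None
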