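"""Intrinsic amino-acid hydrophobicity scales.

The observed hydrophobicity distribution accumulates pairwise contributions
of the form ``(H_i + H_j) * w(r_ij)``, where ``H`` is the intrinsic
hydrophobicity of an amino-acid type.  Scales are stored raw and min-max
normalized to [0, 1] on lookup, so the most hydrophilic residue type maps
to 0.0 and the most hydrophobic to 1.0.  Since the observed distribution is
normalized to sum 1, the RD statistic is invariant to any positive rescaling
of a scale; the [0, 1] convention simply keeps values comparable across
scales.
"""

from __future__ import annotations

import json
from pathlib import Path

from .errors import ConfigurationError

STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Residue-name aliases seen in deposited structures, mapped to parents.
AA_ALIASES = {
    "MSE": "MET",  # selenomethionine
    "SEC": "CYS",
    "PYL": "LYS",
    "HSD": "HIS", "HSE": "HIS", "HSP": "HIS",
    "CYX": "CYS", "CYM": "CYS",
}

# Kyte & Doolittle hydropathy index (raw, unnormalized).
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

# Eisenberg consensus scale, kept as an alternative for sensitivity checks.
EISENBERG = {
    "ILE": 0.73, "PHE": 0.61, "VAL": 0.54, "LEU": 0.53, "TRP": 0.37,
    "MET": 0.26, "ALA": 0.25, "GLY": 0.16, "CYS": 0.04, "TYR": 0.02,
    "PRO": -0.07, "THR": -0.18, "SER": -0.26, "HIS": -0.40, "GLU": -0.62,
    "ASN": -0.64, "GLN": -0.69, "ASP": -0.72, "LYS": -1.10, "ARG": -1.76,
}

_NAMED_SCALES = {
    "kyte-doolittle": KYTE_DOOLITTLE,
    "eisenberg": EISENBERG,
}

DEFAULT_SCALE = "kyte-doolittle"


def normalize_scale(raw: dict[str, float]) -> dict[str, float]:
    """Min-max normalize a raw scale to [0, 1].

    A constant scale (zero range) maps every type to 1.0 so that the
    observed distribution degenerates gracefully to geometry-only weights.
    """
    lo, hi = min(raw.values()), max(raw.values())
    if hi == lo:
        return {aa: 1.0 for aa in raw}
    return {aa: (v - lo) / (hi - lo) for aa, v in raw.items()}


def get_scale(scale: str | Path | dict[str, float] = DEFAULT_SCALE) -> dict[str, float]:
    """Resolve a scale by name, JSON file path, or explicit mapping.

    Returns a mapping from 3-letter code to hydrophobicity in [0, 1].
    Raw values outside [0, 1] are min-max normalized; values already inside
    [0, 1] are taken as-is (so toy scales keep their stated endpoints).
    Coverage of the residue types actually present in a model is checked at
    assignment time.
    """
    if isinstance(scale, dict):
        raw = {k.upper(): float(v) for k, v in scale.items()}
    elif isinstance(scale, Path) or (isinstance(scale, str) and scale not in _NAMED_SCALES):
        path = Path(scale)
        if not path.exists():
            raise ConfigurationError(
                f"unknown scale {scale!r}: not a named scale "
                f"({', '.join(sorted(_NAMED_SCALES))}) and no such file"
            )
        raw = {k.upper(): float(v) for k, v in json.loads(path.read_text()).items()}
    else:
        raw = _NAMED_SCALES[scale]

    vals = raw.values()
    if min(vals) < 0.0 or max(vals) > 1.0:
        raw = normalize_scale(raw)
    return dict(raw)


def scale_names() -> list[str]:
    return sorted(_NAMED_SCALES)
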