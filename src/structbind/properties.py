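"""Amino-acid property scoring of protein sequences and set comparison.

Ships three canonical literature scales — Grantham polarity, Chou-Fasman
alpha-helix propensity and Kyte-Doolittle hydropathy — loaded from a
versioned, checksummed data file.  A protein's property score is the
unweighted mean of the scale value over its standard residues; sets of
proteins (e.g. RNA-released versus static condensate components, or
dsRNA- versus ssRNA-binders) are compared with a two-sample KS test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

from .errors import DegenerateInputError, FormatError
from .interactivity import ks_compare

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
#: residues skipped (ambiguity codes and rare translated residues)
SKIPPED_AA = set("XBZUO")

_SCALES_SHA256 = "77f2b13cf8ee3ac95498ce245f23f1e1d4c9066fe21590dc23287069de5686ae"


@dataclass
class PropertyScale:
    """A named map from the 20 standard amino acids to real values."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.values)
        if missing:
            raise FormatError(f"scale {self.name}: missing residues {sorted(missing)}")
        for aa, v in self.values.items():
            if not isinstance(v, (int, float)) or v != v:
                raise FormatError(f"scale {self.name}: bad value for {aa}")


@dataclass
class PropertyScore:
    protein_id: str
    scale: str
    mean_value: float
    n_scored: int
    n_skipped: int


def _load_scale_data() -> dict:
    blob = resources.files("structbind").joinpath("data/scales.json").read_bytes()
    digest = hashlib.sha256(blob).hexdigest()
    if digest != _SCALES_SHA256:
        raise FormatError(
            f"scales.json checksum mismatch: {digest} != {_SCALES_SHA256}"
        )
    return json.loads(blob)["scales"]


def available_scales() -> list[str]:
    return sorted(_load_scale_data())


def load_scale(name: str) -> PropertyScale:
    """Load a packaged scale by name (see :func:`available_scales`)."""
    data = _load_scale_data()
    if name not in data:
        raise KeyError(f"unknown scale {name!r}; have {sorted(data)}")
    return PropertyScale(name, data[name])


def score_sequence(
    sequence: str, scale: PropertyScale, protein_id: str = ""
) -> PropertyScore:
    """Mean scale value over the standard residues of a sequence.

    Non-standard residues (X, B, Z, U, O and anything not in the scale)
    are skipped and counted in ``n_skipped``; a sequence with no scorable
    residue is degenerate.
    """
    seq = sequence.upper().strip("*")
    total, n = 0.0, 0
    skipped = 0
    for aa in seq:
        if aa in scale.values:
            total += scale.values[aa]
            n += 1
        else:
            skipped += 1
    if n == 0:
        raise DegenerateInputError(f"{protein_id or sequence!r}: no scorable residues")
    return PropertyScore(protein_id, scale.name, total / n, n, skipped)


def score_fasta(sequences: Mapping[str, str], scale: PropertyScale):
    """Score every sequence of an id->sequence mapping under one scale."""
    return [score_sequence(seq, scale, pid) for pid, seq in sequences.items()]


def compare_sets(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample KS comparison of two property-score collections."""
    if len(scores_a) < 3 or len(scores_b) < 3:
        raise DegenerateInputError("need at least 3 scores per set")
    return ks_compare(scores_a, scores_b)
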