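"""Numerical encoding of amino-acid sequences.

Each residue of a sequence is replaced by the value a chosen descriptor
scale assigns it, yielding one real number per position.  The default
descriptor is the Kyte--Doolittle hydropathy scale (index 151).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .descriptors import (
    CANONICAL_RESIDUES,
    DEFAULT_DESCRIPTOR_INDEX,
    DescriptorDatabase,
    NormalizationMode,
    get_scale,
    rescale_scale,
)

logger = logging.getLogger(__name__)

_GAP_CHARS = frozenset("-.")
# Ambiguity codes resolved under the lenient policy.
_AMBIGUOUS = {"B": ("D", "N"), "Z": ("E", "Q")}


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence (one-letter codes)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        stripped = "".join(self.residues.split())
        if not stripped:
            raise ValueError(f"sequence {self.id!r}: empty after whitespace stripping")
        object.__setattr__(self, "residues", stripped.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class EncodedSequence:
    """Descriptor-encoded sequence: one value per admitted residue."""

    values: np.ndarray
    descriptor_index: int
    normalization_mode: NormalizationMode
    source_length: int
    id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != self.source_length:
            raise ValueError("values must be 1-D with length == source_length")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.source_length


def encode(
    seq: SequenceRecord,
    db: DescriptorDatabase,
    descriptor_index: int = DEFAULT_DESCRIPTOR_INDEX,
    mode: NormalizationMode | int = NormalizationMode.NONE,
    residue_policy: str = "strict",
) -> EncodedSequence:
    """Encode a sequence as a vector of descriptor values.

    Parameters
    ----------
    seq
        The input sequence; lowercase input is accepted and uppercased.
    db
        Descriptor database; ``descriptor_index`` is a 1-based index into it.
    mode
        Interval normalization of the *scale* (not the sequence): 0/none,
        1/[-1,1], 2/[0,1].
    residue_policy
        ``strict`` (default) admits only the 20 canonical codes and raises
        on anything else, naming the character and position.  ``lenient``
        maps B to mean(D,N), Z to mean(E,Q), X to the mean of all 20 scale
        values, and strips gap characters ``-`` and ``.`` with a warning.

    Notes
    -----
    Imputation under the lenient policy changes feature values, which is why
    it is opt-in rather than the default.
    """
    if residue_policy not in ("strict", "lenient"):
        raise ValueError(f"unknown residue policy {residue_policy!r}")
    mode = NormalizationMode.from_code(mode)
    scale = rescale_scale(get_scale(db, descriptor_index), mode)
    table = {r: scale.values[r] for r in CANONICAL_RESIDUES}
    if residue_policy == "lenient":
        for code, (a, b) in _AMBIGUOUS.items():
            table[code] = 0.5 * (table[a] + table[b])
        table["X"] = float(np.mean(list(scale.values.values())))

    out: list[float] = []
    n_gaps = 0
    n_ambig = 0
    for pos, ch in enumerate(seq.residues, start=1):
        if ch in table:
            if ch in ("B", "Z", "X") and residue_policy == "lenient":
                n_ambig += 1
            out.append(table[ch])
        elif residue_policy == "lenient" and ch in _GAP_CHARS:
            n_gaps += 1
        else:
            raise ValueError(
                f"sequence {seq.id!r}: non-canonical residue {ch!r} at "
                f"position {pos} (strict policy)"
            )
    if n_gaps or n_ambig:
        logger.warning(
            "sequence %r: lenient policy stripped %d gap(s), imputed %d "
            "ambiguous residue(s)",
            seq.id,
            n_gaps,
            n_ambig,
        )
    if not out:
        raise ValueError(f"sequence {seq.id!r}: empty after gap stripping")
    return EncodedSequence(
        values=np.array(out, dtype=float),
        descriptor_index=descriptor_index,
        normalization_mode=mode,
        source_length=len(out),
        id=seq.id,
    )
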