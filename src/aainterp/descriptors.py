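"""Amino-acid descriptor scales.

A *descriptor scale* maps each of the 20 canonical amino acids to a real
number quantifying some physicochemical or statistical property (hydropathy,
net charge, molecular weight, ...).  The bundled database holds 532 such
scales: 531 all-numeric entries from the AAindex1 flat-file database plus
one empirical alphabet-rank scale (see :func:`load_bundled_database`).

Scales are addressed by 1-based index; index 151 is the Kyte--Doolittle
hydropathy scale, the conventional default for sequence encoding.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import IO, Iterator, Mapping

logger = logging.getLogger(__name__)

#: The 20 canonical one-letter residue codes, in the conventional
#: A R N D C Q E G H I L K M F P S T W Y V order used throughout.
CANONICAL_RESIDUES = "ARNDCQEGHILKMFPSTWYV"

#: Row order of the AAindex1 "I" value block: first line A..I, second L..V,
#: i.e. the pair columns A/L, R/K, N/M, D/F, C/P, Q/S, E/T, G/W, H/Y, I/V.
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"

_DATA_CHUNKS = ("aaindex_scales_1.tsv", "aaindex_scales_2.tsv", "aaindex_scales_3.tsv")

#: Accession and values of the default descriptor (Kyte & Doolittle
#: hydropathy), used for integrity checks at load time.
KYTE_DOOLITTLE_ACCESSION = "KYTJ820101"
DEFAULT_DESCRIPTOR_INDEX = 151


class AAindexParseError(ValueError):
    """Raised on a structurally malformed AAindex1 record."""


class NormalizationMode(enum.Enum):
    """Interval normalization applied to a scale's 20 values.

    Matches the conventional integer codes: 0 = none, 1 = rescale onto
    [-1, 1], 2 = rescale onto [0, 1].  Normalization is global over the 20
    scale values, never per-sequence, so encoded values stay comparable
    across sequences.
    """

    NONE = 0
    SYMMETRIC_UNIT = 1
    UNIT = 2

    @classmethod
    def from_code(cls, code: int | str | "NormalizationMode") -> "NormalizationMode":
        if isinstance(code, cls):
            return code
        try:
            return cls(int(code))
        except (ValueError, TypeError):
            raise ValueError(
                f"unknown normalization mode {code!r}; valid codes are "
                "0 (none), 1 ([-1,1]), 2 ([0,1])"
            ) from None

    @property
    def interval(self) -> tuple[float, float] | None:
        if self is NormalizationMode.SYMMETRIC_UNIT:
            return (-1.0, 1.0)
        if self is NormalizationMode.UNIT:
            return (0.0, 1.0)
        return None


@dataclass(frozen=True)
class DescriptorScale:
    """One named mapping from the 20 canonical residues to real values."""

    accession: str
    description: str
    values: Mapping[str, float]
    empirical: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        keys = set(self.values)
        expected = set(CANONICAL_RESIDUES)
        if keys != expected:
            missing = sorted(expected - keys)
            extra = sorted(keys - expected)
            raise ValueError(
                f"scale {self.accession}: values must cover exactly the 20 "
                f"canonical residues (missing {missing}, unexpected {extra})"
            )
        for res, v in self.values.items():
            fv = float(v)
            if fv != fv or fv in (float("inf"), float("-inf")):
                raise ValueError(f"scale {self.accession}: non-finite value for {res}")
        object.__setattr__(self, "values", dict(self.values))

    def value_of(self, residue: str) -> float:
        return self.values[residue.upper()]

    def as_vector(self) -> list[float]:
        """Values in canonical A..V order."""
        return [self.values[r] for r in CANONICAL_RESIDUES]


@dataclass
class DescriptorDatabase:
    """Ordered, 1-based-indexed collection of descriptor scales."""

    scales: list[DescriptorScale] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.scales:
            if s.accession in seen:
                raise ValueError(f"duplicate accession {s.accession} in database")
            seen.add(s.accession)

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self) -> Iterator[DescriptorScale]:
        return iter(self.scales)

    def get(self, index: int) -> DescriptorScale:
        """Return the scale at 1-based ``index``."""
        return get_scale(self, index)

    def find(self, accession: str) -> int:
        """Return the 1-based index of ``accession`` (ValueError if absent)."""
        for i, s in enumerate(self.scales, start=1):
            if s.accession == accession:
                return i
        raise ValueError(f"accession {accession!r} not in database")


def get_scale(db: DescriptorDatabase, index: int) -> DescriptorScale:
    """Look up a scale by its 1-based descriptor index."""
    if not 1 <= index <= len(db):
        raise IndexError(
            f"descriptor index {index} out of range; valid range is 1..{len(db)}"
        )
    return db.scales[index - 1]


def rescale_scale(scale: DescriptorScale, mode: NormalizationMode) -> DescriptorScale:
    """Affinely map a scale's 20 values onto the mode's interval.

    ``unit`` maps [min, max] -> [0, 1]; ``symmetric_unit`` -> [-1, 1];
    ``none`` returns the scale unchanged.  Residue ordering by value is
    preserved.  A degenerate scale (all 20 values identical) has no defined
    affine image and raises ``ValueError``.
    """
    mode = NormalizationMode.from_code(mode)
    if mode is NormalizationMode.NONE:
        return scale
    vals = scale.as_vector()
    lo, hi = min(vals), max(vals)
    if hi == lo:
        raise ValueError(
            f"scale {scale.accession}: all values identical; interval "
            "normalization is undefined"
        )
    a, b = mode.interval  # type: ignore[misc]
    span = b - a
    new_values = {r: a + (v - lo) * span / (hi - lo) for r, v in scale.values.items()}
    # pin the extremes exactly so repeated rescaling is the identity
    for r, v in scale.values.items():
        if v == lo:
            new_values[r] = a
        elif v == hi:
            new_values[r] = b
    return replace(scale, values=new_values)


def parse_aaindex1(
    stream: IO[str], *, skipped: list[str] | None = None
) -> list[DescriptorScale]:
    """Parse AAindex1 flat-format records into descriptor scales.

    Records whose value block contains the token ``NA`` are skipped (their
    accessions collected into ``skipped`` if given, and logged); this is why
    only 531 of the AAindex1 entries are usable as numeric descriptors.

    Raises :class:`AAindexParseError`, naming the accession and line number,
    on structural problems (missing I line, wrong value count).
    """
    scales: list[DescriptorScale] = []
    accession = ""
    description_parts: list[str] = []
    tokens: list[str] = []
    in_values = False
    saw_i = False
    record_start = 0

    def finish(line_no: int) -> None:
        nonlocal accession, description_parts, tokens, in_values, saw_i
        if not accession and not tokens and not saw_i:
            return
        if not saw_i:
            raise AAindexParseError(
                f"record {accession or '<no accession>'} ending at line "
                f"{line_no}: missing I line"
            )
        if len(tokens) != 20:
            raise AAindexParseError(
                f"record {accession} ending at line {line_no}: expected 20 "
                f"values, found {len(tokens)}"
            )
        if any(t.upper() == "NA" for t in tokens):
            logger.warning("skipping AAindex record %s: contains NA values", accession)
            if skipped is not None:
                skipped.append(accession)
        else:
            row1 = tokens[:10]
            row2 = tokens[10:]
            values = {r: float(v) for r, v in zip(_AAINDEX_ROW1, row1)}
            values.update({r: float(v) for r, v in zip(_AAINDEX_ROW2, row2)})
            scales.append(
                DescriptorScale(
                    accession=accession,
                    description=" ".join(description_parts),
                    values=values,
                )
            )
        accession = ""
        description_parts = []
        tokens = []
        in_values = False
        saw_i = False

    line_no = 0
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if line.startswith("//"):
            finish(line_no)
            continue
        if line[:1] == "H":
            accession = line[1:].strip()
            record_start = line_no
            in_values = False
        elif line[:1] == "D":
            description_parts.append(line[1:].strip())
            in_values = False
        elif line[:1] == "I" and line[:2] in ("I ", "I"):
            saw_i = True
            in_values = True
        elif in_values and (line[:1] == " " or line[:1].isdigit() or line[:1] == "-"):
            tokens.extend(line.split())
        else:
            in_values = False
    if accession or saw_i or tokens:
        raise AAindexParseError(
            f"record {accession or '<no accession>'} starting at line "
            f"{record_start}: unterminated (missing //)"
        )
    return scales


def write_aaindex1(scales: list[DescriptorScale], stream: IO[str]) -> None:
    """Serialize scales back to AAindex1 flat format (H, D, I blocks)."""
    for s in scales:
        stream.write(f"H {s.accession}\n")
        stream.write(f"D {s.description}\n")
        stream.write("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n")
        row1 = " ".join(f"{s.values[r]:9.5g}" for r in _AAINDEX_ROW1)
        row2 = " ".join(f"{s.values[r]:9.5g}" for r in _AAINDEX_ROW2)
        stream.write(f" {row1}\n {row2}\n//\n")


def read_snapshot(stream: IO[str], *, empirical: bool = False) -> list[DescriptorScale]:
    """Read the internal TSV snapshot: accession, description, 20 values
    in canonical A..V order."""
    scales = []
    for line_no, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 22:
            raise ValueError(
                f"snapshot line {line_no}: expected 22 tab-separated fields, "
                f"got {len(parts)}"
            )
        values = {r: float(v) for r, v in zip(CANONICAL_RESIDUES, parts[2:])}
        scales.append(
            DescriptorScale(
                accession=parts[0],
                description=parts[1],
                values=values,
                empirical=empirical,
            )
        )
    return scales


def write_snapshot(scales: list[DescriptorScale], stream: IO[str]) -> None:
    for s in scales:
        vals = "\t".join(f"{v:.10g}" for v in s.as_vector())
        stream.write(f"{s.accession}\t{s.description}\t{vals}\n")


def alphabet_rank_scale() -> DescriptorScale:
    """The bundled empirical descriptor: a synthetic alphabet-rank scale.

    Assigns A=1 ... V=20 in canonical residue order.  It carries no
    physicochemical meaning; it is a clearly-labelled stand-in for the
    otherwise-unspecified 532nd (non-AAindex) descriptor slot.
    """
    return DescriptorScale(
        accession="EMPIRICAL01",
        description="Empirical alphabet-rank scale (synthetic stand-in; A=1..V=20)",
        values={r: float(i) for i, r in enumerate(CANONICAL_RESIDUES, start=1)},
        empirical=True,
    )


def load_bundled_database() -> DescriptorDatabase:
    """Load the bundled 532-scale database.

    531 all-numeric AAindex1 scales in snapshot order (index 151 is the
    Kyte--Doolittle hydropathy scale KYTJ820101) plus the empirical
    alphabet-rank scale at index 532.
    """
    scales: list[DescriptorScale] = []
    pkg = resources.files(__package__) / "data"
    for chunk in _DATA_CHUNKS:
        with (pkg / chunk).open("r", encoding="utf-8") as fh:
            scales.extend(read_snapshot(fh))
    scales.append(alphabet_rank_scale())
    db = DescriptorDatabase(scales)
    kd = db.scales[DEFAULT_DESCRIPTOR_INDEX - 1]
    if kd.accession != KYTE_DOOLITTLE_ACCESSION:
        raise RuntimeError(
            f"bundled database corrupt: index {DEFAULT_DESCRIPTOR_INDEX} is "
            f"{kd.accession}, expected {KYTE_DOOLITTLE_ACCESSION}"
        )
    return db
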