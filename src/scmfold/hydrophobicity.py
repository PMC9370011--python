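"""Hydrophobicity scales, protein records and windowed segment scores.

The early-contact scan works on *segment hydrophobicities*: the per-residue
side-chain transfer free energies of a short contiguous window are summed to
give ``h_{i,w}``, the hydrophobicity of the w-residue segment centered at
residue i.  The built-in scale is the Fauchère–Pliska octanol/water π scale,
on which a change of ~0.45 units corresponds to ~1 kT (±0.1 kT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Fauchère & Pliska side-chain octanol/water transfer values (π, unitless).
#: Glycine is the zero reference; tryptophan is the most hydrophobic residue.
FAUCHERE_PLISKA: dict[str, float] = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}


class UnknownScaleError(KeyError):
    """Requested hydrophobicity scale is not registered."""


class NonStandardResidueError(ValueError):
    """Sequence contains a letter the scale has no value for."""


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named per-residue hydrophobicity scale.

    Parameters
    ----------
    name
        Registry identifier, e.g. ``"fauchere-pliska"``.
    values
        Map from each of the 20 standard one-letter codes to a unitless
        transfer value h_k.
    kt_conversion
        Scale units per kT; 0.45 for the Fauchère–Pliska scale.
    unit_margin_kt
        Estimated error per unit-to-kT conversion, in kT.
    """

    name: str
    values: dict[str, float]
    kt_conversion: float = 0.45
    unit_margin_kt: float = 0.1

    def __post_init__(self) -> None:
        missing = sorted(set(STANDARD_AA) - set(self.values))
        extra = sorted(set(self.values) - set(STANDARD_AA))
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard residues; "
                f"missing {missing}, unexpected {extra}"
            )
        if self.kt_conversion <= 0:
            raise ValueError("kt_conversion must be positive")

    def lookup(self, letter: str, nonstandard: str = "error") -> float:
        """Return h_k for one residue letter.

        ``nonstandard`` is the policy for letters outside the 20 standard
        codes (X, U, B, Z, ...): ``"error"`` raises, ``"zero"`` assigns 0.0
        with a warning.  Silent zeros would bias segment sums, so the warning
        is not suppressible.
        """
        try:
            return self.values[letter]
        except KeyError:
            if nonstandard == "zero":
                warnings.warn(
                    f"residue {letter!r} not on scale {self.name!r}; assigned h = 0",
                    stacklevel=2,
                )
                return 0.0
            raise NonStandardResidueError(
                f"residue {letter!r} has no value on scale {self.name!r} "
                f"(policy 'zero' assigns 0 with a warning)"
            ) from None

    def segment_sum(self, segment: str, nonstandard: str = "error") -> float:
        return sum(self.lookup(ch, nonstandard) for ch in segment)


_SCALES: dict[str, HydrophobicityScale] = {
    "fauchere-pliska": HydrophobicityScale("fauchere-pliska", FAUCHERE_PLISKA),
}


def load_scale(name: str) -> HydrophobicityScale:
    """Look up a registered scale by name."""
    try:
        return _SCALES[name]
    except KeyError:
        raise UnknownScaleError(
            f"unknown scale {name!r}; available: {sorted(_SCALES)}"
        ) from None


def load_scale_file(path: str | Path, name: str | None = None,
                    kt_conversion: float = 0.45) -> HydrophobicityScale:
    """Load a custom scale from a two-column text file (letter, value).

    Blank lines and lines starting with ``#`` are ignored.
    """
    path = Path(path)
    values: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        letter, value = line.split()
        values[letter.upper()] = float(value)
    return HydrophobicityScale(name or path.stem, values, kt_conversion)


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with user-facing residue numbering.

    ``numbering_offset`` maps internal 0-based indices to reported positions:
    ``position = index + numbering_offset``.  The core-p53 fixture uses offset
    94 so its first residue reports as position 94.
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residues must be non-empty")
        if not self.residues.isupper():
            raise ValueError("residues must be uppercase")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def first_position(self) -> int:
        return self.numbering_offset

    @property
    def last_position(self) -> int:
        return self.numbering_offset + len(self.residues) - 1

    def index(self, position: int) -> int:
        """0-based index of a residue given in reported numbering."""
        i = position - self.numbering_offset
        if not 0 <= i < len(self.residues):
            raise IndexError(
                f"position {position} outside {self.first_position}-{self.last_position}"
            )
        return i

    def segment(self, start: int, end: int) -> str:
        """Residues from ``start`` to ``end`` inclusive (reported numbering)."""
        return self.residues[self.index(start): self.index(end) + 1]


@dataclass(frozen=True)
class SegmentWindow:
    """A contiguous window of residues with its summed hydrophobicity."""

    center: int          # reported (offset) numbering
    width: int
    sequence: str
    h_sum: float

    @property
    def start(self) -> int:
        return self.center - _left_extent(self.width)

    @property
    def end(self) -> int:
        return self.center + _right_extent(self.width)

    @property
    def span(self) -> str:
        return f"{self.start}-{self.end}"


def _left_extent(width: int) -> int:
    # odd widths are center-symmetric; even widths anchor the center on the
    # left of the two middle residues (the documented special case for w = 4)
    return (width - 1) // 2


def _right_extent(width: int) -> int:
    return width // 2


def window_hydrophobicity(protein: ProteinRecord, center: int, width: int,
                          scale: HydrophobicityScale,
                          nonstandard: str = "error") -> SegmentWindow:
    """Segment hydrophobicity h_{i,w}: the scale values summed over the
    ``width`` residues centered at ``center`` (reported numbering).

    The window must lie fully inside the protein; overhanging windows raise.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    start = center - _left_extent(width)
    end = center + _right_extent(width)
    if start < protein.first_position or end > protein.last_position:
        raise ValueError(
            f"window {start}-{end} overhangs protein "
            f"{protein.first_position}-{protein.last_position}"
        )
    seq = protein.segment(start, end)
    return SegmentWindow(center, width, seq, scale.segment_sum(seq, nonstandard))


def hydrophobicity_profile(protein: ProteinRecord, width: int,
                           scale: HydrophobicityScale,
                           nonstandard: str = "error") -> list[SegmentWindow]:
    """One window per admissible center, in position order.

    Centers too close to either terminus for a full window are skipped, not
    padded; the profile therefore has ``len - width + 1`` entries.
    """
    if len(protein) < width:
        raise ValueError(
            f"sequence of length {len(protein)} shorter than window width {width}"
        )
    first = protein.first_position + _left_extent(width)
    last = protein.last_position - _right_extent(width)
    return [
        window_hydrophobicity(protein, c, width, scale, nonstandard)
        for c in range(first, last + 1)
    ]
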