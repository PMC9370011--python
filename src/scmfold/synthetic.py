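"""Synthetic sequences, the brute-force scoring oracle, and the core-p53 fixture.

The generator produces i.i.d. background sequences with a controllable
residue composition and optional *planted* segments — short, strongly
hydrophobic 5-mers overwritten at chosen positions — so that scan behaviour
(planted-pair recovery, suppression, ranking) can be tested against known
ground truth without any external data.  No Markov structure is imposed: the
contact scan assumes nothing about local sequence correlation.

``oracle_scan`` re-scores every admissible window pair with an independently
coded double loop; it shares the scale constants but none of the scanning
code, so it can serve as a brute-force cross-check of the main scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .hydrophobicity import (
    STANDARD_AA,
    HydrophobicityScale,
    ProteinRecord,
)
from .scan import ScanConfig


@dataclass(frozen=True)
class GeneratorSpec:
    """Recipe for one synthetic sequence.

    ``plants`` lists (segment, start) insertions in 1-based positions of the
    generated record; planted segments overwrite the background and may not
    overlap each other.
    """

    length: int
    composition: dict[str, float] | None = None
    seed: int = 0
    plants: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.composition is not None:
            if abs(sum(self.composition.values()) - 1.0) > 1e-9:
                raise ValueError("composition probabilities must sum to 1")
            unknown = set(self.composition) - set(STANDARD_AA)
            if unknown:
                raise ValueError(f"unknown residues in composition: {sorted(unknown)}")
        spans = []
        for seg, start in self.plants:
            end = start + len(seg) - 1
            if start < 1 or end > self.length:
                raise ValueError(f"plant {seg!r} at {start} does not fit in {self.length}")
            spans.append((start, end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("planted segments overlap")


def generate_sequence(spec: GeneratorSpec) -> ProteinRecord:
    """Draw a background sequence and overwrite the planted segments.

    Deterministic for a given spec (seeded generator)."""
    rng = np.random.default_rng(spec.seed)
    letters = list(STANDARD_AA)
    if spec.composition is None:
        probs = None
    else:
        probs = [spec.composition.get(ch, 0.0) for ch in letters]
    residues = list(rng.choice(letters, size=spec.length, p=probs))
    for seg, start in spec.plants:
        residues[start - 1: start - 1 + len(seg)] = list(seg.upper())
    return ProteinRecord(id=f"synthetic-seed{spec.seed}", residues="".join(residues))


def oracle_scan(
    protein: ProteinRecord,
    scale: HydrophobicityScale,
    config: ScanConfig | None = None,
) -> list[tuple[int, int, float]]:
    """Brute-force reference scoring of every admissible window pair.

    Returns ``(center_a, center_b, dG_total)`` tuples in center order, with
    centers in the record's reported numbering.  Deliberately naive: a plain
    double loop over all center pairs, summing scale values afresh for each
    window and evaluating the free energy inline.
    """
    config = config or ScanConfig()
    seq = protein.residues
    w = config.width
    left, right = (w - 1) // 2, w // 2
    side_cost = config.sidechain_cost_per_residue * (2 * w)
    hits: list[tuple[int, int, float]] = []
    for ia in range(left, len(seq) - right):
        for ib in range(left, len(seq) - right):
            sep = ib - ia
            if sep < config.min_separation or sep > config.max_separation:
                continue
            h_a = 0.0
            for ch in seq[ia - left: ia + right + 1]:
                h_a += scale.values[ch]
            h_b = 0.0
            for ch in seq[ib - left: ib + right + 1]:
                h_b += scale.values[ch]
            dg = (-(h_a + h_b) / scale.kt_conversion
                  + config.loop_exponent * math.log(sep) + side_cost)
            hits.append((ia + protein.numbering_offset,
                         ib + protein.numbering_offset, dg))
    return hits


# ---------------------------------------------------------------------------
# Core-p53 fixture: residues 94-297 of canonical human p53 (the DNA-binding
# domain), embedded so end-to-end checks need no download.

P53_CORE_OFFSET = 94

_P53_CORE_LINES = (
    "SSSVPSQ",        # 94-100
    "KTYQGSYGFR",     # 101-110
    "LGFLHSGTAK",     # 111-120
    "SVTCTYSPAL",     # 121-130
    "NKMFCQLAKT",     # 131-140
    "CPVQLWVDST",     # 141-150
    "PPPGTRVRAM",     # 151-160
    "AIYKQSQHMT",     # 161-170
    "EVVRRCPHHE",     # 171-180
    "RCSDSDGLAP",     # 181-190
    "PQHLIRVEGN",     # 191-200
    "LRVEYLDDRN",     # 201-210
    "TFRHSVVVPY",     # 211-220
    "EPPEVGSDCT",     # 221-230
    "TIHYNYMCNS",     # 231-240
    "SCMGGMNRRP",     # 241-250
    "ILTIITLEDS",     # 251-260
    "SGNLLGRNSF",     # 261-270
    "EVRVCACPGR",     # 271-280
    "DRRTEEENLR",     # 281-290
    "KKGEPHH",        # 291-297
)

P53_CORE_SEQUENCE = "".join(_P53_CORE_LINES)

#: Landmark segments (reported numbering) used as transcription-integrity
#: checks: a copy error in the embedded sequence fails loudly at fixture load.
P53_LANDMARKS: dict[tuple[int, int], str] = {
    (133, 137): "MFCQL",
    (143, 147): "VQLWV",
    (159, 163): "AMAIY",
    (216, 220): "VVVPY",
    (234, 238): "YNYMC",
    (250, 257): "PILTIITL",
}

#: Published reference stabilities (kT) and their one-standard-deviation
#: uncertainties for the four core-p53 primary contacts, used as explicit
#: inputs to the population stage.
P53_PRINTED_STABILITIES: tuple[float, ...] = (8.9, 8.2, 7.8, 7.8)
P53_PRINTED_UNCERTAINTIES: tuple[float, ...] = (0.3, 0.4, 0.4, 0.4)
P53_CONTACT_LABELS: tuple[str, ...] = ("C1", "C2", "C3", "C4")

#: The aggregation-seeding peptide P8, identical to native residues 250-257.
P8_PEPTIDE = "PILTIITL"


def make_p53_fixture() -> ProteinRecord:
    """The embedded 204-residue core-p53 record (reported positions 94-297).

    Raises if any landmark segment fails to match, so the fixture can never
    silently drift from the published spans.
    """
    record = ProteinRecord(id="core-p53", residues=P53_CORE_SEQUENCE,
                           numbering_offset=P53_CORE_OFFSET)
    if len(record) != 204:
        raise AssertionError(f"core-p53 fixture length {len(record)} != 204")
    for (start, end), expected in P53_LANDMARKS.items():
        actual = record.segment(start, end)
        if actual != expected:
            raise AssertionError(
                f"core-p53 fixture {start}-{end} reads {actual!r}, expected {expected!r}"
            )
    return record
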