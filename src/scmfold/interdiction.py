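"""Folding-interdiction analysis: peptides that compete with primary contacts.

Each primary contact offers two interdiction designs: either segment can be
the template of a folding-interdicting peptide (FIP) that competes for its
partner, the folding-interdiction target region (FITR).  An exogenous
peptide is mapped onto the contacts it can interdict by aligning it against
the native sequence; every matched contact segment yields two assignments,
one per interdiction mode:

* ``bind_partner`` — the peptide mimics the matched segment and binds the
  partner segment, out-competing the intramolecular contact;
* ``mask_segment`` — the peptide binds the matched segment itself, masking
  it from its partner.

Which mode dominates is experimentally undetermined, so both are always
reported.  Attachment scores and the population-redistribution operation are
model extensions beyond the contact-scan formalism and are flagged as such
in every report.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hydrophobicity import ProteinRecord, SegmentWindow
from .populations import ChannelPopulations, boltzmann_populations
from .scan import DEFAULT_KT_CONVERSION, ContactCandidate, ContactSet, ScanConfig

MODE_BIND_PARTNER = "bind_partner"
MODE_MASK_SEGMENT = "mask_segment"


@dataclass(frozen=True)
class FitrDesignation:
    """One FIP/FITR ordering of a contact's two segments."""

    contact_label: str
    fip_template: SegmentWindow
    fitr: SegmentWindow


@dataclass(frozen=True)
class PeptideAssignment:
    """A peptide matched to one segment of one contact, in one mode."""

    peptide: str
    contact_label: str
    matched_segment: str        # "a" or "b"
    overlap_length: int
    mode: str                   # bind_partner | mask_segment
    attachment_score_kt: float  # model extension; negative = favorable
    polymeric_seed: bool = False


@dataclass(frozen=True)
class RedistributedPopulations:
    """Channel populations after blocking a fraction of one channel's flux."""

    baseline: ChannelPopulations
    blocked_label: str
    efficiency: float
    result: ChannelPopulations


def fitr_pairs(contact: ContactCandidate) -> tuple[FitrDesignation, FitrDesignation]:
    """Both FIP/FITR orderings of a contact's segments."""
    return (
        FitrDesignation(contact.label, contact.window_a, contact.window_b),
        FitrDesignation(contact.label, contact.window_b, contact.window_a),
    )


def attachment_score(
    peptide_window: SegmentWindow,
    target_window: SegmentWindow,
    config: ScanConfig | None = None,
    kt_conversion: float = DEFAULT_KT_CONVERSION,
) -> float:
    """Intermolecular attachment free energy in kT (model extension).

    The intramolecular contact formula with the loop-entropy term removed:
    an intermolecular attachment closes no loop, so only the hydrophobic
    gain and the side-chain immobilisation cost remain:

        −(h_pep + h_target)/kt_conversion + sidechain_cost_per_residue · 2w

    Always at least dG_loop more favorable than the same segments' contact.
    """
    config = config or ScanConfig(width=peptide_window.width)
    if peptide_window.width != target_window.width:
        raise ValueError("peptide and target windows must have equal width")
    return (
        -(peptide_window.h_sum + target_window.h_sum) / kt_conversion
        + config.sidechain_cost_per_residue * 2 * peptide_window.width
    )


def _hamming_matches(peptide: str, protein: ProteinRecord, tolerance: int):
    """Start positions (reported numbering) where the peptide aligns
    full-length against the native sequence with <= tolerance mismatches."""
    seq = protein.residues
    L = len(peptide)
    for i in range(len(seq) - L + 1):
        mism = sum(1 for a, b in zip(peptide, seq[i:i + L]) if a != b)
        if mism <= tolerance:
            yield i + protein.numbering_offset


def map_peptide_to_contacts(
    peptide: str,
    protein: ProteinRecord,
    contacts: ContactSet,
    min_overlap: int = 5,
    mismatch_tolerance: int = 0,
    polymeric_seed: bool = False,
    kt_conversion: float = DEFAULT_KT_CONVERSION,
) -> list[PeptideAssignment]:
    """Assignments of a peptide to every contact segment it covers.

    The peptide is aligned full-length against the native sequence (exact by
    default; ``mismatch_tolerance`` allows substitutions).  A contact segment
    is matched when an alignment footprint overlaps it by at least
    ``min_overlap`` residues; each match yields one assignment per
    interdiction mode.  An empty list means the peptide cannot interdict any
    scanned contact.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    peptide = peptide.upper()
    footprints = [
        (start, start + len(peptide) - 1)
        for start in _hamming_matches(peptide, protein, mismatch_tolerance)
    ]
    out: list[PeptideAssignment] = []
    for contact in contacts:
        for tag, window, partner in (
            ("a", contact.window_a, contact.window_b),
            ("b", contact.window_b, contact.window_a),
        ):
            overlap = max(
                (min(e, window.end) - max(s, window.start) + 1 for s, e in footprints),
                default=0,
            )
            if overlap < min_overlap:
                continue
            for mode, target in (
                (MODE_BIND_PARTNER, partner),
                (MODE_MASK_SEGMENT, window),
            ):
                out.append(PeptideAssignment(
                    peptide=peptide,
                    contact_label=contact.label,
                    matched_segment=tag,
                    overlap_length=overlap,
                    mode=mode,
                    attachment_score_kt=attachment_score(
                        window, target, contacts.config, kt_conversion
                    ),
                    polymeric_seed=polymeric_seed,
                ))
    return out


def redistribute_populations(
    baseline: ChannelPopulations, blocked_label: str, efficiency: float
) -> RedistributedPopulations:
    """Block a fraction ``efficiency`` of one channel's nucleation flux and
    reassign the removed mass to the surviving channels in proportion to
    their baseline Boltzmann weights.

    With p_b the blocked fraction: the blocked channel keeps p_b(1−ε) and
    every other channel k gains ε·p_b·p_k/(1−p_b), so the total stays 1.
    At ε = 1 this coincides with Boltzmann weighting over the surviving
    contacts alone.  How blocked flux partitions among survivors is a
    modeling assumption, not a measured quantity.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    if blocked_label not in baseline.labels:
        raise KeyError(f"unknown channel label {blocked_label!r}")
    k = baseline.labels.index(blocked_label)
    p_b = baseline.fractions[k]
    if p_b == 1.0 and efficiency > 0:
        raise ValueError("cannot redistribute: blocked channel is the only channel")
    removed = efficiency * p_b
    fractions = [
        p * (1.0 + removed / (1.0 - p_b)) if i != k else p_b * (1.0 - efficiency)
        for i, p in enumerate(baseline.fractions)
    ]
    result = ChannelPopulations(baseline.labels, baseline.stabilities,
                                tuple(fractions))
    return RedistributedPopulations(baseline, blocked_label, efficiency, result)
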