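"""Primary-contact scan: score all admissible non-local segment pairs.

A primary contact is an early non-local contact between two short hydrophobic
segments that nucleates a folding pathway by closing a loop of ``n_ij``
residues.  Its free energy decomposes into three terms, all in kT:

    dG_cont = dG_hyd + dG_loop + dG_sidechain

* ``dG_hyd``       = −(h_a + h_b) / kt_conversion — hydrophobic stabilisation
  of the paired segments (h sums on the Fauchère–Pliska scale, 0.45 ≈ 1 kT);
* ``dG_loop``      = loop_exponent · ln(n_ij) — entropic cost of closing the
  loop, with the ideal-excluded-volume exponent 3/2 by default;
* ``dG_sidechain`` = 1.09 kT per contact residue over both segments — the
  entropic cost of immobilising the side chains (10.9 kT at width 5).

Negative dG_cont means a stable contact; reports print the positive
magnitude as "stability".  Admissible separations are bounded below by the
optimal minimal loop (~65 residues) and above by the maximum primary loop
(~100 residues), both inclusive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .hydrophobicity import (
    HydrophobicityScale,
    ProteinRecord,
    SegmentWindow,
    hydrophobicity_profile,
)

DEFAULT_KT_CONVERSION = 0.45


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the contact scan.

    Defaults encode the model's standard operating point: 5-residue contact
    windows, loop separations between 65 and 100 residues inclusive, a 3 kT
    reporting cutoff below the best contact, a side-chain entropy cost of
    1.09 kT per contact residue, and the 3/2 loop-closure exponent.
    """

    width: int = 5
    min_separation: int = 65
    max_separation: int = 100
    cutoff_kt: float = 3.0
    sidechain_cost_per_residue: float = 1.09
    loop_exponent: float = 1.5

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("width must be >= 1")
        if not 0 < self.min_separation <= self.max_separation:
            raise ValueError("require 0 < min_separation <= max_separation")
        if self.cutoff_kt < 0:
            raise ValueError("cutoff_kt must be >= 0")

    @property
    def sidechain_cost_kt(self) -> float:
        """Total side-chain cost for one contact: both segments' residues.

        Equals the canonical 10.9 kT at the default width of 5."""
        return self.sidechain_cost_per_residue * 2 * self.width


@dataclass(frozen=True)
class ContactCandidate:
    """A scored pair of segment windows (a is N-terminal, b is C-terminal)."""

    window_a: SegmentWindow
    window_b: SegmentWindow
    n_ij: int
    dG_hyd: float
    dG_loop: float
    dG_sidechain: float
    dG_total: float
    label: str = ""
    uncertainty_kt: float | None = None

    @property
    def stability_kt(self) -> float:
        """Positive magnitude of a stable contact's free energy (report sign)."""
        return -self.dG_total

    def with_label(self, label: str) -> "ContactCandidate":
        return replace(self, label=label)


@dataclass(frozen=True)
class ContactSet:
    """The selected primary contacts, most stable first."""

    contacts: tuple[ContactCandidate, ...]
    config: ScanConfig
    protein_id: str

    def __len__(self) -> int:
        return len(self.contacts)

    def __iter__(self):
        return iter(self.contacts)

    def by_label(self, label: str) -> ContactCandidate:
        for c in self.contacts:
            if c.label == label:
                return c
        raise KeyError(f"no contact labelled {label!r}")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.contacts]

    @property
    def stabilities(self) -> list[float]:
        return [c.stability_kt for c in self.contacts]


def contact_energy_components(
    h_a: float, h_b: float, n_ij: int, config: ScanConfig,
    kt_conversion: float = DEFAULT_KT_CONVERSION,
) -> tuple[float, float, float]:
    """The three free-energy terms (hydrophobic, loop, side-chain) in kT."""
    if n_ij < 1:
        raise ValueError("n_ij must be >= 1")
    dg_hyd = -(h_a + h_b) / kt_conversion
    dg_loop = config.loop_exponent * math.log(n_ij)
    return dg_hyd, dg_loop, config.sidechain_cost_kt


def contact_free_energy(
    h_a: float, h_b: float, n_ij: int, config: ScanConfig | None = None,
    kt_conversion: float = DEFAULT_KT_CONVERSION,
) -> float:
    """Contact free energy dG_cont in kT (negative = stable).

    For the default configuration this is
    ``kT [ −(h_a + h_b)/0.45 + 3/2 ln(n_ij) + 10.9 ]``.
    """
    config = config or ScanConfig()
    return sum(contact_energy_components(h_a, h_b, n_ij, config, kt_conversion))


def enumerate_candidates(
    protein: ProteinRecord,
    scale: HydrophobicityScale,
    config: ScanConfig | None = None,
    nonstandard: str = "error",
) -> list[ContactCandidate]:
    """Score every ordered pair of in-bounds window centers whose separation
    lies within ``[min_separation, max_separation]`` (inclusive), exactly once.

    Returns the full scored grid in (center_a, center_b) order.  If the
    sequence admits no pair, an empty grid is returned with a warning.
    """
    config = config or ScanConfig()
    if len(protein) < config.width:
        raise ValueError("sequence shorter than window width")
    profile = hydrophobicity_profile(protein, config.width, scale, nonstandard)
    grid: list[ContactCandidate] = []
    for ia, wa in enumerate(profile):
        lo = ia + config.min_separation
        hi = min(ia + config.max_separation, len(profile) - 1)
        for ib in range(lo, hi + 1):
            wb = profile[ib]
            n_ij = wb.center - wa.center
            hyd, loop, side = contact_energy_components(
                wa.h_sum, wb.h_sum, n_ij, config, scale.kt_conversion
            )
            grid.append(ContactCandidate(
                wa, wb, n_ij, hyd, loop, side, hyd + loop + side
            ))
    if not grid:
        warnings.warn(
            f"{protein.id}: no admissible segment pair at separations "
            f"{config.min_separation}-{config.max_separation}",
            stacklevel=2,
        )
    return grid


def _rank_key(c: ContactCandidate) -> tuple:
    # deterministic ordering: most stable first, then tighter loop, then
    # N-terminal-most centers
    return (c.dG_total, c.n_ij, c.window_a.center, c.window_b.center)


def _spans_overlap(w1: SegmentWindow, w2: SegmentWindow) -> bool:
    return w1.start <= w2.end and w2.start <= w1.end


def select_primary_contacts(
    grid: list[ContactCandidate], config: ScanConfig | None = None
) -> ContactSet:
    """Collapse shifted variants and keep contacts within the cutoff.

    Non-maximum suppression: a candidate survives only if no better-ranked
    candidate exists whose a-window AND b-window both overlap its own — so a
    plateau of frame-shifted variants collapses to its local optimum, while
    candidates sharing only one segment stay distinct.  Survivors within
    ``cutoff_kt`` of the best contact are ranked most stable first and
    labelled C1, C2, ...
    """
    if not grid:
        raise ValueError("cannot select contacts from an empty grid")
    config = config or ScanConfig()
    by_centers = {(c.window_a.center, c.window_b.center): c for c in grid}
    w = config.width
    retained: list[ContactCandidate] = []
    for c in grid:
        key = _rank_key(c)
        suppressed = False
        # only candidates within one window width in both centers can overlap
        for da in range(-(w - 1), w):
            for db in range(-(w - 1), w):
                if da == 0 and db == 0:
                    continue
                other = by_centers.get(
                    (c.window_a.center + da, c.window_b.center + db)
                )
                if other is None or _rank_key(other) >= key:
                    continue
                if (_spans_overlap(other.window_a, c.window_a)
                        and _spans_overlap(other.window_b, c.window_b)):
                    suppressed = True
                    break
            if suppressed:
                break
        if not suppressed:
            retained.append(c)
    retained.sort(key=_rank_key)
    best = retained[0]
    kept = [
        c.with_label(f"C{i + 1}")
        for i, c in enumerate(
            c for c in retained if c.stability_kt >= best.stability_kt - config.cutoff_kt
        )
    ]
    protein_id = ""  # grid windows carry no record id; caller may set one
    return ContactSet(tuple(kept), config, protein_id)


def scan_protein(
    protein: ProteinRecord,
    scale: HydrophobicityScale,
    config: ScanConfig | None = None,
    nonstandard: str = "error",
) -> ContactSet:
    """Convenience: enumerate, suppress and select in one call."""
    config = config or ScanConfig()
    grid = enumerate_candidates(protein, scale, config, nonstandard)
    if not grid:
        return ContactSet((), config, protein.id)
    selected = select_primary_contacts(grid, config)
    return replace(selected, protein_id=protein.id)
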