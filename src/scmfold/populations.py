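"""Folding-channel populations from contact stabilities.

Each primary contact nucleates a folding channel; the fraction of molecules
entering channel k is taken proportional to the Boltzmann weight of its
contact stability, p_k = exp(s_k) / Σ_m exp(s_m), with s_k the stability
magnitude in kT (equivalently exp(−dG_k/kT)).  Contacts of indistinguishable
stability appear merged as a single kinetic channel in low-resolution
experiments, carrying the sum of their fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ChannelPopulations:
    """Relative channel populations aligned with their contact stabilities."""

    labels: tuple[str, ...]
    stabilities: tuple[float, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.stabilities) == len(self.fractions)):
            raise ValueError("labels, stabilities and fractions must align")
        if abs(sum(self.fractions) - 1.0) > _SUM_TOL:
            raise ValueError("fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")

    def fraction(self, label: str) -> float:
        return self.fractions[self.labels.index(label)]

    @property
    def percents(self) -> list[int]:
        """Integer percentages, rounded half away from zero."""
        return [round_half_away(100.0 * f) for f in self.fractions]


@dataclass(frozen=True)
class PopulationInterval:
    """Signed population change (percentage points) under a one-at-a-time
    perturbation of one contact's own stability by ± its uncertainty."""

    label: str
    shift_up: float
    shift_down: float


@dataclass(frozen=True)
class KineticChannel:
    """Contacts merged into one experimentally observable channel."""

    member_labels: tuple[str, ...]
    combined_fraction: float


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (23.5 → 24, −6.5 → −7)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def boltzmann_populations(
    stabilities: list[float] | tuple[float, ...],
    labels: list[str] | tuple[str, ...] | None = None,
) -> ChannelPopulations:
    """Boltzmann weighting of stability magnitudes.

    Computed as a shifted softmax (the maximum is subtracted before
    exponentiation) so large stabilities cannot overflow.
    """
    if len(stabilities) == 0:
        raise ValueError("at least one stability is required")
    s = np.asarray(stabilities, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("stabilities must be finite")
    w = np.exp(s - s.max())
    fractions = w / w.sum()
    if labels is None:
        labels = [f"C{i + 1}" for i in range(len(s))]
    return ChannelPopulations(tuple(labels), tuple(s.tolist()),
                              tuple(fractions.tolist()))


def perturbation_intervals(
    stabilities: list[float],
    uncertainties: list[float],
    labels: list[str] | None = None,
) -> list[PopulationInterval]:
    """One-at-a-time confidence shifts in percentage points.

    For each contact k the populations are recomputed with s_k → s_k ± u_k
    (all others fixed at their nominal values) and the signed change of
    fraction_k is reported: ``shift_up`` for +u_k (≥ 0), ``shift_down`` for
    −u_k (≤ 0).  This reproduces the asymmetric intervals that joint error
    propagation would not.
    """
    if len(stabilities) != len(uncertainties):
        raise ValueError("stabilities and uncertainties must have equal length")
    baseline = boltzmann_populations(stabilities, labels)
    out: list[PopulationInterval] = []
    for k, (label, u) in enumerate(zip(baseline.labels, uncertainties)):
        shifts = []
        for sign in (+1, -1):
            s = list(stabilities)
            s[k] += sign * u
            p = boltzmann_populations(s, baseline.labels)
            shifts.append(100.0 * (p.fractions[k] - baseline.fractions[k]))
        out.append(PopulationInterval(label, shift_up=shifts[0], shift_down=shifts[1]))
    return out


def merge_channels(
    populations: ChannelPopulations, tolerance_kt: float
) -> list[KineticChannel]:
    """Group contacts whose stabilities are within ``tolerance_kt`` of each
    other, transitively, into merged kinetic channels.

    Merging is transitive along the stability-sorted chain: if s1~s2 and
    s2~s3 then all three share a channel even if |s1−s3| exceeds the
    tolerance.  Channels are returned most populated-stable first (order of
    the most stable member).
    """
    if tolerance_kt < 0:
        raise ValueError("tolerance_kt must be >= 0")
    order = sorted(range(len(populations.labels)),
                   key=lambda i: -populations.stabilities[i])
    groups: list[list[int]] = []
    for i in order:
        if groups and (populations.stabilities[groups[-1][-1]]
                       - populations.stabilities[i]) <= tolerance_kt:
            groups[-1].append(i)
        else:
            groups.append([i])
    return [
        KineticChannel(
            tuple(populations.labels[i] for i in g),
            sum(populations.fractions[i] for i in g),
        )
        for g in groups
    ]
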