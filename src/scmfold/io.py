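"""FASTA input, report assembly, run configuration and the pipeline driver."""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .hydrophobicity import HydrophobicityScale, ProteinRecord, load_scale
from .interdiction import map_peptide_to_contacts, redistribute_populations
from .populations import (
    ChannelPopulations,
    boltzmann_populations,
    merge_channels,
    perturbation_intervals,
)
from .scan import ContactSet, ScanConfig, scan_protein

logger = logging.getLogger("scmfold")

TSV_COLUMNS = [
    "rank", "label", "seg_a_span", "seg_a_seq", "seg_b_span", "seg_b_seq",
    "n_ij", "dG_hyd_kT", "dG_loop_kT", "dG_sidechain_kT", "stability_kT",
]


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the sequences themselves."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    scale_name: str = "fauchere-pliska"
    offset: int = 1
    output_format: str = "tsv"
    uncertainties: list[float] | None = None
    stabilities_override: list[float] | None = None
    merge_tolerance_kt: float = 0.0
    nonstandard: str = "error"
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a JSON config file; unknown keys are rejected."""
        data = json.loads(Path(path).read_text())
        scan = ScanConfig(**data.pop("scan", {}))
        known = {f.name for f in dataclasses.fields(cls)} - {"scan"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(scan=scan, **data)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(data, indent=2) + "\n")


def read_fasta(path: str | Path, offset: int = 1) -> list[ProteinRecord]:
    """Parse a (possibly multi-record, line-wrapped) FASTA file.

    Sequences are uppercased; ``*`` stop characters are stripped with a
    warning; duplicate ids are disambiguated by a numeric suffix.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "*" in seq:
            warnings.warn(f"{rec.id}: stripped '*' stop character(s)", stacklevel=2)
            seq = seq.replace("*", "")
        rec_id = rec.id
        if rec_id in seen:
            seen[rec_id] += 1
            new_id = f"{rec_id}-{seen[rec_id]}"
            warnings.warn(f"duplicate FASTA id {rec_id!r} renamed to {new_id!r}",
                          stacklevel=2)
            rec_id = new_id
        else:
            seen[rec_id] = 1
        records.append(ProteinRecord(id=rec_id, residues=seq, numbering_offset=offset))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, wrap: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i:i + wrap] + "\n")


def contact_records(
    contacts: ContactSet,
    populations: ChannelPopulations | None = None,
    intervals=None,
) -> list[dict]:
    """Per-contact report rows (full precision; formatting happens on output)."""
    by_label_interval = {iv.label: iv for iv in (intervals or [])}
    rows = []
    for rank, c in enumerate(contacts, start=1):
        row = {
            "rank": rank,
            "label": c.label,
            "seg_a_span": c.window_a.span,
            "seg_a_seq": c.window_a.sequence,
            "seg_b_span": c.window_b.span,
            "seg_b_seq": c.window_b.sequence,
            "n_ij": c.n_ij,
            "dG_hyd_kT": c.dG_hyd,
            "dG_loop_kT": c.dG_loop,
            "dG_sidechain_kT": c.dG_sidechain,
            "stability_kT": c.stability_kt,
        }
        if populations is not None:
            frac = populations.fraction(c.label)
            row["population_frac"] = frac
            row["population_pct"] = populations.percents[
                populations.labels.index(c.label)]
        iv = by_label_interval.get(c.label)
        if iv is not None:
            row["pop_shift_up_pp"] = iv.shift_up
            row["pop_shift_down_pp"] = iv.shift_down
        rows.append(row)
    return rows


def contacts_to_tsv(rows: list[dict]) -> str:
    """Deterministic TSV: fixed column order, energies to 4 decimals,
    stability to 1 decimal (report style)."""
    cols = list(TSV_COLUMNS)
    for extra in ("population_pct", "population_frac",
                  "pop_shift_up_pp", "pop_shift_down_pp"):
        if rows and extra in rows[0]:
            cols.append(extra)
    df = pd.DataFrame(rows, columns=cols)
    fmt = {
        "dG_hyd_kT": "{:.4f}", "dG_loop_kT": "{:.4f}", "dG_sidechain_kT": "{:.4f}",
        "stability_kT": "{:.1f}", "population_frac": "{:.6f}",
        "pop_shift_up_pp": "{:.4f}", "pop_shift_down_pp": "{:.4f}",
    }
    for col, f in fmt.items():
        if col in df.columns:
            df[col] = df[col].map(f.format)
    return df.to_csv(sep="\t", index=False)


def analyze_record(
    protein: ProteinRecord,
    config: RunConfig,
    scale: HydrophobicityScale | None = None,
    peptide: str | None = None,
    efficiencies: tuple[float, ...] = (),
) -> dict:
    """Scan one record and assemble its full report bundle as a JSON-ready dict."""
    scale = scale or load_scale(config.scale_name)
    contacts = scan_protein(protein, scale, config.scan, config.nonstandard)
    report: dict = {
        "protein_id": protein.id,
        "n_residues": len(protein),
        "config": dataclasses.asdict(config.scan),
        "contacts": [],
    }
    if len(contacts) == 0:
        logger.warning("%s: no contacts found (sequence too short to scan?)",
                       protein.id)
        return report

    if config.stabilities_override is not None:
        if len(config.stabilities_override) != len(contacts):
            raise ValueError(
                f"{len(config.stabilities_override)} stability overrides for "
                f"{len(contacts)} contacts"
            )
        stabilities = list(config.stabilities_override)
        report["stability_source"] = "override"
    else:
        stabilities = contacts.stabilities
        report["stability_source"] = "scan"

    populations = boltzmann_populations(stabilities, contacts.labels)
    intervals = None
    if config.uncertainties is not None:
        intervals = perturbation_intervals(
            stabilities, config.uncertainties, list(contacts.labels))
    report["contacts"] = contact_records(contacts, populations, intervals)
    report["channels"] = [
        {"members": list(ch.member_labels), "combined_fraction": ch.combined_fraction}
        for ch in merge_channels(populations, config.merge_tolerance_kt)
    ]

    if peptide:
        assignments = map_peptide_to_contacts(peptide, protein, contacts)
        interdiction: dict = {
            "peptide": peptide.upper(),
            "note": ("attachment scores and population redistribution are "
                     "model extensions; redistribution of blocked flux in "
                     "proportion to surviving Boltzmann weights is a modeling "
                     "assumption"),
            "assignments": [dataclasses.asdict(a) for a in assignments],
            "redistributions": [],
        }
        blocked = sorted({a.contact_label for a in assignments})
        for eps in efficiencies:
            for label in blocked:
                red = redistribute_populations(populations, label, eps)
                interdiction["redistributions"].append({
                    "blocked_label": label,
                    "efficiency": eps,
                    "fractions": dict(zip(red.result.labels, red.result.fractions)),
                })
        report["interdiction"] = interdiction
    return report


def run_pipeline(
    fasta_path: str | Path,
    config: RunConfig,
    peptide: str | None = None,
    efficiencies: tuple[float, ...] = (),
) -> dict[str, dict]:
    """Full pipeline over every record of a FASTA file.

    Returns ``{record_id: report}``; records too short to scan produce a
    report with an empty contact list and a logged warning.
    """
    scale = load_scale(config.scale_name)
    reports: dict[str, dict] = {}
    for protein in read_fasta(fasta_path, offset=config.offset):
        if len(protein) < config.scan.min_separation + config.scan.width:
            logger.warning("%s: length %d admits no contact pair; skipping scan",
                           protein.id, len(protein))
            reports[protein.id] = {
                "protein_id": protein.id,
                "n_residues": len(protein),
                "contacts": [],
            }
            continue
        reports[protein.id] = analyze_record(
            protein, config, scale, peptide, efficiencies)
    return reports
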