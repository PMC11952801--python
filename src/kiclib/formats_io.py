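"""Readers and writers for every external format the toolkit touches.

All tabular inputs are flat TSV/CSV files with fixed headers; sequences travel
as FASTA (plain or aligned).  Validation is total: every input row becomes
either a domain record or an error record, never a silent drop.

Coordinates are 1-based and inclusive throughout, matching the residue naming
conventions of the phosphoproteomics literature (e.g. "Thr196 of CBL9").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("kiclib")

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Proteome sequences may additionally carry the ambiguity character X.
PROTEOME_ALPHABET = frozenset(AMINO_ACIDS + "X")
#: Phospho-acceptor residues.
PHOSPHO_RESIDUES = frozenset("STY")

SITE_TABLE_COLUMNS = ["protein_id", "position", "residue", "species", "evidence"]
LIBRARY_COLUMNS = [
    "sequence",
    "protein_id",
    "site_position",
    "site_offset",
    "sources",
    "score",
    "clamped",
]


def setup_logging(level: str = "INFO") -> None:
    """Configure the package logger (idempotent)."""
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def load_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key=value`` configuration file.

    Blank lines and ``#`` comments are ignored; later keys override earlier
    ones.  Values are returned as strings; callers coerce as needed.
    """
    config: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line (expected key=value): {raw!r}")
        key, value = line.split("=", 1)
        config[key.strip()] = value.strip()
    return config


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its species label."""

    id: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if not self.sequence:
            raise ValueError(f"protein {self.id}: empty sequence")
        bad = sorted(set(self.sequence) - PROTEOME_ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id}: characters outside the amino-acid alphabet: "
                + ", ".join(repr(c) for c in bad)
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside protein {self.id} (length {len(self)})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class Phosphosite:
    """An observed or candidate phosphorylated residue on a protein."""

    protein_id: str
    position: int  # 1-based
    residue: str  # S, T or Y
    species: str = ""
    evidence: str = ""

    def __post_init__(self) -> None:
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"{self.protein_id}:{self.position}: residue {self.residue!r} "
                "is not a phospho-acceptor (S/T/Y)"
            )
        if self.position < 1:
            raise ValueError(f"{self.protein_id}: position must be >= 1")


@dataclass(frozen=True)
class RowError:
    """A table row that failed validation, with its reason."""

    row_index: int
    reason: str
    row: dict = field(default_factory=dict, compare=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def _species_from_description(description: str) -> str:
    for token in description.split():
        if token.startswith("species="):
            return token[len("species=") :]
    return ""


def read_proteome(path: str | Path, species: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA into validated records, order preserved.

    The species label is taken from a ``species=...`` token in the header
    description, unless ``species`` overrides it for the whole file.
    Duplicate ids and invalid sequences raise.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate protein id in {path}: {entry.id}")
        seen.add(entry.id)
        records.append(
            ProteinRecord(
                id=entry.id,
                species=species
                if species is not None
                else _species_from_description(entry.description),
                sequence=str(entry.seq).upper(),
            )
        )
    return records


def write_proteome(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA with ``species=`` header tokens."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"species={r.species}")
        for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def read_alignment(path: str | Path, query_id: str | None = None):
    """Read an aligned FASTA into an :class:`~kiclib.conservation.OrthologAlignment`.

    The query row is the record whose id equals ``query_id``; by default the
    first record is the query.
    """
    from .conservation import OrthologAlignment  # deferred: avoid import cycle

    ids: list[str] = []
    species: list[str] = []
    rows: list[str] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        ids.append(entry.id)
        species.append(_species_from_description(entry.description))
        rows.append(str(entry.seq).upper())
    if query_id is None:
        query_row = 0
    else:
        try:
            query_row = ids.index(query_id)
        except ValueError:
            raise ValueError(f"query id {query_id!r} not present in {path}") from None
    return OrthologAlignment(
        rows=rows, species_labels=species, row_ids=ids, query_row=query_row
    )


# ---------------------------------------------------------------------------
# Phosphosite tables (TSV)
# ---------------------------------------------------------------------------


def read_site_table(
    path: str | Path, proteome: Sequence[ProteinRecord]
) -> tuple[list[Phosphosite], list[RowError]]:
    """Read a phosphosite TSV and validate every row against the proteome.

    Required columns: protein_id, position, residue, species (``evidence`` and
    any extra columns are carried along but not interpreted).  Each row is
    returned either as a validated :class:`Phosphosite` or as a
    :class:`RowError`; nothing is silently dropped, and row order is kept.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"protein_id", "position", "residue", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} missing columns: {sorted(missing)}")
    by_id = {p.id: p for p in proteome}

    sites: list[Phosphosite] = []
    errors: list[RowError] = []
    for idx, row in df.iterrows():
        record = row.to_dict()
        protein = by_id.get(row["protein_id"])
        if protein is None:
            errors.append(RowError(idx, f"unknown protein_id {row['protein_id']!r}", record))
            continue
        try:
            position = int(row["position"])
        except ValueError:
            errors.append(RowError(idx, f"non-integer position {row['position']!r}", record))
            continue
        residue = row["residue"].upper()
        if residue not in PHOSPHO_RESIDUES:
            errors.append(RowError(idx, f"residue {residue!r} is not S/T/Y", record))
            continue
        if not 1 <= position <= len(protein):
            errors.append(
                RowError(
                    idx,
                    f"position {position} outside {protein.id} (length {len(protein)})",
                    record,
                )
            )
            continue
        actual = protein.residue(position)
        if actual != residue:
            errors.append(
                RowError(
                    idx,
                    f"residue mismatch at {protein.id}:{position}: "
                    f"table says {residue}, sequence has {actual}",
                    record,
                )
            )
            continue
        sites.append(
            Phosphosite(
                protein_id=row["protein_id"],
                position=position,
                residue=residue,
                species=row["species"],
                evidence=record.get("evidence", ""),
            )
        )
    if errors:
        log.warning("site table %s: %d of %d rows failed validation", path, len(errors), len(df))
    return sites, errors


def write_site_table(sites: Iterable[Phosphosite], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "protein_id": s.protein_id,
                "position": s.position,
                "residue": s.residue,
                "species": s.species,
                "evidence": s.evidence,
            }
            for s in sites
        ],
        columns=SITE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Library peptides (CSV)
# ---------------------------------------------------------------------------


def write_library(peptides: Iterable, path: str | Path) -> None:
    """Write designed peptides as CSV, rows ordered by protein_id then position.

    Source tags are semicolon-joined in sorted order; a missing conservation
    score is written as an empty field.
    """
    rows = [
        {
            "sequence": p.sequence,
            "protein_id": p.protein_id,
            "site_position": p.site_position,
            "site_offset": p.site_offset,
            "sources": ";".join(sorted(p.sources)),
            "score": "" if p.score is None else repr(p.score),
            "clamped": int(p.clamped),
        }
        for p in peptides
    ]
    rows.sort(key=lambda r: (r["protein_id"], r["site_position"]))
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, index=False)


def read_library(path: str | Path) -> list:
    """Read a library CSV back into :class:`~kiclib.library_design.LibraryPeptide`."""
    from .library_design import LibraryPeptide  # deferred: avoid import cycle

    df = pd.read_csv(path, dtype=str).fillna("")
    peptides = []
    for _, row in df.iterrows():
        peptides.append(
            LibraryPeptide(
                sequence=row["sequence"],
                protein_id=row["protein_id"],
                site_position=int(row["site_position"]),
                site_offset=int(row["site_offset"]),
                sources=frozenset(t for t in row["sources"].split(";") if t),
                score=float(row["score"]) if row["score"] else None,
                clamped=bool(int(row["clamped"])),
            )
        )
    return peptides


# ---------------------------------------------------------------------------
# Screen candidate tables (CSV)
# ---------------------------------------------------------------------------


def read_candidate_table(path: str | Path) -> list:
    """Read a search-engine phosphopeptide summary CSV into CandidateRecords.

    Required columns: peptide, phospho_positions (semicolon-joined 1-based
    indices), ascore, ptm_ion_intensity_pct, phospho_psm_count,
    total_psm_count.  Optional: condition, manual_check (0/1).
    """
    from .kic_screen import CandidateRecord  # deferred: avoid import cycle

    df = pd.read_csv(path, dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        manual = row.get("manual_check", "")
        records.append(
            CandidateRecord(
                peptide=row["peptide"],
                phospho_positions=tuple(
                    int(p) for p in row["phospho_positions"].split(";") if p
                ),
                ascore=float(row["ascore"]),
                ptm_ion_intensity_pct=float(row["ptm_ion_intensity_pct"]),
                phospho_psm_count=int(row["phospho_psm_count"]),
                total_psm_count=int(row["total_psm_count"]),
                condition=row.get("condition", "") or "WT+ATP",
                manual_check=None if manual == "" else bool(int(manual)),
            )
        )
    return records


def write_candidate_table(records: Iterable, path: str | Path) -> None:
    rows = [
        {
            "peptide": r.peptide,
            "phospho_positions": ";".join(str(p) for p in r.phospho_positions),
            "ascore": r.ascore,
            "ptm_ion_intensity_pct": r.ptm_ion_intensity_pct,
            "phospho_psm_count": r.phospho_psm_count,
            "total_psm_count": r.total_psm_count,
            "condition": r.condition,
            "manual_check": "" if r.manual_check is None else int(r.manual_check),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Intensity and localization tables (TSV)
# ---------------------------------------------------------------------------


def read_intensity_table(path: str | Path) -> list:
    """Read an in vivo phosphoproteomics intensity TSV.

    Columns: peptide, genotype (ko/wt/ox), treatment (mock/ATP), intensity
    (empty = missing).
    """
    from .overlap_mapping import IntensityRecord  # deferred: avoid import cycle

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for _, row in df.iterrows():
        records.append(
            IntensityRecord(
                peptide=row["peptide"],
                genotype=row["genotype"],
                treatment=row["treatment"],
                intensity=float(row["intensity"]) if row["intensity"] else None,
            )
        )
    return records


def write_intensity_table(records: Iterable, path: str | Path) -> None:
    rows = [
        {
            "peptide": r.peptide,
            "genotype": r.genotype,
            "treatment": r.treatment,
            "intensity": "" if r.intensity is None else repr(r.intensity),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_localization_table(path: str | Path) -> list:
    """Read a localization-evidence TSV: compartment, kind, count."""
    from .kic_screen import LocalizationEvidence  # deferred: avoid import cycle

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        LocalizationEvidence(
            compartment=row["compartment"], kind=row["kind"], count=int(row["count"])
        )
        for _, row in df.iterrows()
    ]
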