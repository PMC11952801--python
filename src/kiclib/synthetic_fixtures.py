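"""Seeded synthetic inputs with known ground truth.

Every downstream module is exercised on generated data: ortholog families
with planted conserved windows, phosphosite tables with known cross-species
conservation labels, screen summary tables with a planted pass set, and
genotype intensity tables with a planted selectable set.  All generators are
pure functions of their configuration -- the same seed always yields
byte-identical output -- so tests and the acceptance checks are reproducible
without any external download.

The default configuration mirrors the study conditions the toolkit targets:
six-species angiosperm ortholog families, the BLOSUM62 background as the
null residue distribution (so unconserved columns score near PM = 0), the
three-criterion screen filter, and a two-fold genotype intensity effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conservation import BLOSUM62_BACKGROUND, GAP, OrthologAlignment
from .formats_io import PHOSPHO_RESIDUES, Phosphosite
from .kic_screen import CandidateRecord
from .overlap_mapping import GENOTYPES, IntensityRecord


def _background_20() -> dict[str, float]:
    probs = {aa: p for aa, p in BLOSUM62_BACKGROUND.items() if aa != GAP}
    total = sum(probs.values())
    return {aa: p / total for aa, p in probs.items()}


@dataclass(frozen=True)
class SimConfig:
    """Configuration shared by all generators."""

    seed: int = 0
    n_families: int = 200
    n_species: int = 6
    protein_length: int = 60
    conserved_window_fraction: float = 0.5
    background_frequencies: Mapping[str, float] = field(default_factory=_background_20)
    n_psm_records: int = 20
    planted_pass_count: int = 7
    intensity_effect: float = 2.0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.protein_length < 1 or self.n_psm_records < 1:
            raise ValueError("all counts must be positive")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if not 0.0 <= self.conserved_window_fraction <= 1.0:
            raise ValueError("conserved_window_fraction must lie in [0, 1]")
        if not 0 <= self.planted_pass_count <= self.n_psm_records:
            raise ValueError("planted_pass_count must not exceed n_psm_records")
        total = sum(self.background_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("background_frequencies must sum to 1")


@dataclass(frozen=True)
class FamilyTruth:
    """Ground truth for one simulated ortholog family.

    The planted site columns are None when the corresponding block is too
    short to hold an 11-column window.
    """

    conserved_columns: frozenset[int]
    conserved_site_column: int | None  # S column, +/-5 flanks all conserved
    background_site_column: int | None  # S column, +/-5 flanks all background


def _draw_residues(rng: np.random.Generator, freqs: Mapping[str, float], n: int) -> list[str]:
    symbols = sorted(freqs)
    probs = np.array([freqs[s] for s in symbols])
    probs = probs / probs.sum()
    return [symbols[i] for i in rng.choice(len(symbols), size=n, p=probs)]


def random_peptide(
    rng: np.random.Generator,
    length: int = 20,
    freqs: Mapping[str, float] | None = None,
) -> str:
    """A random peptide drawn residue-wise from ``freqs`` (default BLOSUM62)."""
    if freqs is None:
        freqs = _background_20()
    return "".join(_draw_residues(rng, freqs, length))


# ---------------------------------------------------------------------------
# Ortholog families
# ---------------------------------------------------------------------------


def simulate_ortholog_family(
    config: SimConfig, family_index: int = 0
) -> tuple[OrthologAlignment, FamilyTruth]:
    """One gap-free ortholog-family alignment with a planted conserved block.

    Columns in the leading block (``conserved_window_fraction`` of the
    alignment) are identical across rows; the remaining columns are drawn
    independently per row from the background.  Two designated site columns
    carry an S in every row: one centered in the conserved block (fully
    conserved flanks) and one centered in the background block.
    """
    if config.n_species < 2:
        raise ValueError("n_species must be >= 2")
    L = config.protein_length
    w = int(round(config.conserved_window_fraction * L))
    rng = np.random.default_rng([config.seed % (2**31), family_index])
    conserved = _draw_residues(rng, config.background_frequencies, w)
    rows = []
    for _ in range(config.n_species):
        background = _draw_residues(rng, config.background_frequencies, L - w)
        rows.append("".join(conserved) + "".join(background))
    site_c = w // 2 if w >= 11 else None
    site_b = w + (L - w) // 2 if L - w >= 11 else None
    for site in (site_c, site_b):
        if site is not None:
            rows = [r[:site] + "S" + r[site + 1 :] for r in rows]
    aln = OrthologAlignment(
        rows=rows,
        species_labels=[f"species{i}" for i in range(config.n_species)],
        row_ids=[f"fam{family_index}_sp{i}" for i in range(config.n_species)],
        query_row=0,
    )
    truth = FamilyTruth(
        conserved_columns=frozenset(range(w)),
        conserved_site_column=site_c,
        background_site_column=site_b,
    )
    return aln, truth


# ---------------------------------------------------------------------------
# Phosphosite tables
# ---------------------------------------------------------------------------


def simulate_phosphosites(
    families: Sequence[OrthologAlignment],
    phospho_rate: float = 0.3,
    cross_species_rate: float = 0.5,
    seed: int = 0,
) -> tuple[list[Phosphosite], dict[tuple[str, int], bool]]:
    """Annotate phosphosites on gap-free families with known conservation.

    Candidate sites are query-row S/T/Y columns where at least one other row
    also carries an acceptor residue (so cross-species annotation is always
    possible).  Each candidate is annotated in the query species with
    probability ``phospho_rate``; with probability ``cross_species_rate`` the
    homologous column is also annotated in one other species, making the
    query site conserved by the source-1 rule.  The returned truth maps
    (query protein id, position) to the planted conserved label.
    """
    if not 0.0 <= phospho_rate <= 1.0 or not 0.0 <= cross_species_rate <= 1.0:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng([seed % (2**31), len(families)])
    sites: list[Phosphosite] = []
    truth: dict[tuple[str, int], bool] = {}
    for aln in families:
        query = aln.rows[aln.query_row]
        query_id = aln.row_ids[aln.query_row]
        for col, residue in enumerate(query):
            if residue not in PHOSPHO_RESIDUES:
                continue
            partners = [
                i
                for i in range(aln.n_rows)
                if i != aln.query_row and aln.rows[i][col] in PHOSPHO_RESIDUES
            ]
            if not partners:
                continue
            if rng.random() >= phospho_rate:
                continue
            position = col + 1  # gap-free rows: column == position - 1
            sites.append(
                Phosphosite(
                    protein_id=query_id,
                    position=position,
                    residue=residue,
                    species=aln.species_labels[aln.query_row],
                    evidence="simulated",
                )
            )
            conserved = rng.random() < cross_species_rate
            truth[(query_id, position)] = conserved
            if conserved:
                partner = partners[int(rng.integers(len(partners)))]
                sites.append(
                    Phosphosite(
                        protein_id=aln.row_ids[partner],
                        position=position,
                        residue=aln.rows[partner][col],
                        species=aln.species_labels[partner],
                        evidence="simulated",
                    )
                )
    return sites, truth


# ---------------------------------------------------------------------------
# Screen summary tables
# ---------------------------------------------------------------------------

_VIOLATIONS = ("ascore", "intensity", "psm")


def simulate_psm_table(
    config: SimConfig,
) -> tuple[list[CandidateRecord], list[tuple[str, ...]]]:
    """A screen summary table with a planted pass set.

    Exactly ``planted_pass_count`` records satisfy all three inclusive
    thresholds (Ascore >= 20, intensity >= 5%, >= 2 phospho PSMs); every
    other record violates exactly one criterion, cycling through the three.
    Returns the records together with the per-record expected failure
    reasons (empty tuple = pass).
    """
    rng = np.random.default_rng([config.seed % (2**31), 1])
    records: list[CandidateRecord] = []
    labels: list[tuple[str, ...]] = []
    for i in range(config.n_psm_records):
        peptide = random_peptide(rng, 20, config.background_frequencies)
        offset = int(rng.integers(5, 16))
        peptide = peptide[: offset - 1] + "S" + peptide[offset:]
        ascore = float(20.0 + 80.0 * rng.random())
        intensity = float(5.0 + 90.0 * rng.random())
        phospho = int(rng.integers(2, 11))
        total = phospho + int(rng.integers(0, 6))
        if i < config.planted_pass_count:
            reasons: tuple[str, ...] = ()
        else:
            violation = _VIOLATIONS[(i - config.planted_pass_count) % 3]
            reasons = (violation,)
            if violation == "ascore":
                ascore = float(19.9 * rng.random())
            elif violation == "intensity":
                intensity = float(4.9 * rng.random())
            else:
                phospho = int(rng.integers(0, 2))
                total = max(total, phospho, 1)
        records.append(
            CandidateRecord(
                peptide=peptide,
                phospho_positions=(offset,),
                ascore=ascore,
                ptm_ion_intensity_pct=intensity,
                phospho_psm_count=phospho,
                total_psm_count=total,
                condition="WT+ATP",
            )
        )
        labels.append(reasons)
    return records, labels


# ---------------------------------------------------------------------------
# Intensity tables
# ---------------------------------------------------------------------------


def simulate_intensity_table(
    config: SimConfig,
    n_peptides: int = 20,
    treatment: str = "mock",
    noise: float = 0.0,
) -> tuple[list[IntensityRecord], frozenset[str]]:
    """A genotype intensity table with a planted selectable set.

    The first half of the peptides follow wt = effect * ko and
    ox = effect * wt (times 1 +/- ``noise``); the rest violate the strict
    chain (wt <= ko).  With noise 0 and effect > the fold-change threshold,
    strategy b selects exactly the planted set.
    """
    if config.intensity_effect <= 1.0:
        raise ValueError("intensity_effect must exceed 1")
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must lie in [0, 1)")
    rng = np.random.default_rng([config.seed % (2**31), 2])
    records: list[IntensityRecord] = []
    planted: set[str] = set()
    n_selectable = n_peptides // 2
    for i in range(n_peptides):
        peptide = random_peptide(rng, 15, config.background_frequencies)
        base = float(10.0 ** rng.uniform(4, 6))
        if i < n_selectable:
            ko = base
            wt = base * config.intensity_effect
            ox = wt * config.intensity_effect
            planted.add(peptide)
        else:
            wt = base
            ko = base * float(rng.uniform(1.0, 2.0))  # chain broken: ko >= wt
            ox = base * float(rng.uniform(0.5, 3.0))
        for genotype, value in zip(GENOTYPES, (ko, wt, ox)):
            jitter = 1.0 + noise * float(rng.uniform(-1.0, 1.0))
            records.append(
                IntensityRecord(
                    peptide=peptide,
                    genotype=genotype,
                    treatment=treatment,
                    intensity=value * jitter,
                )
            )
    return records, frozenset(planted)
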