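"""Filtering, ranking and QC of phosphopeptide identifications from a screen.

Identifications arrive as flat summary rows from the search engine (peptide,
localized phospho positions, Ascore, PTM ion intensity %, spectrum counts,
screening condition).  High-confidence candidates must satisfy all of
Ascore >= 20, PTM ion intensity >= 5% and >= 2 phospho PSMs (thresholds
inclusive); candidates are then ranked by phosphorylation stoichiometry,
(phospho PSMs / total PSMs) x 100.  Monoisotopic masses and theoretical m/z
are recomputed for QC against the instrument's printed values, subcellular
localization is summarised by a weighted consensus (experimental evidence
weighs 5x in silico predictions), and site-centered residue frequencies
summarise the phosphosite motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pyteomics_mass

from .formats_io import AMINO_ACIDS, PHOSPHO_RESIDUES

#: Monoisotopic mass shifts (Da).
PHOSPHO_DELTA = 79.96633
OXIDATION_DELTA = 15.99491
WATER_MONO = _pyteomics_mass.calculate_mass(formula="H2O")  # 18.0105646...
PROTON_MASS = 1.007276

#: Default inclusive filtration thresholds.
MIN_ASCORE = 20.0
MIN_INTENSITY_PCT = 5.0
MIN_PSM = 2

#: The four screening arms: kinase genotype x ATP presence.
CONDITIONS = ("WT+ATP", "WT-ATP", "dead+ATP", "dead-ATP")

#: Weight of experimental localization evidence relative to predictions.
EXPERIMENTAL_WEIGHT = 5

_MOD_RULES = {
    "Phospho": (PHOSPHO_DELTA, PHOSPHO_RESIDUES),
    "Oxidation": (OXIDATION_DELTA, frozenset("M")),
}


@dataclass(frozen=True)
class Modification:
    """A variable modification placed on one peptide residue."""

    name: str  # Phospho or Oxidation
    target_position: int  # 1-based index in the peptide

    def __post_init__(self) -> None:
        if self.name not in _MOD_RULES:
            raise ValueError(f"unknown modification {self.name!r}")
        if self.target_position < 1:
            raise ValueError("target_position must be >= 1")

    @property
    def delta_mass(self) -> float:
        return _MOD_RULES[self.name][0]

    def validate_on(self, peptide: str) -> None:
        if self.target_position > len(peptide):
            raise ValueError(
                f"{self.name} at {self.target_position} outside peptide "
                f"of length {len(peptide)}"
            )
        residue = peptide[self.target_position - 1]
        allowed = _MOD_RULES[self.name][1]
        if residue not in allowed:
            raise ValueError(
                f"{self.name} not allowed on {residue!r} "
                f"(position {self.target_position}); targets: {sorted(allowed)}"
            )


@dataclass(frozen=True)
class CandidateRecord:
    """One identified phosphopeptide with its filtration evidence."""

    peptide: str
    phospho_positions: tuple[int, ...]
    ascore: float
    ptm_ion_intensity_pct: float
    phospho_psm_count: int
    total_psm_count: int
    condition: str = "WT+ATP"
    manual_check: bool | None = None  # optional manual spectrum check

    def __post_init__(self) -> None:
        if self.ascore < 0:
            raise ValueError("ascore must be >= 0")
        if not 0 <= self.phospho_psm_count <= self.total_psm_count:
            raise ValueError(
                "require 0 <= phospho_psm_count <= total_psm_count, got "
                f"{self.phospho_psm_count}/{self.total_psm_count}"
            )
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        for pos in self.phospho_positions:
            if not 1 <= pos <= len(self.peptide):
                raise IndexError(f"phospho position {pos} outside peptide")
            if self.peptide[pos - 1] not in PHOSPHO_RESIDUES:
                raise ValueError(
                    f"phospho position {pos} is {self.peptide[pos - 1]!r}, not S/T/Y"
                )

    @property
    def stoichiometry_pct(self) -> float:
        return stoichiometry(self.phospho_psm_count, self.total_psm_count)


@dataclass(frozen=True)
class LocalizationEvidence:
    """Subcellular-localization evidence for one protein."""

    compartment: str
    kind: str  # experimental or predicted
    count: int

    def __post_init__(self) -> None:
        if self.kind not in ("experimental", "predicted"):
            raise ValueError("kind must be 'experimental' or 'predicted'")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class FilterDecision:
    record: CandidateRecord
    passed: bool
    reasons: tuple[str, ...]  # failed criteria, empty when passed


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Residue frequencies at offsets around localized phosphosites."""

    offsets: tuple[int, ...]
    freqs: Mapping[int, Mapping[str, float]]
    counts: Mapping[int, int]  # contributing residues per offset


# ---------------------------------------------------------------------------
# Filtration and ranking
# ---------------------------------------------------------------------------


def filter_candidates(
    records: Iterable[CandidateRecord],
    min_ascore: float = MIN_ASCORE,
    min_intensity_pct: float = MIN_INTENSITY_PCT,
    min_psm: int = MIN_PSM,
) -> list[FilterDecision]:
    """Apply the three inclusive filtration thresholds to every record.

    Each record gets a decision with the list of criteria it failed
    ("ascore", "intensity", "psm", and "manual_check" when a manual spectrum
    check column is present and negative).
    """
    decisions = []
    for rec in records:
        reasons = []
        if rec.ascore < min_ascore:
            reasons.append("ascore")
        if rec.ptm_ion_intensity_pct < min_intensity_pct:
            reasons.append("intensity")
        if rec.phospho_psm_count < min_psm:
            reasons.append("psm")
        if rec.manual_check is False:
            reasons.append("manual_check")
        decisions.append(FilterDecision(rec, not reasons, tuple(reasons)))
    return decisions


def passing(decisions: Iterable[FilterDecision]) -> list[CandidateRecord]:
    """The records that passed, in input order."""
    return [d.record for d in decisions if d.passed]


def stoichiometry(phospho_psm: int, total_psm: int) -> float:
    """Phosphorylation stoichiometry in percent: 100 * phospho/total PSMs."""
    if total_psm < 1:
        raise ValueError("total_psm must be >= 1")
    if not 0 <= phospho_psm <= total_psm:
        raise ValueError("require 0 <= phospho_psm <= total_psm")
    return 100.0 * phospho_psm / total_psm


def rank_by_stoichiometry(
    records: Iterable[CandidateRecord],
) -> list[CandidateRecord]:
    """Order candidates by stoichiometry descending; ties break by phospho
    PSM count descending, then peptide lexical order."""
    return sorted(
        records,
        key=lambda r: (-r.stoichiometry_pct, -r.phospho_psm_count, r.peptide),
    )


# ---------------------------------------------------------------------------
# Mass QC
# ---------------------------------------------------------------------------


def monoisotopic_mass(
    peptide: str, mods: Sequence[Modification] = ()
) -> float:
    """Neutral monoisotopic peptide mass in Da.

    Standard residue masses plus one water for the chain, plus each
    modification's delta.  Cysteines are left unmodified (synthetic peptides,
    no alkylation).  Modifications on incompatible residues raise.
    """
    if not peptide:
        raise ValueError("empty peptide")
    bad = sorted(set(peptide) - set(AMINO_ACIDS))
    if bad:
        raise ValueError(f"non-standard residues in peptide: {bad}")
    for mod in mods:
        mod.validate_on(peptide)
    return _pyteomics_mass.fast_mass(peptide) + sum(m.delta_mass for m in mods)


def theoretical_mz(mass: float, charge: int) -> float:
    """m/z of the [M + zH]z+ ion: (mass + z * proton) / z."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (mass + charge * PROTON_MASS) / charge


# ---------------------------------------------------------------------------
# Localization consensus
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsensusResult:
    compartment: str
    scores: Mapping[str, int]
    tied: tuple[str, ...]  # all argmax compartments, alphabetical


def localization_consensus(
    evidence: Iterable[LocalizationEvidence],
    experimental_weight: int = EXPERIMENTAL_WEIGHT,
) -> ConsensusResult:
    """Weighted consensus subcellular localization.

    Each compartment scores experimental_weight x experimental count +
    1 x predicted count; the winner is the argmax.  Ties are reported with
    the alphabetically first compartment as the primary.
    """
    evidence = list(evidence)
    if not evidence:
        raise ValueError("empty localization evidence")
    scores: dict[str, int] = {}
    for ev in evidence:
        weight = experimental_weight if ev.kind == "experimental" else 1
        scores[ev.compartment] = scores.get(ev.compartment, 0) + weight * ev.count
    best = max(scores.values())
    tied = tuple(sorted(c for c, s in scores.items() if s == best))
    return ConsensusResult(compartment=tied[0], scores=scores, tied=tied)


# ---------------------------------------------------------------------------
# Motif summary
# ---------------------------------------------------------------------------


def motif_frequency_matrix(
    records: Iterable[CandidateRecord], half_width: int = 5
) -> PositionFrequencyMatrix:
    """Site-centered residue frequencies over all localized phosphosites.

    For every phosphosite, residues at offsets -half_width..+half_width
    (truncated at peptide ends) are tallied; each offset column is normalised
    over the residues that contributed to it.  Offset 0 is the site itself
    and is restricted to S/T/Y by construction.
    """
    offsets = tuple(range(-half_width, half_width + 1))
    tallies: dict[int, dict[str, int]] = {o: {} for o in offsets}
    n_sites = 0
    for rec in records:
        for pos in rec.phospho_positions:
            n_sites += 1
            for offset in offsets:
                idx = pos + offset
                if not 1 <= idx <= len(rec.peptide):
                    continue
                residue = rec.peptide[idx - 1]
                tallies[offset][residue] = tallies[offset].get(residue, 0) + 1
    if n_sites == 0:
        raise ValueError("no localized phosphosites in input")
    freqs: dict[int, dict[str, float]] = {}
    counts: dict[int, int] = {}
    for offset in offsets:
        total = sum(tallies[offset].values())
        counts[offset] = total
        freqs[offset] = (
            {aa: c / total for aa, c in sorted(tallies[offset].items())}
            if total
            else {}
        )
    return PositionFrequencyMatrix(offsets=offsets, freqs=freqs, counts=counts)
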