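"""Design of the synthetic 20-mer phosphopeptide library.

Each phosphosite becomes a 20-residue window of its protein with the site
centered at peptide offset 10 when both flanks allow; near a terminus the
window shifts so that the length stays 20, and offsets forced outside the
acceptable [5, 15] band are flagged terminal-clamped.  Redundancy is removed
greedily at a strict >60% pairwise-identity threshold, the five provenance
sources are merged with Venn-region bookkeeping, and a scored rank-selection
trims the pool to the target library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from collections import Counter
from typing import Iterable, Mapping, Sequence

from .formats_io import AMINO_ACIDS, PHOSPHO_RESIDUES, ProteinRecord
from .overlap_mapping import DEFAULT_PARAMS, AlignmentParams, global_align

PEPTIDE_LENGTH = 20
#: Acceptable site offsets within the peptide (1-based, inclusive).
OFFSET_RANGE = (5, 15)
#: Stricter alternative offset band.
STRICT_OFFSET_RANGE = (6, 14)
#: Identity threshold (strict >) for redundancy removal, in percent.
IDENTITY_THRESHOLD_PCT = 60.0

SOURCE_TAGS = ("source1", "source2", "source3", "source4", "source5")


@dataclass(frozen=True)
class LibraryPeptide:
    """A designed 20-mer with provenance and site bookkeeping."""

    sequence: str
    protein_id: str
    site_position: int  # 1-based position in the parent protein
    site_offset: int  # 1-based position of the site within the peptide
    sources: frozenset[str] = frozenset()
    score: float | None = None
    clamped: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != PEPTIDE_LENGTH:
            raise ValueError(
                f"{self.protein_id}:{self.site_position}: peptide length "
                f"{len(self.sequence)} != {PEPTIDE_LENGTH}"
            )
        if not 1 <= self.site_offset <= PEPTIDE_LENGTH:
            raise ValueError("site_offset outside the peptide")
        if self.sequence[self.site_offset - 1] not in PHOSPHO_RESIDUES:
            raise ValueError(
                f"{self.protein_id}:{self.site_position}: residue at offset "
                f"{self.site_offset} is not S/T/Y"
            )
        lo, hi = OFFSET_RANGE
        if not (lo <= self.site_offset <= hi) and not self.clamped:
            raise ValueError(
                f"offset {self.site_offset} outside [{lo}, {hi}] must be "
                "flagged terminal-clamped"
            )


@dataclass(frozen=True)
class SkippedSite:
    protein_id: str
    site_position: int
    reason: str


@dataclass(frozen=True)
class RemovedPeptide:
    peptide: LibraryPeptide
    retained_by: LibraryPeptide
    identity_pct: float


@dataclass(frozen=True)
class MergeReport:
    """Venn bookkeeping for the multi-source merge."""

    per_source_counts: Mapping[str, int]
    region_counts: Mapping[frozenset, int]
    total_before_dedup: int
    total_unique: int
    removed_redundant: int

    def region(self, *tags: str) -> int:
        return self.region_counts.get(frozenset(tags), 0)


def extract_peptide(
    protein: ProteinRecord,
    site_position: int,
    offset_range: tuple[int, int] = OFFSET_RANGE,
) -> LibraryPeptide:
    """Cut the centered 20-mer window around one phosphosite.

    The site lands at offset 10 when both flanks allow; otherwise the window
    shifts toward the nearer terminus, keeping length 20.  Offsets forced
    outside ``offset_range`` are flagged terminal-clamped.  Proteins shorter
    than 20 residues cannot yield a peptide and raise.
    """
    if len(protein) < PEPTIDE_LENGTH:
        raise ValueError(
            f"protein {protein.id} shorter than {PEPTIDE_LENGTH} residues"
        )
    residue = protein.residue(site_position)
    if residue not in PHOSPHO_RESIDUES:
        raise ValueError(
            f"{protein.id}:{site_position}: residue {residue!r} is not S/T/Y"
        )
    start = site_position - 9  # puts the site at 1-based offset 10
    start = max(1, min(start, len(protein) - PEPTIDE_LENGTH + 1))
    offset = site_position - start + 1
    lo, hi = offset_range
    return LibraryPeptide(
        sequence=protein.sequence[start - 1 : start - 1 + PEPTIDE_LENGTH],
        protein_id=protein.id,
        site_position=site_position,
        site_offset=offset,
        clamped=not lo <= offset <= hi,
    )


def design_peptides(
    proteome: Sequence[ProteinRecord],
    sites: Iterable,
    source: str | None = None,
    offset_range: tuple[int, int] = OFFSET_RANGE,
) -> tuple[list[LibraryPeptide], list[SkippedSite]]:
    """Bulk window extraction with skip-with-reason bookkeeping.

    Windows containing the ambiguity character X are excluded: synthetic
    peptides must be fully specified.
    """
    by_id = {p.id: p for p in proteome}
    peptides: list[LibraryPeptide] = []
    skipped: list[SkippedSite] = []
    tags = frozenset([source]) if source else frozenset()
    for site in sites:
        protein = by_id.get(site.protein_id)
        if protein is None:
            skipped.append(SkippedSite(site.protein_id, site.position, "unknown protein"))
            continue
        try:
            peptide = extract_peptide(protein, site.position, offset_range)
        except ValueError as exc:
            skipped.append(SkippedSite(site.protein_id, site.position, str(exc)))
            continue
        if set(peptide.sequence) - set(AMINO_ACIDS):
            skipped.append(
                SkippedSite(site.protein_id, site.position, "window contains X")
            )
            continue
        peptides.append(replace(peptide, sources=tags))
    return peptides, skipped


def percent_identity(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> float:
    """Pairwise sequence identity in percent, symmetric.

    Equal-length peptides are compared position by position (no alignment);
    unequal lengths are globally aligned first and identical aligned
    positions are counted against the shorter length.
    """
    if not a or not b:
        raise ValueError("peptides must be nonempty")
    if len(a) == len(b):
        matches = sum(1 for x, y in zip(a, b) if x == y)
        return 100.0 * matches / len(a)
    if len(a) > len(b):
        a, b = b, a
    alignment = global_align(a, b, params)
    return 100.0 * alignment.identity_count() / len(a)


def _priority_key(p: LibraryPeptide):
    # Descending score (unscored last), ties by protein then position.
    return (
        p.score is None,
        -(p.score or 0.0),
        p.protein_id,
        p.site_position,
        p.sequence,
    )


def _collapse_exact(
    peptides: Iterable[LibraryPeptide],
) -> list[LibraryPeptide]:
    """Collapse exact sequence duplicates, unioning source tags.

    The surviving metadata (protein, position, score) comes from the
    highest-priority copy; scores keep the maximum over copies.
    """
    by_seq: dict[str, list[LibraryPeptide]] = {}
    for p in peptides:
        by_seq.setdefault(p.sequence, []).append(p)
    collapsed = []
    for seq, group in by_seq.items():
        group.sort(key=_priority_key)
        keeper = group[0]
        tags = frozenset().union(*(p.sources for p in group))
        scores = [p.score for p in group if p.score is not None]
        collapsed.append(
            replace(keeper, sources=tags, score=max(scores) if scores else None)
        )
    collapsed.sort(key=_priority_key)
    return collapsed


def deduplicate(
    peptides: Iterable[LibraryPeptide],
    threshold_pct: float = IDENTITY_THRESHOLD_PCT,
) -> tuple[list[LibraryPeptide], list[RemovedPeptide]]:
    """Greedy redundancy removal at a strict identity threshold.

    Exact duplicates always collapse first (source-tag union).  Peptides are
    then visited in priority order (descending score, ties by protein id then
    position); one is removed iff its identity to an already-retained peptide
    is strictly greater than ``threshold_pct``.  Identity exactly at the
    threshold is retained.
    """
    retained: list[LibraryPeptide] = []
    removed: list[RemovedPeptide] = []
    for candidate in _collapse_exact(peptides):
        hit = None
        for keeper in retained:
            identity = percent_identity(candidate.sequence, keeper.sequence)
            if identity > threshold_pct:
                hit = RemovedPeptide(candidate, keeper, identity)
                break
        if hit is None:
            retained.append(candidate)
        else:
            removed.append(hit)
    return retained, removed


def merge_sources(
    lists: Mapping[str, Sequence[LibraryPeptide]],
) -> tuple[list[LibraryPeptide], MergeReport]:
    """Combine per-source peptide lists with Venn-region bookkeeping.

    Exact duplicates across lists collapse to one peptide carrying the union
    of source tags; region counts are over the collapsed peptides, so the
    disjoint regions sum to the unique total while the per-source counts sum
    to the pre-collapse total.
    """
    per_source = {tag: len(peps) for tag, peps in lists.items()}
    total_before = sum(per_source.values())
    tagged: list[LibraryPeptide] = []
    for tag in sorted(lists):
        for p in lists[tag]:
            tagged.append(replace(p, sources=p.sources | {tag}))
    library = _collapse_exact(tagged)
    regions = Counter(p.sources for p in library)
    report = MergeReport(
        per_source_counts=per_source,
        region_counts=dict(regions),
        total_before_dedup=total_before,
        total_unique=len(library),
        removed_redundant=total_before - len(library),
    )
    return library, report


def rank_select(
    candidates: Sequence[LibraryPeptide],
    target_size: int,
    priority_sources: Sequence[str] = ("source1",),
) -> list[LibraryPeptide]:
    """Top ``target_size`` peptides by conservation score.

    Ordering: score descending, then membership in a priority source, then
    sequence lexical order -- fully deterministic.  Asking for more peptides
    than exist returns everything.
    """
    if target_size < 0:
        raise ValueError("target_size must be >= 0")
    priority = frozenset(priority_sources)
    ranked = sorted(
        candidates,
        key=lambda p: (
            p.score is None,
            -(p.score or 0.0),
            not (p.sources & priority),
            p.sequence,
        ),
    )
    if target_size > len(ranked):
        import logging

        logging.getLogger("kiclib").warning(
            "target size %d exceeds candidate pool (%d); returning all",
            target_size,
            len(ranked),
        )
        return ranked
    return ranked[:target_size]
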