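"""Residue-conservation scoring around phosphosites in ortholog alignments.

A phosphosite's conservation is scored on the multiple sequence alignment
(MSA) of its ortholog group.  Each alignment column C yields a column
distribution p_C over the 21-symbol alphabet (20 amino acids + gap), and a
per-column conservation score

    PM_C = lambda * RE(p_C, r) + (1 - lambda) * RE(q, r),
    r = lambda * p_C + (1 - lambda) * q,

the Jensen-Shannon divergence between the column and the background amino
acid distribution q (here the BLOSUM62 alignment background, gap mass 0).
With lambda = 0.5 and base-2 logarithms, PM is bounded in [0, 1].  The site
score CS_p is the mean PM over an 11-residue window centered on the site
(+/-5 columns), the site column itself excluded; near alignment ends the
window truncates and the mean is taken over the columns available.

Two classification rules are built on this machinery:

* conserved (source 1): the site's alignment column carries an annotated
  phosphosite in >= 2 species, independent of which acceptor residue (S/T/Y)
  is phosphorylated in each;
* potentially conserved (source 2): every non-query ortholog row carries an
  S, T or Y at the site's column (N >= 3 rows required), ranked by CS_p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .formats_io import AMINO_ACIDS, Phosphosite

GAP = "-"
#: The 21-symbol column alphabet: 20 amino acids plus the gap symbol.
COLUMN_ALPHABET = AMINO_ACIDS + GAP

#: Default prior weight for the JSD mixture.
DEFAULT_LAMBDA = 0.5
#: Default window half-width (columns on each side of the site).
DEFAULT_HALF_WIDTH = 5

# BLOSUM62 alignment background frequencies (Capra & Singh conservation-scoring
# convention, order ARNDCQEGHILKMFPSTWYV), normalised to sum to 1.  The gap
# symbol carries zero background mass; gaps enter only through p_C, so the
# mixture r has gap mass exactly when the column does and RE stays finite.
_BLOSUM62_RAW = {
    "A": 0.078, "R": 0.051, "N": 0.041, "D": 0.052, "C": 0.024,
    "Q": 0.034, "E": 0.059, "G": 0.083, "H": 0.025, "I": 0.062,
    "L": 0.092, "K": 0.056, "M": 0.024, "F": 0.044, "P": 0.043,
    "S": 0.059, "T": 0.055, "W": 0.014, "Y": 0.034, "V": 0.072,
}
_TOTAL = sum(_BLOSUM62_RAW.values())
BLOSUM62_BACKGROUND: dict[str, float] = {
    aa: f / _TOTAL for aa, f in _BLOSUM62_RAW.items()
}
BLOSUM62_BACKGROUND[GAP] = 0.0


@dataclass(frozen=True)
class ColumnDistribution:
    """A column's symbol distribution paired with the scoring background."""

    probs: Mapping[str, float]
    background: Mapping[str, float] = field(
        default_factory=lambda: dict(BLOSUM62_BACKGROUND)
    )
    lambda_weight: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        for name, dist in (("probs", self.probs), ("background", self.background)):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
        if not 0.0 < self.lambda_weight <= 1.0:
            raise ValueError(f"lambda must lie in (0, 1], got {self.lambda_weight}")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column PM scores and their window mean CS_p for one site."""

    column_scores: tuple[float, ...]
    window_score: float
    window_columns: tuple[int, ...]
    n: int


@dataclass(frozen=True)
class ConservedSite:
    """A query-species site classified as cross-species conserved."""

    site: Phosphosite
    column: int
    n_species: int
    species: tuple[str, ...]


class OrthologAlignment:
    """An ortholog-group MSA with a designated query row.

    Rows are equal-length gapped strings over the 21-symbol alphabet; each row
    carries an id (protein accession) and a species label.  Residue positions
    are 1-based and ungapped; alignment columns are 0-based.
    """

    def __init__(
        self,
        rows: Sequence[str],
        species_labels: Sequence[str],
        query_row: int = 0,
        row_ids: Sequence[str] | None = None,
    ) -> None:
        rows = [r.upper() for r in rows]
        if len(rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        if len(species_labels) != len(rows):
            raise ValueError("one species label per row required")
        if not 0 <= query_row < len(rows):
            raise ValueError(f"query_row {query_row} out of range")
        alphabet = set(COLUMN_ALPHABET) | {"X"}
        for i, row in enumerate(rows):
            bad = sorted(set(row) - alphabet)
            if bad:
                raise ValueError(f"row {i}: symbols outside the alphabet: {bad}")
        self.rows = list(rows)
        self.species_labels = list(species_labels)
        self.row_ids = list(row_ids) if row_ids is not None else [
            f"row{i}" for i in range(len(rows))
        ]
        if len(self.row_ids) != len(rows):
            raise ValueError("one row id per row required")
        self.query_row = query_row
        # residue index (1-based, ungapped) <-> alignment column (0-based)
        self._res_to_col: list[list[int]] = []
        for row in self.rows:
            self._res_to_col.append([c for c, sym in enumerate(row) if sym != GAP])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, c: int) -> list[str]:
        if not 0 <= c < self.length:
            raise IndexError(f"column {c} outside alignment of length {self.length}")
        return [row[c] for row in self.rows]

    def residue_to_column(self, row: int, position: int) -> int:
        """Alignment column of the 1-based ungapped residue ``position``."""
        mapping = self._res_to_col[row]
        if not 1 <= position <= len(mapping):
            raise IndexError(
                f"residue {position} outside row {row} "
                f"(ungapped length {len(mapping)})"
            )
        return mapping[position - 1]

    def column_to_residue(self, row: int, column: int) -> int | None:
        """1-based ungapped residue at ``column`` of ``row``; None at a gap."""
        if self.rows[row][column] == GAP:
            return None
        return column - self.rows[row][:column].count(GAP) + 1

    def ungapped(self, row: int) -> str:
        return self.rows[row].replace(GAP, "")


# ---------------------------------------------------------------------------
# Column scoring
# ---------------------------------------------------------------------------


def column_distribution(
    column: Sequence[str], alphabet: str = COLUMN_ALPHABET
) -> dict[str, float]:
    """Observed symbol frequencies of one alignment column.

    Each symbol's probability is count/N; the result sums to 1.  Symbols
    outside the alphabet raise.
    """
    if not column:
        raise ValueError("empty column")
    allowed = set(alphabet)
    probs = {sym: 0.0 for sym in alphabet}
    for sym in column:
        if sym not in allowed:
            raise ValueError(f"symbol {sym!r} outside the column alphabet")
        probs[sym] += 1.0
    n = float(len(column))
    return {sym: count / n for sym, count in probs.items()}


def relative_entropy(p: Mapping[str, float], q: Mapping[str, float]) -> float:
    """Kullback-Leibler divergence RE(p, q) in bits.

    Terms with p(a) = 0 contribute nothing; p(a) > 0 where q(a) = 0 is
    undefined and raises (it cannot occur for JSD mixture arguments).
    """
    total = 0.0
    for sym, p_a in p.items():
        if p_a <= 0.0:
            continue
        q_a = q.get(sym, 0.0)
        if q_a <= 0.0:
            raise ValueError(
                f"RE undefined: p({sym!r}) = {p_a} > 0 but q({sym!r}) = 0"
            )
        total += p_a * math.log2(p_a / q_a)
    return total


def jsd_score(
    p_c: Mapping[str, float],
    q: Mapping[str, float] | None = None,
    lam: float = DEFAULT_LAMBDA,
) -> float:
    """Jensen-Shannon conservation score PM of one column distribution.

    PM = lam*RE(p_C, r) + (1-lam)*RE(q, r) with r = lam*p_C + (1-lam)*q.
    With lam = 0.5 and base-2 logs the score is bounded in [0, 1].
    """
    if q is None:
        q = BLOSUM62_BACKGROUND
    if not 0.0 < lam < 1.0:
        raise ValueError(f"lambda must lie in (0, 1), got {lam}")
    symbols = set(p_c) | set(q)
    r = {s: lam * p_c.get(s, 0.0) + (1.0 - lam) * q.get(s, 0.0) for s in symbols}
    return lam * relative_entropy(p_c, r) + (1.0 - lam) * relative_entropy(q, r)


def site_window_score(
    msa: OrthologAlignment,
    site_column: int,
    half_width: int = DEFAULT_HALF_WIDTH,
    background: Mapping[str, float] | None = None,
    lam: float = DEFAULT_LAMBDA,
    include_site: bool = False,
) -> ConservationProfile:
    """Window conservation score CS_p around one alignment column.

    PM is computed for each of the up-to-2*half_width flanking columns; the
    site column is excluded unless ``include_site`` is set.  CS_p is the
    arithmetic mean of the in-window PM values; windows truncate at alignment
    ends and n shrinks accordingly.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if not 0 <= site_column < msa.length:
        raise IndexError(f"site column {site_column} outside alignment")
    if background is None:
        background = BLOSUM62_BACKGROUND
    lo = max(0, site_column - half_width)
    hi = min(msa.length - 1, site_column + half_width)
    window = [
        c for c in range(lo, hi + 1) if include_site or c != site_column
    ]
    if not window:
        raise ValueError("empty conservation window (alignment too short)")
    scores = tuple(
        jsd_score(column_distribution(msa.column(c)), background, lam) for c in window
    )
    return ConservationProfile(
        column_scores=scores,
        window_score=sum(scores) / len(scores),
        window_columns=tuple(window),
        n=len(window),
    )


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------


def _map_site(msa: OrthologAlignment, site: Phosphosite) -> tuple[int, int]:
    """Locate a site's (row, column) in its alignment, with consistency checks."""
    try:
        row = msa.row_ids.index(site.protein_id)
    except ValueError:
        raise ValueError(
            f"site {site.protein_id}:{site.position} not in alignment rows"
        ) from None
    column = msa.residue_to_column(row, site.position)
    actual = msa.rows[row][column]
    if actual == GAP:
        raise ValueError(
            f"site {site.protein_id}:{site.position} maps to a gap column"
        )
    if actual != site.residue:
        raise ValueError(
            f"site {site.protein_id}:{site.position}: alignment has {actual}, "
            f"site table says {site.residue}"
        )
    return row, column


def classify_conserved_sites(
    msas: Iterable[OrthologAlignment], sites: Iterable[Phosphosite]
) -> list[ConservedSite]:
    """Source-1 rule: a query site is conserved iff its alignment column is
    phosphorylated in >= 2 species (any acceptor residue).

    Sites are matched to alignments by protein accession.  The returned list
    covers query-species sites only, in (protein_id, position) order.
    """
    sites = list(sites)
    conserved: list[ConservedSite] = []
    for msa in msas:
        in_family = [s for s in sites if s.protein_id in msa.row_ids]
        by_column: dict[int, list[tuple[Phosphosite, int]]] = {}
        for site in in_family:
            row, column = _map_site(msa, site)
            by_column.setdefault(column, []).append((site, row))
        query_id = msa.row_ids[msa.query_row]
        for column, members in by_column.items():
            species = sorted({msa.species_labels[row] for _, row in members})
            if len(species) < 2:
                continue
            for site, row in members:
                if site.protein_id == query_id:
                    conserved.append(
                        ConservedSite(
                            site=site,
                            column=column,
                            n_species=len(species),
                            species=tuple(species),
                        )
                    )
    conserved.sort(key=lambda c: (c.site.protein_id, c.site.position))
    return conserved


def classify_potentially_conserved(
    msa: OrthologAlignment,
    site: Phosphosite,
    half_width: int = DEFAULT_HALF_WIDTH,
    background: Mapping[str, float] | None = None,
    lam: float = DEFAULT_LAMBDA,
    include_site: bool = False,
) -> tuple[bool, ConservationProfile | None]:
    """Source-2 rule: eligible iff every non-query ortholog row has an S, T or
    Y at the site's alignment column; eligible sites are scored by CS_p.

    Requires N >= 3 rows.
    """
    if msa.n_rows < 3:
        raise ValueError(
            f"potential-conservation rule needs N >= 3 rows, got {msa.n_rows}"
        )
    row, column = _map_site(msa, site)
    if row != msa.query_row:
        raise ValueError(
            f"site {site.protein_id}:{site.position} is not on the query row"
        )
    for i, aligned in enumerate(msa.rows):
        if i == msa.query_row:
            continue
        if aligned[column] not in "STY":
            return False, None
    profile = site_window_score(
        msa, column, half_width=half_width, background=background,
        lam=lam, include_site=include_site,
    )
    return True, profile
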