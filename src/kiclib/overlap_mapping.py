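"""Map in vitro screen candidates onto in vivo phosphoproteomics peptides.

Candidate phosphopeptides from the synthetic-library screen are matched to
peptides observed in planta by optimal global pairwise alignment (match +2,
mismatch -1, gap opening -0.5, gap extension -0.1; a gap run of length g
costs open + (g-1)*extend, end gaps included).  In vivo peptides are then
selected by genotype intensity inequalities across knockout (ko), wild type
(wt) and overexpressor (ox) lines -- strategy a requires the strict chain
ko < wt < ox, strategy b additionally requires both step fold changes to
exceed a threshold (default 1.5) -- and the overlap between the two
experiments is counted at the gene-accession level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

NEG_INF = float("-inf")


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring parameters."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -0.5
    gap_extend: float = -0.1

    def __post_init__(self) -> None:
        if not self.match > 0 >= self.mismatch:
            raise ValueError("require match > 0 >= mismatch")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if abs(self.gap_extend) > abs(self.gap_open):
            raise ValueError("|gap_extend| must not exceed |gap_open|")


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class PairwiseAlignment:
    """One optimal global alignment: gapped strings plus its score."""

    aligned_a: str
    aligned_b: str
    score: float

    def identity_count(self) -> int:
        """Number of aligned positions with identical residues."""
        return sum(
            1
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )


def score_alignment(
    aligned_a: str, aligned_b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> float:
    """Score a gapped alignment pair under the run-aware gap cost."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings must have equal length")
    total = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" and y == "-":
            raise ValueError("column with gaps in both rows")
        if x == "-":
            total += params.gap_extend if in_gap_a else params.gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            total += params.gap_extend if in_gap_b else params.gap_open
            in_gap_b, in_gap_a = True, False
        else:
            total += params.match if x == y else params.mismatch
            in_gap_a = in_gap_b = False
    return total


def global_align(
    a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS
) -> PairwiseAlignment:
    """Optimal global alignment of two sequences (affine gaps, Gotoh DP).

    Exactly one optimal alignment is returned; traceback ties resolve
    diagonal > up (gap in ``b``) > left (gap in ``a``), so the result is
    deterministic across platforms.  End gaps are penalized like any other.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    n, m = len(a), len(b)
    open_, ext = params.gap_open, params.gap_extend
    # M: a[i-1] aligned to b[j-1]; X: gap in b (consumes a); Y: gap in a.
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    # boundaries built by the same additions the traceback recomputes,
    # so float equality comparisons during traceback are exact
    X[1][0] = open_
    for i in range(2, n + 1):
        X[i][0] = X[i - 1][0] + ext
    Y[0][1] = open_
    for j in range(2, m + 1):
        Y[0][j] = Y[0][j - 1] + ext
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = params.match if ai == b[j - 1] else params.mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext, Y[i - 1][j] + open_)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext, X[i][j - 1] + open_)
    # Traceback with fixed state preference M (diagonal) > X (up) > Y (left).
    i, j = n, m
    best = max(M[n][m], X[n][m], Y[n][m])
    for state in "MXY":
        if {"M": M, "X": X, "Y": Y}[state][n][m] == best:
            break
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            sub = params.match if a[i - 1] == b[j - 1] else params.mismatch
            here = M[i][j]
            i, j = i - 1, j - 1
            # compare prev + sub (the forward-pass direction) for exactness
            for prev in "MXY":
                if {"M": M, "X": X, "Y": Y}[prev][i][j] + sub == here:
                    state = prev
                    break
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("traceback lost the optimal path")
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            here = X[i][j]
            i -= 1
            if M[i][j] + open_ == here:
                state = "M"
            elif X[i][j] + ext == here:
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            here = Y[i][j]
            j -= 1
            if M[i][j] + open_ == here:
                state = "M"
            elif Y[i][j] + ext == here:
                state = "Y"
            else:
                state = "X"
    return PairwiseAlignment(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=best,
    )


# ---------------------------------------------------------------------------
# Candidate matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatchRecord:
    """Best in vivo partner for one screen candidate peptide."""

    kic_peptide: str
    invivo_peptide: str
    score: float


def match_candidates(
    kic_peptides: Sequence[str],
    invivo_peptides: Sequence[str],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> list[MatchRecord]:
    """Best-scoring in vivo partner per screen candidate, sorted by score.

    The table is sorted descending by score (ties: candidate then partner
    lexical order), so the output is stable under input permutation.
    """
    if not kic_peptides:
        raise ValueError("empty candidate peptide list")
    if not invivo_peptides:
        raise ValueError("empty in vivo peptide list")
    matches: list[MatchRecord] = []
    for kic in sorted(set(kic_peptides)):
        best_partner = None
        best_score = NEG_INF
        for invivo in sorted(set(invivo_peptides)):
            s = global_align(kic, invivo, params).score
            if s > best_score:
                best_partner, best_score = invivo, s
        matches.append(MatchRecord(kic, best_partner, best_score))
    matches.sort(key=lambda m: (-m.score, m.kic_peptide, m.invivo_peptide))
    return matches


# ---------------------------------------------------------------------------
# Intensity-inequality selection
# ---------------------------------------------------------------------------

GENOTYPES = ("ko", "wt", "ox")


@dataclass(frozen=True)
class IntensityRecord:
    """One peptide intensity observation from the in vivo experiment."""

    peptide: str
    genotype: str  # ko (p2k1-3), wt (Col-0), ox (OXP2K1)
    treatment: str  # mock or ATP
    intensity: float | None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError("intensity must be nonnegative")


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    skipped: tuple[tuple[str, str], ...]  # (peptide, reason)


def _fold_change(numerator: float, denominator: float) -> float:
    if denominator == 0.0:
        return float("inf") if numerator > 0 else 0.0
    return numerator / denominator


def select_by_intensity(
    records: Iterable[IntensityRecord],
    strategy: str,
    fc_threshold: float = 1.5,
    treatment: str | None = None,
) -> SelectionResult:
    """Select peptides whose genotype intensities follow the expected chain.

    Strategy ``a``: ko < wt < ox (strict).  Strategy ``b``: additionally
    wt/ko > fc_threshold and ox/wt > fc_threshold.  Missing intensities count
    as 0; a zero denominator with a positive numerator passes the ratio test
    (absence in the knockout is the strongest qualitative signal).  Peptides
    with all three intensities missing are skipped with a reason.  Replicate
    observations of the same (peptide, genotype) are averaged.
    """
    if strategy not in ("a", "b"):
        raise ValueError("strategy must be 'a' or 'b'")
    sums: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        if treatment is not None and rec.treatment != treatment:
            continue
        if rec.intensity is None:
            sums.setdefault(rec.peptide, {})
            continue
        sums.setdefault(rec.peptide, {}).setdefault(rec.genotype, []).append(
            rec.intensity
        )
    selected: list[str] = []
    skipped: list[tuple[str, str]] = []
    for peptide in sorted(sums):
        by_genotype = sums[peptide]
        if not by_genotype:
            skipped.append((peptide, "all intensities missing"))
            continue
        ko, wt, ox = (
            sum(by_genotype[g]) / len(by_genotype[g]) if g in by_genotype else 0.0
            for g in GENOTYPES
        )
        if not (ko < wt < ox):
            continue
        if strategy == "b":
            if not (
                _fold_change(wt, ko) > fc_threshold
                and _fold_change(ox, wt) > fc_threshold
            ):
                continue
        selected.append(peptide)
    return SelectionResult(tuple(selected), tuple(skipped))


# ---------------------------------------------------------------------------
# Overlap bookkeeping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapSummary:
    overlap_counts: Mapping[str, int]  # per in vivo selection label
    overlap_accessions: Mapping[str, tuple[str, ...]]
    unmapped: tuple[str, ...]


def overlap_summary(
    kic_peptides: Iterable[str],
    selections: Mapping[str, Iterable[str]],
    id_map: Mapping[str, str],
) -> OverlapSummary:
    """Count gene accessions shared between the screen candidates and each
    in vivo selection (typically one per treatment).

    Peptides absent from ``id_map`` are listed as unmapped and excluded.
    """
    unmapped: list[str] = []
    kic_accessions: set[str] = set()
    for peptide in kic_peptides:
        if peptide in id_map:
            kic_accessions.add(id_map[peptide])
        else:
            unmapped.append(peptide)
    counts: dict[str, int] = {}
    shared: dict[str, tuple[str, ...]] = {}
    for label, peptides in selections.items():
        accessions = set()
        for peptide in peptides:
            if peptide in id_map:
                accessions.add(id_map[peptide])
            else:
                unmapped.append(peptide)
        common = tuple(sorted(kic_accessions & accessions))
        counts[label] = len(common)
        shared[label] = common
    return OverlapSummary(counts, shared, tuple(sorted(set(unmapped))))
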