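from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from kiclib import LibraryPeptide, ProteinRecord
from kiclib.synthetic_fixtures import random_peptide

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def make_protein(sequence: str, pid: str = "P1", species: str = "ath") -> ProteinRecord:
    return ProteinRecord(id=pid, species=species, sequence=sequence)


def make_peptide(
    sequence: str,
    pid: str = "P1",
    position: int = 10,
    offset: int = 10,
    sources: frozenset[str] = frozenset({"source1"}),
    score: float | None = None,
) -> LibraryPeptide:
    return LibraryPeptide(
        sequence=sequence,
        protein_id=pid,
        site_position=position,
        site_offset=offset,
        sources=sources,
        score=score,
    )


def random_library_peptide(
    rng: np.random.Generator, pid: str = "P1", position: int = 10,
    score: float | None = None,
) -> LibraryPeptide:
    """A random 20-mer with an S planted at offset 10."""
    seq = random_peptide(rng, 20)
    seq = seq[:9] + "S" + seq[10:]
    return make_peptide(seq, pid=pid, position=position, score=score)
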