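"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import pytest

from cazytraits.filtering import RetainedDomain, coverage_fraction
from cazytraits.hmmio import DomainHit
from cazytraits.registry import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


def make_hit(
    family: str = "GH5",
    accession: str | None = "PF00150",
    genome_id: str = "g1",
    protein_id: str = "p1",
    profile_length: int = 300,
    i_evalue: float = 1e-10,
    hmm_from: int = 1,
    hmm_to: int | None = None,
    env_from: int = 1,
    env_to: int | None = None,
    score: float = 100.0,
) -> DomainHit:
    if hmm_to is None:
        hmm_to = profile_length
    if env_to is None:
        env_to = env_from + (hmm_to - hmm_from)
    return DomainHit(
        genome_id=genome_id,
        protein_id=protein_id,
        family_name=family,
        family_accession=accession,
        profile_length=profile_length,
        i_evalue=i_evalue,
        hmm_from=hmm_from,
        hmm_to=hmm_to,
        env_from=env_from,
        env_to=env_to,
        score=score,
    )


def make_retained(**kwargs) -> RetainedDomain:
    hit = make_hit(**kwargs)
    return RetainedDomain(hit=hit, coverage=coverage_fraction(hit))


def domains_for_protein(
    protein_id: str, families: list[str], genome_id: str = "g1"
) -> list[RetainedDomain]:
    """Disjoint, ordered envelopes for a planted family list."""
    out = []
    pos = 1
    for i, fam in enumerate(families):
        out.append(
            make_retained(
                family=fam,
                accession=None,
                genome_id=genome_id,
                protein_id=protein_id,
                profile_length=200,
                hmm_from=1,
                hmm_to=200,
                env_from=pos,
                env_to=pos + 199,
                i_evalue=10.0 ** -(10 + i),
            )
        )
        pos += 250
    return out
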