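"""Hit retention and overlap resolution.

A per-domain hit is retained when its independent E-value is at most
``evalue_max`` (default 1e-5, inclusive) AND its alignment covers strictly
more than ``coverage_min`` (default 0.5) of the profile's match states.
Coverage is computed on HMM coordinates against the profile length — a short
protein fragment aligning to half a Pfam model is rejected no matter how
significant its score.

Co-located hits surviving the thresholds are thinned greedily, best
(lowest) i-E-value first: a candidate is dropped if its envelope overlaps an
already-accepted domain by more than ``max_overlap_frac`` of the shorter
envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .hmmio import DomainHit, ValidationError

__all__ = ["RetainedDomain", "coverage_fraction", "filter_hits", "resolve_overlaps"]

logger = logging.getLogger(__name__)

EVALUE_MAX_DEFAULT = 1e-5
COVERAGE_MIN_DEFAULT = 0.5
MAX_OVERLAP_FRAC_DEFAULT = 0.5


@dataclass(frozen=True)
class RetainedDomain:
    """A hit that passed the retention thresholds, with its coverage."""

    hit: DomainHit
    coverage: float

    # convenience pass-throughs used throughout downstream code
    @property
    def genome_id(self) -> str:
        return self.hit.genome_id

    @property
    def protein_id(self) -> str:
        return self.hit.protein_id

    @property
    def family_name(self) -> str:
        return self.hit.family_name

    @property
    def family_accession(self) -> str | None:
        return self.hit.family_accession

    @property
    def i_evalue(self) -> float:
        return self.hit.i_evalue

    @property
    def env_from(self) -> int:
        return self.hit.env_from

    @property
    def env_to(self) -> int:
        return self.hit.env_to

    @property
    def score(self) -> float:
        return self.hit.score


def coverage_fraction(hit: DomainHit) -> float:
    """Fraction of the profile's match states covered: (hmm_to-hmm_from+1)/tlen."""
    if hit.profile_length <= 0:
        raise ValidationError(f"profile_length must be positive, got {hit.profile_length}")
    return (hit.hmm_to - hit.hmm_from + 1) / hit.profile_length


def filter_hits(
    hits: Iterable[DomainHit],
    evalue_max: float = EVALUE_MAX_DEFAULT,
    coverage_min: float = COVERAGE_MIN_DEFAULT,
) -> list[RetainedDomain]:
    """Apply the two retention predicates; order preserved.

    E-value bound is inclusive (a hit at exactly ``evalue_max`` is kept);
    coverage bound is strict (exactly ``coverage_min`` is discarded).
    """
    retained: list[RetainedDomain] = []
    n_evalue = n_coverage = 0
    for hit in hits:
        cov = coverage_fraction(hit)
        if hit.i_evalue > evalue_max:
            n_evalue += 1
            continue
        if cov <= coverage_min:
            n_coverage += 1
            continue
        retained.append(RetainedDomain(hit=hit, coverage=cov))
    if n_evalue or n_coverage:
        logger.info(
            "filter_hits: discarded %d by i-Evalue > %g, %d by coverage <= %g; kept %d",
            n_evalue, evalue_max, n_coverage, coverage_min, len(retained),
        )
    return retained


def _overlap(a: RetainedDomain, b: RetainedDomain) -> int:
    return min(a.env_to, b.env_to) - max(a.env_from, b.env_from) + 1


def _envelope_len(d: RetainedDomain) -> int:
    return d.env_to - d.env_from + 1


def violates_overlap(
    a: RetainedDomain, b: RetainedDomain, max_overlap_frac: float
) -> bool:
    """True if the two envelopes overlap by more than the tolerated fraction
    of the shorter one."""
    ov = _overlap(a, b)
    if ov <= 0:
        return False
    return ov > max_overlap_frac * min(_envelope_len(a), _envelope_len(b))


def resolve_overlaps(
    domains: Sequence[RetainedDomain],
    max_overlap_frac: float = MAX_OVERLAP_FRAC_DEFAULT,
) -> list[RetainedDomain]:
    """Greedy envelope tiling for the retained domains of ONE protein.

    Candidates are visited by ascending i-E-value (ties: higher bit score,
    lower env_from, then family name) and accepted unless they overlap an
    already-accepted domain beyond the tolerance.  The result is sorted by
    envelope start (N-terminal first).  Idempotent.
    """
    proteins = {d.protein_id for d in domains}
    if len(proteins) > 1:
        raise ValueError(f"resolve_overlaps expects one protein, got {sorted(proteins)}")
    order = sorted(
        domains, key=lambda d: (d.i_evalue, -d.score, d.env_from, d.family_name)
    )
    accepted: list[RetainedDomain] = []
    for cand in order:
        if not any(violates_overlap(cand, a, max_overlap_frac) for a in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda d: (d.env_from, d.i_evalue, d.family_name))
    return accepted
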