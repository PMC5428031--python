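"""Per-protein domain architectures and their string notation.

An architecture is the N→C ordered list of a protein's retained domains,
written with consecutive repeats collapsed: ``CBM1-GH5-GH6``, ``2(GH5)``,
``8(GH25)-GH18``.  Non-adjacent repeats are not merged
(``GH11-CBM10-GH11-CBM10-GH11`` stays as written).

A protein enters the study only if it carries at least one target-catalytic
domain; accessory CBMs and other domains on such proteins are counted but
never create an entry by themselves.  A protein is *multi-domain* with >= 2
domains of any kind, *multi-activity* with >= 2 catalytic domains (target or
other catalytic), and *hetero-activity* when those catalytic domains span
>= 2 distinct families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .filtering import RetainedDomain
from .registry import DomainRegistry

__all__ = [
    "ProteinArchitecture",
    "ArchitectureType",
    "assemble_protein",
    "assemble_study",
    "encode_architecture",
    "decode_architecture",
    "architecture_inventory",
    "ArchitectureParseError",
]

SEPARATOR = "-"
# the notation in print mixes ASCII hyphens and en/em dashes; accept all
_DASHES = re.compile(r"[‐‒–—−]")
_RUN = re.compile(r"^(\d+)\((.+)\)$")


class ArchitectureParseError(ValueError):
    """Architecture string outside the ``k(NAME)`` grammar."""


@dataclass(frozen=True)
class ProteinArchitecture:
    """One protein's ordered, classified domain content."""

    genome_id: str
    protein_id: str
    domains: tuple[RetainedDomain, ...]
    arch_string: str
    n_total: int
    n_catalytic: int
    n_accessory: int
    n_other: int
    traits: frozenset[str]
    is_multidomain: bool
    is_multiactivity: bool
    is_hetero_activity: bool

    @property
    def family_names(self) -> tuple[str, ...]:
        return tuple(d.family_name for d in self.domains)

    def target_domains(self, registry: DomainRegistry) -> list[RetainedDomain]:
        return [
            d
            for d in self.domains
            if registry.category_of(d.family_name) == "target-catalytic"
        ]


@dataclass(frozen=True)
class ArchitectureType:
    """One architecture string with its study-wide prevalence."""

    arch_string: str
    n_proteins: int
    example_protein_id: str


def encode_architecture(names: Sequence[str]) -> str:
    """Collapse maximal runs: ``[GH5, GH5, CBM10]`` -> ``"2(GH5)-CBM10"``."""
    if not names:
        raise ValueError("cannot encode an empty architecture")
    parts: list[str] = []
    i = 0
    while i < len(names):
        j = i
        while j < len(names) and names[j] == names[i]:
            j += 1
        k = j - i
        parts.append(names[i] if k == 1 else f"{k}({names[i]})")
        i = j
    return SEPARATOR.join(parts)


def decode_architecture(arch_string: str) -> list[str]:
    """Expand an architecture string back to the ordered family-name list."""
    s = _DASHES.sub(SEPARATOR, arch_string).strip()
    if not s:
        raise ArchitectureParseError("empty architecture string")
    names: list[str] = []
    for token in s.split(SEPARATOR):
        token = token.strip()
        if not token:
            raise ArchitectureParseError(f"empty token in {arch_string!r}")
        m = _RUN.match(token)
        if m:
            k = int(m.group(1))
            if k < 2:
                raise ArchitectureParseError(
                    f"run count must be >= 2 in {token!r} ({arch_string!r})"
                )
            names.extend([m.group(2)] * k)
        else:
            if "(" in token or ")" in token:
                raise ArchitectureParseError(f"malformed token {token!r} in {arch_string!r}")
            names.append(token)
    return names


def assemble_protein(
    protein_id: str,
    domains: Sequence[RetainedDomain],
    registry: DomainRegistry,
    require_target: bool = True,
) -> ProteinArchitecture | None:
    """Build the architecture of one protein from its resolved domains.

    Returns ``None`` for an empty domain list, or (with ``require_target``)
    when no target-catalytic domain is present — such proteins are excluded
    from study tables, which is not an error.
    """
    if not domains:
        return None
    if any(d.protein_id != protein_id for d in domains):
        raise ValueError(f"domains do not all belong to protein {protein_id!r}")
    ordered = sorted(domains, key=lambda d: (d.env_from, d.i_evalue, d.family_name))
    cats = [registry.category_of(d.family_name) for d in ordered]
    if require_target and "target-catalytic" not in cats:
        return None
    n_catalytic = sum(c in ("target-catalytic", "other-catalytic") for c in cats)
    n_accessory = sum(c == "accessory-CBM" for c in cats)
    n_other = len(cats) - n_catalytic - n_accessory
    catalytic_families = {
        d.family_name
        for d, c in zip(ordered, cats)
        if c in ("target-catalytic", "other-catalytic")
    }
    traits = frozenset(
        t
        for d, c in zip(ordered, cats)
        if c == "target-catalytic" and (t := registry.trait_of(d.family_name))
    )
    genome_ids = {d.genome_id for d in ordered}
    if len(genome_ids) != 1:
        raise ValueError(f"protein {protein_id!r} spans genomes {sorted(genome_ids)}")
    return ProteinArchitecture(
        genome_id=next(iter(genome_ids)),
        protein_id=protein_id,
        domains=tuple(ordered),
        arch_string=encode_architecture([d.family_name for d in ordered]),
        n_total=len(ordered),
        n_catalytic=n_catalytic,
        n_accessory=n_accessory,
        n_other=n_other,
        traits=traits,
        is_multidomain=len(ordered) >= 2,
        is_multiactivity=n_catalytic >= 2,
        is_hetero_activity=len(catalytic_families) >= 2,
    )


def assemble_study(
    retained: Iterable[RetainedDomain],
    registry: DomainRegistry,
    max_overlap_frac: float | None = None,
) -> list[ProteinArchitecture]:
    """Group retained domains by (genome, protein), resolve overlaps, and
    assemble every protein that carries a target-catalytic domain.

    Input order of first appearance fixes the output protein order, so the
    result is deterministic for a given hit stream.
    """
    from .filtering import MAX_OVERLAP_FRAC_DEFAULT, resolve_overlaps

    frac = MAX_OVERLAP_FRAC_DEFAULT if max_overlap_frac is None else max_overlap_frac
    groups: dict[tuple[str, str], list[RetainedDomain]] = {}
    for d in retained:
        groups.setdefault((d.genome_id, d.protein_id), []).append(d)
    out: list[ProteinArchitecture] = []
    for (_, pid), doms in groups.items():
        arch = assemble_protein(pid, resolve_overlaps(doms, frac), registry)
        if arch is not None:
            out.append(arch)
    return out


def architecture_inventory(
    architectures: Iterable[ProteinArchitecture],
    multidomain_only: bool = False,
) -> list[ArchitectureType]:
    """Tally distinct architecture strings across the study.

    Sorted by descending prevalence, then string; the example is the first
    protein seen with that architecture.
    """
    counts: dict[str, int] = {}
    examples: dict[str, str] = {}
    for a in architectures:
        if multidomain_only and not a.is_multidomain:
            continue
        counts[a.arch_string] = counts.get(a.arch_string, 0) + 1
        examples.setdefault(a.arch_string, f"{a.genome_id}|{a.protein_id}")
    return [
        ArchitectureType(arch_string=s, n_proteins=n, example_protein_id=examples[s])
        for s, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
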