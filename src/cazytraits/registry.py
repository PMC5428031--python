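"""Domain-family registry: which Pfam families count, and as what.

The registry is the single source of classification for the whole pipeline.
Each entry is a domain family with a category:

* ``target-catalytic`` — the glycoside-hydrolase (GH) and lytic polysaccharide
  mono-oxygenase (LPMO, CAZy "AA") families whose substrate traits the study
  quantifies.  Every such entry carries a substrate trait: ``cellulase``,
  ``xylanase``, ``chitinase`` or ``LPMO``.
* ``accessory-CBM`` — non-catalytic carbohydrate-binding modules.
* ``other-catalytic`` — catalytic families outside the target set (e.g. GH25
  lysozyme, GH13 amylase) that still make a protein multi-activity.
* ``other`` — anything else found in a scan.

The default registry holds the sixteen target families with Pfam accessions
(GH5/PF00150 ... AA10/PF03443) plus GH19 (chitinase, no Pfam profile
available, hence no accession — it aggregates to zero unless the user
supplies one), the CBM families by name, and the other-catalytic partners
observed alongside the targets.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "CATEGORIES",
    "TRAITS",
    "RegistryEntry",
    "DomainRegistry",
    "RegistryError",
    "load_registry",
]

CATEGORIES = ("target-catalytic", "accessory-CBM", "other-catalytic", "other")
TRAITS = ("cellulase", "xylanase", "chitinase", "LPMO")

CATALYTIC_CATEGORIES = frozenset({"target-catalytic", "other-catalytic"})


class RegistryError(ValueError):
    """Configuration problem in a registry source."""


@dataclass(frozen=True)
class RegistryEntry:
    """One domain family.

    ``trait`` is present iff the category is ``target-catalytic``; ``note``
    carries free-text annotation such as AA10's dual cellulose/chitin
    substrate (which never affects counting).
    """

    name: str
    category: str
    accession: str | None = None
    trait: str | None = None
    note: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise RegistryError(f"unknown category {self.category!r} for {self.name!r}")
        if self.category == "target-catalytic":
            if self.trait not in TRAITS:
                raise RegistryError(
                    f"target-catalytic entry {self.name!r} needs a trait in {TRAITS}"
                )
        elif self.trait is not None:
            raise RegistryError(
                f"entry {self.name!r} has trait {self.trait!r} but category {self.category!r}"
            )

    @property
    def is_catalytic(self) -> bool:
        return self.category in CATALYTIC_CATEGORIES


# Table-style default: target families with their Pfam accessions and traits.
_TARGETS: tuple[tuple[str, str | None, str, str | None], ...] = (
    ("GH5", "PF00150", "cellulase", None),
    ("GH6", "PF01341", "cellulase", None),
    ("GH7", "PF00840", "cellulase", None),
    ("GH8", "PF01270", "cellulase", None),
    ("GH9", "PF00759", "cellulase", None),
    ("GH10", "PF00331", "xylanase", None),
    ("GH11", "PF00457", "xylanase", None),
    ("GH12", "PF01670", "cellulase", None),
    ("GH18", "PF00704", "chitinase", None),
    ("GH19", None, "chitinase", "no HMM profile available; supply an accession to use"),
    ("GH30", "PF02055", "xylanase", None),
    ("GH44", "PF12891", "cellulase", None),
    ("GH45", "PF02015", "cellulase", None),
    ("GH48", "PF02011", "cellulase", None),
    ("GH85", "PF03644", "chitinase", None),
    ("AA9", "PF03067", "LPMO", "active on cellulose"),
    ("AA10", "PF03443", "LPMO", "dual substrate: cellulose/chitin"),
)

# CBM accessions are not fixed by default; configure them for real scans.
_CBMS = ("CBM1", "CBM10", "CBM18", "CBM19", "CBM20", "CBM5/12", "CBM4/9", "CBM-X2")

# Catalytic partners seen fused to target domains (lysozyme, amylase,
# beta-glucosidase, endo-beta-1,3-glucanase, endo-alpha-1,4-polygalactosaminidase).
_OTHER_CATALYTIC = ("GH3", "GH13", "GH25", "GH81", "GH114")


def _default_entries() -> list[RegistryEntry]:
    entries = [
        RegistryEntry(name=n, accession=a, category="target-catalytic", trait=t, note=note)
        for n, a, t, note in _TARGETS
    ]
    entries += [RegistryEntry(name=n, category="accessory-CBM") for n in _CBMS]
    entries += [RegistryEntry(name=n, category="other-catalytic") for n in _OTHER_CATALYTIC]
    return entries


@dataclass
class DomainRegistry:
    """Lookup table of :class:`RegistryEntry` by name and by accession."""

    entries: list[RegistryEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_name: dict[str, RegistryEntry] = {}
        self._by_accession: dict[str, RegistryEntry] = {}
        for e in self.entries:
            if e.name in self._by_name:
                raise RegistryError(f"duplicate registry name {e.name!r}")
            self._by_name[e.name] = e
            if e.accession is not None:
                if e.accession in self._by_accession:
                    raise RegistryError(f"duplicate registry accession {e.accession!r}")
                self._by_accession[e.accession] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> RegistryEntry | None:
        return self._by_name.get(name)

    def __getitem__(self, name: str) -> RegistryEntry:
        return self._by_name[name]

    def classify(self, name: str, accession: str | None = None) -> RegistryEntry:
        """Resolve a scanned family to its entry, or a one-off ``other`` entry.

        Accession lookup takes priority (accessions are stable across Pfam
        releases; names are case-sensitive).  Version suffixes must already
        be stripped by the caller.
        """
        if accession is not None and accession in self._by_accession:
            return self._by_accession[accession]
        entry = self._by_name.get(name)
        if entry is not None:
            return entry
        return RegistryEntry(name=name, accession=accession, category="other")

    def trait_of(self, name: str) -> str | None:
        entry = self._by_name.get(name)
        return entry.trait if entry is not None else None

    def category_of(self, name: str) -> str:
        entry = self._by_name.get(name)
        return entry.category if entry is not None else "other"

    @property
    def target_families(self) -> list[str]:
        return [e.name for e in self.entries if e.category == "target-catalytic"]

    def families_with_trait(self, trait: str) -> list[str]:
        return [e.name for e in self.entries if e.trait == trait]

    def extended(self, extra: Iterable[RegistryEntry]) -> "DomainRegistry":
        """New registry with ``extra`` entries added; same-name entries override."""
        merged: dict[str, RegistryEntry] = {e.name: e for e in self.entries}
        for e in extra:
            merged[e.name] = e
        return DomainRegistry(entries=list(merged.values()))


def _entry_from_mapping(row: Mapping[str, object]) -> RegistryEntry:
    def clean(key: str) -> str | None:
        v = row.get(key)
        if v is None:
            return None
        v = str(v).strip()
        return v or None

    name = clean("name")
    if not name:
        raise RegistryError(f"registry row missing a name: {dict(row)!r}")
    category = clean("category") or "other"
    return RegistryEntry(
        name=name,
        accession=clean("accession"),
        category=category,
        trait=clean("trait"),
        note=clean("note"),
    )


def load_registry(source: str | Path = "default") -> DomainRegistry:
    """Load the default registry, optionally extended/overridden by a file.

    ``source`` is ``"default"`` or a path to a TSV (columns ``name``,
    ``accession``, ``category``, ``trait``, optional ``note``) or a YAML list
    of mappings with the same keys.  User entries extend the defaults;
    an entry whose name matches a default replaces it.
    """
    base = DomainRegistry(entries=_default_entries())
    if source == "default":
        return base
    path = Path(source)
    if path.suffix.lower() in {".yml", ".yaml"}:
        with open(path) as fh:
            rows = yaml.safe_load(fh) or []
        if not isinstance(rows, list):
            raise RegistryError(f"{path}: expected a YAML list of entries")
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    extra = [_entry_from_mapping(r) for r in rows]
    return base.extended(extra)
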