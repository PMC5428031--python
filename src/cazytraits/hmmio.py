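"""I/O for HMMER3 per-domain tables (domtblout) and study metadata.

The pipeline consumes ``hmmscan --domtblout`` output: proteins are queries,
profile HMMs are targets, so the target-length column is the profile's
match-state count and the envelope columns locate the hit on the protein.

Two dialects are read and written:

* standard 23-column domtblout, one file per genome (``genome_id`` given by
  the caller);
* an extended dialect with one extra leading ``genome_id`` column, for pooled
  multi-genome files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "DomainHit",
    "ParseError",
    "ValidationError",
    "read_domtblout",
    "write_domtblout",
    "read_genome_metadata",
    "write_genome_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "TaxonRecord",
    "RANKS",
]

RANKS = ("phylum", "subphylum", "class", "order", "family", "genus", "species")

_VERSION_SUFFIX = re.compile(r"\.\d+$")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


class ValidationError(ValueError):
    """Well-formed input violating a study-level constraint."""


@dataclass(frozen=True)
class DomainHit:
    """One per-domain hit row: a profile matched on a protein.

    Coordinates are 1-based inclusive; ``hmm_from..hmm_to`` index the profile
    (of ``profile_length`` match states), ``env_from..env_to`` the protein
    envelope.  ``i_evalue`` is the independent per-domain E-value.
    """

    genome_id: str
    protein_id: str
    family_name: str
    family_accession: str | None
    profile_length: int
    i_evalue: float
    hmm_from: int
    hmm_to: int
    env_from: int
    env_to: int
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.hmm_from <= self.hmm_to <= self.profile_length):
            raise ValidationError(
                f"{self.protein_id}/{self.family_name}: hmm coordinates "
                f"{self.hmm_from}..{self.hmm_to} out of profile length {self.profile_length}"
            )
        if not (1 <= self.env_from <= self.env_to):
            raise ValidationError(
                f"{self.protein_id}/{self.family_name}: bad envelope "
                f"{self.env_from}..{self.env_to}"
            )
        if self.i_evalue < 0:
            raise ValidationError(f"negative i-Evalue {self.i_evalue}")


def strip_accession_version(accession: str | None) -> str | None:
    """Drop a trailing Pfam version suffix: ``PF00150.17`` -> ``PF00150``."""
    if accession is None or accession in {"-", ""}:
        return None
    return _VERSION_SUFFIX.sub("", accession)


# Column indices in standard hmmscan domtblout (0-based).
_COL_TARGET, _COL_TACC, _COL_TLEN = 0, 1, 2
_COL_QUERY = 3
_COL_IEVALUE, _COL_DOMSCORE = 12, 13
_COL_HMM_FROM, _COL_HMM_TO = 15, 16
_COL_ENV_FROM, _COL_ENV_TO = 19, 20
_N_COLS = 23


def _parse_row(
    fields: Sequence[str], genome_id: str, path: str, lineno: int
) -> DomainHit:
    def intf(i: int, label: str) -> int:
        try:
            return int(fields[i])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer {label}: {fields[i]!r}") from exc

    def floatf(i: int, label: str) -> float:
        try:
            return float(fields[i])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric {label}: {fields[i]!r}") from exc

    try:
        return DomainHit(
            genome_id=genome_id,
            protein_id=fields[_COL_QUERY],
            family_name=fields[_COL_TARGET],
            family_accession=strip_accession_version(fields[_COL_TACC]),
            profile_length=intf(_COL_TLEN, "target length"),
            i_evalue=floatf(_COL_IEVALUE, "i-Evalue"),
            hmm_from=intf(_COL_HMM_FROM, "hmm from"),
            hmm_to=intf(_COL_HMM_TO, "hmm to"),
            env_from=intf(_COL_ENV_FROM, "env from"),
            env_to=intf(_COL_ENV_TO, "env to"),
            score=floatf(_COL_DOMSCORE, "domain score"),
        )
    except ValidationError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def read_domtblout(
    path: str | Path, genome_id: str | None = None
) -> list[DomainHit]:
    """Parse a domtblout file into :class:`DomainHit` rows, order preserved.

    With ``genome_id=None`` the extended dialect is expected (extra leading
    genome column); otherwise every hit is assigned ``genome_id``.  ``#``
    lines are comments; an empty file yields an empty list.
    """
    hits: list[DomainHit] = []
    name = str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if genome_id is None:
                if len(fields) < _N_COLS + 1:
                    raise ParseError(
                        f"{name}:{lineno}: expected >= {_N_COLS + 1} columns "
                        f"(extended dialect), got {len(fields)}"
                    )
                hits.append(_parse_row(fields[1:], fields[0], name, lineno))
            else:
                if len(fields) < _N_COLS:
                    raise ParseError(
                        f"{name}:{lineno}: expected >= {_N_COLS} columns, got {len(fields)}"
                    )
                hits.append(_parse_row(fields, genome_id, name, lineno))
    return hits


def write_domtblout(
    hits: Iterable[DomainHit], path: str | Path, extended: bool = False
) -> None:
    """Write hits as hmmscan-style domtblout (round-trips with the reader).

    Fields the pipeline does not use (full-sequence E-value/score, c-Evalue,
    alignment coordinates, posterior accuracy) are filled with placeholders;
    ``ali`` coordinates mirror the envelope.  ``extended=True`` prepends the
    genome_id column.
    """
    hits = list(hits)
    with open(path, "w") as fh:
        fh.write("# per-domain hits table (hmmscan orientation: target = profile)\n")
        prefix = "genome_id " if extended else ""
        fh.write(
            f"#{prefix}target_name accession tlen query_name accession qlen "
            "E-value score bias # of c-Evalue i-Evalue score bias "
            "hmm_from hmm_to ali_from ali_to env_from env_to acc description\n"
        )
        for h in hits:
            qlen = h.env_to + 10
            cols = [
                h.family_name,
                h.family_accession or "-",
                str(h.profile_length),
                h.protein_id,
                "-",
                str(qlen),
                f"{h.i_evalue:.3g}",
                f"{h.score:.1f}",
                "0.0",
                "1",
                "1",
                f"{h.i_evalue:.3g}",
                f"{h.i_evalue:.3g}",
                f"{h.score:.1f}",
                "0.0",
                str(h.hmm_from),
                str(h.hmm_to),
                str(h.env_from),
                str(h.env_to),
                str(h.env_from),
                str(h.env_to),
                "0.90",
                "-",
            ]
            if extended:
                cols.insert(0, h.genome_id)
            fh.write(" ".join(cols) + "\n")


def read_genome_metadata(path: str | Path) -> dict[str, int]:
    """Read a TSV of ``genome_id`` and positive ``gene_count``."""
    import csv

    counts: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"genome_id", "gene_count"} <= set(
            reader.fieldnames
        ):
            raise ParseError(f"{path}: need columns genome_id, gene_count")
        for i, row in enumerate(reader, start=2):
            gid = row["genome_id"].strip()
            if gid in counts:
                raise ValidationError(f"{path}:{i}: duplicate genome_id {gid!r}")
            try:
                n = int(row["gene_count"])
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}:{i}: non-integer gene_count {row['gene_count']!r}"
                ) from exc
            if n <= 0:
                raise ValidationError(f"{path}:{i}: gene_count must be positive, got {n}")
            counts[gid] = n
    return counts


def write_genome_metadata(counts: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgene_count\n")
        for gid, n in counts.items():
            fh.write(f"{gid}\t{n}\n")


@dataclass(frozen=True)
class TaxonRecord:
    """Ranked taxonomy of one genome; unknown ranks are absent from ``ranks``."""

    genome_id: str
    ranks: dict[str, str]

    def get(self, rank: str) -> str | None:
        return self.ranks.get(rank)


def read_taxonomy(path: str | Path) -> list[TaxonRecord]:
    """Read a TSV with ``genome_id`` plus any of the seven rank columns."""
    import csv

    records: list[TaxonRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "genome_id" not in reader.fieldnames:
            raise ParseError(f"{path}: need a genome_id column")
        rank_cols = [r for r in RANKS if r in reader.fieldnames]
        for i, row in enumerate(reader, start=2):
            gid = row["genome_id"].strip()
            if gid in seen:
                raise ValidationError(f"{path}:{i}: duplicate genome_id {gid!r}")
            seen.add(gid)
            ranks = {
                r: row[r].strip() for r in rank_cols if row.get(r) and row[r].strip()
            }
            records.append(TaxonRecord(genome_id=gid, ranks=ranks))
    return records


def write_taxonomy(records: Iterable[TaxonRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\t" + "\t".join(RANKS) + "\n")
        for rec in records:
            fh.write(
                rec.genome_id
                + "\t"
                + "\t".join(rec.ranks.get(r, "") for r in RANKS)
                + "\n"
            )
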