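"""Synthetic study generator with planted ground truth.

Emulates a multi-genome fungal survey: per-genome domtblout hit tables,
a gene-count metadata table, a ranked taxonomy, and a machine-readable truth
record.  The planted structure makes every pipeline stage testable exactly:

* every planted domain hit passes the retention filters by construction
  (i-E-value drawn <= 1e-6, profile coverage drawn in (0.6, 1.0]), and every
  decoy hit fails exactly one predicate (half by E-value, half by coverage),
  so filtering correctness is checked by identity, not statistically;
* per-genome trait domain counts are planted (frequency x gene count,
  rounded), so recovered counts must match truth with zero error;
* envelopes within a protein are disjoint and ordered, so the assembled
  architecture string must reproduce the planted one verbatim;
* trait frequencies are conserved at a configurable taxonomic rank: each
  clade at that rank draws its own trait means (between-clade dispersion),
  genomes inside scatter tightly around them (within-clade dispersion),
  planting the low-CoV-at-conserved-rank signal.

Profile lengths per family are simulator internals shipped in a table; they
make coordinates mutually consistent and claim nothing about real Pfam
models.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .hmmio import (
    RANKS,
    DomainHit,
    TaxonRecord,
    write_domtblout,
    write_genome_metadata,
    write_taxonomy,
)
from .registry import TRAITS, DomainRegistry, load_registry

__all__ = [
    "ArchitectureGrammar",
    "SyntheticConfig",
    "SyntheticStudy",
    "generate_study",
    "sample_architecture",
    "recovery_report",
    "ConfigError",
    "PROFILE_LENGTHS",
]


class ConfigError(ValueError):
    """Infeasible or inconsistent generator configuration."""


# Simulator-internal profile lengths (match-state counts) per family.
PROFILE_LENGTHS: dict[str, int] = {
    "GH5": 320, "GH6": 260, "GH7": 420, "GH8": 350, "GH9": 440,
    "GH10": 300, "GH11": 180, "GH12": 200, "GH18": 330, "GH30": 390,
    "GH44": 500, "GH45": 180, "GH48": 600, "GH85": 350,
    "AA9": 220, "AA10": 170,
    "GH25": 200, "GH13": 330, "GH3": 550, "GH81": 600, "GH114": 250,
    "CBM1": 35, "CBM10": 40, "CBM18": 40, "CBM19": 60, "CBM20": 95,
    "CBM5/12": 45, "CBM4/9": 140, "CBM-X2": 90,
}

# Per-trait family sampling weights, proportional to the observed dominance of
# GH5 (cellulose), GH10 (xylan), GH18 (chitin) and AA9 among LPMOs.
FAMILY_WEIGHTS: dict[str, dict[str, float]] = {
    "cellulase": {
        "GH5": 0.63, "GH7": 0.12, "GH12": 0.10, "GH6": 0.07,
        "GH45": 0.04, "GH9": 0.02, "GH44": 0.01, "GH8": 0.005, "GH48": 0.005,
    },
    "xylanase": {"GH10": 0.50, "GH11": 0.36, "GH30": 0.14},
    "chitinase": {"GH18": 0.96, "GH85": 0.04},
    "LPMO": {"AA9": 0.91, "AA10": 0.09},
}


@dataclass(frozen=True)
class ArchitectureGrammar:
    """Sampling rules for per-protein domain layouts.

    ``repeat_lengths`` are (k, weight) options for tandem runs of the primary
    catalytic family (k >= 2); ``hetero_partners`` maps a family to a fused
    partner and which side it goes on.  ``p_multiactivity`` gates everything
    that adds a second catalytic domain; with it at 0 every protein carries
    exactly one catalytic domain.
    """

    p_cbm_nterm: float = 0.10
    p_cbm_cterm: float = 0.06
    cbm_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "CBM1": 0.78, "CBM10": 0.06, "CBM18": 0.06, "CBM20": 0.05, "CBM5/12": 0.05
        }
    )
    p_multiactivity: float = 0.02
    p_hetero_given_multi: float = 0.25
    repeat_lengths: tuple[tuple[int, float], ...] = ((2, 0.92), (3, 0.06), (8, 0.02))
    partner_repeat_lengths: tuple[tuple[int, float], ...] = ((1, 1.0),)
    hetero_partners: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "GH5": ("GH6", "append"),
            "GH10": ("GH11", "append"),
            "GH18": ("GH25", "prepend"),
        }
    )

    def __post_init__(self) -> None:
        for p in (self.p_cbm_nterm, self.p_cbm_cterm, self.p_multiactivity,
                  self.p_hetero_given_multi):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        for k, w in self.repeat_lengths:
            if k < 2:
                raise ConfigError(f"tandem repeat length must be >= 2, got {k}")
            if w < 0:
                raise ConfigError("repeat weights must be non-negative")
        for k, w in self.partner_repeat_lengths:
            if k < 1:
                raise ConfigError(f"partner repeat length must be >= 1, got {k}")
        for fam, (partner, side) in self.hetero_partners.items():
            if side not in ("prepend", "append"):
                raise ConfigError(f"hetero side for {fam} must be prepend/append, got {side!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-level generator settings.

    Trait means are planted frequencies in domains per 1,000 predicted genes;
    ``between_clade_cv``/``within_clade_cv`` disperse them above/below
    ``conserved_rank``.  ``decoy_rate`` is the fraction of emitted hits that
    must fail the retention filters.
    """

    n_genomes: int = 218
    branching: Mapping[str, int] = field(
        default_factory=lambda: {
            "phylum": 2, "subphylum": 2, "class": 2, "order": 1,
            "family": 2, "genus": 2, "species": 2,
        }
    )
    conserved_rank: str = "genus"
    trait_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "cellulase": 1.5, "xylanase": 0.4, "chitinase": 1.0, "LPMO": 0.8
        }
    )
    between_clade_cv: float = 0.6
    within_clade_cv: float = 0.05
    gene_count_range: tuple[int, int] = (5000, 20000)
    grammar: ArchitectureGrammar = field(default_factory=ArchitectureGrammar)
    family_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: FAMILY_WEIGHTS
    )
    decoy_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ConfigError("n_genomes must be >= 1")
        if not 0.0 <= self.decoy_rate < 1.0:
            raise ConfigError("decoy_rate must be in [0, 1)")
        if self.conserved_rank not in RANKS:
            raise ConfigError(f"conserved_rank must be one of {RANKS}")
        if any(m <= 0 for m in self.trait_means.values()):
            raise ConfigError("trait_means must be positive")
        if not (0 <= self.within_clade_cv < self.between_clade_cv):
            raise ConfigError(
                "need within_clade_cv < between_clade_cv for a detectable signal"
            )
        lo, hi = self.gene_count_range
        if not (0 < lo <= hi):
            raise ConfigError("gene_count_range must be positive and ordered")
        for trait, weights in self.family_weights.items():
            if trait not in TRAITS:
                raise ConfigError(f"unknown trait {trait!r} in family_weights")
            if not weights or any(w < 0 for w in weights.values()):
                raise ConfigError(f"bad family weights for {trait}")


@dataclass
class SyntheticStudy:
    """Paths of an emitted study plus its ground truth."""

    study_dir: Path
    domtblout_paths: dict[str, Path]
    metadata_path: Path
    taxonomy_path: Path
    truth_path: Path
    truth: dict


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative noise with the given coefficient of variation."""
    if cv == 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2))))


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    names = sorted(weights)
    w = np.array([weights[n] for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=w / w.sum()))]


def _choice_kw(rng: np.random.Generator, options: Sequence[tuple[int, float]]) -> int:
    ks = [k for k, _ in options]
    w = np.array([wt for _, wt in options], dtype=float)
    return ks[int(rng.choice(len(ks), p=w / w.sum()))]


def sample_architecture(
    trait: str,
    grammar: ArchitectureGrammar,
    family_weights: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
    registry: DomainRegistry,
    max_trait_domains: int | None = None,
) -> tuple[list[str], int]:
    """Sample one protein's ordered family list for a substrate trait.

    Returns the names and how many of them are target-catalytic domains of
    ``trait`` (the planted-count bookkeeping unit).  With
    ``max_trait_domains`` set, the draw never consumes more than that budget
    (falling back to a single-domain protein when the budget is 1).
    """
    budget = math.inf if max_trait_domains is None else max_trait_domains
    if budget < 1:
        raise ConfigError("cannot sample a protein with a zero trait-domain budget")
    primary = _weighted_choice(rng, family_weights[trait])
    names: list[str] = [primary]
    used = 1
    if rng.random() < grammar.p_multiactivity and budget >= 2:
        hetero = (
            primary in grammar.hetero_partners
            and rng.random() < grammar.p_hetero_given_multi
        )
        if hetero:
            partner, side = grammar.hetero_partners[primary]
            k = _choice_kw(rng, grammar.partner_repeat_lengths)
            entry = registry.get(partner)
            consumes = (
                entry is not None
                and entry.category == "target-catalytic"
                and entry.trait == trait
            )
            if not consumes or used + k <= budget:
                block = [partner] * k
                names = block + names if side == "prepend" else names + block
                if consumes:
                    used += k
        else:
            k = _choice_kw(rng, grammar.repeat_lengths)
            if used + (k - 1) <= budget:
                names = [primary] * k
                used = k
    if rng.random() < grammar.p_cbm_nterm:
        names.insert(0, _weighted_choice(rng, grammar.cbm_weights))
    if rng.random() < grammar.p_cbm_cterm:
        names.append(_weighted_choice(rng, grammar.cbm_weights))
    return names, used


def _hit_coordinates(
    family: str, rng: np.random.Generator, fail_coverage: bool = False
) -> tuple[int, int, int, int]:
    """Draw (profile_length, hmm_from, hmm_to, span) for one domain.

    Planted hits cover > 60% of the profile; ``fail_coverage`` draws a span
    of at most half the profile (strictly failing the > 0.5 rule).
    """
    plen = PROFILE_LENGTHS.get(family, 250)
    if fail_coverage:
        lo = max(1, math.ceil(0.2 * plen))
        hi = math.floor(0.5 * plen)
        span = int(rng.integers(lo, hi + 1))
    else:
        u = rng.uniform(0.62, 1.0)
        span = min(plen, max(int(round(u * plen)), math.floor(0.6 * plen) + 1))
    hmm_from = int(rng.integers(1, plen - span + 2))
    return plen, hmm_from, hmm_from + span - 1, span


def _protein_hits(
    genome_id: str,
    protein_id: str,
    names: Sequence[str],
    registry: DomainRegistry,
    rng: np.random.Generator,
) -> list[DomainHit]:
    """Emit passing hits for a planted protein, envelopes disjoint and in
    architecture order."""
    hits: list[DomainHit] = []
    pos = int(rng.integers(1, 30))
    for name in names:
        plen, hmm_from, hmm_to, span = _hit_coordinates(name, rng)
        env_from = pos
        env_to = env_from + span - 1
        pos = env_to + int(rng.integers(5, 40))
        entry = registry.get(name)
        hits.append(
            DomainHit(
                genome_id=genome_id,
                protein_id=protein_id,
                family_name=name,
                family_accession=entry.accession if entry else None,
                profile_length=plen,
                i_evalue=float(10.0 ** -rng.uniform(6.0, 30.0)),
                hmm_from=hmm_from,
                hmm_to=hmm_to,
                env_from=env_from,
                env_to=env_to,
                score=float(rng.uniform(50.0, 300.0)),
            )
        )
    return hits


def _decoy_hit(
    genome_id: str,
    protein_id: str,
    env_start: int,
    registry: DomainRegistry,
    rng: np.random.Generator,
    fail: str,
) -> DomainHit:
    """One hit failing exactly the named predicate ('evalue' or 'coverage')."""
    family = _weighted_choice(rng, FAMILY_WEIGHTS["cellulase"] | FAMILY_WEIGHTS["chitinase"])
    if fail == "evalue":
        plen, hmm_from, hmm_to, span = _hit_coordinates(family, rng)
        i_evalue = float(10.0 ** -rng.uniform(0.0, 4.5))  # > 1e-5, coverage fine
    else:
        plen, hmm_from, hmm_to, span = _hit_coordinates(family, rng, fail_coverage=True)
        i_evalue = float(10.0 ** -rng.uniform(6.0, 20.0))  # passes E-value, fails coverage
    entry = registry.get(family)
    env_from = env_start + int(rng.integers(1, 50))
    return DomainHit(
        genome_id=genome_id,
        protein_id=protein_id,
        family_name=family,
        family_accession=entry.accession if entry else None,
        profile_length=plen,
        i_evalue=i_evalue,
        hmm_from=hmm_from,
        hmm_to=hmm_to,
        env_from=env_from,
        env_to=env_from + span - 1,
        score=float(rng.uniform(5.0, 40.0)),
    )


def _build_taxonomy(
    n_genomes: int, branching: Mapping[str, int]
) -> list[TaxonRecord]:
    """Balanced ranked taxonomy; genomes fill species leaves contiguously so
    multi-genome taxa exist at every rank."""
    factors = [max(1, int(branching.get(r, 1))) for r in RANKS]
    n_leaves = math.prod(factors)
    per_leaf = max(1, math.ceil(n_genomes / n_leaves))
    records = []
    for i in range(n_genomes):
        leaf = min(i // per_leaf, n_leaves - 1)
        path: list[int] = []
        rem = leaf
        for f in reversed(factors):
            path.append(rem % f)
            rem //= f
        path.reverse()
        ranks: dict[str, str] = {}
        for depth, rank in enumerate(RANKS):
            label = ".".join(str(x + 1) for x in path[: depth + 1])
            ranks[rank] = f"{rank[:3]}{label}"
        records.append(TaxonRecord(genome_id=f"g{i + 1:03d}", ranks=ranks))
    return records


def generate_study(
    config: SyntheticConfig,
    out_dir: str | Path,
    registry: DomainRegistry | None = None,
) -> SyntheticStudy:
    """Emit a complete synthetic study under ``out_dir``.

    Writes ``genomes/<genome_id>.domtblout`` (one per genome),
    ``metadata.tsv``, ``taxonomy.tsv`` and ``truth.json``.  Fully determined
    by ``config`` (including its seed): the same config yields byte-identical
    files.
    """
    registry = registry or load_registry()
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    genome_dir = out / "genomes"
    genome_dir.mkdir(parents=True, exist_ok=True)

    taxonomy = _build_taxonomy(config.n_genomes, config.branching)
    clades = [t.ranks[config.conserved_rank] for t in taxonomy]
    clade_means: dict[str, dict[str, float]] = {}
    for clade in dict.fromkeys(clades):  # first-appearance order, deterministic
        clade_means[clade] = {
            t: config.trait_means[t] * _lognormal_factor(rng, config.between_clade_cv)
            for t in TRAITS
        }

    lo, hi = config.gene_count_range
    gene_counts: dict[str, int] = {}
    truth_genomes: dict[str, dict] = {}
    truth_proteins: dict[str, dict[str, str]] = {}
    truth_decoys: list[dict] = []
    domtblout_paths: dict[str, Path] = {}

    from .architecture import encode_architecture

    for rec, clade in zip(taxonomy, clades):
        gid = rec.genome_id
        gene_count = int(rng.integers(lo, hi + 1))
        gene_counts[gid] = gene_count
        planted_freq = {
            t: clade_means[clade][t] * _lognormal_factor(rng, config.within_clade_cv)
            for t in TRAITS
        }
        planted_counts = {
            t: int(round(planted_freq[t] * gene_count / 1000.0)) for t in TRAITS
        }

        hits: list[DomainHit] = []
        archs: dict[str, str] = {}
        pidx = 0
        for trait in TRAITS:
            remaining = planted_counts[trait]
            while remaining > 0:
                names, used = sample_architecture(
                    trait, config.grammar, config.family_weights, rng, registry,
                    max_trait_domains=remaining,
                )
                pidx += 1
                pid = f"prot{pidx:05d}"
                hits.extend(_protein_hits(gid, pid, names, registry, rng))
                archs[pid] = encode_architecture(names)
                remaining -= used

        n_true = len(hits)
        n_decoys = int(round(config.decoy_rate / (1.0 - config.decoy_rate) * n_true))
        protein_ids = list(archs)
        for d in range(n_decoys):
            fail = "evalue" if d % 2 == 0 else "coverage"
            if protein_ids and rng.random() < 0.5:
                pid = protein_ids[int(rng.integers(0, len(protein_ids)))]
                env_start = max((h.env_to for h in hits if h.protein_id == pid), default=1)
            else:
                pid = f"decoy{d + 1:04d}"
                env_start = 1
            hit = _decoy_hit(gid, pid, env_start, registry, rng, fail)
            hits.append(hit)
            truth_decoys.append(
                {
                    "genome_id": gid,
                    "protein_id": pid,
                    "family": hit.family_name,
                    "env_from": hit.env_from,
                    "reason": fail,
                }
            )

        path = genome_dir / f"{gid}.domtblout"
        write_domtblout(hits, path)
        domtblout_paths[gid] = path
        truth_genomes[gid] = {
            "gene_count": gene_count,
            "clade": clade,
            "taxonomy": dict(rec.ranks),
            "trait_counts": planted_counts,
            "trait_freqs": {
                t: 1000.0 * planted_counts[t] / gene_count for t in TRAITS
            },
        }
        truth_proteins[gid] = archs

    metadata_path = out / "metadata.tsv"
    taxonomy_path = out / "taxonomy.tsv"
    write_genome_metadata(gene_counts, metadata_path)
    write_taxonomy(taxonomy, taxonomy_path)

    cfg = asdict(config)
    cfg["grammar"] = {
        k: (dict(v) if isinstance(v, Mapping) else v)
        for k, v in asdict(config.grammar).items()
    }
    truth = {
        "config": json.loads(json.dumps(cfg, default=list)),
        "conserved_rank": config.conserved_rank,
        "genomes": truth_genomes,
        "proteins": truth_proteins,
        "decoys": truth_decoys,
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=1, sort_keys=True))
    return SyntheticStudy(
        study_dir=out,
        domtblout_paths=domtblout_paths,
        metadata_path=metadata_path,
        taxonomy_path=taxonomy_path,
        truth_path=truth_path,
        truth=truth,
    )


def recovery_report(
    truth: dict,
    profiles: Sequence,
    architectures: Sequence,
    seed: int | None = None,
) -> dict:
    """Compare pipeline outputs against the planted truth.

    Reports exact trait-count and frequency recovery errors, architecture
    string mismatches, the conservatism contrast (median CoV at the conserved
    rank vs one rank above), and the adjusted Rand index of the dendrogram
    cut at the planted clade count against the planted clade labels.
    """
    from sklearn.metrics import adjusted_rand_score

    from .stats import conservatism, count_matrix, cut_clusters, dissimilarity

    truth_genomes = truth["genomes"]
    prof_by_id = {p.genome_id: p for p in profiles}
    if set(prof_by_id) != set(truth_genomes):
        raise ValueError("profiles and truth cover different genomes")

    count_err = 0
    freq_err = 0.0
    for gid, tg in truth_genomes.items():
        p = prof_by_id[gid]
        for t in TRAITS:
            count_err = max(count_err, abs(p.trait_counts[t] - tg["trait_counts"][t]))
            freq_err = max(freq_err, abs(p.trait_freqs[t] - tg["trait_freqs"][t]))

    truth_arch = truth["proteins"]
    mismatches = 0
    n_proteins = 0
    seen: dict[str, set[str]] = {g: set() for g in truth_arch}
    for a in architectures:
        n_proteins += 1
        seen[a.genome_id].add(a.protein_id)
        if truth_arch[a.genome_id].get(a.protein_id) != a.arch_string:
            mismatches += 1
    missing = sum(len(set(t) - seen[g]) for g, t in truth_arch.items())

    taxonomy = [
        TaxonRecord(genome_id=g, ranks=dict(tg["taxonomy"]))
        for g, tg in truth_genomes.items()
    ]
    rank = truth["conserved_rank"]
    parent = RANKS[RANKS.index(rank) - 1]
    cons = conservatism(profiles, taxonomy, ranks=(parent, rank))
    med = cons.dropna(subset=["cov"]).groupby("rank")["cov"].median()
    median_cov_conserved = float(med.get(rank, float("nan")))
    median_cov_parent = float(med.get(parent, float("nan")))

    clade_labels = {g: tg["clade"] for g, tg in truth_genomes.items()}
    k = len(set(clade_labels.values()))
    ari = float("nan")
    if k >= 2 and len(truth_genomes) > k:
        dm = dissimilarity(count_matrix(profiles=profiles, level="family"))
        cut = cut_clusters(dm, k)
        ids = sorted(clade_labels)
        ari = float(
            adjusted_rand_score([clade_labels[g] for g in ids], [cut[g] for g in ids])
        )

    return {
        "max_abs_trait_count_error": int(count_err),
        "max_abs_trait_freq_error": float(freq_err),
        "n_proteins_recovered": n_proteins,
        "n_architecture_mismatches": int(mismatches),
        "n_proteins_missing": int(missing),
        "median_cov_conserved_rank": median_cov_conserved,
        "median_cov_parent_rank": median_cov_parent,
        "clade_ari": ari,
    }
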