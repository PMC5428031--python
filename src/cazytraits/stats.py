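"""Comparative statistics over genome profiles.

Covers four analyses:

* pairwise trait correlations (Spearman and Pearson), trait-vs-trait on
  per-genome frequencies and trait-vs-gene-count on raw counts;
* trait conservatism across taxonomic ranks — for every taxon with more than
  one genome, the coefficient of variation (sample SD / mean) of each trait,
  from subphylum down to species;
* genome clustering: count matrices in family, trait or architecture space,
  Bray-Curtis dissimilarity (Euclidean/Jaccard selectable), UPGMA dendrogram
  with Newick output;
* the Mantel permutation test comparing the two distance matrices
  (domain-distribution space vs protein-architecture space).

The Mantel statistic is the Pearson correlation of the lower-triangle
distances; significance is one-sided (greater), p = (1 + #{r_perm >= r_obs})
/ (permutations + 1), permuting one matrix's rows and columns jointly with a
seeded generator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode

from .architecture import ProteinArchitecture
from .hmmio import RANKS, TaxonRecord
from .profiles import GenomeProfile
from .registry import TRAITS

__all__ = [
    "CorrelationResult",
    "MantelResult",
    "trait_correlations",
    "conservatism",
    "count_matrix",
    "dissimilarity",
    "hierarchical_cluster",
    "mantel_test",
]

logger = logging.getLogger(__name__)

CONSERVATISM_RANKS = ("subphylum", "class", "order", "family", "genus", "species")


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r_s: float
    p_s: float
    r_p: float
    p_p: float
    n: int
    basis: str


@dataclass(frozen=True)
class MantelResult:
    r_mantel: float
    p: float
    n_permutations: int
    n: int


def _corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("zero-variance variable; correlation undefined")
        return (float("nan"),) * 4
    r_s, p_s = sps.spearmanr(x, y)
    r_p, p_p = sps.pearsonr(x, y)
    return float(r_s), float(p_s), float(r_p), float(p_p)


def trait_correlations(
    profiles: Sequence[GenomeProfile],
    basis: Literal["frequency", "count"] = "frequency",
) -> list[CorrelationResult]:
    """All trait pairs, plus each trait against the predicted-gene count.

    Trait-vs-trait uses per-genome trait values on the requested ``basis``
    (frequencies per 1,000 genes by default); trait-vs-gene-count always uses
    raw domain counts against gene counts.
    """
    if len(profiles) < 3:
        raise ValueError(f"need >= 3 genomes for correlations, got {len(profiles)}")
    freq = {
        t: np.array(
            [p.trait_freqs[t] if basis == "frequency" else p.trait_counts[t] for p in profiles],
            dtype=float,
        )
        for t in TRAITS
    }
    counts = {t: np.array([p.trait_counts[t] for p in profiles], dtype=float) for t in TRAITS}
    gc = np.array([p.gene_count for p in profiles], dtype=float)
    results: list[CorrelationResult] = []
    n = len(profiles)
    for i, t1 in enumerate(TRAITS):
        for t2 in TRAITS[i + 1 :]:
            r_s, p_s, r_p, p_p = _corr(freq[t1], freq[t2])
            results.append(CorrelationResult((t1, t2), r_s, p_s, r_p, p_p, n, basis))
    for t in TRAITS:
        r_s, p_s, r_p, p_p = _corr(counts[t], gc)
        results.append(CorrelationResult((t, "gene_count"), r_s, p_s, r_p, p_p, n, "count"))
    return results


def correlations_frame(results: Iterable[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "var1": r.pair[0], "var2": r.pair[1],
                "r_spearman": r.r_s, "p_spearman": r.p_s,
                "r_pearson": r.r_p, "p_pearson": r.p_p,
                "n": r.n, "basis": r.basis,
            }
            for r in results
        ]
    )


def conservatism(
    profiles: Sequence[GenomeProfile],
    taxonomy: Sequence[TaxonRecord],
    ranks: Sequence[str] = CONSERVATISM_RANKS,
    basis: Literal["frequency", "count"] = "frequency",
) -> pd.DataFrame:
    """Per-rank, per-taxon, per-trait coefficient of variation.

    Only taxa with more than one genome are reported; CoV = sample SD
    (n-1 denominator) / mean, NA where the mean is zero.  Genomes without a
    taxonomy record are dropped from this analysis (with a warning).
    """
    unknown = [r for r in ranks if r not in RANKS]
    if unknown:
        raise ValueError(f"unknown ranks {unknown}; valid: {RANKS}")
    tax_by_genome = {t.genome_id: t for t in taxonomy}
    kept = [p for p in profiles if p.genome_id in tax_by_genome]
    if len(kept) < len(profiles):
        missing = sorted({p.genome_id for p in profiles} - set(tax_by_genome))
        logger.warning(
            "conservatism: %d genomes lack taxonomy and are dropped: %s",
            len(missing), ", ".join(missing[:5]),
        )
    rows = []
    for rank in ranks:
        groups: dict[str, list[GenomeProfile]] = {}
        for p in kept:
            taxon = tax_by_genome[p.genome_id].get(rank)
            if taxon is not None:
                groups.setdefault(taxon, []).append(p)
        for taxon in sorted(groups):
            members = groups[taxon]
            if len(members) <= 1:
                continue
            for trait in TRAITS:
                vals = np.array(
                    [
                        m.trait_freqs[trait] if basis == "frequency" else m.trait_counts[trait]
                        for m in members
                    ],
                    dtype=float,
                )
                mean = float(vals.mean())
                sd = float(vals.std(ddof=1))
                rows.append(
                    {
                        "rank": rank,
                        "taxon": taxon,
                        "trait": trait,
                        "n_genomes": len(members),
                        "mean": mean,
                        "sd": sd,
                        "cov": sd / mean if mean > 0 else float("nan"),
                    }
                )
    return pd.DataFrame(
        rows, columns=["rank", "taxon", "trait", "n_genomes", "mean", "sd", "cov"]
    )


def count_matrix(
    profiles: Sequence[GenomeProfile] | None = None,
    architectures: Sequence[ProteinArchitecture] | None = None,
    level: Literal["family", "trait", "architecture"] = "family",
) -> pd.DataFrame:
    """Genomes x features count matrix for clustering.

    ``family``/``trait`` need profiles; ``architecture`` needs the assembled
    proteins and uses full architecture strings (accessory domains included)
    as features.  Rows are sorted by genome id, columns by feature name, so
    the matrix is canonical regardless of input order.
    """
    if level in ("family", "trait"):
        if profiles is None:
            raise ValueError(f"level={level!r} requires profiles")
        if level == "family":
            rows = {p.genome_id: p.family_counts for p in profiles}
        else:
            rows = {p.genome_id: p.trait_counts for p in profiles}
        df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    elif level == "architecture":
        if architectures is None:
            raise ValueError("level='architecture' requires architectures")
        counts: dict[str, dict[str, int]] = {}
        for a in architectures:
            row = counts.setdefault(a.genome_id, {})
            row[a.arch_string] = row.get(a.arch_string, 0) + 1
        if profiles is not None:  # keep zero-protein genomes as all-zero rows
            for p in profiles:
                counts.setdefault(p.genome_id, {})
        df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    else:
        raise ValueError(f"unknown level {level!r}")
    if df.empty:
        return df
    return df.sort_index().sort_index(axis=1)


def dissimilarity(
    matrix: pd.DataFrame,
    metric: Literal["braycurtis", "euclidean", "jaccard"] = "braycurtis",
) -> DistanceMatrix:
    """Pairwise dissimilarity between genome rows.

    Bray-Curtis by default; ``jaccard`` is computed on presence/absence.
    A pair of all-zero rows has undefined Bray-Curtis distance; it is defined
    as 0 here (identical emptiness) with a warning.
    """
    if (matrix.values < 0).any():
        raise ValueError("count matrix must be non-negative")
    X = matrix.to_numpy(dtype=float)
    if metric == "jaccard":
        X = (X > 0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = pdist(X, metric=metric)
    if np.isnan(d).any():
        logger.warning(
            "dissimilarity: %d undefined pairs (all-zero rows) set to 0", int(np.isnan(d).sum())
        )
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(squareform(d), ids=list(matrix.index.astype(str)))


def hierarchical_cluster(
    dm: DistanceMatrix,
    method: str = "average",
) -> tuple[str, pd.DataFrame]:
    """Agglomerative clustering (UPGMA by default) of a distance matrix.

    Labels are put in sorted order before linkage so identical matrices give
    identical merge tables whatever the input row order.  Returns the Newick
    string (leaves = genome ids, branch lengths from merge heights) and the
    merge table (SciPy linkage columns).
    """
    if dm.shape[0] < 2:
        raise ValueError("clustering needs >= 2 genomes")
    order = sorted(dm.ids)
    dm = dm.filter(order)
    Z = linkage(squareform(dm.data, checks=False), method=method)
    tree = TreeNode.from_linkage_matrix(Z, order)
    newick = str(tree).strip()
    merges = pd.DataFrame(Z, columns=["left", "right", "height", "n_leaves"])
    return newick, merges


def cut_clusters(dm: DistanceMatrix, k: int, method: str = "average") -> dict[str, int]:
    """Flat cluster labels from cutting the dendrogram into ``k`` groups."""
    from scipy.cluster.hierarchy import fcluster

    order = sorted(dm.ids)
    dm = dm.filter(order)
    Z = linkage(squareform(dm.data, checks=False), method=method)
    labels = fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(order, (int(x) for x in labels)))


def _lower_triangle(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(d.shape[0], k=-1)
    return d[i, j]


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 999,
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    Matrices must share ids (d2 is reordered to d1's labels).  The observed
    statistic is the Pearson correlation of lower-triangle distances; the
    one-sided p-value counts permutations of d2's objects whose correlation
    reaches the observed one.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must share the same ids")
    n = d1.shape[0]
    if n < 3:
        raise ValueError("mantel test needs >= 3 objects")
    d2 = d2.filter(d1.ids)
    x = _lower_triangle(d1.data)
    m2 = d2.data
    y = _lower_triangle(m2)
    if x.std() == 0 or y.std() == 0:
        logger.warning("mantel: constant distance matrix; statistic undefined")
        return MantelResult(float("nan"), float("nan"), permutations, n)
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    r_obs = float(np.dot(xs, ys) / len(x))
    rng = np.random.default_rng(seed)
    tri = np.tril_indices(n, k=-1)
    n_ge = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        yp = m2[np.ix_(perm, perm)][tri]
        sd = yp.std()
        r_perm = float(np.dot(xs, (yp - yp.mean()) / sd) / len(x))
        if r_perm >= r_obs:
            n_ge += 1
    p = (1 + n_ge) / (permutations + 1)
    return MantelResult(r_obs, p, permutations, n)
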