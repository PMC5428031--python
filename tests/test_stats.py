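import io
import math

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode

from cazytraits.hmmio import TaxonRecord
from cazytraits.profiles import GenomeProfile
from cazytraits.registry import TRAITS
from cazytraits.stats import (
    conservatism,
    count_matrix,
    cut_clusters,
    dissimilarity,
    hierarchical_cluster,
    mantel_test,
    trait_correlations,
)
from cazytraits.stats import _corr


def profile(genome_id, gene_count, **freqs) -> GenomeProfile:
    """Profile with trait frequencies given per 1,000 genes (held exactly)."""
    counts = {t: int(round(freqs.get(t, 0.0) * gene_count / 1000)) for t in TRAITS}
    return GenomeProfile(
        genome_id=genome_id,
        gene_count=gene_count,
        family_counts={},
        trait_counts=counts,
        trait_freqs={t: float(freqs.get(t, 0.0)) for t in TRAITS},
        trait_protein_counts=dict(counts),
        n_proteins=sum(counts.values()),
        n_multidomain=0,
    )


# --- correlation oracles ----------------------------------------------------


def brute_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def brute_ranks(x):
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and x[order[j]] == x[order[i]]:
            j += 1
        avg = (i + j + 1) / 2.0  # average of ranks i+1..j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    return ranks


def brute_spearman(x, y):
    return brute_pearson(brute_ranks(x), brute_ranks(y))


def test_correlations_match_bruteforce_oracles():
    rng = np.random.default_rng(42)
    for _ in range(50):
        n = int(rng.integers(4, 21))
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if rng.random() < 0.3:  # inject ties to exercise tie-corrected ranks
            x = np.round(x)
        r_s, _, r_p, _ = _corr(x, y)
        assert r_s == pytest.approx(brute_spearman(list(x), list(y)), abs=1e-12)
        assert r_p == pytest.approx(brute_pearson(list(x), list(y)), abs=1e-12)


def test_perfect_monotone_and_self_correlation():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([2.0, 4.0, 6.0])
    r_s, _, r_p, _ = _corr(x, y)
    assert r_s == pytest.approx(1.0) and r_p == pytest.approx(1.0)
    r_s, _, r_p, _ = _corr(x, x)
    assert r_s == pytest.approx(1.0) and r_p == pytest.approx(1.0)


def test_zero_variance_gives_nan():
    r_s, p_s, r_p, p_p = _corr(np.array([1.0, 2.0, 3.0]), np.array([5.0, 5.0, 5.0]))
    assert all(math.isnan(v) for v in (r_s, p_s, r_p, p_p))


def test_trait_correlations_pairs_and_gene_count():
    profs = [
        profile(f"g{i}", 10000 + 1000 * i,
                cellulase=1.0 + 0.1 * i, xylanase=0.5 + 0.05 * i,
                chitinase=1.0, LPMO=0.8)
        for i in range(6)
    ]
    results = trait_correlations(profs)
    pairs = {r.pair for r in results}
    assert ("cellulase", "xylanase") in pairs
    assert all((t, "gene_count") in pairs for t in TRAITS)
    assert len(results) == 6 + 4
    by_pair = {r.pair: r for r in results}
    assert by_pair[("cellulase", "xylanase")].r_s == pytest.approx(1.0)


def test_trait_correlations_needs_three_genomes():
    with pytest.raises(ValueError):
        trait_correlations([profile("g1", 1000), profile("g2", 1000)])


# --- conservatism -----------------------------------------------------------


def taxonomy_two_genera():
    recs = []
    for i in range(6):
        genus = "genA" if i < 3 else "genB"
        recs.append(TaxonRecord(f"g{i}", {"subphylum": "sub1", "family": "fam1",
                                          "genus": genus, "species": f"sp{i}"}))
    return recs


def test_cov_exact_values():
    # frequencies (1, 2, 3): mean 2, sample sd 1, cov 0.5; identical values: cov 0
    profs = [profile(f"g{i}", 10000, cellulase=v, chitinase=2.0)
             for i, v in enumerate([1.0, 2.0, 3.0])]
    recs = [TaxonRecord(f"g{i}", {"genus": "genA"}) for i in range(3)]
    table = conservatism(profs, recs, ranks=("genus",))
    cell = table[(table.trait == "cellulase")].iloc[0]
    assert cell["mean"] == pytest.approx(2.0)
    assert cell["sd"] == pytest.approx(1.0)
    assert cell["cov"] == pytest.approx(0.5)
    chit = table[(table.trait == "chitinase")].iloc[0]
    assert chit["cov"] == pytest.approx(0.0)


def test_singleton_taxa_excluded_and_zero_mean_is_nan():
    profs = [profile("g0", 10000), profile("g1", 10000), profile("g2", 10000)]
    recs = [
        TaxonRecord("g0", {"genus": "solo"}),
        TaxonRecord("g1", {"genus": "pair"}),
        TaxonRecord("g2", {"genus": "pair"}),
    ]
    table = conservatism(profs, recs, ranks=("genus",))
    assert set(table["taxon"]) == {"pair"}
    assert table["cov"].isna().all()  # all-zero traits: mean 0 -> NA


def test_cov_scale_invariance():
    base = [1.1, 2.3, 3.7, 2.9]
    for c in (1.0, 3.5, 100.0):
        profs = [profile(f"g{i}", 10000, xylanase=v * c) for i, v in enumerate(base)]
        recs = [TaxonRecord(f"g{i}", {"genus": "genA"}) for i in range(4)]
        table = conservatism(profs, recs, ranks=("genus",))
        cov = table[table.trait == "xylanase"]["cov"].iloc[0]
        assert cov == pytest.approx(np.std(base, ddof=1) / np.mean(base))


def test_genomes_without_taxonomy_dropped_with_warning(caplog):
    profs = [profile(f"g{i}", 10000, cellulase=1.0) for i in range(3)]
    recs = taxonomy_two_genera()[:2]
    with caplog.at_level("WARNING"):
        table = conservatism(profs, recs, ranks=("genus",))
    assert "dropped" in caplog.text
    assert set(table["n_genomes"]) == {2}


# --- count matrices and distances ------------------------------------------


def test_count_matrix_family_level():
    p = profile("g1", 10000)
    p.family_counts.update({"GH5": 1})
    mat = count_matrix(profiles=[p], level="family")
    assert mat.loc["g1", "GH5"] == 1 and mat.shape == (1, 1)


def test_count_matrix_architecture_level_distinct_strings(registry):
    from cazytraits.architecture import assemble_protein
    from conftest import domains_for_protein

    archs = [
        assemble_protein("p1", domains_for_protein("p1", ["CBM1", "GH5"]), registry),
        assemble_protein("p2", domains_for_protein("p2", ["GH5"]), registry),
    ]
    mat = count_matrix(architectures=archs, level="architecture")
    assert set(mat.columns) == {"CBM1-GH5", "GH5"}
    assert mat.loc["g1"].tolist() == [1, 1]


def test_count_matrix_empty_study():
    assert count_matrix(profiles=[], level="family").empty


def test_braycurtis_values_and_zero_rows(caplog):
    mat = pd.DataFrame(
        [[1, 1], [1, 0], [0, 1], [0, 0], [0, 0]],
        index=["a", "b", "c", "z1", "z2"], columns=["f1", "f2"],
    )
    with caplog.at_level("WARNING"):
        dm = dissimilarity(mat)
    assert dm["a", "b"] == pytest.approx(1 / 3)  # |1-1|+|1-0| over 3
    assert dm["b", "c"] == pytest.approx(1.0)    # disjoint support
    assert dm["a", "a"] == 0.0
    assert dm["z1", "z2"] == 0.0                 # both empty: defined as 0
    assert "undefined" in caplog.text
    assert np.allclose(dm.data, dm.data.T)
    assert (dm.data >= 0).all() and (dm.data <= 1).all()


def test_identical_rows_distance_zero():
    mat = pd.DataFrame([[3, 2], [3, 2]], index=["a", "b"], columns=["f1", "f2"])
    assert dissimilarity(mat)["a", "b"] == 0.0


# --- clustering -------------------------------------------------------------


def test_two_genome_merge_height():
    dm = DistanceMatrix([[0, 0.4], [0.4, 0]], ids=["a", "b"])
    newick, merges = hierarchical_cluster(dm)
    assert len(merges) == 1
    assert merges["height"].iloc[0] == pytest.approx(0.4)
    tree = TreeNode.read(io.StringIO(newick))
    assert {t.name for t in tree.tips()} == {"a", "b"}


def test_identical_pair_merges_first():
    d = np.array([[0, 0, 0.8], [0, 0, 0.8], [0.8, 0.8, 0]], dtype=float)
    dm = DistanceMatrix(d, ids=["a", "b", "far"])
    newick, merges = hierarchical_cluster(dm)
    assert merges["height"].iloc[0] == pytest.approx(0.0)
    tree = TreeNode.read(io.StringIO(newick))
    assert len(list(tree.tips())) == 3


def test_clustering_invariant_to_row_order():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(8, 3))
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(pts))
    ids = [f"g{i}" for i in range(8)]
    dm1 = DistanceMatrix(d, ids=ids)
    perm = rng.permutation(8)
    dm2 = DistanceMatrix(d[np.ix_(perm, perm)], ids=[ids[i] for i in perm])
    n1, m1 = hierarchical_cluster(dm1)
    n2, m2 = hierarchical_cluster(dm2)
    assert n1 == n2
    assert np.allclose(m1["height"], m2["height"])


def test_cluster_requires_two_genomes():
    with pytest.raises(ValueError):
        hierarchical_cluster(DistanceMatrix([[0.0]], ids=["a"]))


# --- Mantel -----------------------------------------------------------------


def random_dm(n, seed, ids=None):
    rng = np.random.default_rng(seed)
    from scipy.spatial.distance import pdist, squareform

    pts = rng.normal(size=(n, 3))
    return DistanceMatrix(squareform(pdist(pts)), ids=ids or [f"g{i}" for i in range(n)])


def test_mantel_self_correlation():
    dm = random_dm(10, seed=7)
    res = mantel_test(dm, dm, permutations=999, seed=1)
    assert res.r_mantel == pytest.approx(1.0)
    assert res.p == pytest.approx(1 / 1000)


def test_mantel_constant_matrix_is_nan():
    dm = random_dm(6, seed=1)
    const = DistanceMatrix(1 - np.eye(6), ids=list(dm.ids))
    res = mantel_test(dm, const, permutations=99, seed=0)
    assert math.isnan(res.r_mantel) and math.isnan(res.p)


def test_mantel_deterministic_under_seed_and_label_alignment():
    d1 = random_dm(8, seed=3)
    d2 = random_dm(8, seed=4)
    r1 = mantel_test(d1, d2, permutations=199, seed=11)
    r2 = mantel_test(d1, d2, permutations=199, seed=11)
    assert (r1.r_mantel, r1.p) == (r2.r_mantel, r2.p)
    # reordering d2's labels must not change the statistic
    shuffled = d2.filter(list(d2.ids)[::-1])
    r3 = mantel_test(d1, shuffled, permutations=199, seed=11)
    assert r3.r_mantel == pytest.approx(r1.r_mantel)


def test_mantel_statistic_matches_skbio():
    from skbio.stats.distance import mantel as skbio_mantel

    d1 = random_dm(12, seed=5)
    d2 = random_dm(12, seed=6)
    ours = mantel_test(d1, d2, permutations=99, seed=0)
    r_ref, _, _ = skbio_mantel(d1, d2, permutations=0, alternative="greater")
    assert ours.r_mantel == pytest.approx(float(r_ref), abs=1e-12)


def test_mantel_mismatched_labels_error():
    d1 = random_dm(5, seed=1)
    d2 = random_dm(5, seed=2, ids=[f"x{i}" for i in range(5)])
    with pytest.raises(ValueError):
        mantel_test(d1, d2)


def test_cut_clusters_labels():
    d = np.zeros((4, 4))
    for i in (0, 1):
        for j in (2, 3):
            d[i, j] = d[j, i] = 1.0
    dm = DistanceMatrix(d, ids=["a", "b", "c", "d"])
    labels = cut_clusters(dm, 2)
    assert labels["a"] == labels["b"] != labels["c"] == labels["d"]
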