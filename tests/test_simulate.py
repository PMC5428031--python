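import numpy as np
import pytest

from cazytraits.filtering import filter_hits
from cazytraits.hmmio import read_domtblout
from cazytraits.registry import TRAITS
from cazytraits.report import annotate_study
from cazytraits.simulate import (
    ArchitectureGrammar,
    ConfigError,
    SyntheticConfig,
    generate_study,
    recovery_report,
    sample_architecture,
)

SMALL = dict(n_genomes=10, seed=7)


def read_all_hits(study):
    hits = []
    for gid, path in study.domtblout_paths.items():
        hits.extend(read_domtblout(path, genome_id=gid))
    return hits


def test_same_seed_byte_identical(tmp_path):
    cfg = SyntheticConfig(**SMALL)
    s1 = generate_study(cfg, tmp_path / "a")
    s2 = generate_study(cfg, tmp_path / "b")
    for gid in s1.domtblout_paths:
        assert s1.domtblout_paths[gid].read_bytes() == s2.domtblout_paths[gid].read_bytes()
    assert s1.metadata_path.read_bytes() == s2.metadata_path.read_bytes()
    assert s1.taxonomy_path.read_bytes() == s2.taxonomy_path.read_bytes()
    assert s1.truth_path.read_bytes() == s2.truth_path.read_bytes()


def test_different_seed_differs(tmp_path):
    s1 = generate_study(SyntheticConfig(n_genomes=5, seed=1), tmp_path / "a")
    s2 = generate_study(SyntheticConfig(n_genomes=5, seed=2), tmp_path / "b")
    assert s1.truth_path.read_bytes() != s2.truth_path.read_bytes()


def test_zero_decoy_rate_everything_passes(tmp_path):
    study = generate_study(SyntheticConfig(n_genomes=5, decoy_rate=0.0, seed=3), tmp_path)
    hits = read_all_hits(study)
    assert len(filter_hits(hits)) == len(hits)
    assert study.truth["decoys"] == []


def test_decoys_fail_exactly_one_predicate(tmp_path):
    study = generate_study(SyntheticConfig(n_genomes=8, decoy_rate=0.3, seed=5), tmp_path)
    hits = read_all_hits(study)
    decoy_keys = {
        (d["genome_id"], d["protein_id"], d["family"], d["env_from"]): d["reason"]
        for d in study.truth["decoys"]
    }
    assert decoy_keys, "expected decoys at rate 0.3"
    n_decoys_seen = 0
    for h in hits:
        reason = decoy_keys.get((h.genome_id, h.protein_id, h.family_name, h.env_from))
        cov = (h.hmm_to - h.hmm_from + 1) / h.profile_length
        if reason == "evalue":
            n_decoys_seen += 1
            assert h.i_evalue > 1e-5 and cov > 0.5
        elif reason == "coverage":
            n_decoys_seen += 1
            assert h.i_evalue <= 1e-5 and cov <= 0.5
        else:
            assert h.i_evalue <= 1e-5 and cov > 0.5  # planted hits pass both
    assert n_decoys_seen == len(study.truth["decoys"])
    # emitted fraction matches the configured rate
    assert n_decoys_seen / len(hits) == pytest.approx(0.3, abs=0.02)


def test_planted_singletons_are_all_single_domain(tmp_path):
    grammar = ArchitectureGrammar(
        p_cbm_nterm=0.0, p_cbm_cterm=0.0, p_multiactivity=0.0
    )
    cfg = SyntheticConfig(n_genomes=5, grammar=grammar, decoy_rate=0.0, seed=9)
    study = generate_study(cfg, tmp_path)
    res = annotate_study(study_dir=tmp_path)
    assert all(a.n_total == 1 for a in res.architectures)
    fam_df, _ = res.family_summary()
    assert (fam_df["pct_single_domain"] == 100.0).all()


def test_end_to_end_recovery_exact(tmp_path):
    cfg = SyntheticConfig(n_genomes=12, decoy_rate=0.3, seed=21)
    study = generate_study(cfg, tmp_path)
    res = annotate_study(study_dir=tmp_path)
    rep = recovery_report(study.truth, res.profiles, res.architectures)
    assert rep["max_abs_trait_count_error"] == 0
    assert rep["max_abs_trait_freq_error"] == 0.0
    assert rep["n_architecture_mismatches"] == 0
    assert rep["n_proteins_missing"] == 0
    assert -1.0 <= rep["clade_ari"] <= 1.0


def test_truth_consistent_with_emitted_files(tmp_path):
    study = generate_study(SyntheticConfig(**SMALL), tmp_path)
    from cazytraits.hmmio import read_genome_metadata, read_taxonomy

    meta = read_genome_metadata(study.metadata_path)
    assert {g: t["gene_count"] for g, t in study.truth["genomes"].items()} == meta
    tax = {r.genome_id: r.ranks for r in read_taxonomy(study.taxonomy_path)}
    for g, t in study.truth["genomes"].items():
        assert tax[g] == t["taxonomy"]
        # planted counts = freqs x gene_count / 1000 exactly
        for trait in TRAITS:
            assert t["trait_freqs"][trait] * t["gene_count"] / 1000 == pytest.approx(
                t["trait_counts"][trait]
            )


def test_sample_architecture_respects_budget_and_motifs(registry):
    rng = np.random.default_rng(0)
    weights = {"cellulase": {"GH5": 1.0}, "xylanase": {"GH10": 1.0},
               "chitinase": {"GH18": 1.0}, "LPMO": {"AA9": 1.0}}
    # forced hetero pair with leading CBM1 -> CBM1-GH5-GH6 producible
    grammar = ArchitectureGrammar(
        p_cbm_nterm=1.0, p_cbm_cterm=0.0, p_multiactivity=1.0,
        p_hetero_given_multi=1.0, hetero_partners={"GH5": ("GH6", "append")},
        cbm_weights={"CBM1": 1.0},
    )
    names, used = sample_architecture("cellulase", grammar, weights, rng, registry)
    assert names == ["CBM1", "GH5", "GH6"] and used == 2
    # degenerate repeat at 8 for GH25 prepended to GH18 -> 8(GH25)-GH18
    grammar = ArchitectureGrammar(
        p_cbm_nterm=0.0, p_cbm_cterm=0.0, p_multiactivity=1.0,
        p_hetero_given_multi=1.0,
        hetero_partners={"GH18": ("GH25", "prepend")},
        partner_repeat_lengths=((8, 1.0),),
    )
    names, used = sample_architecture("chitinase", grammar, weights, rng, registry)
    assert names == ["GH25"] * 8 + ["GH18"] and used == 1  # GH25 consumes no budget
    # budget of 1 forces a single catalytic domain
    grammar = ArchitectureGrammar(p_multiactivity=1.0, p_hetero_given_multi=0.0,
                                  p_cbm_nterm=0.0, p_cbm_cterm=0.0)
    names, used = sample_architecture(
        "xylanase", grammar, weights, rng, registry, max_trait_domains=1
    )
    assert used == 1 and names == ["GH10"]


def test_multiactivity_zero_means_one_catalytic_domain(registry):
    rng = np.random.default_rng(1)
    grammar = ArchitectureGrammar(p_multiactivity=0.0)
    from cazytraits.simulate import FAMILY_WEIGHTS

    for trait in TRAITS:
        for _ in range(20):
            names, used = sample_architecture(
                trait, grammar, FAMILY_WEIGHTS, rng, registry
            )
            catalytic = [n for n in names if registry.get(n)
                         and registry.get(n).is_catalytic]
            assert len(catalytic) == 1 and used == 1


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_genomes=0),
        dict(decoy_rate=1.0),
        dict(within_clade_cv=0.7, between_clade_cv=0.6),
        dict(trait_means={"cellulase": 0.0}),
        dict(conserved_rank="strain"),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ConfigError):
        SyntheticConfig(**kwargs)


def test_invalid_grammar_rejected():
    with pytest.raises(ConfigError):
        ArchitectureGrammar(repeat_lengths=((0, 1.0),))
    with pytest.raises(ConfigError):
        ArchitectureGrammar(p_multiactivity=1.5)


def test_mean_frequencies_approach_planted_means(tmp_path):
    """Across many genomes, per-trait mean recovered frequency approaches the
    configured study means (clade and genome noise are mean-1)."""
    cfg = SyntheticConfig(n_genomes=120, seed=13, between_clade_cv=0.3,
                          within_clade_cv=0.05)
    study = generate_study(cfg, tmp_path)
    freqs = {t: [] for t in TRAITS}
    for g in study.truth["genomes"].values():
        for t in TRAITS:
            freqs[t].append(g["trait_freqs"][t])
    for t in TRAITS:
        assert np.mean(freqs[t]) == pytest.approx(cfg.trait_means[t], rel=0.25)
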