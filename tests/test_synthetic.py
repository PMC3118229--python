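"""Synthetic corpus generator: chemistry, distributions, ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from scafrank.corpus import corpus_to_frame
from scafrank.landscape import pair_overlap, scaffold_profile
from scafrank.molgraph import canonical_key, normalize, parse_structure
from scafrank.scaffolds import (
    molecular_framework_1,
    molecular_framework_2,
    scaffold_record,
)
from scafrank.synthetic import (
    SUBSTITUENT_LIBRARY,
    TEMPLATE_LIBRARY,
    GeneratorConfig,
    GeneratorConfigError,
    generate_corpus,
    noise_free,
    validate_distribution,
)
from scafrank.triage import run_triage


SMALL = GeneratorConfig(
    seed=3,
    n_targets=10,
    compounds_per_target_max=150,
    cross_screen_pairs=(((0, 1), 0.4), ((2, 3), 0.25)),
)


@pytest.fixture(scope="module")
def small_noise_free():
    corpus, truth = generate_corpus(noise_free(SMALL))
    return corpus, truth


def scaffold_map(triaged):
    out = {}
    for r in triaged.records:
        if r.compound_key not in out:
            out[r.compound_key] = scaffold_record(normalize(parse_structure(r.smiles)))
    return out


# ---------------------------------------------------------------------------
# built-in chemistry
# ---------------------------------------------------------------------------


def test_template_library_is_mf2_pure_and_distinct():
    """Each template must be its own Murcko framework, and the library
    must hold pairwise distinct MF2 graphs — otherwise per-target
    unique-MF2 ground truth would be ill-defined."""
    keys = set()
    for smiles in TEMPLATE_LIBRARY:
        g = normalize(parse_structure(smiles))
        mf2 = molecular_framework_2(molecular_framework_1(g))
        assert mf2.n_atoms == g.n_atoms, smiles
        keys.add(canonical_key(mf2.to_abstract()))
    assert len(keys) == len(TEMPLATE_LIBRARY) >= 30


def test_substituents_are_ring_free():
    from scafrank.molgraph import ring_atoms

    for smiles in SUBSTITUENT_LIBRARY:
        assert ring_atoms(parse_structure(smiles)) == set()


# ---------------------------------------------------------------------------
# config validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kw",
    [
        {"compounds_per_target_exponent": 1.0},
        {"journal_fraction": 1.5},
        {"templates_per_target": (0, 3)},
        {"templates_per_target": (1, 10**6)},
        {"cross_screen_pairs": (((0, 0), 0.5),)},
        {"cross_screen_pairs": (((0, 99999), 0.5),)},
        {"cross_screen_pairs": (((0, 1), 1.5),)},
        {"result_type_mix": (0.5, 0.5, 0.5)},
        {"template_assignment": "sorted"},
        {"template_assignment": "partition", "n_targets": 1000, "templates_per_target": (6, 6)},
    ],
)
def test_infeasible_configs_rejected_before_output(kw):
    with pytest.raises(GeneratorConfigError):
        generate_corpus(GeneratorConfig(**kw))


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def test_same_seed_gives_identical_corpus(tmp_path):
    from scafrank.corpus import write_corpus

    c1, _ = generate_corpus(SMALL)
    c2, _ = generate_corpus(SMALL)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_corpus(c1, p1)
    write_corpus(c2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seed_changes_corpus():
    from dataclasses import replace

    c1, _ = generate_corpus(SMALL)
    c2, _ = generate_corpus(replace(SMALL, seed=SMALL.seed + 1))
    assert not corpus_to_frame(c1).equals(corpus_to_frame(c2))


# ---------------------------------------------------------------------------
# ground-truth recovery
# ---------------------------------------------------------------------------


def test_noise_free_triage_passes_everything(small_noise_free):
    corpus, _truth = small_noise_free
    _triaged, _profiles, report, rejects = run_triage(corpus)
    assert len(rejects) == 0
    assert report.type_b_records == report.input_records
    assert report.human_records == report.input_records
    assert report.post_cap_records == report.input_records  # all quantitative


def test_noise_free_mf2_counts_match_truth(small_noise_free):
    corpus, truth = small_noise_free
    triaged, profiles, _report, _rejects = run_triage(corpus)
    records = scaffold_map(triaged)
    by_gene = {t.gene_id: t for t in truth.targets}
    for prof in profiles.genes:
        out = scaffold_profile(prof, records)
        tt = by_gene[prof.gene_id]
        assert prof.n_compounds == len(tt.post_triage_compounds)
        assert out.scaffold_counts["MF2"] == tt.expected_unique_mf2


def test_cross_screen_overlap_matches_truth(small_noise_free):
    corpus, truth = small_noise_free
    _triaged, profiles, _report, _rejects = run_triage(corpus)
    by_gene = {p.gene_id: p for p in profiles.genes}
    assert truth.pairs
    for pt in truth.pairs:
        a = by_gene[1000 + pt.pair[0]]
        b = by_gene[1000 + pt.pair[1]]
        compounds, documents = pair_overlap(a, b)
        assert compounds == len(pt.shared_compounds)
        assert documents == len(pt.shared_doc_ids)
        assert len(pt.shared_compounds) > 0


def test_noisy_post_triage_truth_matches_pipeline():
    """With contamination on, the generator's replayed-cascade bookkeeping
    still predicts the pipeline's per-target compound sets exactly."""
    corpus, truth = generate_corpus(SMALL)
    _triaged, profiles, _report, _rejects = run_triage(corpus)
    by_gene = {p.gene_id: p for p in profiles.genes}
    for tt in truth.targets:
        expected = len(tt.post_triage_compounds)
        got = by_gene[tt.gene_id].n_compounds if tt.gene_id in by_gene else 0
        assert got == expected


# ---------------------------------------------------------------------------
# distribution diagnostics
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def default_scale_corpus():
    cfg = GeneratorConfig(seed=17, n_targets=80, compounds_per_target_max=600)
    return cfg, generate_corpus(cfg)


def test_doc_size_means_within_three_se(default_scale_corpus):
    cfg, (corpus, _truth) = default_scale_corpus
    diag = validate_distribution(corpus, cfg).set_index("quantity")
    for dtype in ("journal", "patent"):
        row = diag.loc[f"compounds_per_{dtype}_doc_mean"]
        assert abs(row["value"] - row["configured"]) <= 3 * row["se"]


def test_noise_rates_estimated(default_scale_corpus):
    cfg, (corpus, _truth) = default_scale_corpus
    diag = validate_distribution(corpus, cfg).set_index("quantity")
    for q in ("non_type_b_rate", "non_human_rate", "unmapped_rate"):
        row = diag.loc[q]
        assert abs(row["value"] - row["configured"]) <= max(3 * row["se"], 0.02)


def test_zero_noise_rates_exactly_zero(small_noise_free):
    corpus, _truth = small_noise_free
    diag = validate_distribution(corpus, noise_free(SMALL)).set_index("quantity")
    for q in ("non_type_b_rate", "non_human_rate", "unmapped_rate"):
        assert diag.loc[q]["value"] == 0.0


def test_tail_exponent_reported(default_scale_corpus):
    cfg, (corpus, _truth) = default_scale_corpus
    diag = validate_distribution(corpus, cfg).set_index("quantity")
    alpha = diag.loc["compounds_per_target_tail_exponent"]
    # Hill estimate on a bounded discrete power law is biased upward a
    # little; just require the right ballpark and a finite SE
    assert 1.1 < alpha["value"] < 2.6
    assert np.isfinite(alpha["se"])
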