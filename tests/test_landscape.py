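"""Landscape metrics: ranking, summaries, bins, coverage, overlaps, ratios."""

from __future__ import annotations

import random

import pytest

from scafrank.landscape import (
    MissingScaffoldError,
    TargetProfile,
    binned_distribution,
    coverage_cutoff,
    pair_overlap,
    rank_targets,
    scaffold_profile,
    summary_stats,
)
from scafrank.scaffolds import scaffold_record

from conftest import mol


def profile(symbol, compounds, docs=(), gene=None):
    p = TargetProfile(
        gene_id=gene if gene is not None else abs(hash(symbol)) % 99999,
        symbol=symbol,
        splice_name=None,
    )
    p.compound_keys = set(compounds)
    p.doc_ids = set(docs)
    return p


def cset(symbol, n):
    return {f"{symbol}{i}" for i in range(n)}


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def test_rank_ties_break_by_documents():
    a = profile("A", cset("a", 5), {"d1"})
    b = profile("B", cset("b", 3), {"d1", "d2", "d3"})
    c = profile("C", cset("c", 3), {"d1"})
    table = rank_targets([c, b, a], metric="compounds")
    assert [e.profile.symbol for e in table.entries] == ["A", "B", "C"]
    assert [e.ranks["compounds"] for e in table.entries] == [1, 2, 3]


def test_rank_single_profile():
    table = rank_targets([profile("X", cset("x", 2))])
    assert table.entries[0].ranks["compounds"] == 1


def test_rank_unknown_metric():
    with pytest.raises(ValueError, match="metric"):
        rank_targets([profile("X", cset("x", 1))], metric="potency")


def test_rank_by_mf2_reorders_against_brute_force_sort():
    rng = random.Random(5)
    profiles = []
    for i in range(5):
        p = profile(f"T{i}", cset(f"t{i}", rng.randint(5, 40)), {f"d{i}"})
        p.scaffold_counts = {"MF2": rng.randint(1, 20)}
        profiles.append(p)
    table = rank_targets(profiles, metric="MF2")
    expected = sorted(
        profiles,
        key=lambda p: (
            -p.scaffold_counts["MF2"],
            -p.n_compounds,
            -p.n_documents,
            p.symbol,
        ),
    )
    assert [e.profile.symbol for e in table.entries] == [p.symbol for p in expected]


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------


def test_summary_odd_and_even_medians():
    s = summary_stats([profile("A", cset("a", 5)), profile("B", cset("b", 3)), profile("C", cset("c", 2))])
    assert s.summed_compounds == 10
    assert s.average_compounds == 3  # 3.33 to nearest integer
    assert s.median_compounds == 3
    s2 = summary_stats([profile("A", cset("a", 4)), profile("B", cset("b", 2))])
    assert s2.median_compounds == 3  # even-count midpoint


def test_summary_unique_vs_summed_under_cross_screening():
    shared = {"k1", "k2"}
    a = profile("A", shared | {"k3"})
    b = profile("B", shared)
    s = summary_stats([a, b])
    assert s.summed_compounds == 5
    assert s.unique_compounds == 3


def test_summary_empty():
    s = summary_stats([])
    assert s.summed_compounds == 0 and s.n_entries == 0


def test_summary_document_split():
    a = profile("A", cset("a", 1), docs={"j1", "p1"})
    b = profile("B", cset("b", 1), docs={"j1", "p2"})
    s = summary_stats([a, b], doc_types={"j1": "journal", "p1": "patent", "p2": "patent"})
    assert s.summed_documents == 4
    assert s.unique_documents == 3
    assert s.unique_journal_documents == 1
    assert s.unique_patent_documents == 2


# ---------------------------------------------------------------------------
# bins and coverage
# ---------------------------------------------------------------------------


def test_binned_distribution_hand_count():
    ps = [profile("A", cset("a", 5)), profile("B", cset("b", 3)), profile("C", cset("c", 2))]
    assert binned_distribution(ps, [5, 2, 1]) == [(5, 1), (2, 3), (1, 3)]


def test_binned_distribution_edge_below_minimum():
    ps = [profile("A", cset("a", 5)), profile("B", cset("b", 3))]
    assert binned_distribution(ps, [1]) == [(1, 2)]


def test_binned_distribution_rejects_bad_edges():
    with pytest.raises(ValueError):
        binned_distribution([], [5, 5, 1])
    with pytest.raises(ValueError):
        binned_distribution([], [1, 5])


def test_coverage_cutoff_examples():
    ps = [profile("A", cset("a", 5)), profile("B", cset("b", 3)), profile("C", cset("c", 2))]
    assert coverage_cutoff(ps, 0.5) == (1, 5)
    assert coverage_cutoff(ps, 1.0) == (3, 2)
    with pytest.raises(ValueError):
        coverage_cutoff(ps, 0.0)


def test_coverage_cutoff_matches_prefix_sum_oracle():
    rng = random.Random(11)
    counts = [int(rng.paretovariate(1.2)) for _ in range(100)]
    ps = [profile(f"T{i}", cset(f"t{i}", c)) for i, c in enumerate(counts)]
    for fraction in (0.25, 0.5, 0.9, 0.99):
        n, cutoff = coverage_cutoff(ps, fraction)
        ordered = sorted(counts, reverse=True)
        total = sum(ordered)
        acc, oracle_n = 0, None
        for k, c in enumerate(ordered, start=1):
            acc += c
            if acc >= fraction * total:
                oracle_n = k
                break
        assert n == oracle_n
        assert cutoff == ordered[n - 1]
    # monotone in fraction
    ns = [coverage_cutoff(ps, f)[0] for f in (0.1, 0.5, 0.9, 1.0)]
    assert ns == sorted(ns)


# ---------------------------------------------------------------------------
# overlaps
# ---------------------------------------------------------------------------


def test_pair_overlap_disjoint_and_identical():
    a = profile("A", cset("a", 4), docs={"d1", "d2"})
    b = profile("B", cset("b", 3), docs={"d3"})
    assert pair_overlap(a, b) == (0, 0)
    assert pair_overlap(a, a) == (4, 2)


def test_pair_overlap_is_set_intersection():
    a = profile("A", {"x", "y", "z"}, docs={"d1", "d2"})
    b = profile("B", {"y", "z", "w"}, docs={"d2", "d3"})
    assert pair_overlap(a, b) == (2, 1)


# ---------------------------------------------------------------------------
# scaffold aggregation
# ---------------------------------------------------------------------------


def test_scaffold_profile_ratio_one_template():
    # ten decorated benzenes: one MF2, ratio 0.1
    variants = [
        "Cc1ccccc1", "CCc1ccccc1", "CCCc1ccccc1", "CC(C)c1ccccc1",
        "Oc1ccccc1", "COc1ccccc1", "Nc1ccccc1", "CNc1ccccc1",
        "Fc1ccccc1", "Clc1ccccc1",
    ]
    records = {}
    keys = []
    for s in variants:
        rec = scaffold_record(mol(s))
        records[rec.compound_key] = rec
        keys.append(rec.compound_key)
    p = profile("A", set(keys))
    out = scaffold_profile(p, records)
    assert out.scaffold_counts["MF2"] == 1
    assert out.mf2_ratio == pytest.approx(0.1)


def test_scaffold_profile_erasure_cascade():
    records = {}
    keys = []
    for s in ("c1ccccc1", "c1ccncc1", "C1CCCCC1"):
        rec = scaffold_record(mol(s))
        records[rec.compound_key] = rec
        keys.append(rec.compound_key)
    out = scaffold_profile(profile("A", set(keys)), records)
    assert out.scaffold_counts == {"MF1": 3, "MF2": 3, "CS": 2, "ATS": 2, "GS": 1}
    assert out.mf2_ratio == pytest.approx(1.0)
    assert out.gs_ratio == pytest.approx(1 / 3)


def test_scaffold_profile_excludes_acyclic_from_counts():
    records = {}
    keys = []
    for s in ("c1ccccc1", "CCO"):
        rec = scaffold_record(mol(s))
        records[rec.compound_key] = rec
        keys.append(rec.compound_key)
    out = scaffold_profile(profile("A", set(keys)), records)
    assert out.n_compounds == 2
    assert out.scaffold_counts["MF2"] == 1
    assert out.mf2_ratio == pytest.approx(0.5)


def test_scaffold_profile_missing_record_is_hard_error():
    with pytest.raises(MissingScaffoldError, match="ghost"):
        scaffold_profile(profile("A", {"ghost"}), {})
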