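"""Per-target landscape metrics: ranks, summaries, bins, coverage, overlaps.

The landscape view aggregates a triaged corpus into one
:class:`TargetProfile` per protein entry — its unique compound set, its
document set and its unique-scaffold counts at each of the five hierarchy
levels — and derives the tractability metrics: compound-count rank,
document-count rank, scaffold ranks, the MF2:compound ratio and the
GS:compound ratio.  A small ratio means many compounds collapsing onto
few frameworks (low chemical diversity for the effort); a large one means
broad chemotype coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .scaffolds import LEVELS, ScaffoldRecord

RANK_METRICS = ("compounds", "documents", "MF1", "MF2", "CS", "ATS", "GS")


@dataclass
class TargetProfile:
    """Aggregate view of one protein entry (or one gene-level rollup)."""

    gene_id: int | None
    symbol: str | None
    splice_name: str | None
    target_name: str = ""
    compound_keys: set[str] = field(default_factory=set)
    doc_ids: set[str] = field(default_factory=set)
    scaffold_counts: dict[str, int] = field(default_factory=dict)
    mf2_ratio: float | None = None
    gs_ratio: float | None = None

    @property
    def n_compounds(self) -> int:
        return len(self.compound_keys)

    @property
    def n_documents(self) -> int:
        return len(self.doc_ids)

    def metric(self, name: str) -> int:
        if name == "compounds":
            return self.n_compounds
        if name == "documents":
            return self.n_documents
        if name in LEVELS:
            return self.scaffold_counts.get(name, 0)
        raise ValueError(f"unknown metric {name!r}")


@dataclass
class RankedEntry:
    profile: TargetProfile
    ranks: dict[str, int] = field(default_factory=dict)


@dataclass
class Summary:
    n_entries: int = 0
    summed_compounds: int = 0
    unique_compounds: int = 0
    average_compounds: int = 0  # nearest integer
    median_compounds: float = 0.0
    summed_documents: int = 0
    unique_documents: int = 0
    unique_journal_documents: int = 0
    unique_patent_documents: int = 0


@dataclass
class LandscapeTable:
    """Ordered per-target report plus per-metric ranks and a summary."""

    entries: list[RankedEntry]
    order_metric: str
    summary: Summary | None = None


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def _sort_key(profile: TargetProfile, metric: str) -> tuple:
    """Descending metric; ties by compounds (when not the metric), then
    documents, then symbol lexicographically."""
    key = [-profile.metric(metric)]
    if metric != "compounds":
        key.append(-profile.n_compounds)
    key.append(-profile.n_documents)
    key.append(profile.symbol or "")
    return tuple(key)


def rank_targets(
    profiles: Sequence[TargetProfile],
    metric: str = "compounds",
    doc_types: Mapping[str, str] | None = None,
) -> LandscapeTable:
    """Order profiles by the chosen metric and attach ranks for all metrics.

    The output order follows ``metric``; every entry additionally carries
    its rank (1-based position under the same tie-break) for each of
    :data:`RANK_METRICS`.  Deterministic: the tie-break chain
    (metric → compounds → documents → symbol) totally orders any realistic
    profile set.
    """
    if metric not in RANK_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {RANK_METRICS}")
    if not profiles:
        return LandscapeTable(entries=[], order_metric=metric, summary=Summary())
    rank_of: dict[str, dict[int, int]] = {}
    for m in RANK_METRICS:
        ordered = sorted(range(len(profiles)), key=lambda i: _sort_key(profiles[i], m))
        rank_of[m] = {i: pos + 1 for pos, i in enumerate(ordered)}
    order = sorted(range(len(profiles)), key=lambda i: _sort_key(profiles[i], metric))
    entries = [
        RankedEntry(
            profile=profiles[i],
            ranks={m: rank_of[m][i] for m in RANK_METRICS},
        )
        for i in order
    ]
    summary = summary_stats(profiles, doc_types=doc_types)
    return LandscapeTable(entries=entries, order_metric=metric, summary=summary)


def summary_stats(
    profiles: Sequence[TargetProfile],
    doc_types: Mapping[str, str] | None = None,
) -> Summary:
    """Corpus-level summary over protein entries.

    Summed compounds counts each target's unique compound set with
    multiplicity across targets (a cross-screened compound contributes to
    every target it was assayed against); the unique count is the union.
    The average is reported rounded to the nearest integer, the median
    with even-count midpoint averaging.  ``doc_types`` (doc_id → type)
    enables the journal/patent unique-document split.
    """
    if not profiles:
        return Summary()
    counts = sorted(p.n_compounds for p in profiles)
    summed = sum(counts)
    union: set[str] = set()
    doc_union: set[str] = set()
    summed_docs = 0
    for p in profiles:
        union |= p.compound_keys
        doc_union |= p.doc_ids
        summed_docs += p.n_documents
    n = len(profiles)
    mid = n // 2
    median = float(counts[mid]) if n % 2 else (counts[mid - 1] + counts[mid]) / 2.0
    journal = patent = 0
    if doc_types is not None:
        journal = sum(1 for d in doc_union if doc_types.get(d) == "journal")
        patent = sum(1 for d in doc_union if doc_types.get(d) == "patent")
    return Summary(
        n_entries=n,
        summed_compounds=summed,
        unique_compounds=len(union),
        average_compounds=round(summed / n),
        median_compounds=median,
        summed_documents=summed_docs,
        unique_documents=len(doc_union),
        unique_journal_documents=journal,
        unique_patent_documents=patent,
    )


# ---------------------------------------------------------------------------
# distribution views
# ---------------------------------------------------------------------------

#: compounds-per-target bin edges used for the standard binned report
DEFAULT_BIN_EDGES = (10000, 5000, 2000, 1051, 1000, 500, 200, 100, 50, 10, 2, 1)


def binned_distribution(
    profiles: Sequence[TargetProfile],
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> list[tuple[int, int]]:
    """Cumulative binned distribution of compounds-per-target.

    For each edge ``b`` (strictly descending, positive) reports the number
    of profiles with compound count ≥ b, so counts are non-decreasing as
    the edge decreases.
    """
    edges = list(bin_edges)
    if not edges or any(e <= 0 for e in edges) or any(
        a <= b for a, b in zip(edges, edges[1:])
    ):
        raise ValueError("bin edges must be strictly descending positive integers")
    counts = [p.n_compounds for p in profiles]
    return [(b, sum(1 for c in counts if c >= b)) for b in edges]


def coverage_cutoff(
    profiles: Sequence[TargetProfile], fraction: float
) -> tuple[int, int]:
    """Smallest top-N (by compound count) covering ``fraction`` of the
    summed per-target compound counts; returns ``(N, count of the Nth)``.

    Coverage uses summed with-multiplicity counts, matching how the top
    slice of a heavy-tailed compounds-per-target distribution is usually
    quoted (e.g. "the top-N proteins cover 90% of the compounds").
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    counts = sorted((p.n_compounds for p in profiles), reverse=True)
    total = sum(counts)
    if total == 0:
        return (0, 0)
    need = fraction * total
    acc = 0
    for n, c in enumerate(counts, start=1):
        acc += c
        if acc >= need - 1e-9:
            return (n, c)
    return (len(counts), counts[-1] if counts else 0)


def pair_overlap(p1: TargetProfile, p2: TargetProfile) -> tuple[int, int]:
    """Cross-screening overlap of two targets: the number of
    compounds-in-common and documents-in-common (set intersections)."""
    return (
        len(p1.compound_keys & p2.compound_keys),
        len(p1.doc_ids & p2.doc_ids),
    )


# ---------------------------------------------------------------------------
# scaffold aggregation
# ---------------------------------------------------------------------------


class MissingScaffoldError(KeyError):
    """A profile references a compound with no scaffold record."""


def scaffold_profile(
    profile: TargetProfile, records: Mapping[str, ScaffoldRecord]
) -> TargetProfile:
    """Fill a profile's scaffold counts and diversity ratios.

    ``records`` maps compound key → :class:`ScaffoldRecord`.  Acyclic
    compounds are excluded from the unique-scaffold counts at every level
    but still count as compounds, so ratios use the full compound count in
    the denominator.
    """
    unique: dict[str, set[str]] = {lvl: set() for lvl in LEVELS}
    for ck in profile.compound_keys:
        rec = records.get(ck)
        if rec is None:
            raise MissingScaffoldError(f"no scaffold record for compound {ck!r}")
        if rec.acyclic:
            continue
        for lvl in LEVELS:
            unique[lvl].add(rec.key_at(lvl).key)
    counts = {lvl: len(unique[lvl]) for lvl in LEVELS}
    n = profile.n_compounds
    out = replace(profile)
    out.compound_keys = set(profile.compound_keys)
    out.doc_ids = set(profile.doc_ids)
    out.scaffold_counts = counts
    out.mf2_ratio = counts["MF2"] / n if n else None
    out.gs_ratio = counts["GS"] / n if n else None
    return out
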