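"""Stringency triage: from raw corpus to compound-to-target links.

The cascade mirrors how a curated SAR corpus is reduced to a defensible
target listing:

1. keep type-B (in vitro binding) assay results only;
2. keep records whose target maps to a gene identifier;
3. keep human records;
4. apply the per-document extraction caps — every quantitative result is
   kept, ranged results are truncated to the first 200 distinct compounds
   per document, qualitative results to the first 100;
5. assign each structure its unique compound key (normalized canonical
   form), sending unparsable structures to a rejects table;
6. aggregate into per-protein-entry profiles plus gene-level rollups.

The three membership filters commute (set-intersection semantics) and are
idempotent; the cap stage is idempotent but must run on the document's
record order, so the cascade order above is the reported one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import pandas as pd

from .corpus import Corpus, CORPUS_COLUMNS
from .landscape import TargetProfile
from .molgraph import StructureParseError, compound_key, normalize, parse_structure

#: per-document extraction caps by result type (distinct compounds)
CAP_RANGED = 200
CAP_QUALITATIVE = 100


@dataclass
class TriageReport:
    """Record counts at each stage of the cascade plus final summaries."""

    input_records: int = 0
    type_b_records: int = 0
    gene_mapped_records: int = 0
    human_records: int = 0
    post_cap_records: int = 0
    rejected_structures: int = 0
    unique_compounds: int = 0
    protein_entries: int = 0
    gene_ids: int = 0

    def stage_counts(self) -> list[tuple[str, int]]:
        return [
            ("input records", self.input_records),
            ("type-B records", self.type_b_records),
            ("gene-mapped records", self.gene_mapped_records),
            ("human records", self.human_records),
            ("post-cap records", self.post_cap_records),
            ("rejected structures", self.rejected_structures),
            ("unique compounds", self.unique_compounds),
            ("protein entries", self.protein_entries),
            ("gene identifiers", self.gene_ids),
        ]


def filter_type_b(c: Corpus) -> Corpus:
    """Retain exactly the type-B (binding assay) records, order preserved."""
    return c.with_records(r for r in c.records if r.assay_type == "B")


def filter_gene_mapped(c: Corpus) -> Corpus:
    """Retain records whose target carries an Entrez gene identifier."""
    return c.with_records(r for r in c.records if r.target.gene_id is not None)


def filter_human(c: Corpus) -> Corpus:
    """Retain records for human targets (case-insensitive species match)."""
    return c.with_records(r for r in c.records if r.target.is_human)


def apply_extraction_caps(c: Corpus) -> Corpus:
    """Apply the per-document extraction caps.

    Within each document (across all its targets jointly, in input order):
    quantitative records always survive; ranged records survive while the
    document's ranged set spans at most ``CAP_RANGED`` distinct compounds;
    qualitative likewise with ``CAP_QUALITATIVE``.  A compound already
    inside the cap keeps all its records, so exactly-at-cap documents pass
    untruncated.  Idempotent.
    """
    caps = {"ranged": CAP_RANGED, "qualitative": CAP_QUALITATIVE}
    seen: dict[tuple[str, str], dict[str, int]] = {}
    kept = []
    for r in c.records:
        cap = caps.get(r.result_type)
        if cap is None:
            kept.append(r)
            continue
        bucket = seen.setdefault((r.doc_id, r.result_type), {})
        ident = r.compound_key or r.smiles
        if ident in bucket:
            kept.append(r)
        elif len(bucket) < cap:
            bucket[ident] = 1
            kept.append(r)
        # else: beyond the cap — dropped
    return c.with_records(kept)


def assign_compound_keys(c: Corpus) -> tuple[Corpus, pd.DataFrame]:
    """Fill ``compound_key`` with the canonical key of each normalized
    structure; identical structures written differently get identical keys.

    Returns ``(corpus, rejects)``; rows whose SMILES cannot be parsed are
    collected with a reason instead of aborting the run.
    """
    cache: dict[str, str | None] = {}
    kept = []
    reject_rows = []
    for idx, r in enumerate(c.records):
        key = cache.get(r.smiles, "?")
        if key == "?":
            try:
                key = compound_key(normalize(parse_structure(r.smiles)))
            except StructureParseError:
                key = None
            cache[r.smiles] = key
        if key is None:
            reject_rows.append(
                {"row": idx, "reason": f"unparsable structure {r.smiles!r}", "smiles": r.smiles}
            )
            continue
        kept.append(replace(r, compound_key=key))
    rejects = pd.DataFrame(reject_rows, columns=["row", "reason", "smiles"])
    return c.with_records(kept), rejects


@dataclass
class ProfileSet:
    """Protein-entry profiles plus their gene-level rollups."""

    entries: list[TargetProfile] = field(default_factory=list)
    genes: list[TargetProfile] = field(default_factory=list)


def build_profiles(c: Corpus) -> ProfileSet:
    """Aggregate a triaged, keyed corpus into target profiles.

    One profile per distinct (gene_id, splice_name) protein entry, each
    holding its unique compound-key set and document-id set, plus one
    gene-level rollup per gene_id (the union over that gene's entries).
    Records without a gene id or compound key are ignored (the cascade
    removes them before this point).
    """
    entries: dict[tuple, TargetProfile] = {}
    genes: dict[int, TargetProfile] = {}
    for r in c.records:
        if r.target.gene_id is None or r.compound_key is None:
            continue
        ek = r.target.entry_key
        prof = entries.get(ek)
        if prof is None:
            prof = TargetProfile(
                gene_id=r.target.gene_id,
                symbol=r.target.symbol,
                splice_name=r.target.splice_name,
                target_name=r.target.target_name,
            )
            entries[ek] = prof
        prof.compound_keys.add(r.compound_key)
        prof.doc_ids.add(r.doc_id)
        g = genes.get(r.target.gene_id)
        if g is None:
            g = TargetProfile(
                gene_id=r.target.gene_id,
                symbol=r.target.symbol,
                splice_name=None,
                target_name=r.target.target_name,
            )
            genes[r.target.gene_id] = g
        g.compound_keys.add(r.compound_key)
        g.doc_ids.add(r.doc_id)
    return ProfileSet(
        entries=[entries[k] for k in sorted(entries, key=lambda k: (k[0], k[1] or ""))],
        genes=[genes[g] for g in sorted(genes)],
    )


def run_triage(c: Corpus) -> tuple[Corpus, ProfileSet, TriageReport, pd.DataFrame]:
    """Run the full cascade and return the triaged corpus, the profiles,
    the stage-count report and the structure rejects."""
    report = TriageReport(input_records=c.n_records)
    c = filter_type_b(c)
    report.type_b_records = c.n_records
    c = filter_gene_mapped(c)
    report.gene_mapped_records = c.n_records
    c = filter_human(c)
    report.human_records = c.n_records
    c = apply_extraction_caps(c)
    report.post_cap_records = c.n_records
    c, rejects = assign_compound_keys(c)
    report.rejected_structures = len(rejects)
    profiles = build_profiles(c)
    report.unique_compounds = len({r.compound_key for r in c.records})
    report.protein_entries = len(profiles.entries)
    report.gene_ids = len(profiles.genes)
    return c, profiles, report, rejects
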