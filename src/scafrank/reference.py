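"""Published content statistics of the GOSTAR MCD/TGD bioactivity corpus.

The commercial corpus this pipeline was designed around (GVKBIO's GOSTAR
Medicinal Chemistry and Target databases) is not redistributable, but its
published content statistics are, and several of the headline numbers are
pure arithmetic on them.  This module records those operands and the
identities, so the package can verify the arithmetic and report it
without any access to the source data.
"""

from __future__ import annotations

#: Published content statistics for the combined MCD + TGD corpus.
GOSTAR_CONTENT_STATISTICS: dict[str, int] = {
    "total_records": 4_442_492,
    "unique_structures": 2_856_336,
    "unique_structures_patents": 2_118_101,
    "unique_structures_journals": 846_026,
    "quantitative_results_total": 10_294_189,
    "quantitative_results_journals": 5_149_097,
    "quantitative_results_patents": 5_145_092,
    "documents_total": 127_330,
    "documents_journals": 79_487,
    "documents_patents": 47_843,
    "type_b_results": 4_841_851,
    "target_names_type_b": 5_334,
    "protein_ids_type_b": 4_043,
    "human_proteins_type_b": 1_736,
    "human_gene_ids_type_b": 1_654,
    "unique_compounds_human_type_b": 823_179,
}

#: Published per-target landscape summary for the human type-B listing.
GOSTAR_LANDSCAPE_SUMMARY: dict[str, int] = {
    "summed_compounds": 1_673_803,
    "protein_entries": 1_736,
    "summed_documents": 53_440,
    "unique_journal_documents": 12_764,
    "unique_patent_documents": 15_170,
}


def average_compounds_per_target(summed_compounds: int, protein_entries: int) -> int:
    """Mean per-target compound count, reported to the nearest integer."""
    if protein_entries <= 0:
        raise ValueError("protein_entries must be positive")
    return round(summed_compounds / protein_entries)


def records_per_structure(total_records: int, unique_structures: int) -> float:
    """Average redundancy: assay records per unique chemical structure."""
    if unique_structures <= 0:
        raise ValueError("unique_structures must be positive")
    return total_records / unique_structures
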