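"""The D-A-R-C-P corpus model and its tabular formats.

A bioactivity corpus links five curated entities — Document, Assay
description, assay Result, Compound structure, Protein target — one row
per extracted assay result.  The on-disk form is a TSV with a fixed header
(see :data:`CORPUS_COLUMNS`); structures may alternatively arrive in an
SDF joined on a key column.  Reading validates against the closed
vocabularies and collects malformed rows into a rejects table with a
reason, never dropping them silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .landscape import LandscapeTable

CORPUS_COLUMNS = [
    "doc_id",
    "doc_type",
    "target_name",
    "gene_id",
    "symbol",
    "species",
    "splice_name",
    "assay_type",
    "result_type",
    "value",
    "units",
    "smiles",
]

DOC_TYPES = {"journal", "patent"}
ASSAY_TYPES = {"B", "other"}
RESULT_TYPES = {"quantitative", "ranged", "qualitative"}

#: species strings treated as human (matched case-insensitively)
HUMAN_SPECIES = {"human", "homo sapiens"}


class CorpusFormatError(ValueError):
    """Raised when a corpus file is structurally unusable (e.g. a missing
    mandatory column); per-row problems go to the rejects table instead."""


@dataclass(frozen=True)
class Document:
    doc_id: str
    doc_type: str  # "journal" | "patent"
    year: int | None = None


@dataclass(frozen=True)
class Target:
    """One protein (or gene) entry.

    ``gene_id`` is the Entrez Gene identifier; a ``splice_name``
    accompanies a gene_id and makes (gene_id, splice_name) a distinct
    protein entry, while gene_id alone is the gene-level entry.
    """

    target_name: str
    species: str
    gene_id: int | None = None
    symbol: str | None = None
    splice_name: str | None = None

    @property
    def is_human(self) -> bool:
        return self.species.strip().lower() in HUMAN_SPECIES

    @property
    def entry_key(self) -> tuple:
        """Protein-entry identity: (gene_id, splice_name)."""
        return (self.gene_id, self.splice_name)


@dataclass(frozen=True)
class BioactivityRecord:
    """One D-A-R-C-P row: document, assay, result, compound, target."""

    doc_id: str
    target: Target
    assay_type: str  # "B" | "other"
    result_type: str  # "quantitative" | "ranged" | "qualitative"
    smiles: str
    value: float | None = None
    units: str | None = None
    compound_key: str | None = None  # filled by the triage pipeline


@dataclass
class Corpus:
    documents: dict[str, Document] = field(default_factory=dict)
    records: list[BioactivityRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = {r.doc_id for r in self.records} - set(self.documents)
        if missing:
            raise ValueError(f"records reference unknown documents: {sorted(missing)[:5]}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def with_records(self, records: Iterable[BioactivityRecord]) -> "Corpus":
        """Same document table, new record list (documents may be unused)."""
        return Corpus(documents=dict(self.documents), records=list(records))


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip()
    return s or None


def _row_to_record(row: pd.Series, structures: dict[str, str] | None) -> tuple[BioactivityRecord | None, str | None]:
    """Validate one row; returns (record, None) or (None, reason)."""
    doc_id = _opt_str(row["doc_id"])
    if not doc_id:
        return None, "missing doc_id"
    doc_type = _opt_str(row["doc_type"])
    if doc_type not in DOC_TYPES:
        return None, f"doc_type {doc_type!r} not in {sorted(DOC_TYPES)}"
    assay_type = _opt_str(row["assay_type"])
    if assay_type not in ASSAY_TYPES:
        return None, f"assay_type {assay_type!r} not in {sorted(ASSAY_TYPES)}"
    result_type = _opt_str(row["result_type"])
    if result_type not in RESULT_TYPES:
        return None, f"result_type {result_type!r} not in {sorted(RESULT_TYPES)}"
    target_name = _opt_str(row["target_name"])
    if not target_name:
        return None, "missing target_name"
    species = _opt_str(row["species"])
    if not species:
        return None, "missing species"
    gene_raw = _opt_str(row["gene_id"])
    gene_id: int | None = None
    if gene_raw is not None:
        try:
            gene_id = int(float(gene_raw))
        except ValueError:
            return None, f"gene_id {gene_raw!r} is not an integer"
    splice_name = _opt_str(row["splice_name"])
    if splice_name is not None and gene_id is None:
        return None, "splice_name without gene_id"
    value_raw = _opt_str(row["value"])
    value: float | None = None
    if value_raw is not None:
        try:
            value = float(value_raw)
        except ValueError:
            return None, f"value {value_raw!r} is not numeric"
    if result_type == "quantitative" and value is None:
        return None, "quantitative record without a value"
    if structures is not None:
        ref = _opt_str(row["smiles"])
        if ref not in structures:
            return None, f"structure key {ref!r} not in SDF"
        smiles = structures[ref]
    else:
        smiles = _opt_str(row["smiles"])
        if not smiles:
            return None, "missing smiles"
    return (
        BioactivityRecord(
            doc_id=doc_id,
            target=Target(
                target_name=target_name,
                species=species,
                gene_id=gene_id,
                symbol=_opt_str(row["symbol"]),
                splice_name=splice_name,
            ),
            assay_type=assay_type,
            result_type=result_type,
            smiles=smiles,
            value=value,
            units=_opt_str(row["units"]),
        ),
        None,
    )


def read_corpus(
    records_path: str | Path,
    format: str = "tsv",
    structures_path: str | Path | None = None,
) -> tuple[Corpus, pd.DataFrame]:
    """Read a corpus TSV (or TSV + SDF) into a validated :class:`Corpus`.

    Returns ``(corpus, rejects)`` where ``rejects`` holds every malformed
    input row together with a human-readable reason — accepted plus
    rejected rows always account for every input row.

    With ``format="sdf+tsv"`` the ``smiles`` column is read as a join key
    into the SDF at ``structures_path`` (matched against molecule names),
    and the SDF's structures are converted to SMILES.

    Raises
    ------
    CorpusFormatError
        If a mandatory column is missing from the header.
    """
    if format not in {"tsv", "sdf+tsv"}:
        raise CorpusFormatError(f"unknown corpus format {format!r}")
    df = pd.read_csv(records_path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CORPUS_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    structures: dict[str, str] | None = None
    if format == "sdf+tsv":
        if structures_path is None:
            raise CorpusFormatError("format sdf+tsv requires structures_path")
        from rdkit import Chem

        from .molgraph import read_sdf_file, _rdkit_from_graph

        structures = {
            name: Chem.MolToSmiles(_rdkit_from_graph(g))
            for name, g in read_sdf_file(structures_path)
        }

    records: list[BioactivityRecord] = []
    documents: dict[str, Document] = {}
    reject_rows: list[dict] = []
    for idx, row in df.iterrows():
        rec, reason = _row_to_record(row, structures)
        if rec is None:
            reject_rows.append({"row": idx, "reason": reason, **row.to_dict()})
            continue
        doc = documents.get(rec.doc_id)
        if doc is None:
            year = None
            documents[rec.doc_id] = Document(
                doc_id=rec.doc_id, doc_type=_opt_str(row["doc_type"]), year=year
            )
        elif doc.doc_type != _opt_str(row["doc_type"]):
            reject_rows.append(
                {"row": idx, "reason": f"doc_type conflict for document {rec.doc_id}", **row.to_dict()}
            )
            continue
        records.append(rec)

    rejects = pd.DataFrame(reject_rows, columns=["row", "reason", *CORPUS_COLUMNS])
    return Corpus(documents=documents, records=records), rejects


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def corpus_to_frame(corpus: Corpus) -> pd.DataFrame:
    rows = []
    for r in corpus.records:
        doc = corpus.documents[r.doc_id]
        rows.append(
            {
                "doc_id": r.doc_id,
                "doc_type": doc.doc_type,
                "target_name": r.target.target_name,
                "gene_id": "" if r.target.gene_id is None else str(r.target.gene_id),
                "symbol": r.target.symbol or "",
                "species": r.target.species,
                "splice_name": r.target.splice_name or "",
                "assay_type": r.assay_type,
                "result_type": r.result_type,
                "value": "" if r.value is None else repr(r.value),
                "units": r.units or "",
                "smiles": r.smiles,
            }
        )
    return pd.DataFrame(rows, columns=CORPUS_COLUMNS)


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus as the canonical TSV (round-trips through
    :func:`read_corpus` with counts and field values preserved)."""
    corpus_to_frame(corpus).to_csv(path, sep="\t", index=False)


def write_rejects(rejects: pd.DataFrame, path: str | Path) -> None:
    rejects.to_csv(path, sep="\t", index=False)


LANDSCAPE_COLUMNS = [
    "symbol",
    "gene_id",
    "splice_name",
    "compounds",
    "documents",
    "MF1",
    "MF2",
    "CS",
    "ATS",
    "GS",
    "mf2_ratio",
    "gs_ratio",
    "rank_compounds",
    "rank_documents",
    "rank_MF1",
    "rank_MF2",
    "rank_CS",
    "rank_ATS",
    "rank_GS",
]


def write_landscape(table: "LandscapeTable", path: str | Path) -> None:
    """Write the per-target landscape report as TSV.

    One row per target entry: identity, compound and document counts, the
    five unique-scaffold counts, the MF2:compound and GS:compound ratios
    (3 decimals) and the rank under each metric.  Column order is stable;
    an empty table yields a header-only file.
    """
    rows = []
    for entry in table.entries:
        p = entry.profile
        row = {
            "symbol": p.symbol or "",
            "gene_id": "" if p.gene_id is None else str(p.gene_id),
            "splice_name": p.splice_name or "",
            "compounds": p.n_compounds,
            "documents": p.n_documents,
            **{lvl: p.scaffold_counts.get(lvl, 0) for lvl in ("MF1", "MF2", "CS", "ATS", "GS")},
            "mf2_ratio": f"{p.mf2_ratio:.3f}" if p.mf2_ratio is not None else "",
            "gs_ratio": f"{p.gs_ratio:.3f}" if p.gs_ratio is not None else "",
        }
        for metric, rank in entry.ranks.items():
            row[f"rank_{metric}"] = rank
        rows.append(row)
    pd.DataFrame(rows, columns=LANDSCAPE_COLUMNS).to_csv(path, sep="\t", index=False)
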