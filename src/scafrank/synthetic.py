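"""Synthetic SAR-corpus generator with exact ground truth.

Real corpora of this kind come from commercial curation (document-centric
extraction of structure-activity data), so pipeline testing needs an
emulator with the same statistical structure and full bookkeeping:

* a heavy-tailed (discrete power-law) compounds-per-target distribution;
* a journal/patent document mix with distinct compounds-per-document
  means (defaults 14 and 44, the typical extraction averages for papers
  and patents);
* a mixture of assay types, species and gene-mapping completeness so the
  stringency triage has something to remove;
* cross-screened target pairs that share compounds and co-occur in shared
  documents (para-target emulation);
* compounds built by decorating ring-system templates with acyclic
  substituents — substituents are ring-free by construction, so every
  compound's MF2 framework IS its template, and per-target unique-MF2
  recovery is exact, not approximate.

Everything is driven by a single seed; identical config + seed gives a
byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .corpus import BioactivityRecord, Corpus, Document, Target

# ---------------------------------------------------------------------------
# built-in chemistry
# ---------------------------------------------------------------------------

#: Ring-system templates: distinct MF2-level frameworks (each template is a
#: fixpoint of the MF1/MF2 pruning — pure rings plus linkers, no exocyclic
#: decoration) spanning 1-4 ring systems, aromatic and saturated, fused and
#: linked, so the CS/ATS/GS collapse cases all occur in generated corpora.
TEMPLATE_LIBRARY: tuple[str, ...] = (
    "c1ccccc1",                      # benzene
    "c1ccncc1",                      # pyridine
    "c1cncnc1",                      # pyrimidine
    "c1cnccn1",                      # pyrazine
    "c1ccoc1",                       # furan
    "c1ccsc1",                       # thiophene
    "c1cc[nH]c1",                    # pyrrole
    "c1c[nH]cn1",                    # imidazole
    "c1cnco1",                       # oxazole
    "c1cncs1",                       # thiazole
    "C1CCCCC1",                      # cyclohexane
    "C1CCCC1",                       # cyclopentane
    "C1CCNCC1",                      # piperidine
    "C1CNCCN1",                      # piperazine
    "C1COCCN1",                      # morpholine
    "C1CCOC1",                       # tetrahydrofuran
    "C1CCOCC1",                      # tetrahydropyran
    "C1CCNC1",                       # pyrrolidine
    "c1ccc2ccccc2c1",                # naphthalene
    "c1ccc2ncccc2c1",                # quinoline
    "c1cc2ccncc2cc1",                # isoquinoline
    "c1ccc2[nH]ccc2c1",              # indole
    "c1ccc2[nH]cnc2c1",              # benzimidazole
    "c1ccc2occc2c1",                 # benzofuran
    "c1ccc2sccc2c1",                 # benzothiophene
    "c1ncc2[nH]cnc2n1",              # purine
    "c1ccc2ncncc2c1",                # quinazoline-like diazanaphthalene
    "c1ccc(-c2ccccc2)cc1",           # biphenyl
    "c1ccc(Cc2ccccc2)cc1",           # diphenylmethane (CH2 linker)
    "c1ccc(Oc2ccccc2)cc1",           # diphenyl ether (O linker)
    "c1ccc(-c2ccncc2)cc1",           # phenylpyridine
    "C1CCN(c2ccccc2)CC1",            # N-phenylpiperidine
    "C(=C/c1ccccc1)\\c1ccccc1",      # stilbene (interior linker double bond)
    "c1ccc2c(c1)Cc1ccccc1-2",        # fluorene
    "c1ccc2c(c1)[nH]c1ccccc12",      # carbazole
    "c1ccc2c(c1)oc1ccccc12",         # dibenzofuran
    "c1ccc2cc3ccccc3cc2c1",          # anthracene
    "C1CC2CCC1CC2",                  # bicyclo[2.2.2]octane
    "C1CCC2CCCCC2C1",                # decalin
    "C1CCC2(CC1)CCCCC2",             # spiro[5.5]undecane
    "C1CCC2C(C1)CCC1C2CCC2CCCC12",   # gonane (steroid 4-ring skeleton)
    "c1ccc(-c2ccc(-c3ccccc3)cc2)cc1",  # p-terphenyl
)

#: Acyclic substituents (attachment atom first); ring-free by construction.
SUBSTITUENT_LIBRARY: tuple[str, ...] = (
    "C", "CC", "CCC", "C(C)C", "CCCC", "C(C)(C)C",
    "O", "OC", "OCC", "N", "NC", "N(C)C",
    "F", "Cl", "Br", "C#N", "C(F)(F)F",
    "C(=O)O", "C(=O)N", "C(=O)C", "CO", "CCO",
    "S(C)(=O)=O", "SC", "C=C", "CC#N",
)


class GeneratorConfigError(ValueError):
    """Raised for an infeasible generator configuration, before any output."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    Defaults emulate the broad shape of a curated SAR corpus: a power-law
    compounds-per-target tail (exponent 1.6), journal documents averaging
    14 compounds each and patents 44, a journal share of 0.62, and modest
    contamination by non-binding assays, non-human species and unmapped
    targets for the triage to remove.
    """

    seed: int = 0
    n_targets: int = 100
    compounds_per_target_exponent: float = 1.6
    # a zeta tail with exponent 1.6 truncated at [13, 3000] puts the median
    # compounds-per-target near 41, the shape a curated SAR corpus shows
    compounds_per_target_min: int = 13
    compounds_per_target_max: int = 3000
    templates_per_target: tuple[int, int] = (1, 6)
    #: "random": templates drawn independently per target (targets may share
    #: a template); "partition": a shuffled deal without replacement, so
    #: template sets are disjoint across targets
    template_assignment: str = "random"
    cross_screen_pairs: tuple[tuple[tuple[int, int], float], ...] = (
        ((0, 1), 0.4),
        ((2, 3), 0.25),
    )
    journal_fraction: float = 0.62
    compounds_per_doc_mean_journal: float = 14.0
    compounds_per_doc_mean_patent: float = 44.0
    assay_b_fraction: float = 0.85
    human_fraction: float = 0.90
    gene_mapped_fraction: float = 0.95
    result_type_mix: tuple[float, float, float] = (0.75, 0.15, 0.10)

    def validate(self) -> None:
        fracs = {
            "journal_fraction": self.journal_fraction,
            "assay_b_fraction": self.assay_b_fraction,
            "human_fraction": self.human_fraction,
            "gene_mapped_fraction": self.gene_mapped_fraction,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise GeneratorConfigError(f"{name} must be in [0,1], got {v}")
        if self.compounds_per_target_exponent <= 1.0:
            raise GeneratorConfigError("power-law exponent must be > 1")
        if self.n_targets < 1:
            raise GeneratorConfigError("n_targets must be >= 1")
        lo, hi = self.templates_per_target
        if not (1 <= lo <= hi):
            raise GeneratorConfigError("templates_per_target must be 1 <= lo <= hi")
        if hi > len(TEMPLATE_LIBRARY):
            raise GeneratorConfigError(
                f"templates_per_target max {hi} exceeds library size {len(TEMPLATE_LIBRARY)}"
            )
        if self.template_assignment not in {"random", "partition"}:
            raise GeneratorConfigError(
                f"template_assignment must be 'random' or 'partition', got {self.template_assignment!r}"
            )
        if (
            self.template_assignment == "partition"
            and self.n_targets * hi > len(TEMPLATE_LIBRARY)
        ):
            raise GeneratorConfigError(
                f"partition assignment may need up to {self.n_targets * hi} templates, "
                f"library holds {len(TEMPLATE_LIBRARY)}"
            )
        if not (
            0 < self.compounds_per_target_min <= self.compounds_per_target_max
        ):
            raise GeneratorConfigError("compound count range must be 0 < min <= max")
        if abs(sum(self.result_type_mix) - 1.0) > 1e-9 or any(
            f < 0 for f in self.result_type_mix
        ):
            raise GeneratorConfigError("result_type_mix must be non-negative and sum to 1")
        for (i, j), frac in self.cross_screen_pairs:
            if not (0 <= i < self.n_targets and 0 <= j < self.n_targets) or i == j:
                raise GeneratorConfigError(f"bad cross-screen pair ({i},{j})")
            if not (0.0 <= frac <= 1.0):
                raise GeneratorConfigError(f"shared fraction {frac} out of [0,1]")
        if self.compounds_per_doc_mean_journal < 1 or self.compounds_per_doc_mean_patent < 1:
            raise GeneratorConfigError("compounds-per-document means must be >= 1")


def noise_free(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of a config with every contamination channel switched off and
    all results quantitative (nothing for the triage to remove)."""
    from dataclasses import replace

    return replace(
        config,
        assay_b_fraction=1.0,
        human_fraction=1.0,
        gene_mapped_fraction=1.0,
        result_type_mix=(1.0, 0.0, 0.0),
    )


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class TargetTruth:
    index: int
    gene_id: int
    symbol: str
    template_ids: tuple[int, ...]
    compounds: list[str] = field(default_factory=list)  # canonical SMILES
    post_triage_compounds: list[str] = field(default_factory=list)
    expected_unique_mf2: int = 0


@dataclass
class PairTruth:
    """Exact post-triage intersections for one cross-screened target pair,
    computed from the emitted records (not from the design intent)."""

    pair: tuple[int, int]
    shared_compounds: list[str] = field(default_factory=list)
    shared_doc_ids: list[str] = field(default_factory=list)


@dataclass
class GroundTruth:
    """Exact bookkeeping of what the generator emitted — consistent with
    the corpus by construction, never estimated."""

    targets: list[TargetTruth] = field(default_factory=list)
    pairs: list[PairTruth] = field(default_factory=list)
    template_of: dict[str, int] = field(default_factory=dict)  # SMILES → template


# ---------------------------------------------------------------------------
# compound construction
# ---------------------------------------------------------------------------

_TEMPLATE_MOLS = None


def _template_mols() -> list[Chem.Mol]:
    global _TEMPLATE_MOLS
    if _TEMPLATE_MOLS is None:
        _TEMPLATE_MOLS = [Chem.MolFromSmiles(s) for s in TEMPLATE_LIBRARY]
        assert all(m is not None for m in _TEMPLATE_MOLS)
    return _TEMPLATE_MOLS


def _open_sites(mol: Chem.Mol) -> list[int]:
    """Carbon atoms with at least one implicit hydrogen to substitute."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _decorate(rng: np.random.Generator, template_idx: int) -> str | None:
    """Attach 0-3 acyclic substituents at random open template positions;
    returns the canonical SMILES, or None if the assembly fails valence."""
    template = _template_mols()[template_idx]
    sites = _open_sites(template)
    k = int(rng.integers(0, 4))
    k = min(k, len(sites))
    chosen = sorted(rng.choice(len(sites), size=k, replace=False)) if k else []
    mol = Chem.Mol(template)
    for site_pos in chosen:
        sub_idx = int(rng.integers(0, len(SUBSTITUENT_LIBRARY)))
        sub = Chem.MolFromSmiles(SUBSTITUENT_LIBRARY[sub_idx])
        offset = mol.GetNumAtoms()
        combined = Chem.RWMol(Chem.CombineMols(mol, sub))
        combined.AddBond(sites[site_pos], offset, Chem.BondType.SINGLE)
        mol = combined.GetMol()
        try:
            Chem.SanitizeMol(mol)
        except Exception:
            return None
    return Chem.MolToSmiles(mol)


def _make_compounds(
    rng: np.random.Generator,
    template_ids: Sequence[int],
    n: int,
    template_of: dict[str, int],
) -> list[str]:
    """Generate up to ``n`` distinct compounds over the target's templates.

    Every template in ``template_ids`` is used at least once when n allows,
    so the per-target unique-MF2 ground truth is predictable."""
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    limit = 100 * n + 200
    forced = list(template_ids[: min(n, len(template_ids))])
    while len(out) < n and attempts < limit:
        attempts += 1
        if forced:
            t = forced[0]
        else:
            t = int(template_ids[int(rng.integers(0, len(template_ids)))])
        smi = _decorate(rng, t)
        if smi is None or smi in seen:
            continue
        if smi in template_of and template_of[smi] != t:  # pragma: no cover
            continue
        if forced:
            forced.pop(0)
        seen.add(smi)
        template_of.setdefault(smi, t)
        out.append(smi)
    return out


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------


def _power_law_counts(rng: np.random.Generator, cfg: GeneratorConfig) -> np.ndarray:
    lo, hi = cfg.compounds_per_target_min, cfg.compounds_per_target_max
    support = np.arange(lo, hi + 1, dtype=float)
    weights = support ** (-cfg.compounds_per_target_exponent)
    weights /= weights.sum()
    return rng.choice(np.arange(lo, hi + 1), size=cfg.n_targets, p=weights)


def _next_chunk(
    rng: np.random.Generator, items: list[str], pos: int, mean: float
) -> tuple[list[str], int]:
    size = int(rng.geometric(1.0 / mean))
    fresh = items[pos : pos + size]
    n_earlier = pos
    pos += len(fresh)
    shortfall = min(size - len(fresh), n_earlier)
    if shortfall > 0:
        picked = rng.choice(n_earlier, size=shortfall, replace=False)
        fresh = fresh + [items[int(k)] for k in sorted(picked)]
    return fresh, pos


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, GroundTruth]:
    """Generate one corpus plus its exact ground truth.

    Fully reproducible from ``config.seed``: the same config yields a
    byte-identical corpus TSV.  Raises :class:`GeneratorConfigError` for
    infeasible configs before emitting anything.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth()

    counts = _power_law_counts(rng, config)
    lo, hi = config.templates_per_target
    pool = list(rng.permutation(len(TEMPLATE_LIBRARY)))
    pool_pos = 0
    for i in range(config.n_targets):
        n_templates = int(rng.integers(lo, hi + 1))
        if config.template_assignment == "partition":
            template_ids = tuple(int(t) for t in pool[pool_pos : pool_pos + n_templates])
            pool_pos += n_templates
        else:
            template_ids = tuple(
                int(t)
                for t in rng.choice(len(TEMPLATE_LIBRARY), size=n_templates, replace=False)
            )
        tt = TargetTruth(
            index=i,
            gene_id=1000 + i,
            symbol=f"TGT{i:03d}",
            template_ids=template_ids,
        )
        tt.compounds = _make_compounds(rng, template_ids, int(counts[i]), truth.template_of)
        truth.targets.append(tt)

    # cross-screened pairs: move a shared slice of i's compounds into j
    for (i, j), frac in config.cross_screen_pairs:
        ti, tj = truth.targets[i], truth.targets[j]
        n_shared = int(round(frac * min(len(ti.compounds), len(tj.compounds))))
        pool = [c for c in ti.compounds if c not in set(tj.compounds)]
        n_shared = min(n_shared, len(pool))
        idx = rng.choice(len(pool), size=n_shared, replace=False) if n_shared else []
        shared = [pool[int(k)] for k in sorted(idx)]
        tj.compounds.extend(shared)
        truth.pairs.append(PairTruth(pair=(i, j), shared_compounds=shared))

    # documents and records
    documents: dict[str, Document] = {}
    records: list[BioactivityRecord] = []
    doc_counter = 0
    result_names = ("quantitative", "ranged", "qualitative")
    mix = np.asarray(config.result_type_mix)

    def _new_doc(rng: np.random.Generator) -> Document:
        nonlocal doc_counter
        doc_counter += 1
        dt = "journal" if rng.random() < config.journal_fraction else "patent"
        d = Document(doc_id=f"D{doc_counter:06d}", doc_type=dt)
        documents[d.doc_id] = d
        return d

    def _emit(
        target_indices: list[int], compound_slice: list[str], doc: Document, rt: str
    ) -> None:
        for i in target_indices:
            tt = truth.targets[i]
            for smi in compound_slice:
                assay = "B" if rng.random() < config.assay_b_fraction else "other"
                human = rng.random() < config.human_fraction
                mapped = rng.random() < config.gene_mapped_fraction
                species = "human" if human else ("rat" if rng.random() < 0.5 else "mouse")
                value = (
                    round(float(rng.uniform(1.0, 10000.0)), 1)
                    if rt == "quantitative"
                    else None
                )
                records.append(
                    BioactivityRecord(
                        doc_id=doc.doc_id,
                        target=Target(
                            target_name=f"synthetic protein {tt.gene_id}",
                            species=species,
                            gene_id=tt.gene_id if mapped else None,
                            symbol=tt.symbol if mapped else None,
                            splice_name=None,
                        ),
                        assay_type=assay,
                        result_type=rt,
                        smiles=smi,
                        value=value,
                        units="nM" if value is not None else None,
                    )
                )

    def _doc_mean(doc: Document) -> float:
        return (
            config.compounds_per_doc_mean_journal
            if doc.doc_type == "journal"
            else config.compounds_per_doc_mean_patent
        )

    # Documents over the per-target fresh-compound streams.  Each document
    # draws a type, a result type and a shifted-geometric size, fills from
    # a primary target (picked in proportion to its remaining compounds)
    # and spills into further targets when that stream runs dry — large
    # patents routinely report several targets — so document sizes follow
    # the configured distribution rather than being clipped per target.
    shared_sets = {p.pair: set(p.shared_compounds) for p in truth.pairs}
    streams: dict[int, list[str]] = {}
    for i, tt in enumerate(truth.targets):
        own = [
            c
            for c in tt.compounds
            if not any(
                c in shared_sets[p.pair] for p in truth.pairs if p.pair[1] == i
            )
        ]
        if own:
            streams[i] = own
    while streams:
        doc = _new_doc(rng)
        rt = result_names[int(rng.choice(3, p=mix))]
        fill = int(rng.geometric(1.0 / _doc_mean(doc)))
        primary = True
        while fill > 0 and streams:
            keys = sorted(streams)
            if primary:
                weights = np.array([len(streams[k]) for k in keys], dtype=float)
                t = keys[int(rng.choice(len(keys), p=weights / weights.sum()))]
                primary = False
            else:
                t = keys[int(rng.integers(0, len(keys)))]
            chunk = streams[t][:fill]
            del streams[t][: len(chunk)]
            if not streams[t]:
                del streams[t]
            _emit([t], chunk, doc, rt)
            fill -= len(chunk)

    # dedicated cross-screening documents carry both targets' results for
    # the shared compounds (padded with re-reported shared compounds when
    # the drawn size overshoots)
    for p in truth.pairs:
        i, j = p.pair
        pos = 0
        while pos < len(p.shared_compounds):
            doc = _new_doc(rng)
            rt = result_names[int(rng.choice(3, p=mix))]
            chunk, pos = _next_chunk(rng, p.shared_compounds, pos, _doc_mean(doc))
            _emit([i, j], chunk, doc, rt)

    corpus = Corpus(documents=documents, records=records)
    _fill_post_triage_truth(corpus, truth)
    return corpus, truth


def _fill_post_triage_truth(corpus: Corpus, truth: GroundTruth) -> None:
    """Replay the stringency-cascade semantics (membership filters, then
    per-document distinct-compound caps) over the emitted record stream to
    record each target's expected post-triage compound set."""
    from .triage import CAP_QUALITATIVE, CAP_RANGED

    caps = {"ranged": CAP_RANGED, "qualitative": CAP_QUALITATIVE}
    by_gene: dict[int, set[str]] = {}
    docs_by_gene: dict[int, set[str]] = {}
    cap_state: dict[tuple[str, str], set[str]] = {}
    for r in corpus.records:
        if r.assay_type != "B" or r.target.gene_id is None or not r.target.is_human:
            continue
        cap = caps.get(r.result_type)
        if cap is not None:
            bucket = cap_state.setdefault((r.doc_id, r.result_type), set())
            if r.smiles not in bucket:
                if len(bucket) >= cap:
                    continue
                bucket.add(r.smiles)
        by_gene.setdefault(r.target.gene_id, set()).add(r.smiles)
        docs_by_gene.setdefault(r.target.gene_id, set()).add(r.doc_id)
    for tt in truth.targets:
        tt.post_triage_compounds = sorted(by_gene.get(tt.gene_id, set()))
        tt.expected_unique_mf2 = len(
            {truth.template_of[s] for s in tt.post_triage_compounds}
        )
    for p in truth.pairs:
        gi = truth.targets[p.pair[0]].gene_id
        gj = truth.targets[p.pair[1]].gene_id
        p.shared_compounds = sorted(
            by_gene.get(gi, set()) & by_gene.get(gj, set())
        )
        p.shared_doc_ids = sorted(
            docs_by_gene.get(gi, set()) & docs_by_gene.get(gj, set())
        )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------


def validate_distribution(corpus: Corpus, config: GeneratorConfig) -> pd.DataFrame:
    """Compare the emitted corpus against the configured study conditions.

    Reports the per-document-type mean of distinct compounds per document,
    the empirical power-law tail exponent of compounds-per-target (Hill
    MLE above the configured minimum), and the realised contamination
    rates, each with a standard error where one is defined.
    """
    doc_compounds: dict[str, set[str]] = {}
    per_gene: dict[int | None, set[str]] = {}
    n = len(corpus.records)
    non_b = non_human = unmapped = 0
    for r in corpus.records:
        doc_compounds.setdefault(r.doc_id, set()).add(r.smiles)
        per_gene.setdefault(r.target.gene_id, set()).add(r.smiles)
        non_b += r.assay_type != "B"
        non_human += not r.target.is_human
        unmapped += r.target.gene_id is None

    rows = []
    for dtype, cfg_mean in (
        ("journal", config.compounds_per_doc_mean_journal),
        ("patent", config.compounds_per_doc_mean_patent),
    ):
        sizes = [
            len(cs)
            for d, cs in doc_compounds.items()
            if corpus.documents[d].doc_type == dtype
        ]
        if sizes:
            arr = np.asarray(sizes, dtype=float)
            rows.append(
                {
                    "quantity": f"compounds_per_{dtype}_doc_mean",
                    "value": float(arr.mean()),
                    "se": float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else np.nan,
                    "configured": cfg_mean,
                }
            )

    counts = np.asarray(
        [len(v) for g, v in per_gene.items() if g is not None], dtype=float
    )
    xmin = config.compounds_per_target_min
    tail = counts[counts >= xmin]
    if len(tail) > 1 and np.any(tail > xmin):
        # Hill estimator with the discrete -1/2 shift
        alpha = 1.0 + len(tail) / np.sum(np.log(tail / (xmin - 0.5)))
        se = (alpha - 1.0) / np.sqrt(len(tail))
        rows.append(
            {
                "quantity": "compounds_per_target_tail_exponent",
                "value": float(alpha),
                "se": float(se),
                "configured": config.compounds_per_target_exponent,
            }
        )

    for name, count, cfg_rate in (
        ("non_type_b_rate", non_b, 1.0 - config.assay_b_fraction),
        ("non_human_rate", non_human, 1.0 - config.human_fraction),
        ("unmapped_rate", unmapped, 1.0 - config.gene_mapped_fraction),
    ):
        p = count / n if n else 0.0
        rows.append(
            {
                "quantity": name,
                "value": p,
                "se": float(np.sqrt(p * (1 - p) / n)) if n else np.nan,
                "configured": cfg_rate,
            }
        )
    return pd.DataFrame(rows, columns=["quantity", "value", "se", "configured"])
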