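# Methods

This note records the models, conventions and numerical choices behind
`scafrank`, the assumptions they rest on, and what the synthetic-corpus
tests do and do not demonstrate about real data.

## Structure model and normalization

A compound is an element-labeled, bond-order-labeled undirected simple
graph (`MolecularGraph`): nodes carry element and formal charge, edges
carry order 1/2/3 or aromatic, hydrogens are implicit and never nodes.
Stereochemistry and tautomer state are discarded throughout — every
scaffold level is constitutional, so keeping them would only split
records that the analysis treats as equivalent.

Normalization, applied before keying or scaffolding, is:

1. largest connected component (salt/solvent stripping; ties broken by
   bond count, then by the sorted label multiset, so the choice is
   deterministic);
2. charge neutralization wherever a proton can be added or removed
   without changing heavy-atom connectivity (RDKit's uncharger;
   quaternary centres keep their charge);
3. aromaticity as perceived by RDKit at parse time.

No tautomer canonicalization is performed: registration practice varies,
any rule set would be arbitrary, and the cost is only that distinct
drawn tautomers count as distinct compounds. Normalization is
idempotent.

One implementation subtlety: rebuilding an RDKit molecule from the graph
loses pyrrole-type N–H placement, which can make kekulization fail or —
worse — succeed under a wrong tautomer with different perceived
aromaticity. The rebuilder therefore searches H placements over
candidate aromatic nitrogens and accepts only a placement that
reproduces the input bond orders exactly, falling back to the first
sanitizable placement otherwise.

## Unique-compound identity

Compound keys are the canonical form of the normalized full structure
with both node (element+charge) and edge (bond order) labels respected.
This plays the role an InChIKey plays in registration systems but is
self-contained and connectivity-level only: no stereo layer, no
tautomer folding. Two SMILES spellings of one structure always collide;
stereoisomers always collide too (by design, see above).

## Canonical graph labeling

"Unique scaffolds per level" requires an exact canonical form, not a
hash. The algorithm is iterative neighbourhood-invariant (colour)
refinement — a node's colour is refined by the multiset of
(edge label, neighbour colour) pairs until stable — followed by
individualization: each member of the first non-singleton colour class
is individualized in turn, refinement re-run, and the search recursed;
the key is the lexicographically minimal adjacency encoding over all
discrete leaves. The search is exhaustive, so equal keys imply
isomorphic graphs and vice versa; there are no collisions by
construction. Worst-case cost is exponential (highly regular graphs),
but molecular frameworks are nearly rigid: refinement typically leaves
only small symmetric cells (a benzene ring contributes 12 leaves). A
size bound (default 256 nodes) guards against pathological inputs.

Ring membership is "lies on some cycle", computed as endpoints of
non-bridge edges. A smallest-ring basis is never needed: the pruning
operators only ask whether an atom is cyclic.

## The five scaffold levels

* **MF1** deletes, to a fixpoint, every degree-1 non-ring atom attached
  through a single bond. A terminal atom held by a double, triple or
  aromatic bond survives (aromatic counts as multiple). Note the
  consequence: an unsaturated side chain terminating in a double bond
  (e.g. an allyl or acyl group) is retained in MF1 end-to-end, because
  its terminal atom never becomes deletable.
* **MF2** re-runs the pruning on MF1 without the multiple-bond
  exemption, removing the doubly-bonded terminals — the classical
  Murcko framework. "Removing exocyclic double bonds" is implemented as
  removing the doubly-bonded terminal *atom*, not merely downgrading the
  bond: downgrading would expose the atom to side-chain pruning on the
  next pass anyway, so the results coincide and the one-step form is
  simpler. Double bonds *interior* to the framework (e.g. a stilbene
  linker) are preserved as drawn; whether the original curation tools
  downgraded such bonds is unknowable, so counts on compounds with
  unsaturated linkers may differ from historical tools.
* **CS / ATS / GS** are label erasures of MF2 and only of MF2: CS blanks
  node labels (bond orders kept, so benzene ≠ cyclohexane), ATS blanks
  edge labels including aromaticity (elements kept, so pyridine ≠
  benzene), GS blanks both. ATS drops formal charges together with the
  bond orders.

Acyclic molecules carry no framework at any level: they are flagged,
excluded from every scaffold count, but retained in compound counts and
ratio denominators. Murcko frameworks are undefined without a ring, and
silently assigning an empty-graph key would let all acyclic compounds
collapse into one phantom "scaffold".

Invariants the test suite enforces: MF1/MF2 idempotence; atom-set
containment MF2 ⊆ MF1 ⊆ molecule; cyclomatic-number conservation across
all five levels; per-target unique-count monotonicity
GS ≤ {CS, ATS} ≤ MF2 ≤ MF1 ≤ compounds.

## Triage cascade

Filter order is type-B → gene-mapped → human → caps → keys. The three
membership filters are pure row predicates, hence idempotent and
order-commuting; the cascade order matters only for stage counts and for
the cap stage, which must see each document's records in input order.
Species matching is binary: "human"/"homo sapiens" case-insensitively,
everything else non-human.

Caps are applied per document across all of that document's targets
jointly (extraction happens at document level, before target mapping):
quantitative records are never capped; ranged records are truncated to
the first 200 distinct compounds in input order, qualitative to the
first 100; a compound already inside the cap keeps all its later
records. "First N in input order" makes truncation deterministic; how
the original curators chose which exemplified compounds to extract is
not recoverable. Whether the historical caps were per document or per
document-target pair is likewise unstated; per-document is implemented.

Unparsable structures are routed to a rejects table with the offending
string; they never abort a run.

Profiles are built at two granularities: one per (gene id, splice name)
protein entry, plus a gene-level rollup per gene id (the union over its
entries). The gene-level universe is the default for ranking; splice
entries remain available for the supplementary view.

## Landscape metrics

* **Ranking**: descending by the chosen metric, ties broken by compound
  count (when not the metric), then document count, then symbol. The
  tie-break chain is this package's convention — corpus-scale data
  rarely ties, but determinism requires one.
* **Summary**: the average is reported to the nearest integer, the
  median with even-count midpoint averaging. Summed compound counts are
  with multiplicity across targets; the unique count is the union.
* **Coverage**: smallest top-N whose summed (with-multiplicity) counts
  reach the requested fraction of the summed total. Using the summed
  rather than unique totals matches how "top-N targets cover X% of the
  compounds" is quoted alongside a summed total.
* **Bins**: "targets at or above b" counts profiles with ≥ b compounds;
  this cumulative reading is the only one under which the bottom bin
  equals the number of entries. Default edges: 10000, 5000, 2000, 1051,
  1000, 500, 200, 100, 50, 10, 2, 1.
* **Ratios**: MF2:compounds and GS:compounds, written to 3 decimals (one
  more than typically printed, to avoid rounding-induced ties in ranked
  output).
* **Overlap**: plain set-intersection cardinalities of compound keys and
  document ids.

## Synthetic corpus generator

The generator emulates a document-centric curated SAR corpus with exact
bookkeeping, so recovery tests are equality checks, not approximations.

* **Compounds**: a ring-system template (42 built-in frameworks spanning
  1–4 rings, aromatic/saturated, fused/linked, each a fixpoint of the
  MF1/MF2 pruning and pairwise MF2-distinct) decorated with 0–3 acyclic
  substituents at random open carbon positions. Substituents are
  ring-free, and single-point attachment cannot create a ring, so each
  compound's MF2 equals its template — per-target unique-MF2 ground
  truth is exact.
* **Compounds-per-target**: discrete power law with exponent 1.6
  truncated to [13, 3000]. The exponent qualitatively reproduces a
  ~90%-of-mass-in-the-top-sixth shape; the lower bound 13 puts the
  median near 41, the shape reported for corpora of this kind. These are
  calibrations of the emulator, not claims about any particular corpus.
* **Documents**: each document draws a type (journal with probability
  0.62), one result type, and a shifted-geometric size with mean 14
  (journal) or 44 (patent) distinct compounds. Documents fill from a
  primary target picked in proportion to its remaining compounds and
  spill into further targets when that stream runs dry — large patents
  routinely report several targets — so realised document sizes follow
  the configured distribution instead of being clipped by small targets.
* **Cross-screening**: configured pairs share a fraction of the smaller
  partner's compounds; dedicated documents carry both targets' results
  for the shared compounds. Pair ground truth (shared compound and
  document lists) is computed from the emitted records after replaying
  the triage semantics, so it is exact even under contamination noise.
* **Contamination**: per-record non-binding assay types, non-human
  species and unmapped targets at configured rates (defaults 0.15,
  0.10, 0.05) give the triage something to remove; ground truth replays
  the cascade (filters, then per-document caps) over the emitted stream.
* **Determinism**: one `numpy` generator seeded from the config; the
  same config yields a byte-identical corpus TSV.

What the generator does *not* emulate: medicinal-chemistry series logic
(substituents are chemically plausible but unoptimized), potency realism
(values are placeholders), patent families, per-year structure, and
scaffold-hopping between related frameworks. Passing recovery tests
therefore shows the pipeline computes its definitions exactly on corpora
with the right statistical shape — not that the triage choices are
optimal for any particular real corpus.

## Problem sizes and runtime choices

The acceptance checks use a 25-target / one-template-per-target /
400-compounds-per-target noise-free corpus (~10,000 compounds) for exact
MF2 recovery, an 80-target default-conditions corpus for overlap,
coverage and document-size diagnostics, and 500 random ≤ 9-node graphs
(checked pairwise within degree-sequence buckets against a VF2 oracle)
for the canonical form. These sizes exercise every code path at full
fidelity while keeping a complete run in the order of a minute.

## Known limitations

* Connectivity-level compound identity merges stereoisomers; corpora
  keyed by full InChIKey would count slightly more unique compounds.
* The MF1 retention rule keeps entire unsaturation-terminated side
  chains (see above); this follows the stated definition literally but
  may differ from historical implementations on such compounds.
* Canonical labeling is exponential on highly regular non-molecular
  graphs; the capacity bound fails loudly rather than degrading.
* Qualitative results are stored valueless; nothing downstream consumes
  result values, so no information is lost to the analysis.
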