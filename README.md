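# scafrank

Target-landscape analysis of compound-to-target bioactivity corpora:
stringency triage, a five-level molecular framework/scaffold hierarchy, and
scaffold-based ranking of protein targets by chemical tractability.

## The problem

Medicinal-chemistry corpora curated from journals and patents link
documents (D), assay descriptions (A), assay results (R), compound
structures (C) and protein targets (P). Ranking targets by how many
compounds have been assayed against them gives a de facto chemical
tractability ranking — but raw compound counts conflate effort with
diversity: a target hit by 10,000 near-identical analogues is less
tractable than one hit by 3,000 compounds spanning hundreds of chemotypes.

`scafrank` implements the full analysis for such corpora:

1. **Stringency triage** — keep in vitro binding ("type-B") assay
   results, targets mapped to an Entrez Gene identifier, human records;
   apply the per-document extraction caps used in curated corpora (all
   quantitative results, at most 200 distinct compounds with ranged
   results and 100 with qualitative results per document); deduplicate
   structures by a canonical connectivity key.
2. **Scaffold hierarchy** — for each compound, five progressive
   Bemis–Murcko-style abstractions:
   * **MF1**: terminal side chains removed; atoms attached through
     double/triple/aromatic bonds (exocyclic =O, =CH₂, …) kept;
   * **MF2**: those doubly-bonded terminals removed too — the classical
     Murcko framework (rings + linkers);
   * **CS** (carbon scaffold): MF2 with atom types erased, bond orders kept;
   * **ATS** (atom-type scaffold): MF2 with bond orders erased, atom types kept;
   * **GS** (graph scaffold): the bare graph skeleton.

   The cyclomatic ring count |E| − |V| + |components| is conserved at
   every level. Each level is canonicalized with an exact (refinement +
   individualization, collision-free) graph canonical form, so "unique
   scaffolds" means unique up to isomorphism under that level's labels.
3. **Landscape metrics** — per-target unique compounds, documents and
   scaffold counts; rankings under any metric with a deterministic
   tie-break; summed/unique/average/median summaries; cumulative binned
   distributions; top-N coverage cutoffs; cross-screening overlap
   (compounds-in-common / documents-in-common) for para-target pairs; and
   the diversity ratios MF2:compounds and GS:compounds (larger ⇒ more
   chemotypes per unit of effort ⇒ higher tractability).

Because corpora of this kind are commercial, the package ships a
first-class **synthetic corpus generator** with exact ground truth:
compounds are built by decorating ring-system templates with acyclic
substituents (so each compound's MF2 *is* its template and recovery is
exact), with a heavy-tailed compounds-per-target distribution,
journal/patent documents with distinct size means (14 / 44 distinct
compounds per document), configurable contamination for the triage to
remove, and cross-screened target pairs.

## Worked example

Scaffold record for atorvastatin (four rings, all five levels present):

```python
>>> import scafrank as sr
>>> rec = sr.scaffold_record(sr.normalize(sr.parse_structure(
...     "CC(C)c1c(C(=O)Nc2ccccc2)c(-c2ccccc2)c(-c2ccc(F)cc2)n1"
...     "CC[C@@H](O)C[C@@H](O)CC(=O)O")))
>>> rec.acyclic, rec.ring_count
(False, 4)
>>> rec.mf1_key.key[:30]
'34|C,C,C,C,C,C,C,C,C,C,C,C,C,C'
```

The MF1 retains 34 atoms (frameworks plus the kept exocyclic oxygens);
the GS collapses to a 25-node unlabeled skeleton; the ring count 4 is
identical at every level.

End-to-end pipeline on a small synthetic corpus:

```bash
$ cat run.yaml
outdir: run
simulate:
  n_targets: 8
  compounds_per_target_min: 20
  compounds_per_target_max: 200
  templates_per_target: [1, 3]
  cross_screen_pairs: [[[0, 1], 0.4]]
seed: 1
coverage_fraction: 0.9
bin_edges: [100, 50, 10, 1]

$ scafrank report --config run.yaml
$ cat run/summary.txt
protein entries	8
summed compounds	451
unique compounds	433
average compounds-per-target	56
median compounds-per-target	33
summed documents	38
unique journal documents	18
unique patent documents	11
top-6 targets cover 90% of compounds (cutoff 30)
bin>=100	2
...
```

The summed count (451) exceeds the unique union (433) because
cross-screened compounds count once per target; the coverage line says
the 6 most-assayed targets account for 90% of the summed compounds, the
6th having 30. `run/landscape.tsv` holds the per-target report:

```
symbol  gene_id  ...  compounds  documents  MF1  MF2  CS  ATS  GS  mf2_ratio  gs_ratio
TGT001  1001     ...  133        10         45   5    5   5    5   0.038      0.038
TGT003  1003     ...  105        9          36   2    2   2    2   0.019      0.019
```

TGT001's 133 compounds collapse to 5 Murcko frameworks — an MF2:compound
ratio of 0.038, i.e. long analogue series on few chemotypes. The
cross-screening overlap of the configured para-target pair:

```bash
$ scafrank overlap --in run/triaged.tsv --target-a TGT000 --target-b TGT001
TGT000/TGT001: 18 compounds-in-common, 2 documents-in-common
```

Every subcommand (`simulate`, `triage`, `scaffold`, `rank`, `overlap`,
`bins`, `report`) is a thin wrapper over the library API
(`scafrank.generate_corpus`, `run_triage`, `scaffold_record`,
`rank_targets`, …).

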