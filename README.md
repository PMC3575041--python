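# clingenmap

Clinic–genomic relation mining over UMLS-style terminology files.

Translational research needs bridges between what clinicians record
(symptoms, lab tests, pathology states, coded with SNOMED CT) and what
molecular biologists study (genes, proteins, publications). `clingenmap`
builds such bridges for colorectal cancer by traversing the flat files of a
local UMLS installation — MRCONSO (concept atoms), MRREL (relations), MRCOC
(co-occurrences), MRSTY (semantic types) — and validating the resulting
candidate relations against MeSH-indexed literature. It is aimed at
translational-bioinformatics researchers who have (or can emulate) a UMLS
subset and want a reproducible, testable relation-mining pipeline rather
than ad-hoc SQL over the raw files.

## Methods in brief

Let *G* be a set of genomic concepts (genes) and *C* a set of clinical
concepts. Two mapping methods produce candidate relations:

* **Direct mapping.** For a source concept *s*, resolve *s* to its CUI(s)
  in MRCONSO, collect every concept one MRREL/MRCOC step away, keep those
  with the desired semantic type from MRSTY (gene-like `T028` when mapping
  into *G*; sign/symptom, finding, disease, lab-procedure types when mapping
  into *C*), and intersect with the opposite set. Running *G*→*C* and
  *C*→*G* gives directed relation sets.

* **Indirect mapping via disease.** For a gene *g* let *U₁* be its related
  disease concepts (disease semantic types `T047`/`T191`); for a clinical
  item *c* let *U₂* be the same. If *U₁* ∩ *U₂* contains a disease that is
  itself colorectal-cancer-related — its preferred term satisfies
  *(colon ∨ colorectal ∨ colonic ∨ rectal) ∧ (cancer ∨ carcinoma ∨
  adenoma)* — then (*g*, *c*) is an undirected candidate relation with the
  shared diseases as evidence.

* **Literature validation.** A candidate (*X*, *Y*) passes when at least one
  article is indexed with `X′[MeSH Terms] AND Y′[MeSH Terms] AND Colorectal
  neoplasms[MeSH Terms]`, where *X′*, *Y′* are MeSH terms of the two
  concepts taken from MRCONSO. Counts come from an offline index file or,
  behind an explicit flag, the live NCBI E-utilities esearch endpoint.

Companion modules implement the same keyword combination as a
field-restricted search over OMIM-style entries (title + allelic variants)
with gene→protein and gene→article joins over NCBI-style association
tables, and a parser/renderer for SNOMED CT postcoordinated expressions
(`focus:attribute=value,...`).

Because real UMLS/OMIM releases are licensed and version-drifting, the
package ships a seeded fixture generator that emits miniature RRF files,
concept sets and literature indexes *with known ground truth*, so the whole
pipeline is verifiable end to end without any download.

## Worked example

Run the self-checking demo: it generates a synthetic terminology (38
concepts: 10 genes, 10 clinical findings, 8 diseases, 10 unrelated
compounds), maps, validates against the generated literature index, and
compares everything to the generator's ground truth:

```sh
$ clingenmap demo --seed 1 --out demo_out
direct relations:    13
indirect relations:  25
combined candidates: 36
validated relations: 17
ground truth recovered: yes
```

Read: 13 gene–finding pairs were linked by an explicit relation or
co-occurrence row; 25 pairs shared a colorectal-cancer disease neighbour;
deduplicating pairs found by both methods left 36 distinct candidates, of
which 17 had a supporting literature record and passed validation. The
final line confirms all three sets equal the ground truth planted by the
generator. `demo_out/` contains the relation TSV, the validation report and
a JSON summary.

Individual steps are available as `clingenmap make-fixtures`, `map-direct`,
`map-indirect`, `validate` and `extract-genes`; postcoordinated expressions
round-trip through `compose-expr`:

```sh
$ clingenmap compose-expr "21522001 |abdominal pain| : 272741003 |laterality| = 77710000 |left|, 246113005 |severity| = 24484000 |severe|" --with-terms
21522001 |abdominal pain|:272741003 |laterality|=77710000 |left|,246113005 |severity|=24484000 |severe|
```

The packaged table of representative validated relations (ten clinical
items with their gene lists, e.g. *Colorectal neoplasms staging* → APC,
CCND1, CTNNB1, MTHFR, PPARG, TP53) loads via
`clingenmap.load_table1_relations()`.

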