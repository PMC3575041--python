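# Methods

## Problem and model

The package mines candidate relations between a genomic concept set *G*
(genes) and a clinical concept set *C* (coded clinical items) from the four
flat files of a UMLS-style terminology installation, then gates the
candidates by literature co-occurrence. The underlying model is purely
set-theoretic — no weighting, ranking or multi-hop graph expansion:

* A concept reference (term string, `SAB:CODE`, or explicit CUI) resolves
  to the CUIs of its non-suppressed MRCONSO atoms. Ambiguity is preserved:
  a term that names several concepts contributes all of them, because
  silently picking one would drop candidates invisibly.
* `related(s)` is the union of counterpart CUIs of qualifying MRREL rows
  (non-suppressed; both orientations by default; optional REL-label
  whitelist) and MRCOC rows with frequency ≥ a threshold (default 1).
  Self-relations are ignored.
* **Direct mapping**: for each source CUI *s*,
  `related(s)` is filtered to the target role's semantic types and
  intersected with the resolved target set; each hit is one directed
  candidate with the qualifying rows as evidence.
* **Indirect mapping**: with `U(x) = related(x)` filtered to disease types,
  the pair (*g*, *c*) is a candidate iff `U(g) ∩ U(c)` contains a
  colorectal-cancer-related disease; those diseases are the evidence and
  the relation is undirected, since nothing in the construction orients it.
* **Validation**: a candidate passes iff some indexed article carries a
  MeSH term of each concept plus the fixed context heading
  "Colorectal neoplasms" (template
  `X[MeSH Terms] AND Y[MeSH Terms] AND Colorectal neoplasms[MeSH Terms]`).
  The clinical concept supplies X and the genomic concept Y. The pass
  threshold is ≥ 1 article; the raw hit count is stored so stricter gates
  can be applied downstream without re-querying.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| genomic semantic types | `{T028}` | Gene or Genome is the standard type for gene concepts |
| clinical semantic types | `{T184, T033, T047, T191, T059}` | signs/symptoms, findings, diseases, neoplasms, lab procedures — the clinical item kinds the relation table covers |
| disease semantic types | `{T047, T191}` | Disease or Syndrome plus Neoplastic Process |
| REL whitelist | empty (all labels) | the most inclusive reading of "related"; narrow via config |
| `min_cooccurrence_frequency` | 1 | any recorded co-occurrence counts; raise to demand stronger signals |
| relations bidirectional | yes | MRREL stores many relations in one orientation only |
| suppressed rows | excluded | standard terminology practice; config-includable |
| CRC disease test | keyword match on preferred term | `(colon∨colorectal∨colonic∨rectal) ∧ (cancer∨carcinoma∨adenoma)`, whole-word; an explicit CUI list overrides it |
| validation context term | "Colorectal neoplasms" | pins hits to the disease of interest |

The CRC keyword test deliberately reuses the OMIM search's whole-word
matcher rather than substring matching: the keyword list contains both
"colon" and "colonic" as separate forms, which only makes sense under
whole-word semantics, and substring matching would fire "colon" inside
"semicolon". One shared matcher also keeps the two filters consistent.

MeSH synonym handling: a CUI can have several MeSH atoms. Validation tries
(x, y) term combinations in order — preferred atoms first, then main
headings (`MH`) before entry terms — until the first hit, which degrades to
the single-term behaviour when each concept has exactly one MeSH term. A
concept without MeSH atoms fails validation explicitly (zero hits, logged)
rather than being guessed at.

## RRF handling

Only the columns the pipeline interprets are typed; all other columns are
carried as opaque strings, so write∘read is byte-identical and
release-to-release column drift is absorbed rather than modelled. Lines are
UTF-8, `|`-delimited with the trailing empty field dropped. A line with too
few columns is a hard error naming the line number — no silent drops. The
knowledge base is in-memory and indexed by CUI, lower-cased term, and
(vocabulary, code); it targets fixture-to-subset scale, not a full release
load.

Term lookup is case-insensitive exact match. No stemming or fuzzy
normalisation is applied: resolving a source concept against MRCONSO is
specified only as a search, and exact matching is the minimal faithful
reading; anything fuzzier would manufacture relations the inputs do not
assert.

## Synthetic fixtures and what they show

`FixtureSpec` defaults generate 38 concepts — 10 genes, 10 clinical
findings, 8 diseases (half colorectal-cancer-related by name), 10
unrelated compounds — with each gene–finding pair directly linked with
probability 0.15, each gene/finding–disease pair linked with probability
0.30, and 60% of true relations given a supporting literature record so the
validation gate genuinely filters. Links are randomly MRREL or MRCOC rows
in random orientation; degenerate rows (a self-relation, a suppressed
relation) are planted so the traversal's exclusions are exercised. These
sizes keep each fixture in the ≤ 50-concept regime where brute-force
enumeration remains a practical oracle, and the probabilities give fixtures
that contain, at typical seeds, tens of true relations of both kinds plus
rejected noise.

Ground truth (direct pairs, indirect pairs, literature-supported pairs) is
computed by the generator's own bookkeeping — set intersections over the
links it sampled — never by calling the mapping engine, so recovery tests
are non-circular. The OMIM snapshot generator likewise plants positive
entries by construction and restricts negative entries' decoy text to a
single keyword group, making the expected match set exact.

What passing these tests does **not** show: real RRF files have messier
term strings, many more semantic types, relation labels with meaningful
semantics, co-occurrence counts spanning orders of magnitude, and concepts
with dozens of synonyms. The fixtures validate the set algebra and the
plumbing, not the linguistic coverage of real terminologies; on a real
installation the semantic-type sets and the REL whitelist are the knobs
that control precision.

## Numerical and ordering choices

* All outputs are sorted by (genomic CUI, clinical CUI, method); evidence
  tuples are sorted internally; identical inputs give byte-identical files.
* Deduplication merges method tags (`direct+indirect`), unions evidence,
  and collapses conflicting directions to `undirected`; it is idempotent.
* The postcoordination grammar is the flat subset only (focus +
  attribute=value list, optional `|term|` displays, whitespace tolerated);
  codes are opaque digit strings, not checked against a terminology server.
* The live literature backend reads only the esearch `Count` field,
  throttles to ≤ 3 requests/s and retries network failures 3 times with
  exponential backoff; a response without a parseable count is a distinct
  error, and no failure path ever reports zero hits.

## Known limitations

* One-step traversal only; no transitive expansion, no relation weighting
  or ranking (a natural next step would be quantifying relations by
  co-occurrence strength).
* Whether both MRREL and MRCOC must support a direct relation is
  configurable but defaults to either-sufficient, the more inclusive
  reading.
* OMIM access is file-based (JSON-lines snapshots); there is no live
  downloader, since OMIM distribution is licensed and keyed.
* The in-memory knowledge base is not meant for a full terminology release;
  loading one would need on-disk indexes out of scope here.
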