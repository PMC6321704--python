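# Methods

## The annotation model

`placorep` treats immunity-gene identification as classification over
*annotated domain architectures*, not over raw sequence. The unit of
analysis is one predicted protein with (a) a set of domain intervals from
an InterProScan-style functional annotation, (b) a signal-peptide (SP) and
transmembrane (TM) topology call, and (c) optional gene-level mappings
(KEGG KO, EggNOG and OrthoMCL orthologous groups, best Swiss-Prot hit,
PANTHER family). All coordinates are 1-based inclusive residues and are
never converted.

Assumptions inherited from this design:

* domain detection upstream is trusted — the pipeline never re-scans
  sequences, so a domain the annotation missed is missing here too (this is
  exactly why the intelectin family needs a second, mapping-based route);
* protein identifiers equal gene identifiers, so architecture labels can be
  joined directly to gene loci and mapping tables.

### Architecture building

InterProScan reports the same biological domain from several member
databases. Hits sharing an accession key are merged when their intervals
reciprocally overlap by more than **30 % of the shorter interval**;
disjoint repeats of the same domain stay separate, so rules count domain
occurrences rather than redundant hits. The threshold is a compromise:
high enough that tandem repeats (LRR, SRCR, WD40 blocks) are not fused,
low enough that jittered boundaries from different HMM libraries collapse.
Keys are InterPro accessions where the hit carries one, and
`analysis:signature` otherwise — the fibrinogen C-terminal globular fold is
only reachable as `SUPERFAMILY:SSF56496`, and keeping such hits addressable
is load-bearing for the FReD screen.

### Positional conventions

The terms "N-terminal", "central" and "C-terminal" are operationalised as
**thirds of the protein length**, assigned by the midpoint of the merged
interval. Thirds are symmetric, parameter-free and testable; any sharper
definition would be arbitrary without structural information.

Membrane sidedness is assigned only to membrane proteins. For a single-TM
protein with an SP, the type-I convention applies: the region N-terminal to
the TM is extracellular. Without an SP the orientation flips and the
protein is flagged `single_tm_no_sp_orientation` (low confidence). For 7-TM
receptors the region before TM1 is extracellular regardless of SP (the
GPCR convention), and sidedness alternates across each crossing. A domain
whose midpoint lies inside a TM segment gets no sidedness. These
conventions are exactly what the LRR-receptor-candidate rule
("extracellular LRRs, single TM") and the GPCR-CTLD subclass rely on.

### The rule engine

A family rule is a conjunction of clauses evaluated in a fixed canonical
order (required accession groups, forbidden accessions, occurrence counts,
TM constraint, SP constraint, length bounds, positional constraints,
PANTHER mapping), with `any_of` providing disjunction and nested subclass
rules evaluated only on proteins that pass the parent. Evaluation is pure;
diagnostics record every clause and name the first failing one, which is
how the test suite verifies that each planted decoy fails for exactly the
intended reason. Conflicting labels are never resolved silently: a protein
keeps every label whose rule passes, and cross-family tensions surface as
flags (e.g. `sr_class_overlap` when a protein carries two of the three
scavenger-receptor domain classes — an observation, not an error, since
their disjointness is an empirical property of one genome, not a
constraint).

Parameter choices in the packaged rule set that deserve justification:

* **intelectin length cutoff 400 AA** — placozoan intelectins are ~250 AA;
  400 leaves headroom for boundary noise while excluding every multi-domain
  FReD protein;
* **fibrillin-like cutoff 1000 AA** — separates the two giant FReD-bearing
  fibrillin-related proteins from all short secreted FReD models;
* **Death-clan group** = {DD, CARD, DED, PYD, death-like domain fold}: the
  literature treats these homotypic-interaction domains as one clan, and
  MyD88-like adaptors are defined by *any* of them next to a TIR/SEFIR
  domain;
* **NLR rule forbids LRRs** — the placozoan NLR inventory this rule set
  describes contains no LRR-bearing members; an NB-ARC+LRR protein is a
  different (canonical-NLR-like) architecture and must not inflate the
  inventory;
* the **giant LRR+TIR proteins** (~3000 AA, no TM) receive only the
  descriptive `TIR_DC` label plus a `giant_lrr_tir` flag: their receptor
  status is genuinely undecidable from architecture alone, so the engine
  records no functional claim.

### Evidence tiers

Pathway-ortholog support is reported as the full subset of four
independent tiers, never collapsed to one score (whether the tiers are
cumulative is not decidable from their definition, so the subset is the
honest output): (1) all expected domains observed; (2) KEGG KO matches the
node; (3) at least two of EggNOG OG, OrthoMCL OG and best Swiss-Prot hit
agree — "the best Swiss-Prot hit supports the node" is operationalised as
membership of the hit accession in the node's packaged allow-list; (4) a
phylogenetic-validation flag supplied as input (tree inference is upstream
of this package). The packaged roster covers the MyD88-dependent branch
only. A supported gene with missing expected domains is
`present_with_missing_domains` — the uncertain-homology case that the
IRAK-like kinases (no Death domain) and the NF-κB-like gene exemplify.

### Clusters and ortholog groups

Gene clusters are defined on adjacency: per-scaffold ordinal ranks, a run
of members with at most `max_gap` (default 1) intervening non-members, and
a minimum reported size of 2 (smaller runs are listed as singletons).
Adjacency rather than base-pair distance keeps the definition assembly-
scale-free; both knobs are exposed as CLI flags.

Ortholog groups are strictly per-query, one representative per subject
taxon: the lowest-e-value hit at a 1e-10 cutoff, ties broken by higher
bitscore then lexicographically smaller subject id. The tie-break beyond
the e-value is this package's own documented convention, exposed in the
API; hits to the query's own taxon are included by default and can be
excluded. No reciprocality is required.

## The synthetic-data generator

`h2_repertoire_spec()` encodes, template by template, the published
*Trichoplax* sp. H2 inventory: 16 TIR proteins (two ~3000-AA LRR+TIR
giants and two TIR+CARD MyD88-like adaptors among them), one SEFIR+DD
MyD88-like and one SEFIR+TM protein, 9+1 LRR single-TM receptor
candidates, 82 scavenger receptors (45 SRCR / 36 CTLD of which 28 are 7-TM
GPCRs / 1 CD36), 12 TM-less CTLD proteins (8 secreted), 18 SSF56496 FReD
models (two fibrillin-like), 15 PANTHER-only intelectins — the 31
intelectins placed as clusters of 9/8/5/4/3 genes plus two singletons —
one concrete arrangement with five clusters of between two and nine genes
and all but two genes clustered — 42 NLRs (3 NACHT / 39 NB-ARC; CARD/DLD effectors with two
DDs; WD40 or TPR repeats; 12 Apaf-1 architectures), 24 arrestins (17 at
consecutive ordinals on `scaffold_76`), two adjacent caspase+CARD genes,
one C1q-like factor, two CD109 genes, one DLD-bearing kinase, a clustered
set of five DD-less IRAK-like kinases, one NF-κB-like gene with two
adjacent RHD-only neighbours, and a TLR-pathway evidence cast (TRAF6,
TAK1, TAB2, IKKβ, NEMO, p38, JNK, Jun) carrying the mapping-table entries
that drive the tier logic. Twenty ankyrin-repeat decoys stand in for the
genome's large ANK background at desk scale, plus four targeted decoys
each violating exactly one named rule clause (TM-less SRCR → scavenger TM
clause; NB-ARC+LRR → NLR forbid clause; 500-AA secreted FReD → intelectin
length clause; CARD-only → MyD88-like require clause). No protein carries
a RIG-I, cGAS, STING or complement-factor accession.

What the generator emulates: annotation tables whose architecture
inventory, topology calls, gene order and mapping entries have the same
joint structure a real annotated genome would present to this pipeline.
What it does not emulate: sequence content (random amino-acid strings —
the pipeline never reads them analytically), annotation noise (missed or
spurious domains beyond the planted decoys), fragmented gene models,
assembly errors, and real inter-gene distances. Passing tests therefore
demonstrate that the *procedure* — rules, merging, orientation, tiers,
clustering, best-hit selection — is implemented correctly and
deterministically, not that any upstream annotation of a real genome is
accurate.

Determinism: one `random.Random(seed)` drives instantiation, layout,
coordinates and sequences in a fixed order, so a bundle regenerates byte
for byte under one seed; changing the seed permutes identifiers and
coordinates but cannot change any family count, because counts live in the
templates. Fixture scale (~300 proteins, the published totals plus decoys
and background) keeps every test and the acceptance recomputation at
desk scale — seconds on one CPU.

## Numerical and degenerate-input choices

* Empty annotation files parse to empty lists; an empty proteome yields an
  empty classification and all-zero counts, exit 0.
* Malformed rows (wrong column count, non-integer or inverted coordinates,
  overlapping TM segments, duplicate gene ids) reject the whole file with
  the offending row or identifier named — silent row-skipping would bias
  counts.
* Per-scaffold ordinals sort by (start, end, gene id), so parsing is stable
  under row permutation even with tied starts.
* Region boundaries: a midpoint exactly on the first-third boundary is
  N-terminal; exactly on the second is central (closed lower thirds).
* `best_hit_per_taxon` compares `(evalue, -bitscore, subject_id)` tuples;
  equality of all three makes the records interchangeable.

## Known limitations

* Positional thirds are a convention; proteins with extreme length
  asymmetry between domains may be assigned differently than a curator
  would.
* Membrane orientation for single-TM proteins without a signal peptide is
  a guess (flagged, never silently trusted).
* The evidence integrator validates neither the KO/OG assignments nor the
  phylogenetic flags it is given; garbage mappings in, garbage tiers out.
* Cluster detection by adjacency ignores base-pair distance entirely; on
  highly fragmented assemblies, scaffold boundaries truncate clusters.
* The rule set describes one genome's inventory conventions (e.g. the NLR
  LRR exclusion); applying it to other taxa may require editing the YAML,
  which is the supported path (`--rules`).
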