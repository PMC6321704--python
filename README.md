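# placorep

Rule-based annotation of an innate-immunity gene repertoire from protein
domain architectures.

Placozoans are the simplest free-living animals, yet they host intracellular
bacterial symbionts and must both manage those partners and fend off
pathogens. Surveying what their genomes encode for innate immunity —
pattern-recognition receptor candidates, scavenger receptors, secreted
lectins, NOD-like receptors, the Toll-like receptor (TLR) signalling
cascade — is an annotation problem: the genes are defined not by overall
sequence similarity but by *domain architecture* (which InterPro domains a
protein carries, where, on which side of the membrane) combined with
orthology evidence from independent mapping services.

`placorep` packages that annotation procedure as a reusable, testable
pipeline for anyone classifying an invertebrate proteome from standard
functional-annotation output. It never runs InterProScan, BLAST or Phobius
itself; it consumes their tabular results.

## What it does

* **Architectures** — merges redundant per-database InterProScan hits into
  ordered per-protein domain strings (same-accession hits reciprocally
  overlapping by >30 % of the shorter interval collapse into one domain),
  combined with signal-peptide/transmembrane topology.
* **Family rules** — a declarative rule engine over architectures:
  required/forbidden accession groups, occurrence counts, TM and
  signal-peptide constraints, positional constraints (N-terminal / central /
  C-terminal thirds; extracellular vs intracellular from membrane topology),
  and length bounds. The packaged rule set covers TIR/SEFIR adaptors,
  LRR + single-TM receptor candidates, MyD88-like adaptors, scavenger
  receptors (SRCR / CTLD / CD36 subclasses, including the 7-TM GPCR-CTLD
  class), secreted CTLD lectins, fibrinogen-related-domain (FReD) models and
  intelectins, NOD-like receptors (NLRs) and Apaf-1 architectures,
  arrestins, caspase+CARD genes, C1q-like factors, and absence screens for
  RIG-I, cGAS, STING and complement key factors.
* **Evidence tiers** — integrates, per TLR-pathway node, four independent
  support lines: (1) domain composition, (2) KEGG KO mapping, (3) agreement
  of two of {EggNOG OG, OrthoMCL OG, best Swiss-Prot hit}, (4) phylogenetic
  validation; genes with support but missing expected domains are flagged
  `present_with_missing_domains`.
* **Genomic clusters** — detects tandem clusters of family members on
  scaffolds by gene adjacency (ordinal ranks, tolerated gap of intervening
  non-members).
* **Ortholog groups** — per-taxon best-hit selection (lowest e-value at an
  e-value cutoff, ties by bitscore then subject id) and per-query group
  assembly over precomputed tabular homology hits, with FASTA export.
* **Synthetic fixtures** — a seeded generator that emits complete annotation
  bundles (FASTA, InterProScan-style TSV, topology TSV, GFF3, mapping
  tables, hit tables) from declarative specs, including the packaged
  `h2_repertoire_spec()` transcribing the published *Trichoplax* sp. H2
  inventory plus rule-violating decoys and a ground-truth manifest.

## Worked example

Generate the packaged H2-repertoire bundle and classify it:

```sh
placorep simulate --out demo/bundle --seed 42
placorep classify --domains demo/bundle/domains.tsv \
                  --topology demo/bundle/topology.tsv \
                  --mappings demo/bundle/mappings \
                  --out demo/cls
```

`demo/cls/summary.json` then contains (abridged):

```json
{
  "families": {
    "TIR_DC": 16,
    "scavenger_receptor": 82,
    "NLR": 42,
    "Apaf1_like": 12,
    "intelectin": 31,
    "arrestin": 24,
    "secreted_CTLD": 8,
    "fibrillin_like": 2
  },
  "subclasses": {
    "scavenger_receptor": {"SRCR_type": 45, "CTLD_type": 36,
                           "CD36_type": 1, "GPCR_CTLD": 28},
    "NLR": {"NACHT_type": 3, "NB_ARC_type": 39}
  },
  "fred_ssf56496": 18,
  "intelectin_panther_only": 15
}
```

Reading: of 297 synthetic proteins, 16 carry a TIR domain; 82 are
membrane scavenger receptors (45 SRCR-type, 36 CTLD-type of which 28 are
seven-TM GPCRs, 1 CD36); 42 are NLRs (39 with an NB-ARC NOD domain, 12 of
them Apaf-1 architectures); 18 gene models carry a FReD detectable only via
the SUPERFAMILY SSF56496 signature and 15 more are intelectins by PANTHER
mapping alone, 31 intelectins in total. The absence screens (RIG-I, cGAS,
STING, complement factors) all report zero, and every planted decoy (e.g. a
TM-less SRCR protein, an NB-ARC+LRR protein) is rejected by exactly the rule
clause it violates.

Cluster detection on the 31 intelectin genes:

```sh
placorep classify ... # as above, then collect intelectin gene ids
placorep clusters --gff demo/bundle/loci.gff3 --members intelectins.txt \
                  --family intelectin --out demo/clusters.tsv
# [placorep] 5 clusters (sizes [9, 8, 5, 4, 3]), 2 singletons
```

The evidence report (`placorep evidence ...`) marks TLR, IκBα, TRIF and
TBK1 absent, IRAK-like kinases and the NF-κB-like gene
`present_with_missing_domains` (no Death domain), and MyD88, TRAF6, TAK1,
the IKK components and the MAP-kinase branch present.

## Library use

```python
from placorep import (h2_repertoire_spec, generate_fixture, build_proteome,
                      builtin_ruleset, classify_proteome, summarize)
from placorep import io

bundle = generate_fixture(h2_repertoire_spec(seed=42), "bundle/")
archs = build_proteome(io.parse_interproscan_tsv(bundle.domains_tsv),
                       io.parse_topology_tsv(bundle.topology_tsv))
labels = classify_proteome(archs, builtin_ruleset(),
                           io.load_mapping_tables(bundle.mappings_dir))
```

See `docs/methods.md` for the conventions (coordinate system, positional
thirds, membrane orientation, tie-breaks) and their rationale.
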