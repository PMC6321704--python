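"""Seeded synthetic annotation bundles for end-to-end testing.

The generator emits everything the pipeline consumes — protein FASTA,
InterProScan-style domain TSV, topology TSV, GFF3 gene loci, mapping
tables, tabular homology hits and an ORF FASTA — from a declarative
:class:`FixtureSpec`, together with a ground-truth manifest of expected
labels per protein.

Sequences are random strings over the amino-acid alphabet: domain content
lives only in the annotation tables, because the pipeline operates on
annotation output and never re-detects domains.

:func:`h2_repertoire_spec` returns the packaged spec transcribing the
published *Trichoplax* sp. H2 inventory (TIR proteins, scavenger
receptors, intelectins and their genomic clusters, NOD-like receptors,
arrestins, pathway orthologs) plus rule-violating decoys.  Changing the
seed changes identifiers and coordinates but no family count; re-running
with one seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import vocab
from .io import (
    DomainHit,
    GeneLocus,
    HitRecord,
    MappingTables,
    TopologyCall,
    write_blast_tab,
    write_fasta,
    write_gff3_loci,
    write_interproscan_tsv,
    write_mapping_tables,
    write_topology_tsv,
)

__all__ = [
    "DomainTemplate",
    "ArchTemplate",
    "FixtureSpec",
    "FixtureBundle",
    "h2_repertoire_spec",
    "generate_fixture",
    "spec_to_yaml",
    "spec_from_yaml",
    "read_truth_manifest",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
BACKGROUND_SCAFFOLDS = tuple(f"scaffold_{i}" for i in range(1, 9))
ANNOTATION_DATE = "2019-01-05"


@dataclass(frozen=True)
class DomainTemplate:
    """One domain block: an accession key placed at fractional coordinates.

    ``copies`` > 1 spreads that many repeats evenly across the fractional
    window; a ``(min, max)`` range draws the repeat number per instance
    (family counts never depend on it).
    """

    key: str
    frac_start: float
    frac_end: float
    copies: int | tuple[int, int] = 1


@dataclass(frozen=True)
class ArchTemplate:
    """A protein blueprint instantiated ``count`` times."""

    name: str
    count: int
    domains: tuple[DomainTemplate, ...] = ()
    tm: tuple[tuple[float, float], ...] = ()  # fractional TM segments
    sp: bool = False
    length_range: tuple[int, int] = (200, 400)
    placements: tuple[str, ...] = ()  # per-instance: background|isolated|cluster:<scaffold>
    kegg_ko: str | None = None
    eggnog_og: str | None = None
    orthomcl_og: str | None = None
    swissprot: str | None = None
    panther: str | None = None
    phylo_nodes: tuple[str, ...] = ()
    expected_labels: tuple[str, ...] = ()
    expected_subclasses: tuple[str, ...] = ()  # "family:subclass"
    expected_flags: tuple[str, ...] = ()
    decoy_for: str = ""

    def placement(self, i: int) -> str:
        return self.placements[i] if self.placements else "background"

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"template {self.name}: count must be >= 1")
        if self.placements and len(self.placements) != self.count:
            raise ValueError(
                f"template {self.name}: {len(self.placements)} placements for "
                f"{self.count} instances"
            )


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    entries: tuple[ArchTemplate, ...]

    def __post_init__(self) -> None:
        for t in self.entries:
            for d in t.domains:
                if d.key not in vocab.SIGNATURES:
                    raise ValueError(
                        f"template {t.name}: key {d.key!r} not in the rule vocabulary"
                    )


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of one generated bundle."""

    root: Path

    @property
    def proteins_fasta(self) -> Path:
        return self.root / "proteins.fasta"

    @property
    def domains_tsv(self) -> Path:
        return self.root / "domains.tsv"

    @property
    def topology_tsv(self) -> Path:
        return self.root / "topology.tsv"

    @property
    def loci_gff3(self) -> Path:
        return self.root / "loci.gff3"

    @property
    def mappings_dir(self) -> Path:
        return self.root / "mappings"

    @property
    def phylo_tsv(self) -> Path:
        return self.root / "mappings" / "phylo.tsv"

    @property
    def hits_tsv(self) -> Path:
        return self.root / "hits.tsv"

    @property
    def orfs_fasta(self) -> Path:
        return self.root / "orfs.fasta"

    @property
    def truth_manifest(self) -> Path:
        return self.root / "truth_manifest.tsv"


# ---------------------------------------------------------------------------
# the packaged H2-repertoire spec
# ---------------------------------------------------------------------------

def h2_repertoire_spec(seed: int = 42) -> FixtureSpec:
    """Spec transcribing the published H2 repertoire inventory + decoys.

    Printed totals encoded here: 16 TIR proteins (2 giant LRR+TIR, 2
    MyD88-like TIR+CARD among them), 9+1 LRR single-TM candidates, 1
    SEFIR+TM, 1 MyD88-like SEFIR+DD, 82 scavenger receptors (45 SRCR + 36
    CTLD of which 28 are 7-TM GPCRs + 1 CD36), 12 TM-less CTLD proteins (8
    secreted), 18 SSF56496 FReD models (2 fibrillin-like), 15 PANTHER-only
    intelectins (11 secreted; the 31 intelectins form 5 clusters of sizes
    9/8/5/4/3 plus 2 singletons), 42 NLRs (3 NACHT / 39 NB-ARC, 12 Apaf-1
    architectures, 2 DD effectors, WD40 or TPR repeats, no LRRs), 24
    arrestins (17 in a tight cluster on scaffold_76), 2 adjacent
    caspase+CARD genes, 1 C1q-like, 2 CD109, 1 DLD kinase, a clustered set
    of DD-less IRAK-like kinases, 1 NF-kB-like with 2 adjacent RHD-only
    genes, 20 ankyrin-repeat decoys, and no RIG-I/cGAS/STING/complement
    accessions anywhere.
    """
    V = vocab
    T, D = ArchTemplate, DomainTemplate
    itln = V.PANTHER_INTELECTIN
    entries: list[ArchTemplate] = [
        # --- TIR / SEFIR repertoire (16 TIR proteins in total) ------------
        T("tir_plain", 12, (D(V.TIR, 0.50, 0.72),), length_range=(300, 600),
          expected_labels=("TIR_DC",)),
        T("tir_lrr_giant", 2,
          (D(V.LRR, 0.05, 0.38, copies=4), D(V.ANK, 0.44, 0.62, copies=2),
           D(V.TIR, 0.78, 0.88)),
          length_range=(2900, 3100),
          expected_labels=("TIR_DC",), expected_flags=("giant_lrr_tir",)),
        T("myd88_tir_card", 2, (D(V.CARD, 0.05, 0.18), D(V.TIR, 0.55, 0.78)),
          length_range=(280, 360),
          kegg_ko="K04729", eggnog_og="KOG_MYD88", orthomcl_og="OG_MYD88",
          swissprot="Q99836", phylo_nodes=("MyD88",),
          expected_labels=("MyD88_like", "TIR_DC")),
        T("myd88_sefir_dd", 1, (D(V.DD, 0.05, 0.18), D(V.SEFIR, 0.55, 0.78)),
          length_range=(290, 340),
          expected_labels=("MyD88_like", "SEFIR_DC")),
        T("sefir_tm", 1, (D(V.SEFIR, 0.55, 0.80),), tm=((0.35, 0.40),), sp=True,
          length_range=(420, 520),
          expected_labels=("SEFIR_DC", "SEFIR_TM")),
        # --- candidate extracellular receptor arms ------------------------
        T("lrr_tm", 9, (D(V.LRR, 0.08, 0.52, copies=3),), tm=((0.62, 0.67),),
          sp=True, length_range=(600, 800),
          expected_labels=("LRR_TM_candidate",)),
        T("lrr_tm_ig", 1,
          (D(V.LRR, 0.08, 0.38, copies=2), D(V.IG_LIKE, 0.44, 0.56)),
          tm=((0.62, 0.67),), sp=True, length_range=(650, 800),
          expected_labels=("LRR_TM_candidate",)),
        # --- scavenger receptors (82) --------------------------------------
        T("sr_srcr", 45, (D(V.SRCR, 0.08, 0.55, copies=(1, 6)),),
          tm=((0.68, 0.73),), sp=True, length_range=(500, 1500),
          expected_labels=("scavenger_receptor",),
          expected_subclasses=("scavenger_receptor:SRCR_type",)),
        T("sr_ctld_1tm", 8, (D(V.CTLD, 0.08, 0.50, copies=(1, 2)),),
          tm=((0.68, 0.73),), sp=True, length_range=(450, 900),
          expected_labels=("scavenger_receptor",),
          expected_subclasses=("scavenger_receptor:CTLD_type",)),
        T("sr_gpcr_ctld", 28,
          (D(V.CTLD, 0.05, 0.22), D(V.GPCR_SECRETIN, 0.44, 0.92)),
          tm=tuple((0.40 + 0.08 * i, 0.42 + 0.08 * i) for i in range(7)),
          sp=True, length_range=(700, 1100),
          expected_labels=("scavenger_receptor",),
          expected_subclasses=("scavenger_receptor:CTLD_type",
                               "scavenger_receptor:GPCR_CTLD")),
        T("sr_cd36", 1, (D(V.CD36, 0.15, 0.80),),
          tm=((0.04, 0.07), (0.88, 0.92)), length_range=(450, 520),
          expected_labels=("scavenger_receptor",),
          expected_subclasses=("scavenger_receptor:CD36_type",)),
        # --- TM-less CTLD proteins (12, 8 secreted) ------------------------
        T("ctld_secreted", 8, (D(V.CTLD, 0.25, 0.80, copies=(1, 3)),), sp=True,
          length_range=(160, 400), expected_labels=("secreted_CTLD",)),
        T("ctld_notm_nosp", 4, (D(V.CTLD, 0.25, 0.80, copies=(1, 3)),),
          length_range=(160, 400)),
        # --- FReD repertoire ----------------------------------------------
        T("intelectin_ssf", 15, (D(V.SSF_FRED, 0.10, 0.38),), sp=True,
          length_range=(230, 280), panther=itln,
          placements=tuple(["cluster:scaffold_12"] * 5
                           + ["cluster:scaffold_13"] * 5
                           + ["cluster:scaffold_14"] * 5),
          expected_labels=("FReD_model", "intelectin")),
        T("intelectin_ssf_nosp", 1, (D(V.SSF_FRED, 0.10, 0.38),),
          length_range=(230, 280), panther=itln,
          placements=("cluster:scaffold_12",),
          expected_labels=("FReD_model", "intelectin")),
        T("fibrillin_like_fred", 2,
          (D(V.EGF_CA, 0.10, 0.70, copies=4), D(V.SSF_FRED, 0.84, 0.92)),
          sp=True, length_range=(2800, 3200),
          expected_labels=("FReD_model", "fibrillin_like")),
        T("intelectin_panther_sp", 11, (), sp=True, length_range=(200, 300),
          panther=itln,
          placements=tuple(["cluster:scaffold_12"] * 3
                           + ["cluster:scaffold_13"] * 3
                           + ["cluster:scaffold_15"] * 3
                           + ["cluster:scaffold_16"] * 2),
          expected_labels=("intelectin",)),
        T("intelectin_panther_nosp", 4, (), length_range=(200, 300),
          panther=itln,
          placements=("cluster:scaffold_15", "cluster:scaffold_16",
                      "isolated", "isolated"),
          expected_labels=("intelectin",)),
        # --- NOD-like receptors (42) ---------------------------------------
        T("apaf_card_wd40", 10,
          (D(V.CARD, 0.03, 0.12), D(V.NB_ARC, 0.42, 0.58),
           D(V.WD40, 0.72, 0.96, copies=3)),
          length_range=(1000, 1400),
          placements=tuple(["cluster:scaffold_20"] * 3 + ["background"] * 7),
          expected_labels=("Apaf1_like", "NLR"),
          expected_subclasses=("NLR:NB_ARC_type", "NLR:effector_CARD",
                               "NLR:repeat_WD40")),
        T("apaf_dld_wd40", 2,
          (D(V.DLD, 0.03, 0.12), D(V.NB_ARC, 0.42, 0.58),
           D(V.WD40, 0.72, 0.96, copies=3)),
          length_range=(1000, 1400),
          expected_labels=("Apaf1_like", "NLR"),
          expected_subclasses=("NLR:NB_ARC_type", "NLR:effector_DLD",
                               "NLR:repeat_WD40")),
        T("nlr_card_tpr", 15,
          (D(V.CARD, 0.03, 0.12), D(V.NB_ARC, 0.42, 0.58),
           D(V.TPR, 0.72, 0.96, copies=(2, 4))),
          length_range=(900, 1300),
          placements=tuple(["cluster:scaffold_20"] * 3 + ["background"] * 12),
          expected_labels=("NLR",),
          expected_subclasses=("NLR:NB_ARC_type", "NLR:effector_CARD",
                               "NLR:repeat_TPR")),
        T("nlr_dld_tpr", 6,
          (D(V.DLD, 0.03, 0.12), D(V.NB_ARC, 0.42, 0.58),
           D(V.TPR, 0.72, 0.96, copies=(2, 4))),
          length_range=(900, 1300),
          expected_labels=("NLR",),
          expected_subclasses=("NLR:NB_ARC_type", "NLR:effector_DLD",
                               "NLR:repeat_TPR")),
        T("nlr_dd_wd40", 2,
          (D(V.DD, 0.03, 0.12), D(V.NB_ARC, 0.42, 0.58),
           D(V.WD40, 0.72, 0.96, copies=3)),
          length_range=(900, 1300),
          expected_labels=("NLR",),
          expected_subclasses=("NLR:NB_ARC_type", "NLR:effector_DD",
                               "NLR:repeat_WD40")),
        T("nlr_plain_wd40", 4,
          (D(V.NB_ARC, 0.42, 0.58), D(V.WD40, 0.72, 0.96, copies=3)),
          length_range=(800, 1200),
          expected_labels=("NLR",),
          expected_subclasses=("NLR:NB_ARC_type", "NLR:repeat_WD40")),
        T("nlr_nacht_card_tpr", 2,
          (D(V.CARD, 0.03, 0.12), D(V.NACHT, 0.42, 0.58),
           D(V.TPR, 0.72, 0.96, copies=3)),
          length_range=(900, 1300),
          expected_labels=("NLR",),
          expected_subclasses=("NLR:NACHT_type", "NLR:effector_CARD",
                               "NLR:repeat_TPR")),
        T("nlr_nacht_dld_wd40", 1,
          (D(V.DLD, 0.03, 0.12), D(V.NACHT, 0.42, 0.58),
           D(V.WD40, 0.72, 0.96, copies=3)),
          length_range=(900, 1300),
          expected_labels=("NLR",),
          expected_subclasses=("NLR:NACHT_type", "NLR:effector_DLD",
                               "NLR:repeat_WD40")),
        # --- apoptosis, complement-adjacent, arrestins ---------------------
        T("caspase_card", 2, (D(V.CARD, 0.04, 0.15), D(V.CASPASE, 0.45, 0.80)),
          length_range=(400, 500), placements=("cluster:scaffold_60",) * 2,
          expected_labels=("caspase_CARD",)),
        T("c1q_like_gene", 1, (D(V.C1Q, 0.50, 0.88),), sp=True,
          length_range=(230, 260), expected_labels=("C1q_like",)),
        T("cd109", 2, (D(V.A2M, 0.25, 0.85),), sp=True,
          length_range=(1350, 1450), expected_labels=("a2m_family",)),
        T("arrestin_cluster", 17,
          (D(V.ARRESTIN_N, 0.06, 0.32), D(V.ARRESTIN_C, 0.62, 0.92)),
          length_range=(350, 450), placements=("cluster:scaffold_76",) * 17,
          expected_labels=("arrestin",)),
        T("arrestin_scattered", 7,
          (D(V.ARRESTIN_N, 0.06, 0.32), D(V.ARRESTIN_C, 0.62, 0.92)),
          length_range=(350, 450), placements=("isolated",) * 7,
          expected_labels=("arrestin",)),
        # --- TLR-pathway evidence genes ------------------------------------
        T("dld_kinase", 1, (D(V.DLD, 0.04, 0.14), D(V.KINASE, 0.40, 0.72)),
          length_range=(450, 550), expected_labels=("death_kinase",)),
        T("irak_like", 5, (D(V.KINASE, 0.35, 0.70),), length_range=(350, 600),
          kegg_ko="K04730", placements=("cluster:scaffold_40",) * 5),
        T("nfkb_like_gene", 1,
          (D(V.RHD, 0.08, 0.32), D(V.ANK, 0.50, 0.90, copies=3)),
          length_range=(900, 1100), kegg_ko="K02580",
          eggnog_og="KOG_NFKB", orthomcl_og="OG_NFKB",
          placements=("cluster:scaffold_52",),
          expected_labels=("nfkb_like", "rel_family")),
        T("rhd_only", 2, (D(V.RHD, 0.25, 0.60),), length_range=(300, 450),
          placements=("cluster:scaffold_52",) * 2,
          expected_labels=("rel_family",)),
        T("traf6_like", 1, (D(V.TRAF, 0.30, 0.70),), length_range=(500, 600),
          kegg_ko="K03175", eggnog_og="KOG_TRAF6", orthomcl_og="OG_TRAF6",
          swissprot="Q9Y4K3", phylo_nodes=("TRAF6",)),
        T("tak1_like", 1, (D(V.KINASE, 0.30, 0.70),), length_range=(550, 650),
          kegg_ko="K04427", eggnog_og="KOG_TAK1", orthomcl_og="OG_TAK1",
          swissprot="O43318", phylo_nodes=("TAK1",)),
        T("tab2_like", 1, (D(V.CUE, 0.20, 0.40),), length_range=(600, 700),
          kegg_ko="K04404", eggnog_og="KOG_TAB2", orthomcl_og="OG_TAB2"),
        T("ikkb_like", 1, (D(V.KINASE, 0.10, 0.45),), length_range=(700, 800),
          kegg_ko="K07209", eggnog_og="KOG_IKKB", orthomcl_og="OG_IKKB",
          swissprot="O14920"),
        T("nemo_like", 1, (D(V.NEMO_N, 0.05, 0.30),), length_range=(380, 450),
          kegg_ko="K07210", eggnog_og="KOG_NEMO", orthomcl_og="OG_NEMO"),
        T("p38_like", 1, (D(V.KINASE, 0.15, 0.85),), length_range=(350, 400),
          kegg_ko="K04441", eggnog_og="KOG_P38", orthomcl_og="OG_P38",
          swissprot="Q16539"),
        T("jnk_like", 1, (D(V.KINASE, 0.15, 0.85),), length_range=(380, 430),
          kegg_ko="K04440", eggnog_og="KOG_JNK", orthomcl_og="OG_JNK"),
        T("jun_like", 1, (D(V.BZIP, 0.55, 0.75),), length_range=(280, 340),
          kegg_ko="K04448", eggnog_og="KOG_JUN", orthomcl_og="OG_JUN",
          swissprot="P05412"),
        # --- decoys ---------------------------------------------------------
        T("ank_decoy", 20, (D(V.ANK, 0.20, 0.80, copies=(2, 4)),),
          length_range=(300, 900), decoy_for="ankyrin_background"),
        T("decoy_srcr_no_tm", 1, (D(V.SRCR, 0.10, 0.50, copies=2),), sp=True,
          length_range=(300, 500), decoy_for="scavenger_receptor:tm"),
        T("decoy_nbarc_lrr", 1,
          (D(V.CARD, 0.03, 0.10), D(V.NB_ARC, 0.42, 0.58),
           D(V.LRR, 0.72, 0.96, copies=2)),
          length_range=(900, 1200), decoy_for="NLR:forbid"),
        T("decoy_fred_long", 1, (D(V.FRED, 0.30, 0.55),), sp=True,
          length_range=(480, 520), expected_labels=("FReD_model",),
          decoy_for="intelectin/by_architecture:max_length"),
        T("decoy_card_only", 1, (D(V.CARD, 0.05, 0.20),),
          length_range=(250, 350), decoy_for="MyD88_like:require_any[0]"),
        # --- background filler ---------------------------------------------
        T("filler", 30, (), length_range=(150, 400)),
    ]
    return FixtureSpec(seed=seed, entries=tuple(entries))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class _Instance:
    protein_id: str
    template: ArchTemplate
    index: int
    length: int
    placement: str
    topo: TopologyCall | None = None
    hits: list[DomainHit] = field(default_factory=list)


def _instantiate(spec: FixtureSpec, rng: random.Random) -> list[_Instance]:
    instances: list[_Instance] = []
    for t in spec.entries:
        for i in range(t.count):
            instances.append(
                _Instance(
                    protein_id="",
                    template=t,
                    index=i,
                    length=rng.randint(*t.length_range),
                    placement=t.placement(i),
                )
            )
    numbers = rng.sample(range(10000, 100000), len(instances))
    for inst, num in zip(instances, numbers):
        inst.protein_id = f"TriH2_{num:05d}"
    return instances


def _make_topology(inst: _Instance, rng: random.Random) -> TopologyCall:
    t, L = inst.template, inst.length
    sp_end = rng.randint(17, 28) if t.sp else None
    segments = []
    for fs, fe in t.tm:
        s = max(1, round(fs * L))
        e = min(L, max(s + 10, round(fe * L)))
        segments.append((s, e))
    return TopologyCall(
        protein_id=inst.protein_id,
        length=L,
        has_signal_peptide=t.sp,
        sp_end=sp_end,
        tm_segments=tuple(segments),
    )


def _domain_rows(inst: _Instance, rng: random.Random) -> list[DomainHit]:
    t, L = inst.template, inst.length
    rows: list[DomainHit] = []
    for d in t.domains:
        n = d.copies if isinstance(d.copies, int) else rng.randint(*d.copies)
        step = (d.frac_end - d.frac_start) / n
        width = 0.7 * step
        for i in range(n):
            fs = d.frac_start + i * step
            s = max(1, round(fs * L))
            e = min(L, max(s, round((fs + width) * L)))
            analysis, sig, desc, ipr, ipr_desc = vocab.SIGNATURES[d.key]
            score = 10 ** -rng.uniform(6.0, 40.0)
            rows.append(
                DomainHit(
                    protein_id=inst.protein_id,
                    analysis=analysis,
                    signature_acc=sig,
                    signature_desc=desc,
                    start=s,
                    end=e,
                    seq_length=L,
                    score=score,
                    interpro_acc=ipr,
                    interpro_desc=None if ipr is None else ipr_desc,
                    date=ANNOTATION_DATE,
                )
            )
            if d.key in vocab.SECONDARY_SIGNATURES:
                # a redundant same-domain hit from a second member database,
                # jittered but well above the merge-overlap threshold
                a2, sig2, desc2 = vocab.SECONDARY_SIGNATURES[d.key]
                s2 = max(1, s + rng.randint(-6, 6))
                e2 = min(L, max(s2 + 5, e + rng.randint(-6, 6)))
                rows.append(
                    DomainHit(
                        protein_id=inst.protein_id,
                        analysis=a2,
                        signature_acc=sig2,
                        signature_desc=desc2,
                        start=s2,
                        end=e2,
                        seq_length=L,
                        score=10 ** -rng.uniform(6.0, 40.0),
                        interpro_acc=ipr,
                        interpro_desc=None if ipr is None else ipr_desc,
                        date=ANNOTATION_DATE,
                    )
                )
    rows.sort(key=lambda h: (h.start, h.end, h.signature_acc))
    return rows


def _layout(
    instances: Sequence[_Instance], rng: random.Random
) -> dict[str, list[_Instance]]:
    """Assign every instance a scaffold and an order along it."""
    clusters: dict[str, list[_Instance]] = {}
    isolated: list[_Instance] = []
    background: list[_Instance] = []
    for inst in instances:
        if inst.placement.startswith("cluster:"):
            clusters.setdefault(inst.placement.split(":", 1)[1], []).append(inst)
        elif inst.placement == "isolated":
            isolated.append(inst)
        else:
            background.append(inst)
    rng.shuffle(background)
    scaffolds: dict[str, list[_Instance]] = {s: [] for s in BACKGROUND_SCAFFOLDS}
    for i, inst in enumerate(background):
        scaffolds[BACKGROUND_SCAFFOLDS[i % len(BACKGROUND_SCAFFOLDS)]].append(inst)
    # isolated instances: one per background scaffold in rotation, inserted
    # at spread positions so no two family members become neighbours
    per_scaffold: dict[str, list[_Instance]] = {}
    for j, inst in enumerate(isolated):
        per_scaffold.setdefault(
            BACKGROUND_SCAFFOLDS[j % len(BACKGROUND_SCAFFOLDS)], []
        ).append(inst)
    for scaffold, insts in per_scaffold.items():
        base = scaffolds[scaffold]
        for k, inst in enumerate(insts):
            pos = (k + 1) * (len(base) + 1) // (len(insts) + 1)
            base.insert(min(pos, len(base)), inst)
    scaffolds.update({s: members for s, members in clusters.items()})
    return {s: scaffolds[s] for s in sorted(scaffolds)}


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> FixtureBundle:
    """Write a complete annotation bundle under ``out_dir``.

    Deterministic given ``spec.seed``: re-running produces byte-identical
    files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    instances = _instantiate(spec, rng)
    for inst in instances:
        inst.topo = _make_topology(inst, rng)
        inst.hits = _domain_rows(inst, rng)

    layout = _layout(instances, rng)
    loci: list[GeneLocus] = []
    for scaffold, members in layout.items():
        cur = rng.randint(1000, 5000)
        for inst in members:
            glen = 3 * inst.length + rng.randint(100, 800)
            loci.append(
                GeneLocus(
                    gene_id=inst.protein_id,
                    scaffold=scaffold,
                    start=cur,
                    end=cur + glen,
                    strand=rng.choice("+-"),
                )
            )
            cur += glen + rng.randint(300, 4000)

    sequences = {
        inst.protein_id: "".join(rng.choices(AA_ALPHABET, k=inst.length))
        for inst in instances
    }

    tables = MappingTables()
    phylo_rows: list[tuple[str, str]] = []
    for inst in instances:
        t = inst.template
        if t.kegg_ko:
            tables.kegg_ko[inst.protein_id] = t.kegg_ko
        if t.eggnog_og:
            tables.eggnog_og[inst.protein_id] = t.eggnog_og
        if t.orthomcl_og:
            tables.orthomcl_og[inst.protein_id] = t.orthomcl_og
        if t.swissprot:
            tables.swissprot_best[inst.protein_id] = t.swissprot
        if t.panther:
            tables.panther_family[inst.protein_id] = t.panther
        for node in t.phylo_nodes:
            phylo_rows.append((inst.protein_id, node))

    hits, orfs = _homology_table(rng)

    write_fasta(out / "proteins.fasta", sequences)
    write_interproscan_tsv(out / "domains.tsv", [h for i in instances for h in i.hits])
    write_topology_tsv(out / "topology.tsv", [i.topo for i in instances])
    write_gff3_loci(out / "loci.gff3", loci)
    write_mapping_tables(out / "mappings", tables)
    (out / "mappings" / "phylo.tsv").write_text(
        "".join(f"{g}\t{n}\n" for g, n in sorted(phylo_rows))
    )
    write_blast_tab(out / "hits.tsv", hits)
    write_fasta(out / "orfs.fasta", orfs)
    _write_manifest(out / "truth_manifest.tsv", instances)
    return FixtureBundle(root=out)


#: reference queries and taxa of the synthetic homology table
HOMOLOGY_QUERIES = (
    "HSAP|MYD88", "HSAP|TRAF6", "HSAP|MAP3K7", "HSAP|IKBKB", "HSAP|MAPK14",
    "HSAP|JUN",
)
HOMOLOGY_TAXA = ("HSAP", "MMUS", "DMEL", "CELE", "NVEC", "AQUE", "TADH", "TRH2")


def _homology_table(rng: random.Random) -> tuple[list[HitRecord], dict[str, str]]:
    hits: list[HitRecord] = []
    orfs: dict[str, str] = {}
    for q in HOMOLOGY_QUERIES:
        gene = q.split("|", 1)[1]
        for taxon in HOMOLOGY_TAXA:
            for j in range(rng.randint(1, 3)):
                subject = f"{taxon}|{gene}_{j}"
                evalue = 10 ** -rng.uniform(2.0, 60.0)
                bitscore = round(40 + 1.8 * -math.log10(evalue) + rng.uniform(0, 5), 1)
                if subject not in orfs:
                    orfs[subject] = "".join(
                        rng.choices(AA_ALPHABET, k=rng.randint(90, 300))
                    )
                hits.append(
                    HitRecord(
                        query_id=q,
                        subject_id=subject,
                        subject_taxon=taxon,
                        percent_identity=round(rng.uniform(20, 95), 1),
                        align_length=rng.randint(80, 400),
                        extra=(
                            str(rng.randint(0, 120)),
                            str(rng.randint(0, 12)),
                            "1", "100", "1", "100",
                        ),
                        evalue=evalue,
                        bitscore=bitscore,
                    )
                )
    return hits, orfs


def _write_manifest(path: Path, instances: Sequence[_Instance]) -> None:
    lines = ["protein_id\ttemplate\tlabels\tsubclasses\tflags\tdecoy_for"]
    for inst in sorted(instances, key=lambda i: i.protein_id):
        t = inst.template
        lines.append(
            "\t".join(
                [
                    inst.protein_id,
                    t.name,
                    ";".join(sorted(t.expected_labels)),
                    ";".join(sorted(t.expected_subclasses)),
                    ";".join(sorted(t.expected_flags)),
                    t.decoy_for or "-",
                ]
            )
        )
    path.write_text("".join(line + "\n" for line in lines))


def read_truth_manifest(path: str | Path) -> list[dict[str, object]]:
    rows = []
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        pid, template, labels, subs, flags, decoy = line.split("\t")
        rows.append(
            {
                "protein_id": pid,
                "template": template,
                "labels": frozenset(l for l in labels.split(";") if l),
                "subclasses": frozenset(s for s in subs.split(";") if s),
                "flags": frozenset(f for f in flags.split(";") if f),
                "decoy_for": "" if decoy == "-" else decoy,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# YAML (de)serialisation of specs
# ---------------------------------------------------------------------------

def spec_to_yaml(spec: FixtureSpec, path: str | Path) -> None:
    doc = {
        "seed": spec.seed,
        "entries": [
            {
                "name": t.name,
                "count": t.count,
                "domains": [
                    {
                        "key": d.key,
                        "frac_start": d.frac_start,
                        "frac_end": d.frac_end,
                        "copies": list(d.copies)
                        if isinstance(d.copies, tuple)
                        else d.copies,
                    }
                    for d in t.domains
                ],
                "tm": [list(seg) for seg in t.tm],
                "sp": t.sp,
                "length_range": list(t.length_range),
                "placements": list(t.placements),
                "kegg_ko": t.kegg_ko,
                "eggnog_og": t.eggnog_og,
                "orthomcl_og": t.orthomcl_og,
                "swissprot": t.swissprot,
                "panther": t.panther,
                "phylo_nodes": list(t.phylo_nodes),
                "expected_labels": list(t.expected_labels),
                "expected_subclasses": list(t.expected_subclasses),
                "expected_flags": list(t.expected_flags),
                "decoy_for": t.decoy_for,
            }
            for t in spec.entries
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def spec_from_yaml(path: str | Path) -> FixtureSpec:
    doc = yaml.safe_load(Path(path).read_text())
    entries = []
    for d in doc["entries"]:
        entries.append(
            ArchTemplate(
                name=d["name"],
                count=d["count"],
                domains=tuple(
                    DomainTemplate(
                        key=x["key"],
                        frac_start=x["frac_start"],
                        frac_end=x["frac_end"],
                        copies=tuple(x["copies"])
                        if isinstance(x["copies"], list)
                        else x["copies"],
                    )
                    for x in d.get("domains", [])
                ),
                tm=tuple(tuple(seg) for seg in d.get("tm", [])),
                sp=d.get("sp", False),
                length_range=tuple(d["length_range"]),
                placements=tuple(d.get("placements", [])),
                kegg_ko=d.get("kegg_ko"),
                eggnog_og=d.get("eggnog_og"),
                orthomcl_og=d.get("orthomcl_og"),
                swissprot=d.get("swissprot"),
                panther=d.get("panther"),
                phylo_nodes=tuple(d.get("phylo_nodes", [])),
                expected_labels=tuple(d.get("expected_labels", [])),
                expected_subclasses=tuple(d.get("expected_subclasses", [])),
                expected_flags=tuple(d.get("expected_flags", [])),
                decoy_for=d.get("decoy_for", ""),
            )
        )
    return FixtureSpec(seed=doc["seed"], entries=tuple(entries))
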