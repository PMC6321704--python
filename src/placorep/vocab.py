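"""Controlled vocabulary of domain accession keys used by the rule set.

A *key* identifies one detectable domain class.  Keys are InterPro
accessions (``IPR######``) wherever the member-database hit carries one;
hits that lack an InterPro mapping are keyed ``"<analysis>:<signature>"``
(the fibrinogen C-terminal globular fold is only reachable through the
SUPERFAMILY signature SSF56496, so it is such a key).
"""

from __future__ import annotations

# -- extracellular recognition -------------------------------------------
LRR = "IPR032675"  # leucine-rich repeat
TIR = "IPR000157"  # Toll/interleukin-1 receptor homology domain
SEFIR = "IPR013568"  # SEF/IL-17R (SEFIR) domain
CTLD = "IPR001304"  # C-type lectin domain
SRCR = "IPR001190"  # scavenger receptor cysteine-rich domain
CD36 = "IPR002159"  # CD36 family
FRED = "IPR002181"  # fibrinogen-related domain (C-terminal globular)
SSF_FRED = "SUPERFAMILY:SSF56496"  # fibrinogen C-terminal domain-like fold

# -- intracellular sensing -----------------------------------------------
NACHT = "IPR007111"
NB_ARC = "IPR002182"
RIG_I_CTD = "IPR021673"  # RIG-I C-terminal regulatory domain
MAB21 = "IPR024810"  # Mab-21 domain of cGAS
STING_A = "IPR029158"
STING_B = "IPR033952"

# -- Death-clan protein-interaction domains ------------------------------
DD = "IPR000488"  # Death domain
CARD = "IPR001315"  # caspase recruitment domain
DED = "IPR001875"  # death effector domain
PYD = "IPR004020"  # pyrin domain
DLD = "IPR011029"  # death-like domain fold

# -- repeats and folds ----------------------------------------------------
WD40 = "IPR001680"
TPR = "IPR019734"
ANK = "IPR002110"
IG_LIKE = "IPR007110"
EGF_CA = "IPR001881"  # calcium-binding EGF-like (fibrillin-type proteins)

# -- signalling / effectors ----------------------------------------------
ARRESTIN_N = "IPR011021"
ARRESTIN_C = "IPR011022"
RHD = "IPR011539"  # Rel homology DNA-binding domain
KINASE = "IPR000719"  # protein kinase catalytic domain
CASPASE = "IPR011600"  # peptidase C14, caspase-like
GPCR_SECRETIN = "IPR000832"  # GPCR family 2, secretin/adhesion-like
BZIP = "IPR004827"
TRAF = "IPR008974"  # TRAF-like
CUE = "IPR003892"  # ubiquitin-binding (TAB2-like adaptor)
NEMO_N = "IPR034735"

# -- complement-related ---------------------------------------------------
C1Q = "IPR001073"
A2M = "IPR001599"  # alpha-2-macroglobulin family (CD109)
C345C = "IPR001134"  # complement C3/C4/C5 C-terminal domain
ANAPHYLATOXIN = "IPR000020"

#: PANTHER family label used by the mapping-table route to intelectins.
PANTHER_INTELECTIN = "PTHR12119:intelectin"

#: every key the packaged rule set and fixture generator may reference
KNOWN_KEYS: frozenset[str] = frozenset(
    v
    for k, v in list(globals().items())
    if k.isupper() and isinstance(v, str) and k not in {"PANTHER_INTELECTIN"}
)

#: member-database metadata used when keys are written back to
#: InterProScan-style TSV: key -> (analysis, signature_acc, signature_desc,
#: interpro_acc or None, interpro_desc)
SIGNATURES: dict[str, tuple[str, str, str, str | None, str]] = {
    LRR: ("Pfam", "PF13855", "Leucine rich repeat", LRR, "Leucine-rich repeat"),
    TIR: ("Pfam", "PF01582", "TIR domain", TIR, "Toll/interleukin-1 receptor homology (TIR) domain"),
    SEFIR: ("Pfam", "PF08357", "SEFIR domain", SEFIR, "SEFIR domain"),
    CTLD: ("Pfam", "PF00059", "Lectin C-type domain", CTLD, "C-type lectin-like"),
    SRCR: ("Pfam", "PF00530", "Scavenger receptor cysteine-rich domain", SRCR, "SRCR domain"),
    CD36: ("Pfam", "PF01130", "CD36 family", CD36, "CD36 family"),
    FRED: ("Pfam", "PF00147", "Fibrinogen beta and gamma chains, C-terminal globular domain", FRED, "Fibrinogen, alpha/beta/gamma chain, C-terminal globular domain"),
    SSF_FRED: ("SUPERFAMILY", "SSF56496", "Fibrinogen C-terminal domain-like", None, "-"),
    NACHT: ("Pfam", "PF05729", "NACHT domain", NACHT, "NACHT nucleoside triphosphatase"),
    NB_ARC: ("Pfam", "PF00931", "NB-ARC domain", NB_ARC, "NB-ARC"),
    RIG_I_CTD: ("Pfam", "PF11648", "RIG-I C-terminal regulatory domain", RIG_I_CTD, "RIG-I receptor, C-terminal"),
    MAB21: ("Pfam", "PF03281", "Mab-21 protein", MAB21, "Mab-21 domain"),
    STING_A: ("Pfam", "PF15009", "TMEM173 / STING", STING_A, "Stimulator of interferon genes protein"),
    STING_B: ("Gene3D", "G3DSA:3.40.50.12100", "STING, C-terminal binding domain", STING_B, "Stimulator of interferon genes protein, C-terminal"),
    DD: ("Pfam", "PF00531", "Death domain", DD, "Death domain"),
    CARD: ("Pfam", "PF00619", "Caspase recruitment domain", CARD, "CARD domain"),
    DED: ("Pfam", "PF01335", "Death effector domain", DED, "Death effector domain"),
    PYD: ("Pfam", "PF02758", "PAAD/DAPIN/Pyrin domain", PYD, "Pyrin domain"),
    DLD: ("Gene3D", "G3DSA:1.10.533.10", "Death-like domain", DLD, "Death-like domain superfamily"),
    WD40: ("Pfam", "PF00400", "WD domain, G-beta repeat", WD40, "WD40 repeat"),
    TPR: ("Pfam", "PF00515", "Tetratricopeptide repeat", TPR, "Tetratricopeptide repeat"),
    ANK: ("Pfam", "PF00023", "Ankyrin repeat", ANK, "Ankyrin repeat"),
    IG_LIKE: ("Pfam", "PF13927", "Immunoglobulin-like domain", IG_LIKE, "Immunoglobulin-like fold"),
    EGF_CA: ("Pfam", "PF07645", "Calcium-binding EGF domain", EGF_CA, "EGF-type, calcium-binding"),
    ARRESTIN_N: ("Pfam", "PF00339", "Arrestin (or S-antigen), N-terminal domain", ARRESTIN_N, "Arrestin-like, N-terminal"),
    ARRESTIN_C: ("Pfam", "PF02752", "Arrestin (or S-antigen), C-terminal domain", ARRESTIN_C, "Arrestin-like, C-terminal"),
    RHD: ("Pfam", "PF00554", "Rel homology DNA-binding domain", RHD, "Rel homology domain, DNA-binding"),
    KINASE: ("Pfam", "PF00069", "Protein kinase domain", KINASE, "Protein kinase domain"),
    CASPASE: ("Pfam", "PF00656", "Caspase domain", CASPASE, "Peptidase C14, caspase-like"),
    GPCR_SECRETIN: ("Pfam", "PF00002", "7 transmembrane receptor (Secretin family)", GPCR_SECRETIN, "GPCR, family 2, secretin-like"),
    BZIP: ("Pfam", "PF00170", "bZIP transcription factor", BZIP, "Basic-leucine zipper domain"),
    TRAF: ("Pfam", "PF02176", "TRAF-type zinc finger", TRAF, "TRAF-like"),
    CUE: ("Pfam", "PF02845", "CUE domain", CUE, "CUE domain"),
    NEMO_N: ("Pfam", "PF16516", "NEMO N-terminal domain", NEMO_N, "NEMO, N-terminal"),
    C1Q: ("Pfam", "PF00386", "C1q domain", C1Q, "C1q domain"),
    A2M: ("Pfam", "PF00207", "Alpha-2-macroglobulin family", A2M, "Alpha-2-macroglobulin"),
    C345C: ("Pfam", "PF03212", "Netrin C-terminal (complement C345C) domain", C345C, "Complement C3/4/5, C-terminal C345C"),
    ANAPHYLATOXIN: ("Pfam", "PF01821", "Anaphylotoxin-like domain", ANAPHYLATOXIN, "Anaphylatoxin/fibulin"),
}

#: secondary signatures for keys that InterProScan typically reports from
#: more than one member database (exercises redundant-hit merging)
SECONDARY_SIGNATURES: dict[str, tuple[str, str, str]] = {
    SRCR: ("SMART", "SM00202", "Scavenger receptor Cys-rich"),
}
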