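# Packaged family-classification rules for the placozoan innate-immunity
# repertoire.  Accession groups may be referenced as "@name" inside rules.
groups:
  death_clan: [IPR000488, IPR001315, IPR001875, IPR004020, IPR011029]  # DD, CARD, DED, PYD, DLD
  card_dld: [IPR001315, IPR011029]
  tir_sefir: [IPR000157, IPR013568]
  sr_domains: [IPR001190, IPR001304, IPR002159]  # SRCR, CTLD, CD36
  nod: [IPR007111, IPR002182]  # NACHT, NB-ARC
  fred: [IPR002181, "SUPERFAMILY:SSF56496"]

rules:
  - name: TIR_DC
    description: TIR-domain containing protein
    require_any: [[IPR000157]]

  - name: SEFIR_DC
    description: SEFIR-domain containing protein
    require_any: [[IPR013568]]

  - name: LRR_TM_candidate
    description: >-
      Candidate extracellular arm of a bipartite TLR-like receptor:
      extracellular LRRs, a single TM, and no intracellular TIR/SEFIR.
    require_any: [[IPR032675]]
    forbid: ["@tir_sefir"]
    tm: exactly:1
    positions:
      - [[IPR032675], extracellular]

  - name: SEFIR_TM
    description: SEFIR-domain transmembrane protein (cytoplasmic-transducer candidate)
    require_any: [[IPR013568]]
    tm: exactly:1

  - name: MyD88_like
    description: >-
      MyD88-like adaptor: a TIR or SEFIR domain together with a Death-clan
      domain, no transmembrane segment.
    require_any: [["@tir_sefir"], ["@death_clan"]]
    tm: exactly:0

  - name: scavenger_receptor
    description: membrane receptor with SRCR, CTLD or CD36 domains
    require_any: [["@sr_domains"]]
    tm: at_least:1
    subclasses:
      - name: SRCR_type
        require_any: [[IPR001190]]
      - name: CTLD_type
        require_any: [[IPR001304]]
      - name: CD36_type
        require_any: [[IPR002159]]
      - name: GPCR_CTLD
        description: CTLD-bearing secretin/adhesion-family GPCR (7 TM helices)
        require_any: [[IPR001304]]
        tm: exactly:7

  - name: secreted_CTLD
    description: secreted lectin-like protein with 1-3 CTLDs and no TM
    require_any: [[IPR001304]]
    tm: exactly:0
    sp: yes

  - name: FReD_model
    description: gene model carrying a fibrinogen-related domain
    require_any: [["@fred"]]

  - name: intelectin
    description: >-
      Short secreted FReD protein, or a gene model assigned to the
      intelectin family by the PANTHER classification.
    any_of:
      - name: by_architecture
        require_any: [["@fred"]]
        sp: yes
        max_length: 400
      - name: by_panther
        panther_any: ["PTHR12119:intelectin"]

  - name: fibrillin_like
    description: large (>1000 AA) fibrillin-related FReD protein
    require_any: [["@fred"]]
    min_length: 1000

  - name: NLR
    description: >-
      NOD-like receptor of the placozoan inventory: central NACHT or
      NB-ARC domain; the inventory contains no LRR-bearing members.
    require_any: [["@nod"]]
    forbid: [IPR032675]
    positions:
      - [["@nod"], central]
    subclasses:
      - name: NACHT_type
        require_any: [[IPR007111]]
      - name: NB_ARC_type
        require_any: [[IPR002182]]
      - name: effector_CARD
        positions: [[[IPR001315], n_terminal]]
      - name: effector_DLD
        positions: [[[IPR011029], n_terminal]]
      - name: effector_DD
        positions: [[[IPR000488], n_terminal]]
      - name: repeat_WD40
        positions: [[[IPR001680], c_terminal]]
      - name: repeat_TPR
        positions: [[[IPR019734], c_terminal]]

  - name: Apaf1_like
    description: Apaf-1 architecture (NB-ARC + N-terminal CARD/DLD + C-terminal WD40)
    require_any: [[IPR002182]]
    forbid: [IPR032675]
    positions:
      - [["@card_dld"], n_terminal]
      - [[IPR001680], c_terminal]
      - [[IPR002182], central]

  - name: arrestin
    description: arrestin (N- and C-terminal arrestin-like domains)
    require_any: [[IPR011021], [IPR011022]]
    positions:
      - [[IPR011021], n_terminal]
      - [[IPR011022], c_terminal]

  - name: caspase_CARD
    description: caspase-like domain with an N-terminal CARD
    require_any: [[IPR011600]]
    positions:
      - [[IPR001315], n_terminal]

  - name: C1q_like
    description: C1q-domain factor
    require_any: [[IPR001073]]

  - name: a2m_family
    description: alpha-2-macroglobulin family member (CD109)
    require_any: [[IPR001599]]

  - name: death_kinase
    description: protein kinase carrying a Death-clan domain
    require_any: [[IPR000719], ["@death_clan"]]

  - name: nfkb_like
    description: NF-kB-like protein (Rel homology domain plus ankyrin repeats)
    require_any: [[IPR011539], [IPR002110]]

  - name: rel_family
    description: NF-kB/Rel family member (Rel homology domain)
    require_any: [[IPR011539]]

  # -- absence screens ----------------------------------------------------
  - name: RIG_I
    description: RIG-I-like receptor screen (expected empty)
    require_any: [[IPR021673]]
    absence_screen: true

  - name: cGAS
    description: cGAS (Mab-21 domain) screen (expected empty)
    require_any: [[IPR024810]]
    absence_screen: true

  - name: STING
    description: STING screen (expected empty)
    require_any: [[IPR029158, IPR033952]]
    absence_screen: true

  - name: complement_factor
    description: complement key-factor domain screen (expected empty)
    require_any: [[IPR001134, IPR000020]]
    absence_screen: true
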