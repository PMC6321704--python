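# Reference TLR-pathway node roster (MyD88-dependent branch only).
# expected_domains are InterPro accession keys the node's canonical protein
# carries; ko / eggnog / orthomcl / swissprot state how each mapping source
# is matched to the node.
nodes:
  - name: TLR
    expected_domains: [IPR000157, IPR032675]
    ko: K10159
    eggnog: KOG_TLR
    orthomcl: OG_TLR
    swissprot: [O60603]
  - name: MyD88
    expected_domains: [IPR000157]
    ko: K04729
    eggnog: KOG_MYD88
    orthomcl: OG_MYD88
    swissprot: [Q99836]
  - name: IRAK
    expected_domains: [IPR000719, IPR000488]
    ko: K04730
    eggnog: KOG_IRAK
    orthomcl: OG_IRAK
    swissprot: [P51617]
  - name: TRAF6
    expected_domains: [IPR008974]
    ko: K03175
    eggnog: KOG_TRAF6
    orthomcl: OG_TRAF6
    swissprot: [Q9Y4K3]
  - name: TAK1
    expected_domains: [IPR000719]
    ko: K04427
    eggnog: KOG_TAK1
    orthomcl: OG_TAK1
    swissprot: [O43318]
  - name: TAB2
    expected_domains: [IPR003892]
    ko: K04404
    eggnog: KOG_TAB2
    orthomcl: OG_TAB2
    swissprot: [Q9NYJ8]
  - name: IKKbeta
    expected_domains: [IPR000719]
    ko: K07209
    eggnog: KOG_IKKB
    orthomcl: OG_IKKB
    swissprot: [O14920]
  - name: NEMO
    expected_domains: [IPR034735]
    ko: K07210
    eggnog: KOG_NEMO
    orthomcl: OG_NEMO
    swissprot: [Q9Y6K9]
  - name: IkBalpha
    expected_domains: [IPR002110]
    ko: K04734
    eggnog: KOG_IKBA
    orthomcl: OG_IKBA
    swissprot: [P25963]
  - name: NFkB
    expected_domains: [IPR011539, IPR002110, IPR000488]
    ko: K02580
    eggnog: KOG_NFKB
    orthomcl: OG_NFKB
    swissprot: [P19838]
  - name: p38
    expected_domains: [IPR000719]
    ko: K04441
    eggnog: KOG_P38
    orthomcl: OG_P38
    swissprot: [Q16539]
  - name: JNK
    expected_domains: [IPR000719]
    ko: K04440
    eggnog: KOG_JNK
    orthomcl: OG_JNK
    swissprot: [P45983]
  - name: AP-1
    expected_domains: [IPR004827]
    ko: K04448
    eggnog: KOG_JUN
    orthomcl: OG_JUN
    swissprot: [P05412]
  - name: TRIF
    expected_domains: [IPR000157]
    ko: K05842
    eggnog: KOG_TRIF
    orthomcl: OG_TRIF
    swissprot: [Q8IUC6]
  - name: TBK1
    expected_domains: [IPR000719]
    ko: K05410
    eggnog: KOG_TBK1
    orthomcl: OG_TBK1
    swissprot: [Q9UHD2]
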