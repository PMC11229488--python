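# Illustrative subset of DNA motifs associated with double-strand breaks,
# for use with phbreak's motif scanner.  Users reproducing a specific
# published break-motif catalog should supply their own config in this
# layout.
motifs:
  - name: topoII_consensus
    kind: iupac
    pattern: RNYNNCNNGYNGKTNYNY
    max_mismatches: 2
  - name: ig_switch_GAGCT
    kind: iupac
    pattern: GAGCT
    max_mismatches: 0
  - name: ig_switch_GGGGT
    kind: iupac
    pattern: GGGGT
    max_mismatches: 0
  - name: chi_like
    kind: iupac
    pattern: GCTGGTGG
    max_mismatches: 0
  - name: rss_12
    kind: rss
    spacer: 12
    spacer_slack: 1
    heptamer_mismatches: 1
    nonamer_mismatches: 1
  - name: rss_23
    kind: rss
    spacer: 23
    spacer_slack: 1
    heptamer_mismatches: 1
    nonamer_mismatches: 1
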