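# Synthetic totivirus fixture architecture: a 4712-nt yeast-totivirus-like
# genome layout (two non-overlapping ORFs, -1 PRF signal before the ORF1
# stop, five companion-isolate point mutations).  Consumed by
# totiscan.synthetic_data.architecture_from_yaml / `totiscan simulate`.
name: synthetic-totivirus
total_length: 4712
stop_codon: UAA
orfs:
  - {start: 98, end: 2161}    # frame 2, 2064 nt, 687-aa coat protein ORF
  - {start: 2410, end: 4653}  # frame 1, 2244 nt, 747-aa RdRp ORF
slippery:
  start: 2104
  heptamer: UGUUUUC           # relaxed-dialect XXXYYYZ heptamer
pseudoknot:
  start: 2130                 # extent 2130-2154 (25 nt)
  stem1: 5
  stem2: 4
  loops: [2, 2, 3]
minus_one_frame:
  stop_free_from: 1990        # => 172-nt ORF1 overlap, 1518-aa fusion
mutations:
  - {position: 84, effect: utr}
  - {position: 1003, effect: silent}
  - {position: 1336, effect: silent}
  - {position: 1952, effect: nonsynonymous}
  - {position: 3507, effect: silent}
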