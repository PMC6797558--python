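# Curated default consensus patterns for the eight conserved motifs (I-VIII)
# of dsRNA-virus RNA-dependent RNA polymerases.  These are illustrative
# configuration distilled from the comparative RdRp literature (the motif
# cores around the catalytic Asp residues and the GDD/SDD triad), NOT data
# printed by any single study; supply your own set with --motifs for real
# analyses.  Syntax: exact residues, [..] alternatives, x wildcard, {n,m}
# repetition of the preceding token.
motifs:
  - {id: I, pattern: "Gx{2}[ST]x{2,4}[DE]"}
  - {id: II, pattern: "[KR]x{2,3}G[ILMV]"}
  - {id: III, pattern: "[ILMV]x{2}DYx{2}F"}
  - {id: IV, pattern: "Dx{4,5}D"}
  - {id: V, pattern: "Gx{3}[ST]x{3}[NG]"}
  - {id: VI, pattern: "[SG]G[DN]D"}
  - {id: VII, pattern: "[KR]x{2,3}[ILMV]x{2}[FY]"}
  - {id: VIII, pattern: "E[FYW]x[KR]"}
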