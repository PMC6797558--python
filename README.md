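# totiscan

Annotation of totivirus-like double-stranded RNA genomes: ORF architecture,
−1 programmed ribosomal frameshifting (−1 PRF) signals, CP-RdRp fusion
products, and comparison of near-identical genomes from different hosts.

## The problem

Totiviruses (family *Totiviridae*) carry a single linear dsRNA genome of
roughly 4.6–7 kbp whose plus strand encodes two large ORFs: a coat protein
(CP, ORF1) and an RNA-dependent RNA polymerase (RdRp, ORF2). In yeast-style
totiviruses the RdRp is expressed as a CP-RdRp fusion via −1 ribosomal
frameshifting: in the region preceding the ORF1 stop codon, the ribosome
encounters

1. a **slippery heptamer** of the general form `XXXYYYZ` (X any base,
   Y ∈ {A, U}, Z ∈ {A, C, U}) at which the P- and A-site tRNAs re-pair one
   nucleotide upstream;
2. a short **spacer**; and
3. an **H-type pseudoknot** — the loop of a hairpin (stem 1) base-pairs
   with downstream sequence (stem 2), producing crossed helices that pause
   the ribosome over the heptamer.

A single −1 slip at the heptamer sends translation into the ORF2 reading
frame, producing a CP-RdRp fusion whose length follows from pure coordinate
arithmetic: with one nucleotide read twice, the translated length is the
ORF1-start-to-downstream-stop span plus one. When essentially the same
virus is sequenced from two fungal hosts (evidence of recent horizontal
transmission), the genomes are collinear and differ by a handful of point
substitutions, each classifiable as UTR, silent (synonymous) or
amino-acid-changing by re-translating the affected codon.

`totiscan` implements each of these steps as a library of small, composable
functions plus a CLI, and ships a **synthetic-genome generator** that plants
a complete totivirus architecture (ORFs, PRF elements, companion-isolate
mutations) into seeded random sequence, so the entire pipeline can be
exercised and tested without downloading any accession.

## Worked example

Generate the built-in 4712-nt totivirus-like fixture and its companion
isolate, then annotate:

```
$ totiscan simulate --seed 1 --out genome.fa --mutant isolate2.fa
wrote synthetic-totivirus (4712 nt) to genome.fa
wrote synthetic-totivirus-isolate2 to isolate2.fa

$ totiscan annotate genome.fa
ORF1: 98-2161 (2064 nt, frame 2), 687 aa, 77.328 kDa
ORF2: 2410-4653 (2244 nt, frame 1), 747 aa, 83.398 kDa
```

The two ORFs (frames numbered `((start−1) mod 3) + 1`) leave a 97-nt 5′-UTR,
a 248-nt intergenic region and a 59-nt 3′-UTR; molecular weights are
average-mass sums over the residues plus one water. Scan for the −1 PRF
signal:

```
$ totiscan prf genome.fa
slippery UGUUUUC at 2104-2110
spacer 19 nt
pseudoknot at 2130-2154 (EFE -32.0 kcal/mol)
fusion product 1518 aa, 170.277 kDa, overlap 172 nt
```

`UGUUUUC` matches the *relaxed* heptamer dialect (the X-triplet identity is
not enforced — naturally occurring sites require this). EFE is the
estimated free energy of the pseudoknot, the sum of per-base-pair scores
(GC −3, AU −2, GU −1 kcal/mol); more negative is more stable. The fusion
arithmetic: span 98..4653 = 4556 nt, plus the one re-read nucleotide at the
slip = 4557 nt = 1519 codons, i.e. a 1518-aa protein excluding the stop.
The stop-free −1 frame reaches back to nt 1990, overlapping the last 172 nt
of ORF1. Finally, compare the two isolates:

```
$ totiscan compare genome.fa isolate2.fa
5 substitutions over 4712 nt (99.89% identity)
  utr: 1
  silent: 3
  nonsynonymous: 1
```

Each command also writes machine-readable output (`--json`, `--gff`,
`--tsv`). GFF3 output uses 1-based inclusive plus-strand coordinates with
`CDS` for ORFs and the literal types `five_prime_UTR`, `three_prime_UTR`,
`intergenic`, `slippery_site`, `spacer` and `pseudoknot` in column 3.

Consensus motif patterns for `totiscan protein --motifs` use exact residue
letters, `[ACD]` alternatives, `x` wildcards and `{n,m}` repetition; a
curated illustrative set for the eight conserved RdRp motifs (I–VIII) of
dsRNA viruses is packaged as the default.

## Layout

- `src/totiscan/genome_model.py` — sequence/coordinate types, FASTA/GFF3/JSON I/O
- `src/totiscan/orf_annotation.py` — ORF finding, architecture, translation, MW
- `src/totiscan/prf_scanner.py` — slippery sites, pseudoknots, fusion products
- `src/totiscan/comparative.py` — collinear genome comparison and effect calls
- `src/totiscan/protein_analysis.py` — pairwise alignment, residue/motif mapping
- `src/totiscan/synthetic_data.py` — planted-architecture genome generator
- `docs/methods.md` — models, conventions, parameter defaults and limitations
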