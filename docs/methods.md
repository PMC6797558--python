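# Methods

This note records the models implemented by `totiscan`, the conventions and
defaults chosen where several were defensible, what the synthetic generator
does and does not emulate, and the package's known limitations. Nothing
here states a number the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and alphabet

All public coordinates are 1-based and inclusive at both ends; a region
`[start, end]` has length `end − start + 1`. Sequences are held in the RNA
alphabet (A, C, G, U); T is converted to U on input and can be restored on
FASTA output (`--dna`). IUPAC ambiguity codes are rejected by default with
an error naming the character and position — the analyses assume a
finished, single-molecule consensus sequence — and can be admitted
explicitly, in which case they simply never match any scan pattern. Only
the plus strand is modelled: the genomes this package targets annotate
their coding content entirely on the positive-sense strand.

## ORF model

An ORF is AUG-initiated, ends at the next in-frame stop codon (stop
included in the span, excluded from the protein), and is maximal: its AUG
is the 5′-most AUG after the previous in-frame stop. Frames are numbered
`((start − 1) mod 3) + 1`, the unique numbering that reproduces the
conventional frame labels of yeast-totivirus annotations from the
coordinates alone. The default minimum ORF length is 300 nt, appropriate
for genomes whose real ORFs are two orders of magnitude above the random
background; it is configurable everywhere.

Translation uses the standard genetic code (translation table 1) — the
genomes in scope terminate with an ochre (UAA) codon and show no signs of
alternative decoding. Protein molecular weights are average-mass sums over
residues plus one water (18.01528 Da), reported in kDa to 3 decimals; this
matches the convention of the common protein-parameter tools. The empty
chain therefore weighs 0.018 kDa, and MW is additive up to one water.

Architecture derivation complements the ORF set: 5′-UTR before the first
ORF, intergenic regions between consecutive ORFs, 3′-UTR after the last.
Zero-length UTRs are represented as absent rather than as empty regions.
The derived regions always partition `[1, genome length]`; overlapping
ORFs are rejected with a pointer to the PRF analysis, since overlap is the
signature of a frameshift product rather than of two independent genes.

## −1 PRF detection

**Slippery heptamer.** The canonical consensus is `XXXYYYZ` with
X ∈ {A,C,G,U} identical, Y ∈ {A,U} identical, Z ∈ {A,C,U}. Naturally
occurring sites violate the X-identity (e.g. `UGUUUUC`), so the scanner's
default is a *relaxed* dialect that leaves the X triplet unconstrained;
the strict dialect remains available, and strict hits are a subset of
relaxed hits on every sequence.

**Pseudoknot.** Candidates are enumerated exhaustively in a bounded window:
every pair of helices (stem 1, stem 2) such that stem 2's 5′ half lies in
stem 1's loop and its 3′ half lies strictly downstream of stem 1 — the
crossing topology of an H-type pseudoknot. Plain hairpins are rejected.
Stems need at least 3 contiguous canonical pairs (Watson-Crick or GU
wobble); loops are bounded at 20 nt; the default window is 60 nt. Each
candidate is scored by an estimated free energy (EFE): the sum of
per-base-pair scores, GC −3.0, AU −2.0, GU −1.0 kcal/mol. This deliberately
simple additive model is not a thermodynamic prediction; at these window
sizes exhaustive enumeration plus a stability ranking is sufficient for
detection, and the scores are configurable. Candidates are ranked by EFE
ascending, ties broken by smaller total extent, then 5′-most start.

**Signal assembly.** The detector scans a window (default 150 nt) upstream
of the upstream ORF's stop codon for heptamers; for each, pseudoknot
candidates downstream are admissible when the implied spacer (pseudoknot
start − heptamer end − 1) is 4–20 nt. The best complete signal minimizes
(pseudoknot EFE, pseudoknot extent, spacer length, heptamer start). Spacer
length enters the ranking because the relaxed dialect makes every heptamer
trail 1-nt-shifted 5′ variants of itself (the X positions are
unconstrained), so "5′-most heptamer" would systematically select a
shifted artifact; among signals sharing a pseudoknot, the shorter spacer is
the canonical geometry. When no complete signal exists a partial signal is
returned with diagnostics instead of an error. Window defaults were chosen
to cover yeast-totivirus geometry (heptamer ending ~50 nt before the ORF1
stop, ~19-nt spacer, ~25-nt pseudoknot) with margin.

**Fusion product.** Tandem slippage is modelled as one nucleotide read
twice. Translation proceeds in the upstream ORF's frame through the last
full codon ending at or before the heptamer's final nucleotide, re-reads
that boundary nucleotide as the first base of a −1-frame codon, and
continues to the first −1-frame stop. The translated length is therefore
`span + 1` nucleotides (span = ORF1 start to the last nt of the −1-frame
stop) and is invariant to moving the slip boundary by whole codons — the
convention only redistributes residues at the junction, never the length —
which the suite asserts for offsets of ±1 codon. (A ±1 *nucleotide*
convention change cannot keep both halves in frame, so whole codons are
the meaningful perturbation.) The reported overlap is the distance from
the 5′-most stop-free −1-frame codon start (walking back from the slip)
to the ORF1 end, inclusive. Failure modes are explicit errors: a −1 frame
with no stop before the genome end ("runaway"), and a stop codon
immediately after the slip.

## Genome comparison

Comparison assumes equal-length, collinear genomes — the
horizontal-transfer scenario where the same virus is sequenced from two
hosts; diverged genomes needing alignment are explicitly out of scope
rather than half-supported. Differences are per-position mismatches. Each
substitution is mapped to its region; inside an ORF it gets a codon index
(`floor((pos − orf_start)/3) + 1`), codon position (1–3), and an effect
call made by substituting the single base into the reference genome's
codon and re-translating: `silent` when the amino acid is unchanged,
`nonsynonymous` otherwise. Substitutions are evaluated one at a time; two
hits in the same codon trigger a warning since their joint effect is not
modelled. Percent identity is `100 × (n_sites − n_diff)/n_sites`, rounded
half-even to 2 decimals (so 5 differences over 4712 nt → 99.89). The TSV
report prints U alongside its DNA letter so RNA-internal output remains
comparable with DNA-deposited records.

## Protein analysis

Residue correspondence ("which CP position carries the catalytic His?") is
answered by optimal global pairwise alignment with affine gaps (BLOSUM62;
gap of length k costs 10 + 1·k by default, end gaps included), then
reading the aligned column. Pairwise alignment is a deliberate desk-scale
stand-in for the structure-aware multiple alignments used in comparative
virology; for the unambiguous-homology cases it serves here the mapping is
insensitive to the scoring details. Among co-optimal alignments the
aligner's first enumerated alignment is taken, which is deterministic
across runs; alignment *scores* are additionally verified against an
independent cubic-time oracle. Motif presence is a consensus-pattern scan
(exact letters, `[..]` alternatives, `x` wildcard, `{n,m}` repetition)
reporting all leftmost non-overlapping hits per motif plus a flag for
"all motifs present in listed order". The packaged RdRp motif set (I–VIII)
is illustrative curated configuration, not data from any single study; no
quantitative result depends on it.

## Synthetic genomes

The generator consumes a declarative architecture — ORF coordinates, stop
codon type, heptamer and position, pseudoknot layout (stem/loop lengths),
the position from which the −1 frame must be stop-free, and a mutation
list — and emits a genome by plant-then-repair: fixed elements are written
and locked; the neutral background (uniform over A/C/G/U by default, GC
bias configurable, since no measured composition is being emulated and no
tested quantity depends on it) is repaired codon-by-codon until no
constrained frame contains a stop, no forbidden AUG precedes a planted
start in its frame, and every mutation-site codon admits its requested
effect class. Pseudoknot stems are planted as seeded G/C sequences and
their reverse complements, making the planted structure maximally stable
under the detector's default scores. The candidate is then verified
end-to-end — the ORF finder must recover exactly the planted ORFs (and
nothing else at the 300-nt threshold) and the PRF detector exactly the
planted signal — with accidental competitors (a chance ORF, heptamer or
helix in the random fill) degraded by seeded point changes at unlocked
positions. All randomness flows from one seeded generator, so output is a
deterministic function of (architecture, seed); an unsatisfiable
architecture raises an error rather than degrading silently.

The built-in fixture encodes a 4712-nt yeast-totivirus-like layout (ORFs at
98–2161 and 2410–4653, heptamer `UGUUUUC` at 2104–2110, pseudoknot at
2130–2154, −1 frame stop-free from nt 1990, five companion mutations with
a 1 UTR / 3 silent / 1 amino-acid-changing split). The companion-isolate
mutator chooses, per specified position and seeded, a base realizing the
requested class, and errors where none exists (e.g. no synonymous change
at any position of AUG).

What the generator does **not** emulate: real nucleotide composition and
codon usage, sequencing error, quasispecies variation, RNA secondary
structure outside the planted pseudoknot, and any homology in the encoded
proteins (they are random-sequence translations). Pipeline tests on these
genomes therefore demonstrate the correctness of the coordinate
arithmetic, scanning and classification logic — not performance on noisy
or diverged real data.

## Verification and problem sizes

Scanners are checked against independent brute-force oracles that share no
code with the implementation: the ORF finder against an
every-AUG-walk-to-stop enumerator (200 random genomes up to 10 kb), the
pseudoknot enumerator against naive nested loops over all region pairs
(100 random windows), and alignment scores against the naive cubic-time
affine-gap recurrence (100 random pairs up to 30 aa). Full-pipeline
recovery of every architecture quantity is asserted across 20 generator
seeds, and the mutation-effect split across 50 seeds. The whole suite runs
in a few minutes on one CPU; a single generate-plus-annotate cycle takes
about one to three seconds, and `scripts/acceptance.py` completes in a few
seconds.

## Known limitations

- No minus-strand or six-frame annotation; no stop/restart (victorivirus-
  style) expression model.
- Pseudoknot EFE is a detection score, not a folding free energy; no
  kinetic model of frameshifting efficiency is attempted.
- Comparison requires equal-length collinear genomes; there is no
  alignment mode.
- Pairwise alignment replaces multiple alignment for residue mapping;
  profile/HMM searches and database lookups are out of scope.
- The GFF3 writer emits descriptive literal feature types for PRF elements
  rather than Sequence Ontology terms (documented in the README).
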