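"""Plus-strand ORF detection, genome architecture derivation, and translation.

ORFs are AUG-initiated, run to the next in-frame stop (stop codon included in
the ORF span, excluded from the protein), and are maximal: each ORF's AUG is
the 5'-most AUG after the previous in-frame stop.  Frames are numbered
1..3 as ``((start - 1) mod 3) + 1``, which reproduces the frame labels used
for yeast-totivirus-style genomes (e.g. an ORF starting at nt 98 is frame 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight as _bio_mw

from .genome_model import GenomeRecord, Region

START_CODON = "AUG"
STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

#: Water mass added once per chain (average masses), in Da.
WATER_DA = 18.01528


class TranslationError(ValueError):
    pass


@dataclass(frozen=True)
class OrfAnnotation:
    """One annotated plus-strand ORF, including its translation."""

    name: str
    region: Region
    frame: int
    start_codon: str
    stop_codon: str
    protein: str
    protein_length: int
    molecular_weight: float  # kDa, average-mass, 3 decimals

    def __post_init__(self) -> None:
        if self.region.length % 3 != 0:
            raise ValueError(f"{self.name}: ORF length {self.region.length} not divisible by 3")
        if self.protein_length != self.region.length // 3 - 1:
            raise ValueError(f"{self.name}: protein length inconsistent with ORF span")
        if self.frame != (self.region.start - 1) % 3 + 1:
            raise ValueError(f"{self.name}: frame inconsistent with start coordinate")


@dataclass(frozen=True)
class ArchitectureAnnotation:
    """UTR / ORF / intergenic layout of a genome.

    Zero-length UTRs (an ORF flush with a genome end) are represented as
    ``None`` since regions are non-empty by construction.
    """

    genome_length: int
    five_prime_utr: Region | None
    orfs: tuple[OrfAnnotation, ...]
    intergenic: tuple[Region, ...]
    three_prime_utr: Region | None

    def regions(self) -> list[Region]:
        """All non-empty regions in genome order; they partition the genome."""
        parts: list[Region] = []
        if self.five_prime_utr:
            parts.append(self.five_prime_utr)
        parts.extend(o.region for o in self.orfs)
        parts.extend(self.intergenic)
        if self.three_prime_utr:
            parts.append(self.three_prime_utr)
        return sorted(parts, key=lambda r: r.start)

    def region_of(self, position: int) -> tuple[str, OrfAnnotation | None]:
        """Label of the region containing ``position`` (ORF name if in an ORF)."""
        if not (1 <= position <= self.genome_length):
            raise ValueError(f"position {position} outside genome of length {self.genome_length}")
        for orf in self.orfs:
            if orf.region.contains(position):
                return orf.name, orf
        if self.five_prime_utr and self.five_prime_utr.contains(position):
            return "five_prime_utr", None
        if self.three_prime_utr and self.three_prime_utr.contains(position):
            return "three_prime_utr", None
        return "intergenic", None


def translate(cds: str) -> str:
    """Translate an RNA CDS with the standard genetic code.

    The trailing stop codon, if present, is removed.  An internal stop raises
    :class:`TranslationError` naming the 1-based codon index, as does a length
    not divisible by 3.
    """
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise TranslationError(f"internal stop at codon {aa.index('*') + 1}")
    return aa


def molecular_weight_kda(protein: str) -> float:
    """Average-mass molecular weight of a protein chain in kDa (3 decimals).

    Sum of average residue masses plus one water (18.01528 Da); the empty
    chain therefore weighs 0.018 kDa.  Non-standard residues are an error.
    """
    if not protein:
        return round(WATER_DA / 1000.0, 3)
    try:
        da = _bio_mw(protein, seq_type="protein")
    except ValueError as exc:
        raise ValueError(f"non-standard residue in protein: {exc}") from None
    return round(da / 1000.0, 3)


def _annotate_orf(genome: GenomeRecord, start: int, end: int, name: str) -> OrfAnnotation:
    cds = genome.slice(start, end)
    return OrfAnnotation(
        name=name,
        region=Region(start, end, "orf"),
        frame=(start - 1) % 3 + 1,
        start_codon=cds[:3],
        stop_codon=cds[-3:],
        protein=translate(cds),
        protein_length=len(cds) // 3 - 1,
        molecular_weight=molecular_weight_kda(translate(cds)),
    )


def find_orfs(genome: GenomeRecord, min_length_nt: int = 300) -> list[OrfAnnotation]:
    """All maximal AUG-to-stop plus-strand ORFs of nt length >= ``min_length_nt``.

    Scans the three plus-strand frames; within a frame, an ORF opens at the
    first AUG after the previous in-frame stop and closes at the next in-frame
    stop (ORFs without a stop codon before the genome end are discarded).
    Output is sorted by start and named ORF1, ORF2, ... in genome order.
    """
    seq = genome.sequence
    found: list[tuple[int, int]] = []
    for offset in range(3):
        pending: int | None = None
        for i in range(offset, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_CODONS:
                if pending is not None:
                    span = (i + 3) - pending
                    if span >= min_length_nt:
                        found.append((pending + 1, i + 3))
                    pending = None
            elif codon == START_CODON and pending is None:
                pending = i
    found.sort()
    return [
        _annotate_orf(genome, start, end, f"ORF{k}")
        for k, (start, end) in enumerate(found, start=1)
    ]


def derive_architecture(genome: GenomeRecord, orfs: list[OrfAnnotation]) -> ArchitectureAnnotation:
    """Compute UTRs and intergenic regions by complementation of the ORF set.

    ORFs must be non-overlapping (overlap suggests a frameshift product and is
    reported as an error pointing at the PRF analysis).  With zero ORFs the
    whole genome becomes one intergenic region and a warning is issued.  The
    returned regions always partition [1, genome length].
    """
    orfs = sorted(orfs, key=lambda o: o.region.start)
    if not orfs:
        warnings.warn("no ORFs: architecture is a single intergenic region")
        return ArchitectureAnnotation(
            genome_length=genome.length,
            five_prime_utr=None,
            orfs=(),
            intergenic=(Region(1, genome.length, "intergenic"),),
            three_prime_utr=None,
        )
    for a, b in zip(orfs, orfs[1:]):
        if b.region.start <= a.region.end:
            raise ValueError(
                f"{a.name} and {b.name} overlap ({a.region.end} >= {b.region.start}); "
                "overlapping ORFs indicate a frameshift product — use the PRF analysis"
            )
        if a.region.end > genome.length or b.region.end > genome.length:
            raise ValueError("ORF outside genome bounds")

    utr5 = Region(1, orfs[0].region.start - 1, "five_prime_utr") if orfs[0].region.start > 1 else None
    utr3 = (
        Region(orfs[-1].region.end + 1, genome.length, "three_prime_utr")
        if orfs[-1].region.end < genome.length
        else None
    )
    intergenic = tuple(
        Region(a.region.end + 1, b.region.start - 1, "intergenic")
        for a, b in zip(orfs, orfs[1:])
        if b.region.start - a.region.end > 1
    )
    arch = ArchitectureAnnotation(
        genome_length=genome.length,
        five_prime_utr=utr5,
        orfs=tuple(orfs),
        intergenic=intergenic,
        three_prime_utr=utr3,
    )
    assert sum(r.length for r in arch.regions()) == genome.length
    return arch
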