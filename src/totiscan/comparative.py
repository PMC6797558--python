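"""Comparison of near-identical, same-length genomes.

Intended for the horizontal-transfer scenario where essentially the same
virus is sequenced from two hosts: the genomes are collinear, so differences
are a handful of point substitutions.  Each substitution is assigned to a
genome region and, inside an ORF, classified as silent (synonymous) or
nonsynonymous by re-translating the affected codon.  Diverged genomes that
require alignment are out of scope.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

from Bio.Seq import Seq

from .genome_model import GenomeRecord
from .orf_annotation import ArchitectureAnnotation

EFFECT_CLASSES = ("utr", "intergenic", "silent", "nonsynonymous")


@dataclass(frozen=True)
class SubstitutionRecord:
    """One point difference between two same-length genomes."""

    position: int  # 1-based nt
    ref_base: str
    alt_base: str
    region_label: str  # five_prime_utr / three_prime_utr / intergenic / ORF name
    codon_index: int | None = None  # 1-based codon within the ORF
    codon_position: int | None = None  # 1, 2 or 3
    ref_aa: str | None = None
    alt_aa: str | None = None
    effect: str = "utr"

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("substitution must change the base")
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect {self.effect!r}")


@dataclass(frozen=True)
class ComparisonReport:
    n_sites: int
    n_diff: int
    percent_identity: float
    substitutions: tuple[SubstitutionRecord, ...]
    effect_counts: dict


def diff_genomes(a: GenomeRecord, b: GenomeRecord) -> list[tuple[int, str, str]]:
    """All mismatch positions between two equal-length genomes, ascending.

    Unequal lengths are an explicit error: this module assumes collinearity
    and does not align (use a dedicated aligner for diverged genomes).
    """
    if a.length != b.length:
        raise ValueError(
            f"genomes differ in length ({a.length} vs {b.length}); "
            "collinear comparison requires equal lengths — align first"
        )
    return [
        (i + 1, ca, cb)
        for i, (ca, cb) in enumerate(zip(a.sequence, b.sequence))
        if ca != cb
    ]


def percent_identity(n_sites: int, n_diff: int) -> float:
    """Percent identity over ``n_sites`` positions, half-even to 2 decimals."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if not (0 <= n_diff <= n_sites):
        raise ValueError("n_diff must lie in [0, n_sites]")
    return round(100.0 * (n_sites - n_diff) / n_sites, 2)


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())  # '*' for stops


def classify_substitutions(
    diffs: list[tuple[int, str, str]],
    architecture: ArchitectureAnnotation,
    genome_a: GenomeRecord,
) -> list[SubstitutionRecord]:
    """Map each difference to its region and coding effect.

    Each substitution is evaluated independently against ``genome_a``'s codon
    (the alternate codon is the reference codon with the single base
    replaced).  Two or more substitutions hitting the same codon trigger a
    warning, since their joint amino-acid effect is not modelled.
    """
    seen_codons: Counter = Counter()
    records: list[SubstitutionRecord] = []
    for position, ref_base, alt_base in diffs:
        label, orf = architecture.region_of(position)
        if orf is None:
            effect = "intergenic" if label == "intergenic" else "utr"
            records.append(
                SubstitutionRecord(
                    position=position,
                    ref_base=ref_base,
                    alt_base=alt_base,
                    region_label=label,
                    effect=effect,
                )
            )
            continue
        offset = position - orf.region.start
        codon_index = offset // 3 + 1
        codon_position = offset % 3 + 1
        codon_start = orf.region.start + (codon_index - 1) * 3
        ref_codon = genome_a.slice(codon_start, codon_start + 2)
        alt_codon = (
            ref_codon[: codon_position - 1] + alt_base + ref_codon[codon_position:]
        )
        ref_aa = _translate_codon(ref_codon)
        alt_aa = _translate_codon(alt_codon)
        seen_codons[(orf.name, codon_index)] += 1
        if seen_codons[(orf.name, codon_index)] == 2:
            warnings.warn(
                f"codon {codon_index} of {orf.name} hit by multiple substitutions; "
                "effects are classified one base at a time"
            )
        records.append(
            SubstitutionRecord(
                position=position,
                ref_base=ref_base,
                alt_base=alt_base,
                region_label=orf.name,
                codon_index=codon_index,
                codon_position=codon_position,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                effect="silent" if ref_aa == alt_aa else "nonsynonymous",
            )
        )
    return records


def compare_genomes(
    a: GenomeRecord,
    b: GenomeRecord,
    architecture: ArchitectureAnnotation,
) -> ComparisonReport:
    """Full collinear comparison: diff, identity, and effect classification."""
    diffs = diff_genomes(a, b)
    subs = classify_substitutions(diffs, architecture, a)
    counts = Counter(s.effect for s in subs)
    return ComparisonReport(
        n_sites=a.length,
        n_diff=len(diffs),
        percent_identity=percent_identity(a.length, len(diffs)),
        substitutions=tuple(subs),
        effect_counts={k: counts.get(k, 0) for k in EFFECT_CLASSES},
    )


def substitutions_tsv(records: list[SubstitutionRecord], chrom: str) -> str:
    """VCF-like TSV (CHROM, POS, REF, ALT, REGION, EFFECT) of substitutions.

    REF/ALT are printed in both alphabets (RNA with the DNA letter in
    parentheses when they differ) so reports remain comparable with
    DNA-deposited records.
    """

    def both(base: str) -> str:
        return f"{base}({base.replace('U', 'T')})" if base == "U" else base

    lines = ["CHROM\tPOS\tREF\tALT\tREGION\tEFFECT"]
    for r in records:
        lines.append(
            f"{chrom}\t{r.position}\t{both(r.ref_base)}\t{both(r.alt_base)}"
            f"\t{r.region_label}\t{r.effect}"
        )
    return "\n".join(lines) + "\n"
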