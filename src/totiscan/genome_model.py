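"""Core sequence/coordinate types and file I/O for totivirus genome annotation.

All coordinates in the public data model are 1-based and inclusive at both
ends, matching the convention of GenBank feature tables and GFF3.  Sequences
are held internally in the RNA alphabet (A, C, G, U); DNA input is converted
on read (T -> U) and can be converted back on write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, is_dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
#: IUPAC ambiguity codes accepted when ``allow_ambiguous`` is set.
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")

REGION_LABELS = frozenset(
    {
        "five_prime_utr",
        "orf",
        "intergenic",
        "three_prime_utr",
        "slippery_site",
        "spacer",
        "pseudoknot",
    }
)


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains characters outside the allowed alphabet."""


@dataclass(frozen=True)
class GenomeRecord:
    """A named, linear, plus-strand nucleotide sequence in the RNA alphabet.

    Parameters
    ----------
    id : str
        Sequence identifier (the FASTA header word).
    sequence : str
        Nucleotide sequence over {A, C, G, U} (ambiguity codes only when
        explicitly permitted at read time).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = [
            (i + 1, c)
            for i, c in enumerate(self.sequence)
            if c not in RNA_ALPHABET and c not in IUPAC_AMBIGUITY
        ]
        if bad:
            detail = ", ".join(f"{c!r} at position {i}" for i, c in bad[:10])
            raise SequenceAlphabetError(
                f"genome {self.id!r}: non-nucleotide characters: {detail}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Subsequence at 1-based inclusive coordinates [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"slice [{start}, {end}] out of bounds for genome of length {self.length}"
            )
        return self.sequence[start - 1 : end]


@dataclass(frozen=True, order=True)
class Region:
    """A 1-based inclusive interval on a genome with a semantic label."""

    start: int
    end: int
    label: str = "orf"

    def __post_init__(self) -> None:
        if self.label not in REGION_LABELS:
            raise ValueError(f"unknown region label {self.label!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end}]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


def normalize_sequence(raw: str, *, allow_ambiguous: bool = False) -> str:
    """Uppercase, convert T to U, and validate the nucleotide alphabet.

    Raises :class:`SequenceAlphabetError` naming every offending character and
    its 1-based position (first ten shown).
    """
    seq = raw.upper().replace("T", "U")
    allowed = RNA_ALPHABET | (IUPAC_AMBIGUITY if allow_ambiguous else frozenset())
    bad = [(i + 1, c) for i, c in enumerate(seq) if c not in allowed]
    if bad:
        detail = ", ".join(f"{c!r} at position {i}" for i, c in bad[:10])
        raise SequenceAlphabetError(f"non-nucleotide characters: {detail}")
    return seq


def read_fasta(path: str | Path, *, allow_ambiguous: bool = False) -> list[GenomeRecord]:
    """Read a nucleotide FASTA file into :class:`GenomeRecord` objects.

    T is normalized to U so DNA and RNA input are equivalent.  By default any
    IUPAC ambiguity code is rejected with an error naming the character and
    position; pass ``allow_ambiguous=True`` to keep ambiguity codes in the
    sequence (they never match scan patterns downstream).
    """
    records: list[GenomeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seq = normalize_sequence(str(rec.seq), allow_ambiguous=allow_ambiguous)
        except SequenceAlphabetError as exc:
            raise SequenceAlphabetError(f"record {rec.id!r}: {exc}") from None
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, *, dna: bool = False) -> None:
    """Write records as FASTA; ``dna=True`` converts U back to T on output."""
    out = []
    for rec in records:
        seq = rec.sequence.replace("U", "T") if dna else rec.sequence
        out.append(SeqRecord(Seq(seq), id=rec.id, description=""))
    SeqIO.write(out, str(path), "fasta")


# GFF3 column-3 types: CDS for ORFs, the region label verbatim for the PRF
# elements and UTR/intergenic regions (documented in the README).
_GFF_TYPE = {
    "orf": "CDS",
    "five_prime_utr": "five_prime_UTR",
    "three_prime_utr": "three_prime_UTR",
    "intergenic": "intergenic",
    "slippery_site": "slippery_site",
    "spacer": "spacer",
    "pseudoknot": "pseudoknot",
}


def write_gff3(features: Sequence, genome: GenomeRecord, path: str | Path) -> None:
    """Write plus-strand features to GFF3 (1-based inclusive, deterministic).

    ``features`` may mix :class:`Region` objects and any object exposing a
    ``region`` attribute and a ``name`` (e.g. an ORF annotation).  All bounds
    are validated before anything is written.
    """
    rows: list[tuple[Region, str, str]] = []
    for feat in features:
        if isinstance(feat, Region):
            region, name = feat, feat.label
        else:
            region, name = feat.region, getattr(feat, "name", feat.region.label)
        if region.end > genome.length:
            raise ValueError(
                f"feature {name!r} [{region.start}, {region.end}] exceeds "
                f"genome length {genome.length}"
            )
        rows.append((region, _GFF_TYPE[region.label], name))
    rows.sort(key=lambda r: (r[0].start, r[0].end, r[1]))

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for region, gff_type, name in rows:
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "totiscan",
                        gff_type,
                        str(region.start),
                        str(region.end),
                        ".",
                        "+",
                        ".",
                        f"ID={name}",
                    ]
                )
                + "\n"
            )


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        d = {}
        for f in fields(obj):
            d[f.name] = _jsonable(getattr(obj, f.name))
        if isinstance(obj, Region):
            d["length"] = obj.length
        return d
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def build_report(
    genome: GenomeRecord,
    *,
    architecture=None,
    prf=None,
    comparison=None,
) -> dict:
    """Assemble a machine-readable annotation report as a plain dict.

    Keys are stable across runs; sequence content is summarised by length,
    not embedded, except for ORF/fusion proteins.
    """
    report: dict = {
        "genome": {"id": genome.id, "length": genome.length},
    }
    if architecture is not None:
        report["architecture"] = _jsonable(architecture)
    if prf is not None:
        report["prf_signal"] = _jsonable(prf)
    if comparison is not None:
        report["comparison"] = _jsonable(comparison)
    return report


def write_report(report: dict, path: str | Path) -> None:
    """Write a report dict as deterministic (sorted-key) JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
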