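"""Residue mapping and motif scanning on annotated viral proteins.

Conserved-residue questions ("which position of this CP corresponds to the
catalytic His of the reference virus?") are answered by pairwise global
alignment with affine gaps against a reference protein, then reading the
aligned column.  RdRp motif presence (the eight motifs, I-VIII, conserved in
dsRNA-virus polymerases) is checked by scanning user-supplied consensus
patterns; a curated default set ships as configuration in
``data/rdrp_motifs.yaml``.

Consensus pattern syntax: exact residue letters; ``[ACD]`` for alternatives;
``x`` (or ``X``) for any residue; ``{n}`` / ``{n,m}`` repetition applied to
the preceding token.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import yaml
from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment with a query<->reference coordinate map."""

    aligned_query: str
    aligned_reference: str
    score: float
    identity: float  # % identical columns over alignment length
    coordinate_map: tuple[tuple[int, int], ...]  # (query_pos, ref_pos), 1-based

    def query_position_of(self, reference_position: int) -> int | None:
        for q, r in self.coordinate_map:
            if r == reference_position:
                return q
        return None


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    query_start: int  # 1-based aa coordinates
    query_end: int
    matched_subsequence: str
    pattern: str


@dataclass(frozen=True)
class MotifScanResult:
    hits: tuple[MotifHit, ...]
    all_present_in_order: bool


def align_pair(
    query: str,
    reference: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> AlignmentResult:
    """Optimal global alignment of two proteins with affine gap penalties.

    A gap of length k costs ``gap_open + k * gap_extend`` (end gaps
    included).  Among co-optimal alignments the first of the aligner's
    deterministic enumeration is returned, so output is reproducible.
    """
    for name, s in (("query", query), ("reference", reference)):
        if not s:
            raise ValueError(f"empty {name} sequence")
        bad = set(s) - AA_ALPHABET
        if bad:
            raise ValueError(f"{name} contains non-standard residues {sorted(bad)}")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    alignment = next(iter(aligner.align(query, reference)))
    aligned_q, aligned_r = str(alignment[0]), str(alignment[1])

    coord_map: list[tuple[int, int]] = []
    identical = 0
    qi = ri = 0
    for cq, cr in zip(aligned_q, aligned_r):
        if cq != "-":
            qi += 1
        if cr != "-":
            ri += 1
        if cq != "-" and cr != "-":
            coord_map.append((qi, ri))
            if cq == cr:
                identical += 1
    return AlignmentResult(
        aligned_query=aligned_q,
        aligned_reference=aligned_r,
        score=float(alignment.score),
        identity=round(100.0 * identical / len(aligned_q), 2),
        coordinate_map=tuple(coord_map),
    )


def map_residue(alignment: AlignmentResult, reference_position: int) -> int | None:
    """Query position aligned to a reference position, or None if gapped.

    Positions are 1-based; an out-of-range reference position is an error.
    """
    n_ref = len(alignment.aligned_reference.replace("-", ""))
    if not (1 <= reference_position <= n_ref):
        raise ValueError(
            f"reference position {reference_position} outside [1, {n_ref}]"
        )
    return alignment.query_position_of(reference_position)


_TOKEN = re.compile(
    r"(?P<set>\[[A-Z]+\])|(?P<any>[xX])|(?P<res>[A-Z])|(?P<rep>\{\d+(,\d+)?\})"
)


def compile_consensus(pattern: str) -> re.Pattern:
    """Compile a consensus pattern to a regular expression.

    Raises ValueError naming the pattern on any malformed input (unknown
    characters, repetition without a preceding token, residues outside the
    standard alphabet).
    """
    pos = 0
    parts: list[str] = []
    while pos < len(pattern):
        m = _TOKEN.match(pattern, pos)
        if m is None:
            raise ValueError(f"malformed consensus pattern {pattern!r} at offset {pos}")
        if m.lastgroup == "set":
            residues = m.group("set")[1:-1]
            if not set(residues) <= AA_ALPHABET:
                raise ValueError(f"malformed consensus pattern {pattern!r}: bad set {residues}")
            parts.append(f"[{residues}]")
        elif m.lastgroup == "any":
            parts.append(".")
        elif m.lastgroup == "res":
            if m.group("res") not in AA_ALPHABET:
                raise ValueError(
                    f"malformed consensus pattern {pattern!r}: residue {m.group('res')}"
                )
            parts.append(m.group("res"))
        else:  # repetition
            if not parts:
                raise ValueError(
                    f"malformed consensus pattern {pattern!r}: repetition with no token"
                )
            parts[-1] += m.group("rep")
        pos = m.end()
    return re.compile("".join(parts))


def scan_motifs(protein: str, motif_set: list[tuple[str, str]]) -> MotifScanResult:
    """Scan a protein for every motif; summary flag for ordered presence.

    ``motif_set`` is a list of (motif_id, consensus pattern).  Per motif, all
    non-overlapping leftmost matches are reported.  The summary flag is true
    when every motif has at least one hit and their first hits appear in the
    listed order along the protein (strictly increasing starts).  The hit
    list is independent of ``motif_set`` ordering.
    """
    hits: list[MotifHit] = []
    first_start: dict[str, int] = {}
    for motif_id, pattern in motif_set:
        rx = compile_consensus(pattern)
        for m in rx.finditer(protein):
            hits.append(
                MotifHit(
                    motif_id=motif_id,
                    query_start=m.start() + 1,
                    query_end=m.end(),
                    matched_subsequence=m.group(),
                    pattern=pattern,
                )
            )
            first_start.setdefault(motif_id, m.start() + 1)
    hits.sort(key=lambda h: (h.query_start, h.query_end, h.motif_id))
    ids = [mid for mid, _ in motif_set]
    in_order = all(mid in first_start for mid in ids) and all(
        first_start[a] < first_start[b] for a, b in zip(ids, ids[1:])
    )
    return MotifScanResult(hits=tuple(hits), all_present_in_order=in_order)


def load_motif_set(path: str | None = None) -> list[tuple[str, str]]:
    """Load a motif set from YAML (``{motifs: [{id, pattern}, ...]}``).

    With no path, the package's curated default RdRp motif set is returned.
    """
    if path is None:
        text = (
            resources.files("totiscan").joinpath("data/rdrp_motifs.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    return [(str(m["id"]), str(m["pattern"])) for m in doc["motifs"]]
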