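"""Detection of -1 programmed ribosomal frameshifting (-1 PRF) elements.

A -1 PRF signal in a totivirus-like genome consists of three elements in the
region preceding the upstream ORF's stop codon:

* a slippery heptamer of the general form XXXYYYZ (X any base, Y in {A, U},
  Z in {A, C, U}); a *relaxed* dialect drops the X-identity requirement,
  which naturally occurring sites (e.g. UGUUUUC) require;
* a short spacer;
* an H-type pseudoknot: the loop of a hairpin (stem 1) base-pairs with
  sequence downstream of the hairpin (stem 2), producing crossed helices.

Pseudoknot candidates are found by exhaustive enumeration of helix pairs in a
bounded window and ranked by an estimated free energy (EFE): the sum of
per-base-pair scores (GC -3.0, AU -2.0, GU -1.0 kcal/mol by default), more
negative meaning more stable.

The predicted fusion product models tandem slippage as one nucleotide read
twice: translation proceeds in the upstream ORF's frame to the codon boundary
at (or offset from) the heptamer's last nucleotide, slips back one
nucleotide, and continues in the -1 frame to the first stop codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .genome_model import GenomeRecord, Region
from .orf_annotation import (
    STOP_CODONS,
    OrfAnnotation,
    TranslationError,
    molecular_weight_kda,
    translate,
)

#: Default per-base-pair EFE scores, kcal/mol.
DEFAULT_PAIR_SCORES = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

SLIPPERY_Y = frozenset("AU")
SLIPPERY_Z = frozenset("ACU")
SLIPPERY_X = frozenset("ACGU")


@dataclass(frozen=True)
class SlipperySite:
    """A heptamer at which the ribosome can slip -1 nt."""

    region: Region  # 7 nt, label slippery_site
    heptamer: str
    dialect: str  # "strict" or "relaxed"

    def __post_init__(self) -> None:
        if self.region.length != 7 or len(self.heptamer) != 7:
            raise ValueError("slippery site must be exactly 7 nt")


@dataclass(frozen=True)
class Pseudoknot:
    """An H-type pseudoknot candidate: two crossed helices with loops."""

    region: Region  # full extent, label pseudoknot
    stem1: tuple[Region, Region]  # (5' half, 3' half)
    stem2: tuple[Region, Region]
    loops: tuple[Region, ...]
    efe: float  # kcal/mol, sum of pair scores


@dataclass(frozen=True)
class FusionProduct:
    """Predicted ORF1-extension product of a single -1 frameshift."""

    cds_span: Region  # ORF1 start .. last nt of the -1 frame stop
    slip_position: int  # 0-frame codon boundary at which the slip is applied
    protein: str
    protein_length: int
    molecular_weight: float  # kDa
    overlap_nt: int  # length of the 0-frame / -1-frame same-sequence overlap


@dataclass(frozen=True)
class PrfSignal:
    """Slippery site + spacer + pseudoknot (+ fusion product) bundle.

    Missing elements are ``None`` and explained in ``diagnostics``.
    """

    slippery: SlipperySite | None
    spacer: Region | None
    pseudoknot: Pseudoknot | None
    fusion: FusionProduct | None
    diagnostics: tuple[str, ...] = ()

    @property
    def complete(self) -> bool:
        return (
            self.slippery is not None
            and self.spacer is not None
            and self.pseudoknot is not None
        )


def is_slippery(heptamer: str, dialect: str = "relaxed") -> bool:
    """Whether a 7-mer matches the XXXYYYZ slippery consensus.

    ``strict``: X1=X2=X3 (any base), Y4=Y5=Y6 in {A, U}, Z7 in {A, C, U}.
    ``relaxed``: as strict but the X triplet unconstrained (any bases).
    """
    if len(heptamer) != 7:
        return False
    x, y, z = heptamer[:3], heptamer[3:6], heptamer[6]
    if any(c not in SLIPPERY_X for c in heptamer):
        return False
    if not (y[0] == y[1] == y[2] and y[0] in SLIPPERY_Y and z in SLIPPERY_Z):
        return False
    if dialect == "strict":
        return x[0] == x[1] == x[2]
    if dialect == "relaxed":
        return True
    raise ValueError(f"unknown slippery dialect {dialect!r}")


def scan_slippery(
    genome: GenomeRecord,
    window: Region | None = None,
    dialect: str = "relaxed",
) -> list[SlipperySite]:
    """All slippery heptamers whose 7 nt lie entirely within ``window``.

    Hits are returned in ascending start order.  A window shorter than 7 nt
    yields an empty list with a warning.
    """
    if window is None:
        window = Region(1, genome.length, "orf")
    if window.end > genome.length:
        raise ValueError("window outside genome")
    if window.length < 7:
        warnings.warn("window shorter than 7 nt: no slippery site can fit")
        return []
    hits = []
    for start in range(window.start, window.end - 5):
        hept = genome.slice(start, start + 6)
        if is_slippery(hept, dialect):
            hits.append(
                SlipperySite(
                    region=Region(start, start + 6, "slippery_site"),
                    heptamer=hept,
                    dialect=dialect,
                )
            )
    return hits


def _helices(seq: str, lo: int, hi: int, min_stem: int, pair_scores) -> list[tuple[int, int, int, float]]:
    """All helices (left_start, right_end, length, efe) with contiguous pairing.

    Coordinates are absolute 1-based; the helix pairs seq[a+j] with seq[d-j]
    for j in [0, length).  Every length from ``min_stem`` up to the maximal
    contiguous run is emitted (shorter stems are distinct candidates); the
    EFE of each is accumulated while the run is extended.
    """
    out = []
    for a in range(lo, hi + 1):
        for d in range(a + 2 * min_stem - 1, hi + 1):
            kmax_geom = (d - a + 1) // 2  # halves may not overlap
            k = 0
            efe = 0.0
            while k < kmax_geom:
                score = pair_scores.get((seq[a + k - 1], seq[d - k - 1]))
                if score is None:
                    break
                efe += score
                k += 1
                if k >= min_stem:
                    out.append((a, d, k, efe))
    return out


def find_pseudoknot(
    genome: GenomeRecord,
    search_start: int,
    max_extent: int = 60,
    min_stem: int = 3,
    max_loop: int = 20,
    pair_scores: dict | None = None,
) -> list[Pseudoknot]:
    """Exhaustively enumerate H-type pseudoknots in a bounded window.

    Candidates lie entirely within ``[search_start, search_start + max_extent - 1]``
    (clipped at the genome end).  A candidate is a pair of helices (stem 1,
    stem 2) such that stem 2's 5' half lies inside stem 1's loop and its 3'
    half lies strictly downstream of stem 1 — the crossing topology of an
    H-type pseudoknot.  Plain hairpins (no crossing helix) are not reported.
    Loops are bounded by ``max_loop``; stems need at least ``min_stem``
    contiguous canonical pairs (Watson-Crick or GU wobble).

    Returns all candidates ranked by EFE ascending, ties broken by smaller
    total extent, then by 5'-most start.
    """
    if not (1 <= search_start <= genome.length):
        raise ValueError("search_start outside genome")
    scores = DEFAULT_PAIR_SCORES if pair_scores is None else pair_scores
    lo = search_start
    hi = min(genome.length, search_start + max_extent - 1)
    seq = genome.sequence
    helices = _helices(seq, lo, hi, min_stem, scores)

    out: list[Pseudoknot] = []
    for a1, d1, L1, efe1 in helices:
        loop1_lo, loop1_hi = a1 + L1, d1 - L1  # stem 1 loop, inclusive
        if loop1_lo > loop1_hi:
            continue
        for a2, d2, L2, efe2 in helices:
            # stem 2 5' half inside stem 1's loop; 3' half downstream of stem 1
            if a2 < loop1_lo or a2 + L2 - 1 > loop1_hi:
                continue
            if d2 - L2 + 1 <= d1:
                continue
            loop_a = a2 - loop1_lo
            loop_b = loop1_hi - (a2 + L2 - 1)
            loop_c = (d2 - L2 + 1) - (d1 + 1)
            if max(loop_a, loop_b, loop_c) > max_loop:
                continue
            loops = []
            if loop_a > 0:
                loops.append(Region(loop1_lo, a2 - 1, "pseudoknot"))
            if loop_b > 0:
                loops.append(Region(a2 + L2, loop1_hi, "pseudoknot"))
            if loop_c > 0:
                loops.append(Region(d1 + 1, d2 - L2, "pseudoknot"))
            out.append(
                Pseudoknot(
                    region=Region(a1, d2, "pseudoknot"),
                    stem1=(
                        Region(a1, a1 + L1 - 1, "pseudoknot"),
                        Region(d1 - L1 + 1, d1, "pseudoknot"),
                    ),
                    stem2=(
                        Region(a2, a2 + L2 - 1, "pseudoknot"),
                        Region(d2 - L2 + 1, d2, "pseudoknot"),
                    ),
                    loops=tuple(loops),
                    efe=efe1 + efe2,
                )
            )
    out.sort(key=lambda p: (p.efe, p.region.length, p.region.start))
    return out


def build_fusion(
    genome: GenomeRecord,
    orf1: OrfAnnotation,
    slippery: SlipperySite,
    slip_codon_offset: int = 0,
) -> FusionProduct:
    """Construct the ORF1-extension fusion product of a single -1 slip.

    Translation runs in ORF1's frame from its AUG through the last full
    ORF1-frame codon ending at or before the heptamer's last nucleotide,
    re-reads that boundary nucleotide in the -1 frame, and continues to the
    first -1-frame stop codon.  The translated nucleotide count is therefore
    the cds span plus one, and the protein length is independent of
    ``slip_codon_offset`` (whole-codon shifts of the slip boundary, for
    convention-robustness checks).

    ``overlap_nt`` is the length of the overlap between ORF1 and the
    stop-free extended -1 reading frame: ORF1's end minus the 5'-most
    -1-frame codon start reachable from the slip without crossing a stop,
    plus one.
    """
    seq = genome.sequence
    slip_end = slippery.region.end
    if not (orf1.region.start <= slippery.region.start and slip_end <= orf1.region.end - 3):
        raise ValueError("slippery site must lie inside ORF1, upstream of its stop codon")

    # last ORF1-frame codon end at or before the heptamer's last nt
    codon_end_phase = (orf1.region.start + 2) % 3
    p = slip_end - ((slip_end - codon_end_phase) % 3)
    p += 3 * slip_codon_offset
    if not (orf1.region.start + 2 <= p <= orf1.region.end):
        raise ValueError("slip boundary outside ORF1")

    # -1 frame: codons start at p (nucleotide p is read twice)
    stop_start = None
    q = p
    while q + 2 <= genome.length:
        if seq[q - 1 : q + 2] in STOP_CODONS:
            stop_start = q
            break
        q += 3
    if stop_start is None:
        raise ValueError("runaway fusion frame: no -1-frame stop before genome end")
    if stop_start == p:
        raise ValueError(f"internal stop immediately after slip at position {p}")
    stop_end = stop_start + 2

    zero_part = seq[orf1.region.start - 1 : p]
    minus_part = seq[p - 1 : stop_end]
    try:
        protein = translate(zero_part + minus_part)
    except TranslationError as exc:
        raise ValueError(f"fusion translation failed: {exc}") from None

    # 5'-most stop-free -1-frame codon start at or upstream of the slip
    r = p
    while r - 3 >= 1 and seq[r - 4 : r - 1] not in STOP_CODONS:
        r -= 3
    overlap_nt = orf1.region.end - r + 1

    return FusionProduct(
        cds_span=Region(orf1.region.start, stop_end, "orf"),
        slip_position=p,
        protein=protein,
        protein_length=len(protein),
        molecular_weight=molecular_weight_kda(protein),
        overlap_nt=overlap_nt,
    )


def detect_prf(
    genome: GenomeRecord,
    orf1: OrfAnnotation,
    downstream_orf: OrfAnnotation | None = None,
    *,
    dialect: str = "relaxed",
    window_nt: int = 150,
    min_spacer: int = 4,
    max_spacer: int = 20,
    pk_max_extent: int = 60,
    min_stem: int = 3,
    max_loop: int = 20,
    with_fusion: bool = True,
) -> PrfSignal:
    """Scan the region preceding ORF1's stop codon for a complete -1 PRF signal.

    Every slippery heptamer (per ``dialect``) in the ``window_nt`` window
    upstream of the stop codon is considered; for each, pseudoknot candidates
    are enumerated downstream, and a candidate is admissible if the implied
    spacer length (pseudoknot start - heptamer end - 1) lies in
    [``min_spacer``, ``max_spacer``].  The best complete signal is returned:
    lowest pseudoknot EFE, then smallest pseudoknot extent, then shortest
    spacer (canonical -1 PRF spacers are short, and under the relaxed dialect
    any heptamer has valid 1-nt-shifted 5' variants, so spacer length — not
    heptamer start — is the meaningful geometric tie-break), then 5'-most
    heptamer.  If no complete signal exists, a partial signal with
    diagnostics is returned instead.
    """
    if downstream_orf is not None and downstream_orf.region.start <= orf1.region.end:
        raise ValueError("downstream ORF must start after ORF1 ends")

    stop_start = orf1.region.end - 2
    win_lo = max(orf1.region.start, stop_start - window_nt)
    win_hi = stop_start - 1
    if win_hi < win_lo:
        return PrfSignal(None, None, None, None, ("ORF1 too short for a scan window",))
    sites = scan_slippery(genome, Region(win_lo, win_hi, "orf"), dialect)
    if not sites:
        return PrfSignal(
            None, None, None, None,
            (f"no {dialect}-dialect slippery heptamer in [{win_lo}, {win_hi}]",),
        )

    best: tuple[float, int, int, int] | None = None
    best_site: SlipperySite | None = None
    best_pk: Pseudoknot | None = None
    for site in sites:
        search_start = site.region.end + 1 + min_spacer
        if search_start > genome.length:
            continue
        window_len = (max_spacer - min_spacer) + pk_max_extent
        cands = find_pseudoknot(
            genome, search_start, max_extent=window_len,
            min_stem=min_stem, max_loop=max_loop,
        )
        for pk in cands:
            spacer_len = pk.region.start - site.region.end - 1
            if not (min_spacer <= spacer_len <= max_spacer):
                continue
            if pk.region.length > pk_max_extent:
                continue
            key = (pk.efe, pk.region.length, spacer_len, site.region.start)
            if best is None or key < best:
                best, best_site, best_pk = key, site, pk
            break  # candidates are ranked; first admissible is this site's best

    if best_pk is None or best_site is None:
        return PrfSignal(
            slippery=sites[0],
            spacer=None,
            pseudoknot=None,
            fusion=None,
            diagnostics=("slippery site(s) found but no admissible pseudoknot downstream",),
        )

    spacer = Region(best_site.region.end + 1, best_pk.region.start - 1, "spacer")
    fusion = None
    diagnostics: tuple[str, ...] = ()
    if with_fusion:
        try:
            fusion = build_fusion(genome, orf1, best_site)
        except ValueError as exc:
            diagnostics = (f"fusion construction failed: {exc}",)
    return PrfSignal(
        slippery=best_site,
        spacer=spacer,
        pseudoknot=best_pk,
        fusion=fusion,
        diagnostics=diagnostics,
    )
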