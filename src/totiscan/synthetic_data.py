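"""Synthetic totivirus-like genomes with planted, recoverable architecture.

The generator builds a genome from a declarative :class:`GenomeArchitecture`:
ORF coordinates with AUG starts and declared stop codons, a slippery
heptamer, an H-type pseudoknot with complementary planted stems, a -1 frame
kept stop-free from a declared position through the fusion stop, and a list
of point mutations for a companion "second isolate".  Everything else is
neutral random sequence drawn from the seed (uniform over A/C/G/U by
default, optional GC bias).

Constraint satisfaction is plant-then-repair: fixed elements are written
first and locked; random fill is then repaired codon-by-codon (no internal
stops in any constrained frame, no AUG upstream of a planted start in its
frame, mutation-site codons kept compatible with their requested effect
class), and the finished candidate is verified end-to-end — the ORF finder
must recover exactly the planted ORFs and the PRF scanner exactly the
planted signal — with targeted, seeded repairs on any accidental competitor.
All draws come from one seeded generator, so output is a deterministic
function of (architecture, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .genome_model import GenomeRecord
from .orf_annotation import (
    START_CODON,
    STOP_CODONS,
    derive_architecture,
    find_orfs,
    translate,
)
from .prf_scanner import detect_prf, is_slippery

BASES = ("A", "C", "G", "U")
COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

MUTATION_CLASSES = ("utr", "silent", "nonsynonymous")


class ArchitectureError(ValueError):
    """Raised for self-inconsistent architectures or unsatisfiable constraints."""


@dataclass(frozen=True)
class PseudoknotSpec:
    """Layout of a planted H-type pseudoknot.

    Segments in 5'->3' order: stem1 5' half, loop A, stem2 5' half, loop B,
    stem1 3' half, loop C, stem2 3' half.  Stems are planted as complementary
    G/C pairs (maximally stable under the detector's default pair scores).
    """

    start: int
    stem1: int
    stem2: int
    loops: tuple[int, int, int]

    @property
    def end(self) -> int:
        return self.start + 2 * self.stem1 + 2 * self.stem2 + sum(self.loops) - 1

    def segments(self) -> dict[str, tuple[int, int]]:
        """1-based inclusive (start, end) of each segment."""
        p = self.start
        out = {}
        for name, length in (
            ("stem1_5p", self.stem1),
            ("loop_a", self.loops[0]),
            ("stem2_5p", self.stem2),
            ("loop_b", self.loops[1]),
            ("stem1_3p", self.stem1),
            ("loop_c", self.loops[2]),
            ("stem2_3p", self.stem2),
        ):
            out[name] = (p, p + length - 1) if length > 0 else (p, p - 1)
            p += length
        return out


@dataclass(frozen=True)
class GenomeArchitecture:
    """Declarative layout consumed by :func:`generate_genome`."""

    name: str
    total_length: int
    orfs: tuple[tuple[int, int], ...]
    slippery_start: int
    slippery_heptamer: str
    pseudoknot: PseudoknotSpec
    minus_one_stop_free_from: int
    mutations: tuple[tuple[int, str], ...] = ()
    stop_codon: str = "UAA"
    gc_bias: float = 0.5  # probability mass on G+C in neutral fill
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_length <= 0:
            raise ArchitectureError("total_length must be positive")
        if self.stop_codon not in STOP_CODONS:
            raise ArchitectureError(f"stop codon {self.stop_codon!r} is not a stop")
        if not self.orfs:
            raise ArchitectureError("at least one ORF required")
        prev_end = 0
        for start, end in self.orfs:
            if not (1 <= start < end <= self.total_length):
                raise ArchitectureError(f"ORF ({start}, {end}) outside genome")
            if (end - start + 1) % 3 != 0:
                raise ArchitectureError(
                    f"ORF ({start}, {end}) length {end - start + 1} not divisible by 3"
                )
            if start <= prev_end:
                raise ArchitectureError("ORFs must be non-overlapping and ordered")
            prev_end = end
        o1s, o1e = self.orfs[0]
        hept = self.slippery_heptamer
        if len(hept) != 7 or not is_slippery(hept, "relaxed"):
            raise ArchitectureError(f"heptamer {hept!r} is not a relaxed slippery site")
        slip_end = self.slippery_start + 6
        if not (o1s <= self.slippery_start and slip_end <= o1e - 3):
            raise ArchitectureError("slippery site must lie inside ORF1, before its stop")
        pk = self.pseudoknot
        spacer = pk.start - slip_end - 1
        if not (4 <= spacer <= 20):
            raise ArchitectureError(f"spacer length {spacer} outside [4, 20]")
        if pk.end > self.total_length:
            raise ArchitectureError("pseudoknot extends past genome end")
        if min(pk.stem1, pk.stem2) < 3 or max(pk.loops) > 20 or min(pk.loops) < 0:
            raise ArchitectureError("pseudoknot stems must be >= 3, loops in [0, 20]")
        # -1 frame bookkeeping: codon starts in the -1 frame sit one nt 5'
        # of ORF1-frame starts; the fusion must terminate at the last ORF's stop.
        sf = self.minus_one_stop_free_from
        if sf % 3 != (o1s - 1) % 3:
            raise ArchitectureError(
                f"minus_one_stop_free_from {sf} is not a -1-frame codon start"
            )
        if not (1 <= sf - 3 - 1 + 1 and sf < o1e):
            raise ArchitectureError("stop-free origin must leave room for its 5' stop")
        last_stop_start = self.orfs[-1][1] - 2
        if last_stop_start % 3 != sf % 3:
            raise ArchitectureError(
                "last ORF stop is not in the -1 frame of ORF1; fusion cannot terminate"
            )
        for pos, effect in self.mutations:
            if not (1 <= pos <= self.total_length):
                raise ArchitectureError(f"mutation position {pos} outside genome")
            if effect not in MUTATION_CLASSES:
                raise ArchitectureError(f"unknown mutation effect {effect!r}")
            inside = any(s <= pos <= e for s, e in self.orfs)
            if effect == "utr" and inside:
                raise ArchitectureError(f"utr mutation at {pos} lies inside an ORF")
            if effect in ("silent", "nonsynonymous") and not inside:
                raise ArchitectureError(f"{effect} mutation at {pos} lies outside ORFs")

    # Quantities the architecture implies (used by tests and reports).
    @property
    def spacer_length(self) -> int:
        return self.pseudoknot.start - (self.slippery_start + 6) - 1

    @property
    def fusion_protein_length(self) -> int:
        span = self.orfs[-1][1] - self.orfs[0][0] + 1
        return (span + 1) // 3 - 1

    @property
    def overlap_nt(self) -> int:
        return self.orfs[0][1] - self.minus_one_stop_free_from + 1


def tktv1_architecture(seed: int = 0) -> GenomeArchitecture:
    """The TkTV1-style fixture: a 4712-nt yeast-totivirus-like layout.

    5'-UTR 97 nt; ORF1 at 98-2161 (frame 2); 248-nt intergenic region; ORF2
    at 2410-4653 (frame 1); 3'-UTR 59 nt; slippery heptamer UGUUUUC at
    2104-2110; 19-nt spacer; pseudoknot at 2130-2154; -1 frame stop-free
    from 1990 (172-nt ORF1 overlap; 1518-aa fusion product); five companion
    mutations at 84, 1003, 1336, 1952, 3507 (one UTR, three silent, one
    amino-acid-changing).
    """
    return GenomeArchitecture(
        name="synthetic-totivirus",
        total_length=4712,
        orfs=((98, 2161), (2410, 4653)),
        slippery_start=2104,
        slippery_heptamer="UGUUUUC",
        pseudoknot=PseudoknotSpec(start=2130, stem1=5, stem2=4, loops=(2, 2, 3)),
        minus_one_stop_free_from=1990,
        mutations=(
            (84, "utr"),
            (1003, "silent"),
            (1336, "silent"),
            (1952, "nonsynonymous"),
            (3507, "silent"),
        ),
        stop_codon="UAA",
        seed=seed,
    )


def architecture_from_yaml(path: str | Path | None = None, seed: int = 0) -> GenomeArchitecture:
    """Load an architecture from YAML (default: the packaged tktv1 layout)."""
    if path is None:
        text = resources.files("totiscan").joinpath("data/tktv1.yaml").read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    pk = doc["pseudoknot"]
    return GenomeArchitecture(
        name=str(doc.get("name", "synthetic-genome")),
        total_length=int(doc["total_length"]),
        orfs=tuple((int(o["start"]), int(o["end"])) for o in doc["orfs"]),
        slippery_start=int(doc["slippery"]["start"]),
        slippery_heptamer=str(doc["slippery"]["heptamer"]),
        pseudoknot=PseudoknotSpec(
            start=int(pk["start"]),
            stem1=int(pk["stem1"]),
            stem2=int(pk["stem2"]),
            loops=tuple(int(x) for x in pk["loops"]),
        ),
        minus_one_stop_free_from=int(doc["minus_one_frame"]["stop_free_from"]),
        mutations=tuple(
            (int(m["position"]), str(m["effect"])) for m in doc.get("mutations", [])
        ),
        stop_codon=str(doc.get("stop_codon", "UAA")),
        gc_bias=float(doc.get("gc_bias", 0.5)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generation internals


def _base_probs(gc_bias: float) -> np.ndarray:
    at = (1.0 - gc_bias) / 2.0
    gc = gc_bias / 2.0
    return np.array([at, gc, gc, at])  # A, C, G, U


class _Builder:
    """Mutable genome under construction with locked positions (0-based ops)."""

    def __init__(self, arch: GenomeArchitecture, rng: np.random.Generator):
        self.arch = arch
        self.rng = rng
        self.probs = _base_probs(arch.gc_bias)
        self.seq = [
            BASES[i] for i in rng.choice(4, size=arch.total_length, p=self.probs)
        ]
        self.locked: set[int] = set()  # 1-based positions

    def plant(self, start: int, text: str, lock: bool = True) -> None:
        for i, c in enumerate(text):
            self.seq[start - 1 + i] = c
            if lock:
                self.locked.add(start + i)

    def codon(self, start: int) -> str:
        return "".join(self.seq[start - 1 : start + 2])

    def draw_base(self) -> str:
        return BASES[self.rng.choice(4, p=self.probs)]

    def resample_codon(self, start: int, ok, tries: int = 40) -> bool:
        """Resample unlocked bases of the codon at ``start`` until ``ok(codon)``."""
        free = [p for p in (start, start + 1, start + 2) if p not in self.locked]
        if not free:
            return ok(self.codon(start))
        for _ in range(tries):
            for p in free:
                self.seq[p - 1] = self.draw_base()
            if ok(self.codon(start)):
                return True
        return False

    def record(self) -> GenomeRecord:
        return GenomeRecord(id=self.arch.name, sequence="".join(self.seq))


def _plant_fixed_elements(b: _Builder) -> None:
    arch = b.arch
    for start, end in arch.orfs:
        b.plant(start, START_CODON)
        b.plant(end - 2, arch.stop_codon)
    b.plant(arch.slippery_start, arch.slippery_heptamer)
    # 5' boundary of the stop-free -1 frame: a stop codon just upstream
    b.plant(arch.minus_one_stop_free_from - 3, arch.stop_codon)
    # pseudoknot stems: seeded G/C sequences and their reverse complements
    seg = arch.pseudoknot.segments()
    for five, three, length in (
        ("stem1_5p", "stem1_3p", arch.pseudoknot.stem1),
        ("stem2_5p", "stem2_3p", arch.pseudoknot.stem2),
    ):
        left = "".join(b.rng.choice(["G", "C"], size=length))
        right = "".join(COMPLEMENT[c] for c in reversed(left))
        b.plant(seg[five][0], left)
        b.plant(seg[three][0], right)


def _synonymous_choices(codon: str, codon_position: int) -> list[str]:
    ref_aa = translate_codon(codon)
    out = []
    for base in BASES:
        if base == codon[codon_position - 1]:
            continue
        alt = codon[: codon_position - 1] + base + codon[codon_position:]
        if translate_codon(alt) == ref_aa:
            out.append(base)
    return out


def _nonsynonymous_choices(codon: str, codon_position: int) -> list[str]:
    ref_aa = translate_codon(codon)
    out = []
    for base in BASES:
        if base == codon[codon_position - 1]:
            continue
        alt = codon[: codon_position - 1] + base + codon[codon_position:]
        aa = translate_codon(alt)
        if aa != ref_aa and aa != "*":
            out.append(base)
    return out


def translate_codon(codon: str) -> str:
    """Single-codon translation; '*' for stop codons."""
    if codon in STOP_CODONS:
        return "*"
    return translate(codon) if codon != "AUG" else "M"


def _local_constraints(arch: GenomeArchitecture) -> list[tuple[int, str, int]]:
    """(codon_start, kind, codon_position) triples; kind drives the check."""
    cons: list[tuple[int, str, int]] = []
    for start, end in arch.orfs:
        for c in range(start + 3, end - 4, 3):  # interior codons only
            cons.append((c, "no_stop", 0))
    # stop-free -1 frame through to the fusion stop (exclusive)
    fusion_stop_start = arch.orfs[-1][1] - 2
    for c in range(arch.minus_one_stop_free_from, fusion_stop_start, 3):
        cons.append((c, "no_stop", 0))
    # no AUG upstream of a planted start, in that ORF's frame
    for start, _end in arch.orfs:
        first = (start - 1) % 3 + 1
        for c in range(first, start - 2, 3):
            if c != start:
                cons.append((c, "no_aug", 0))
    # mutation-site codons must admit the requested effect class
    for pos, effect in arch.mutations:
        if effect == "utr":
            continue
        for start, end in arch.orfs:
            if start <= pos <= end:
                offset = pos - start
                cstart = start + (offset // 3) * 3
                cons.append((cstart, f"mut_{effect}", offset % 3 + 1))
                break
    return sorted(set(cons))


def _codon_ok(kind: str, codon_position: int):
    if kind == "no_stop":
        return lambda c: c not in STOP_CODONS
    if kind == "no_aug":
        return lambda c: c != START_CODON
    if kind == "mut_silent":
        return lambda c: c not in STOP_CODONS and bool(
            _synonymous_choices(c, codon_position)
        )
    if kind == "mut_nonsynonymous":
        return lambda c: c not in STOP_CODONS and bool(
            _nonsynonymous_choices(c, codon_position)
        )
    raise AssertionError(kind)


def _repair_local(b: _Builder, cons, max_passes: int = 60) -> bool:
    for _ in range(max_passes):
        dirty = False
        for cstart, kind, cpos in cons:
            ok = _codon_ok(kind, cpos)
            if ok(b.codon(cstart)):
                continue
            if not b.resample_codon(cstart, ok):
                raise ArchitectureError(
                    f"unsatisfiable constraint {kind} at codon starting {cstart} "
                    "(all positions locked)"
                )
            dirty = True
        if not dirty:
            return True
    return False


def _verify_and_repair_global(b: _Builder, max_rounds: int = 60) -> bool:
    """Planted elements must be exactly what the package's scanners recover."""
    arch = b.arch
    min_len = min(300, min(e - s + 1 for s, e in arch.orfs))
    cons = _local_constraints(arch)
    for _ in range(max_rounds):
        if not _repair_local(b, cons):
            return False
        rec = b.record()
        orfs = find_orfs(rec, min_length_nt=min_len)
        got = [(o.region.start, o.region.end) for o in orfs]
        planted = list(arch.orfs)
        extra = [span for span in got if span not in planted]
        if extra:
            start = extra[0][0]  # degrade the spurious ORF's AUG
            if not b.resample_codon(start, lambda c: c != START_CODON):
                return False
            continue
        if got != planted:
            return False  # a planted ORF failed to surface; redraw

        orf1 = orfs[0]
        sig = detect_prf(rec, orf1, dialect="relaxed", with_fusion=True)
        slip_region = (arch.slippery_start, arch.slippery_start + 6)
        pk_region = (arch.pseudoknot.start, arch.pseudoknot.end)
        if sig.slippery is None or sig.pseudoknot is None:
            return False
        got_slip = (sig.slippery.region.start, sig.slippery.region.end)
        got_pk = (sig.pseudoknot.region.start, sig.pseudoknot.region.end)
        if got_pk != pk_region:
            if not _degrade_competitor(b, sig.pseudoknot):
                return False
            continue
        if got_slip != slip_region:
            if not _degrade_heptamer(b, got_slip[0]):
                return False
            continue
        if sig.fusion is None:
            return False
        if (
            sig.fusion.protein_length != arch.fusion_protein_length
            or sig.fusion.overlap_nt != arch.overlap_nt
            or sig.spacer.length != arch.spacer_length
        ):
            return False
        return True
    return False


def _degrade_competitor(b: _Builder, pk) -> bool:
    """Break an accidental pseudoknot by resampling one unlocked stem base."""
    for half in (*pk.stem1, *pk.stem2):
        for pos in range(half.start, half.end + 1):
            if pos not in b.locked:
                old = b.seq[pos - 1]
                for _ in range(10):
                    b.seq[pos - 1] = b.draw_base()
                    if b.seq[pos - 1] != old:
                        return True
    return False


def _degrade_heptamer(b: _Builder, start: int) -> bool:
    """Break an accidental slippery site at its Y/Z positions (4..7)."""
    for pos in range(start + 3, start + 7):
        if pos not in b.locked:
            b.seq[pos - 1] = "G" if b.seq[pos - 1] != "G" else "C"
            return True
    return False


def generate_genome(arch: GenomeArchitecture, seed: int | None = None) -> GenomeRecord:
    """Generate a genome realizing ``arch`` exactly, deterministically.

    The returned genome satisfies every declared constraint *as recovered by
    the package's own scanners*: `find_orfs` (at min length 300 or the
    smallest planted ORF) returns exactly the planted ORFs, and `detect_prf`
    returns the planted slippery site, spacer and pseudoknot with the implied
    fusion product.  Raises :class:`ArchitectureError` if the constraint set
    cannot be satisfied within the retry budget.
    """
    seed = arch.seed if seed is None else seed
    for attempt in range(50):
        rng = np.random.default_rng((seed, attempt))
        b = _Builder(arch, rng)
        _plant_fixed_elements(b)
        try:
            if _verify_and_repair_global(b):
                return b.record()
        except ArchitectureError:
            raise
    raise ArchitectureError(
        f"could not satisfy architecture {arch.name!r} within the retry budget; "
        "first failing constraint: planted-element recovery"
    )


def generate_mutant(
    genome: GenomeRecord,
    mutation_specs: tuple[tuple[int, str], ...],
    seed: int,
    mutant_id: str | None = None,
) -> GenomeRecord:
    """Apply one seeded substitution per spec, honouring each effect class.

    ``silent`` picks a base preserving the codon's amino acid (error listing
    the codon when none exists, e.g. at position 1 or 2, or in an AUG/UGG
    codon); ``nonsynonymous`` picks a base changing it without creating a
    stop; ``utr`` (usable in any non-coding region) picks any different
    base.  Exactly the specified positions change and nothing else.
    """
    rng = np.random.default_rng(seed)
    arch = derive_architecture(genome, find_orfs(genome))
    seq = list(genome.sequence)
    for pos, effect in sorted(mutation_specs):
        if effect not in MUTATION_CLASSES:
            raise ValueError(f"unknown mutation effect {effect!r}")
        label, orf = arch.region_of(pos)
        ref = seq[pos - 1]
        if effect == "utr":
            if orf is not None:
                raise ValueError(f"utr mutation requested at coding position {pos}")
            choices = [c for c in BASES if c != ref]
        else:
            if orf is None:
                raise ValueError(f"{effect} mutation requested at non-coding position {pos}")
            offset = pos - orf.region.start
            cstart = orf.region.start + (offset // 3) * 3
            codon = "".join(seq[cstart - 1 : cstart + 2])
            cpos = offset % 3 + 1
            if effect == "silent":
                choices = _synonymous_choices(codon, cpos)
                if not choices:
                    raise ValueError(
                        f"no synonymous substitution exists at position {pos} "
                        f"(codon {codon}, codon position {cpos})"
                    )
            else:
                choices = _nonsynonymous_choices(codon, cpos)
                if not choices:
                    raise ValueError(
                        f"no non-stop amino-acid-changing substitution at position {pos} "
                        f"(codon {codon}, codon position {cpos})"
                    )
        seq[pos - 1] = choices[rng.integers(len(choices))]
    return GenomeRecord(
        id=mutant_id or f"{genome.id}-isolate2", sequence="".join(seq)
    )


def generate_isolate_pair(
    arch: GenomeArchitecture, seed: int | None = None
) -> tuple[GenomeRecord, GenomeRecord]:
    """The fixture genome and its mutated companion isolate."""
    genome = generate_genome(arch, seed)
    mutant = generate_mutant(
        genome, arch.mutations, seed=(arch.seed if seed is None else seed) + 1
    )
    return genome, mutant
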