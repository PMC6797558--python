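"""Independent brute-force oracles used to cross-check the scanners.

These deliberately re-derive results from first principles (exhaustive
enumeration, naive cubic DP) and share no code with the package internals.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

STOPS = {"UAA", "UAG", "UGA"}
PAIRS = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "U"): -2.0,
    ("U", "A"): -2.0,
    ("G", "U"): -1.0,
    ("U", "G"): -1.0,
}

_B62 = substitution_matrices.load("BLOSUM62")
_NEG = float("-inf")


def bruteforce_orfs(seq: str, min_len: int) -> list[tuple[int, int]]:
    """Every AUG walked to its next in-frame stop; per stop, the 5'-most AUG."""
    n = len(seq)
    by_stop: dict[int, int] = {}
    for i in range(n - 2):
        if seq[i : i + 3] == "AUG":
            j = i
            while j + 2 < n:
                if seq[j : j + 3] in STOPS:
                    end, start = j + 3, i + 1
                    if end not in by_stop or start < by_stop[end]:
                        by_stop[end] = start
                    break
                j += 3
    return sorted((s, e) for e, s in by_stop.items() if e - s + 1 >= min_len)


def _pairs_ok(s: str, a: int, d: int, length: int) -> bool:
    return all((s[a - 1 + j], s[d - 1 - j]) in PAIRS for j in range(length))


def _efe(s: str, a: int, d: int, length: int) -> float:
    return sum(PAIRS[(s[a - 1 + j], s[d - 1 - j])] for j in range(length))


def bruteforce_pseudoknots(
    s: str, min_stem: int = 3, max_loop: int = 20
) -> set[tuple[int, int, int, int, int, int, float]]:
    """All H-type helix pairs in a window, as (a1, L1, d1, a2, L2, d2, efe).

    Nested loops over every candidate stem-1 (left start a1, right end d1,
    length L1) and stem-2 region pair, with per-pair complementarity checks.
    """
    n = len(s)
    out = set()
    for a1 in range(1, n + 1):
        for d1 in range(a1, n + 1):
            for L1 in range(min_stem, (d1 - a1 + 1) // 2 + 1):
                if not _pairs_ok(s, a1, d1, L1):
                    break
                lo1, hi1 = a1 + L1, d1 - L1
                for a2 in range(lo1, hi1 + 1):
                    if a2 - lo1 > max_loop:
                        break
                    for d2 in range(d1 + 1, n + 1):
                        for L2 in range(min_stem, (d2 - a2 + 1) // 2 + 1):
                            if not _pairs_ok(s, a2, d2, L2):
                                break
                            if a2 + L2 - 1 > hi1:
                                break
                            if d2 - L2 + 1 < d1 + 1:
                                continue
                            loop_b = hi1 - (a2 + L2 - 1)
                            loop_c = (d2 - L2 + 1) - (d1 + 1)
                            if loop_b > max_loop or loop_c > max_loop:
                                continue
                            out.add(
                                (a1, L1, d1, a2, L2, d2,
                                 _efe(s, a1, d1, L1) + _efe(s, a2, d2, L2))
                            )
    return out


def pseudoknot_tuples(candidates) -> set[tuple[int, int, int, int, int, int, float]]:
    """Convert scanner output to the oracle's tuple form."""
    return {
        (p.stem1[0].start, p.stem1[0].length, p.stem1[1].end,
         p.stem2[0].start, p.stem2[0].length, p.stem2[1].end, p.efe)
        for p in candidates
    }


def cubic_global_affine(x: str, y: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Optimal global affine-gap score by the naive cubic-time recurrence.

    A gap of length k costs gap_open + k * gap_extend; end gaps are charged.
    """
    n, m = len(x), len(y)
    D = [[_NEG] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            best = _NEG
            if i > 0 and j > 0:
                best = D[i - 1][j - 1] + _B62[x[i - 1], y[j - 1]]
            for k in range(1, i + 1):
                v = D[i - k][j] - (gap_open + k * gap_extend)
                if v > best:
                    best = v
            for k in range(1, j + 1):
                v = D[i][j - k] - (gap_open + k * gap_extend)
                if v > best:
                    best = v
            D[i][j] = best
    return D[n][m]
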