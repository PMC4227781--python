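"""Independent brute-force oracles used to validate the implementation.

Each oracle is written from the definition of the quantity it computes,
sharing no code with the package: six-frame ORF enumeration, memoised
recursion over all local/global alignments, exhaustive enumeration of nested
RNA pairings, and quadratic longest-common-substring search.
"""

from __future__ import annotations

from functools import lru_cache

WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
GU = {("G", "T"), ("T", "G")}
STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "GTG", "TTG"}

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# ORF enumeration
# ---------------------------------------------------------------------------

def orfs_six_frame(seq: str, min_len: int) -> set[tuple[int, int, str]]:
    """All maximal ORFs on both strands by direct position enumeration."""
    out = set()
    for strand, s in (("+", seq), ("-", rc(seq))):
        n = len(s)
        for frame in range(3):
            stops = [i for i in range(frame, n - 2, 3) if s[i : i + 3] in STOPS]
            prev = frame - 3
            for stop in stops:
                starts = [
                    i for i in range(prev + 3, stop, 3) if s[i : i + 3] in STARTS
                ]
                if starts:
                    a, b = starts[0], stop + 3
                    if b - a >= min_len and "N" not in s[a:b]:
                        coords = (a, b) if strand == "+" else (n - b, n - a)
                        out.add((coords[0], coords[1], strand))
                prev = stop
    return out


# ---------------------------------------------------------------------------
# Local alignment (Smith-Waterman, affine gaps)
# ---------------------------------------------------------------------------

def sw_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score over all alignments, by memoised recursion.

    A gap of length L costs gap_open + (L - 1) * gap_extend.  ``sub`` is a
    callable (x, y) -> score.
    """

    @lru_cache(maxsize=None)
    def h(i: int, j: int) -> tuple[float, float, float]:
        """(best ending diag, best ending gap-in-b, best ending gap-in-a)
        for alignments ending at a[i-1] / b[j-1]."""
        if i == 0 or j == 0:
            return (float("-inf"), float("-inf"), float("-inf"))
        hd, he, hf = h(i - 1, j - 1)
        diag = max(hd, he, hf, 0.0) + sub(a[i - 1], b[j - 1])
        hd2, he2, hf2 = h(i, j - 1)
        e = max(hd2 + gap_open, he2 + gap_extend, hf2 + gap_open)
        hd3, he3, hf3 = h(i - 1, j)
        f = max(hd3 + gap_open, hf3 + gap_extend, he3 + gap_open)
        return (diag, e, f)

    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            best = max(best, max(h(i, j)))
    h.cache_clear()
    return best


# ---------------------------------------------------------------------------
# Global alignment identity
# ---------------------------------------------------------------------------

def global_identity_oracle(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> float:
    """Identity of the optimal global alignment, maximising
    (score, matches, -columns) lexicographically over all alignments."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> tuple[int, int, int]:
        if i == len(a) and j == len(b):
            return (0, 0, 0)
        options = []
        if i < len(a) and j < len(b):
            s, m, c = best(i + 1, j + 1)
            eq = a[i] == b[j]
            options.append((s + (match if eq else mismatch), m + int(eq), c - 1))
        if i < len(a):
            s, m, c = best(i + 1, j)
            options.append((s + gap, m, c - 1))
        if j < len(b):
            s, m, c = best(i, j + 1)
            options.append((s + gap, m, c - 1))
        return max(options)

    s, m, c = best(0, 0)
    best.cache_clear()
    return m / (-c)


# ---------------------------------------------------------------------------
# Nested pairing enumeration
# ---------------------------------------------------------------------------

def _pairable(x: str, y: str) -> bool:
    return (x, y) in WC or (x, y) in GU


def enumerate_pairings(
    seq: str,
    min_loop: int = 3,
    forced: frozenset = frozenset(),
    forbidden: frozenset = frozenset(),
) -> list[tuple[tuple[int, int], ...]]:
    """Every nested pairing of the sequence, as sorted pair tuples."""

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        if j - i <= min_loop:
            return [()]
        out = list(enum(i + 1, j))
        for k in range(i + min_loop + 1, j):
            if i in forbidden or k in forbidden:
                continue
            if not _pairable(seq[i], seq[k]):
                continue
            for left in enum(i + 1, k):
                for right in enum(k + 1, j):
                    out.append(tuple(sorted(((i, k),) + left + right)))
        return out

    res = enum(0, len(seq))
    enum.cache_clear()
    return res


def best_constrained_pairing(
    seq: str,
    min_loop: int = 3,
    forced: frozenset = frozenset(),
    forbidden: frozenset = frozenset(),
) -> tuple[tuple[int, int], ...]:
    """The maximal-pair nested pairing containing all forced pairs, ties
    broken by lexicographically smallest pair list."""
    candidates = [
        p
        for p in enumerate_pairings(seq, min_loop, forced, forbidden)
        if forced <= set(p)
    ]
    if not candidates:
        raise ValueError("forced pairs unrealisable")
    best_len = max(len(p) for p in candidates)
    return min(p for p in candidates if len(p) == best_len)


# ---------------------------------------------------------------------------
# Longest common substring
# ---------------------------------------------------------------------------

def lcs_oracle(a: str, b: str) -> int:
    """Length of the longest common substring by direct enumeration."""
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
            else:
                break
    return best
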