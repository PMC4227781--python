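"""Group-I-intron structural annotation.

This module carries the structural half of IStron detection:

* :func:`annotate_p1` — reconstruct the P1 duplex formed by the last 4-6 nt of
  the 5' exon and the internal guide sequence (IGS) near the intron start,
  including the conserved U-G wobble that marks the 5' splice site.  Group A
  elements embed the wobble inside the IGS stem (canonical pairs on both
  sides); group B elements place it one bp past the splice junction with an
  internal loop immediately 3' of it.
* :func:`scan_intron_signature` — motif-anchored scan of an upstream window
  for candidate intron starts (target-site motif, stop-codon start triplet,
  IGS complementarity with one wobble, GAAC-family motif downstream).
* :func:`constrained_fold` — Nussinov-style base-pair maximisation with forced
  pairs and forbidden spans, the stand-in for constrained thermodynamic
  folding of the ribozyme.
* :func:`find_ir_hairpin` / :func:`enumerate_stems` — ungapped inverted-repeat
  stem-loops; the IR stem enclosing the IS ORF region is long and extremely
  AU-rich in group B elements (15-34 bp, >80% AU pairs) and short and
  compositionally balanced in group A (6-10 bp).

All detection runs on the DNA alphabet (T for U); fold results are reported in
the RNA view.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .grammar import (
    GAAC_MOTIFS,
    STOP_TRIPLETS,
    TERMINI,
    as_dna,
    as_rna,
    can_pair,
    is_au_pair,
    is_wc,
    is_wobble,
    match_target_site,
)


class ConstraintError(ValueError):
    """Raised when folding constraints are contradictory."""


# ---------------------------------------------------------------------------
# P1 / IGS annotation
# ---------------------------------------------------------------------------

@dataclass
class P1Annotation:
    """The P1 duplex at the 5' splice site.

    ``igs_length`` counts the exon bases paired with the IGS (4-6 in real
    elements).  ``topology`` is ``embedded-wobble`` when the U-G wobble has
    canonical pairs on both sides (group A), ``loop-adjacent-shifted`` when
    the wobble is the first intron base and its 3' neighbour is unpaired
    (group B; the wobble sits one bp past the splice junction, ``shift_bp``
    1), or ``absent`` when no valid register exists.
    ``pairing`` lists (junction_offset, igs_index) pairs where negative
    offsets are exon bases (-1 = last exon base) and non-negative offsets are
    intron bases; ``igs_index`` is an index into the intron head.
    """

    igs_length: int
    wobble_index_in_intron: int
    topology: str
    shift_bp: int
    pairing: list[tuple[int, int]] = field(default_factory=list)
    igs_span: tuple[int, int] = (0, 0)
    wobble_pair: tuple[int, int] = (-1, -1)

    def __post_init__(self) -> None:
        if self.topology == "loop-adjacent-shifted" and self.shift_bp != 1:
            raise ValueError("loop-adjacent-shifted topology implies shift_bp = 1")


_P1_ABSENT = ("absent", 0, -1)


def annotate_p1(
    exon_tail: str,
    intron_head: str,
    min_igs: int = 4,
    max_igs: int = 6,
    min_loop: int = 3,
) -> P1Annotation:
    """Find the P1 register between a 5'-exon tail and an intron head.

    The splice-proximal strand of the duplex is the last ``a`` exon bases plus
    the first ``b`` intron bases (``b`` in 0-2); it pairs antiparallel with an
    IGS window further into the intron head.  All pairs must be Watson-Crick
    except exactly one U-G wobble, and the wobble must either be embedded
    (canonical pairs on both sides) or sit at the shift-1 loop-adjacent
    position; other registers are not valid P1 configurations.  The search
    maximises the exon-side pairing length ``a`` within [min_igs, max_igs];
    within equal ``a`` the wobble-at-junction registers (b=1) are preferred,
    then the IGS placement closest to the splice site.
    """
    if not (4 <= min_igs <= max_igs <= 6):
        raise ValueError("require 4 <= min_igs <= max_igs <= 6")
    for name, s in (("exon_tail", exon_tail), ("intron_head", intron_head)):
        bad = set(s.upper()) - set("ACGUT")
        if bad:
            raise ValueError(f"non-RNA characters in {name}: {sorted(bad)}")
    exon = as_dna(exon_tail)
    head = as_dna(intron_head)

    for a in range(max_igs, min_igs - 1, -1):
        if a > len(exon):
            continue
        for b in (1, 2, 0):
            k = a + b
            if b > len(head):
                continue
            strand = exon[-a:] + head[:b]
            for w0 in range(b + min_loop, len(head) - k + 1):
                igs = head[w0 : w0 + k]
                wobble_at = -1
                ok = True
                for i in range(k):
                    x, y = strand[i], igs[k - 1 - i]
                    if is_wc(x, y):
                        continue
                    if is_wobble(x, y) and wobble_at < 0:
                        wobble_at = i
                        continue
                    ok = False
                    break
                if not ok or wobble_at < 0:
                    continue
                embedded = 0 < wobble_at < k - 1
                shifted = wobble_at == a and b == 1
                if not (embedded or shifted):
                    continue
                pairing = [(i - a, w0 + (k - 1 - i)) for i in range(k)]
                if wobble_at >= a:  # wobble base is the first intron base (U)
                    wobble_index = wobble_at - a
                else:  # wobble G sits in the IGS
                    wobble_index = w0 + (k - 1 - wobble_at)
                if shifted:
                    topology, shift = "loop-adjacent-shifted", 1
                else:
                    topology = "embedded-wobble"
                    shift = max(0, wobble_at - (a - 1))
                return P1Annotation(
                    igs_length=a,
                    wobble_index_in_intron=wobble_index,
                    topology=topology,
                    shift_bp=shift,
                    pairing=pairing,
                    igs_span=(w0, w0 + k),
                    wobble_pair=(wobble_at - a, w0 + (k - 1 - wobble_at)),
                )
    return P1Annotation(igs_length=0, wobble_index_in_intron=-1, topology="absent", shift_bp=0)


# ---------------------------------------------------------------------------
# Candidate scan
# ---------------------------------------------------------------------------

@dataclass
class IntronCandidate:
    """A putative intron start inside an upstream window (window coordinates)."""

    window: object  # UpstreamWindow or None for bare-sequence scans
    intron_start: int
    start_triplet: str
    site_hypotheses: list[tuple[str, str]]
    igs_pairing: list[tuple[int, int]]
    wobble: tuple[int, int]
    p1: P1Annotation
    gaac_span: tuple[int, int] | None
    terminus_span: tuple[int, int] | None
    terminus_motif: str | None
    score: float


def _find_gaac(seq: str, start: int, stop: int) -> tuple[int, int] | None:
    best = None
    for motif in GAAC_MOTIFS:
        i = seq.find(motif, start, stop)
        if i >= 0 and (best is None or i < best[0]):
            best = (i, i + len(motif))
    return best


def scan_intron_signature(
    window,
    motif_table=None,
    *,
    min_igs: int = 4,
    max_igs: int = 6,
    exon_context: int = 8,
    head_context: int = 24,
    gaac_window: tuple[int, int] = (20, 500),
    min_intron_len: int = 100,
    require_gaac: bool = False,
) -> list[IntronCandidate]:
    """Motif-anchored scan for intron-start candidates in an upstream window.

    A candidate requires (a) a target-site motif ending immediately 5' of a
    TAA/TAG/TGA triplet, (b) a valid P1 register (IGS complementarity >= 4 nt
    with one U-G wobble) between the exon tail and intron head, and (c)
    optionally a GAAC-family motif downstream (weighted evidence, or mandatory
    with ``require_gaac``).  Candidates are scored by summed evidence weights
    (IGS length + 2 for GAAC + 1 for a group-consistent terminus motif) and
    sorted by descending score, then ascending position.
    """
    seq = as_dna(window if isinstance(window, str) else window.sequence)
    win = None if isinstance(window, str) else window
    if motif_table is None:
        matcher = match_target_site
    elif callable(motif_table):
        matcher = motif_table
    else:
        table = tuple(motif_table)

        def matcher(flank, _table=table):
            f = as_dna(flank)
            return [(m, g) for m, g in _table if f.endswith(m)]
    out: list[IntronCandidate] = []
    n = len(seq)
    for p in range(2, n - min(10, n)):
        if seq[p : p + 3] not in STOP_TRIPLETS:
            continue
        hyps = matcher(seq[max(0, p - 6) : p])
        if not hyps:
            continue
        tail = seq[max(0, p - exon_context) : p]
        head = seq[p : p + head_context]
        if len(tail) < min_igs or "N" in tail or "N" in head:
            continue
        p1 = annotate_p1(tail, head, min_igs, max_igs)
        if p1.topology == "absent":
            continue
        gaac = _find_gaac(seq, p + gaac_window[0], min(n, p + gaac_window[1]))
        if require_gaac and gaac is None:
            continue
        term_span = None
        term_motif = None
        for _, group in hyps:
            motif = TERMINI[group]
            i = seq.find(motif, p + min_intron_len)
            if i >= 0 and (term_span is None or i < term_span[0]):
                term_span, term_motif = (i, i + len(motif)), motif
        score = p1.igs_length + (2.0 if gaac else 0.0) + (1.0 if term_span else 0.0)
        wobble_pair = (p1.wobble_pair[0] + p, p1.wobble_pair[1] + p)
        out.append(
            IntronCandidate(
                window=win,
                intron_start=p,
                start_triplet=seq[p : p + 3],
                site_hypotheses=hyps,
                igs_pairing=[(off, p + idx) for off, idx in p1.pairing],
                wobble=wobble_pair,
                p1=p1,
                gaac_span=gaac,
                terminus_span=term_span,
                terminus_motif=term_motif,
                score=score,
            )
        )
    out.sort(key=lambda c: (-c.score, c.intron_start))
    return out


# ---------------------------------------------------------------------------
# Constrained base-pair maximisation (Nussinov-style)
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    sequence: str  # RNA view
    pairs: list[tuple[int, int]]
    pair_count: int

    def dot_bracket(self) -> str:
        marks = ["."] * len(self.sequence)
        for i, j in self.pairs:
            marks[i], marks[j] = "(", ")"
        return "".join(marks)


def constrained_fold(
    rna: str,
    forced_pairs: Sequence[tuple[int, int]] = (),
    forbidden_spans: Sequence[tuple[int, int]] = (),
    min_loop: int = 3,
) -> FoldResult:
    """Maximum-base-pair nested folding under forced/forbidden constraints.

    Returns the nested pairing with the maximal number of pairs that contains
    every forced pair and pairs no base inside a forbidden span; ties are
    broken by the lexicographically smallest sorted pair list.  Pairs are
    Watson-Crick or G-U.  Contradictory constraints raise
    :class:`ConstraintError` naming the offending pairs.
    """
    if min_loop < 3:
        raise ValueError("min_loop must be >= 3")
    seq = as_dna(rna)
    n = len(seq)
    forbidden = np.zeros(n, dtype=bool)
    for s, e in forbidden_spans:
        forbidden[max(0, s) : min(n, e)] = True

    forced = sorted((min(i, j), max(i, j)) for i, j in forced_pairs)
    partner: dict[int, int] = {}
    for i, j in forced:
        if not (0 <= i < j < n):
            raise ConstraintError(f"forced pair {(i, j)} out of range")
        if j - i - 1 < min_loop:
            raise ConstraintError(f"forced pair {(i, j)} violates min_loop={min_loop}")
        if not can_pair(seq[i], seq[j]):
            raise ConstraintError(f"forced pair {(i, j)} is not WC or G-U ({seq[i]}-{seq[j]})")
        if forbidden[i] or forbidden[j]:
            raise ConstraintError(f"forced pair {(i, j)} lies in a forbidden span")
        if i in partner or j in partner:
            raise ConstraintError(f"forced pair {(i, j)} shares a base with another forced pair")
        partner[i] = j
        partner[j] = i
    for (i1, j1) in forced:
        for (i2, j2) in forced:
            if i1 < i2 < j1 < j2:
                raise ConstraintError(f"forced pairs {(i1, j1)} and {(i2, j2)} cross")

    def allowed(x: int, y: int) -> bool:
        if forbidden[x] or forbidden[y] or y - x - 1 < min_loop:
            return False
        if x in partner and partner[x] != y:
            return False
        if y in partner and partner[y] != x:
            return False
        return can_pair(seq[x], seq[y])

    forced_set = set(forced)

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> tuple[int, int, tuple[tuple[int, int], ...]]:
        """Best (n_forced, n_pairs, pairs) for the interval [i, j)."""
        if j - i <= min_loop:
            return (0, 0, ())
        # option: i unpaired
        cand = best(i + 1, j)
        for k in range(i + min_loop + 1, j):
            if not allowed(i, k):
                continue
            f = 1 if (i, k) in forced_set else 0
            fin, nin, pin = best(i + 1, k)
            fout, nout, pout = best(k + 1, j)
            # pairs inside [i+1,k) all precede pairs in [k+1,j) in sorted order
            trial = (f + fin + fout, 1 + nin + nout, ((i, k),) + pin + pout)
            if (trial[0], trial[1]) > (cand[0], cand[1]) or (
                (trial[0], trial[1]) == (cand[0], cand[1]) and trial[2] < cand[2]
            ):
                cand = trial
        return cand

    nf, npairs, pairs = best(0, n)
    best.cache_clear()
    if nf < len(forced):
        missing = [p for p in forced if p not in set(pairs)]
        raise ConstraintError(f"forced pairs could not be realised: {missing}")
    return FoldResult(sequence=as_rna(seq), pairs=sorted(pairs), pair_count=npairs)


# ---------------------------------------------------------------------------
# Inverted-repeat stem-loops
# ---------------------------------------------------------------------------

@dataclass
class HairpinStem:
    """An ungapped inverted-repeat stem-loop (region coordinates)."""

    arm5: tuple[int, int]
    arm3: tuple[int, int]
    loop: tuple[int, int]
    stem_length_bp: int
    au_pair_fraction: float
    mismatches: int = 0

    @property
    def loop_length(self) -> int:
        return self.loop[1] - self.loop[0]


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def _encode(region: str) -> np.ndarray:
    return np.fromiter((_CODE.get(c, 4) for c in region.upper()), dtype=np.int8, count=len(region))


def _pair_matrix(allow_gu: bool) -> np.ndarray:
    m = np.zeros((5, 5), dtype=bool)
    for a, b in (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")):
        m[_CODE[a], _CODE[b]] = True
    if allow_gu:
        m[_CODE["G"], _CODE["T"]] = True
        m[_CODE["T"], _CODE["G"]] = True
    return m


_AU = np.zeros((5, 5), dtype=bool)
_AU[_CODE["A"], _CODE["T"]] = True
_AU[_CODE["T"], _CODE["A"]] = True


def enumerate_stems(
    region: str,
    min_stem_bp: int = 4,
    max_loop_nt: int = 2500,
    allow_gu: bool = True,
    min_loop_nt: int = 3,
) -> list[HairpinStem]:
    """All maximal ungapped inverted-repeat stems in a region.

    A stem is a maximal run of complementary position pairs on one
    anti-diagonal (x + y constant), trimmed so the loop between the innermost
    pair is at least ``min_loop_nt``; stems whose loop exceeds ``max_loop_nt``
    or with fewer than ``min_stem_bp`` pairs are dropped.  N never pairs.

    Run lengths are computed by a row-wise dynamic programme over the
    complementarity matrix: R[x, y] extends R[x-1, y+1] whenever (x, y) can
    pair, so each maximal anti-diagonal run is read off at its innermost
    cell.
    """
    code = _encode(region)
    n = len(code)
    if n < 2 * min_stem_bp + min_loop_nt:
        return []
    comp = _pair_matrix(allow_gu)[code[:, None], code[None, :]]
    comp &= np.triu(np.ones((n, n), dtype=bool), k=min_loop_nt + 1)
    au_m = _AU[code[:, None], code[None, :]]

    run = np.zeros((n, n), dtype=np.int32)
    au = np.zeros((n, n), dtype=np.int32)
    run[0] = comp[0]
    au[0] = comp[0] & au_m[0]
    for x in range(1, n):
        cx = comp[x]
        run[x, :-1] = np.where(cx[:-1], run[x - 1, 1:] + 1, 0)
        run[x, -1] = cx[-1]
        au[x, :-1] = np.where(cx[:-1], au[x - 1, 1:] + au_m[x, :-1], 0)
        au[x, -1] = cx[-1] & au_m[x, -1]

    # a run is maximal where its inner continuation cannot pair
    inner = np.zeros((n, n), dtype=bool)
    inner[:-1, 1:] = comp[1:, :-1]
    xs, ys = np.nonzero((run >= min_stem_bp) & ~inner)
    loops = ys - xs - 1
    keep = loops <= max_loop_nt
    stems: list[HairpinStem] = []
    for x, y in zip(xs[keep].tolist(), ys[keep].tolist()):
        length = int(run[x, y])
        x0 = x - length + 1
        stems.append(
            HairpinStem(
                arm5=(x0, x + 1),
                arm3=(y, y + length),
                loop=(x + 1, y),
                stem_length_bp=length,
                au_pair_fraction=int(au[x, y]) / length,
                mismatches=0,
            )
        )
    return stems


def find_ir_hairpin(
    region: str,
    min_stem_bp: int = 4,
    max_loop_nt: int = 2500,
    allow_gu: bool = True,
) -> HairpinStem | None:
    """Highest-scoring ungapped inverted repeat in a region.

    Scoring is stem length; ties prefer the smaller loop, then the smaller
    5'-arm start.  Returns None when no stem satisfies the thresholds.
    """
    if min_stem_bp < 4:
        raise ValueError("min_stem_bp must be >= 4")
    stems = enumerate_stems(region, min_stem_bp, max_loop_nt, allow_gu)
    if not stems:
        return None
    return min(stems, key=lambda h: (-h.stem_length_bp, h.loop_length, h.arm5[0]))
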