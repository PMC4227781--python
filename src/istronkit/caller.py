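"""IStron calling: boundary resolution, classification and annotation.

An intron candidate plus a mobile ORF becomes an IStron call once its
boundaries are fixed.  Three boundary methods are combined:

(i)   known ends — the candidate 3' terminus is matched against the known
      element end motifs (TCAG for group A, CGG for group B, CAG for the
      B-variant) downstream of the mobile ORF;
(ii)  homolog alignment — the flanks are aligned against IStron-less
      homologous loci and the boundaries placed at the insertion breakpoint;
(iii) structural enclosure — the IS ORF must lie inside the intron's
      structural span, anchored by the IR stem whose arms flank the ORF
      region and whose 3' arm abuts the terminus.

When the methods disagree on the 3' boundary, homolog alignment wins, then
known ends, then structure: the homolog is the only method with an external
witness.  A candidate whose intron 3' end falls upstream of the mobile gene
is an independent intron + IS pair, not an IStron, and is rejected.

Group assignment uses target site + terminus only (A: T-rich pentanucleotide
+ TCAG; B: GG-ending site + CGG; B-variant: AG + CAG); P1 topology and
IR-stem statistics are attached as corroborating, non-deciding flags because
real elements include one exception to the P1 pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grammar import (
    TERMINI,
    GROUP_A_TARGET_SITES,
    major_group,
    match_target_site,
    match_terminus,
)
from .records import GenomeRecord, flip_record
from .screen import (
    MobileORF,
    UpstreamWindow,
    extract_upstream,
    find_orfs,
    load_reference_orfs,
    local_align_protein,
    screen_mobile_orfs,
    translate_orf,
)
from .structure import (
    HairpinStem,
    IntronCandidate,
    P1Annotation,
    annotate_p1,
    enumerate_stems,
    scan_intron_signature,
)

logger = logging.getLogger(__name__)

ORF_COMPOSITIONS = (
    "ORF_A+ORF_B",
    "dORF_A+ORF_B",
    "phiORF_A+ORF_B",
    "ORF_B_only",
    "dORF_B_only",
    "no_ORF",
)

#: fraction of the intact reference length below which an ORF is truncated
DELTA_THRESHOLD = 0.8
#: minimum reference coverage to consider an ORF present at all
PRESENCE_THRESHOLD = 0.2

MIN_ISTRON_NT = 100
MAX_ISTRON_NT = 2600
TERMINUS_TAIL_SLACK = 24


@dataclass
class DRAnnotation:
    dr_sequence: str
    dr5_span: tuple[int, int]
    dr3_span: tuple[int, int]

    @property
    def length(self) -> int:
        return len(self.dr_sequence)


@dataclass
class IStronModel:
    """One called IStron (genome coordinates, 0-based half-open)."""

    name: str
    genome_id: str
    strand: str
    exon5_end: int
    istron_start: int
    istron_end: int
    target_site: tuple[str, tuple[int, int]] | None
    group: str
    terminus_motif: str | None
    p1: P1Annotation | None = None
    ir_stem: HairpinStem | None = None
    dr: DRAnnotation | None = None
    orf_a: tuple[tuple[int, int], str] | None = None
    orf_b: tuple[tuple[int, int], str] | None = None
    orf_composition: str = "no_ORF"
    is_family: str | None = None
    boundary_evidence: frozenset = frozenset()
    tsd_absent: bool = True
    flags: list[str] = field(default_factory=list)
    score: float = 0.0
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.istron_start != self.exon5_end:
            raise ValueError("istron_start must equal exon5_end")
        if not (self.istron_start < self.istron_end):
            raise ValueError("empty istron span")


def name_istron(genus: str, species: str, index: int, suffix: str | None = None) -> str:
    """Element naming: genus initial + species initial + 'ISt' + index.

    A strain/contig suffix can be appended through ``suffix`` for species
    whose naming needs disambiguation; no suffix is guessed.
    """
    if not genus or not species or index < 1:
        raise ValueError("genus/species must be non-empty and index >= 1")
    name = genus[0].upper() + species[0].lower() + "ISt" + str(index)
    return f"{name}-{suffix}" if suffix else name


def detect_target_site(five_flank: str, site_table=None) -> list[tuple[str, str]]:
    """All (motif, group) hypotheses whose motif is a suffix of the flank."""
    if len(five_flank) < 2:
        return []
    if site_table is None:
        return match_target_site(five_flank)
    flank = five_flank.upper()
    return [(m, g) for m, g in site_table if flank.endswith(m)]


def classify_group(model: IStronModel) -> tuple[str, list[str]]:
    """Decide A / B / B-variant / unclassified from target site + terminus.

    P1 topology and IR-stem statistics are appended as corroborating flags
    only; a site/terminus conflict yields 'unclassified' with a conflict
    flag.
    """
    flags: list[str] = []
    site = model.target_site[0] if model.target_site else None
    term = model.terminus_motif
    group = "unclassified"
    if site and term:
        if site in GROUP_A_TARGET_SITES and term == "TCAG":
            group = "A"
        elif site.endswith("GG") and term == "CGG":
            group = "B"
        elif site == "AG" and term == "CAG":
            group = "B-variant"
        else:
            flags.append("site-terminus-conflict")
    else:
        flags.append("missing-site-or-terminus")
    if model.p1 is not None and model.p1.topology != "absent":
        expected = "embedded-wobble" if group == "A" else "loop-adjacent-shifted"
        if group in ("A", "B", "B-variant") and model.p1.topology != expected:
            flags.append(f"p1-topology-atypical:{model.p1.topology}")
    if model.ir_stem is not None and group in ("B", "B-variant"):
        if model.ir_stem.stem_length_bp < 15 or model.ir_stem.au_pair_fraction < 0.8:
            flags.append("ir-stem-atypical-for-B")
    return group, flags


# ---------------------------------------------------------------------------
# Direct repeats
# ---------------------------------------------------------------------------

def _longest_common_substring(a: str, b: str) -> tuple[int, int, int]:
    """(length, start_a, start_b) of the longest common substring; ties prefer
    the smallest start in ``a`` then in ``b``."""
    best = (0, 0, 0)
    if not a or not b:
        return best
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                length = cur[j]
                cand = (length, i - length, j - length)
                if length > best[0] or (
                    length == best[0] and (cand[1], cand[2]) < (best[1], best[2])
                ):
                    best = cand
        prev = cur
    return best


def find_drs(
    ir_region: str, ir_stem: HairpinStem, min_dr: int = 8, upstream_window: int = 40
) -> DRAnnotation | None:
    """The group-B direct repeat: longest exact common substring between the
    5' IR arm and the window immediately upstream of the 3' IR arm.

    Spans are in ``ir_region`` coordinates; returns None below ``min_dr``.
    """
    if min_dr < 8:
        raise ValueError("min_dr must be >= 8")
    a5_start, a5_end = ir_stem.arm5
    a3_start = ir_stem.arm3[0]
    w_start = max(0, a3_start - upstream_window)
    arm5 = ir_region[a5_start:a5_end]
    window = ir_region[w_start:a3_start]
    length, ia, ib = _longest_common_substring(arm5, window)
    if length < min_dr:
        return None
    return DRAnnotation(
        dr_sequence=arm5[ia : ia + length],
        dr5_span=(a5_start + ia, a5_start + ia + length),
        dr3_span=(w_start + ib, w_start + ib + length),
    )


# ---------------------------------------------------------------------------
# ORF composition
# ---------------------------------------------------------------------------

def _six_frame_fragments(nt: str, min_aa: int = 15):
    """(frame, aa_start, peptide) fragments between stops, forward frames."""
    from Bio.Seq import Seq

    for frame in range(3):
        trimmed = nt[frame : frame + (len(nt) - frame) // 3 * 3]
        if len(trimmed) < 3 * min_aa:
            continue
        prot = str(Seq(trimmed).translate())
        pos = 0
        for chunk in prot.split("*"):
            if len(chunk) >= min_aa:
                yield frame, pos, chunk
            pos += len(chunk) + 1


def _ref_coverage(nt_region: str, refs: dict[str, str], which: str, min_fragment_score: float = 45.0):
    """Best reference coverage of a nucleotide region for ORF A or B refs.

    Returns (ref_id, coverage_fraction, best_score) where coverage is the
    union of aligned reference spans across all six-frame fragments.
    """
    best = (None, 0.0, 0.0)
    for ref_id, ref_seq in refs.items():
        if which not in ref_id:
            continue
        intervals: list[tuple[int, int]] = []
        top = 0.0
        for _frame, _pos, pep in _six_frame_fragments(nt_region):
            aln = local_align_protein(pep, ref_seq, gap_open=-11.0, gap_extend=-8.0)
            if aln.score < min_fragment_score:
                continue
            top = max(top, aln.score)
            intervals.extend(aln.spans_b)
        if not intervals:
            continue
        intervals.sort()
        covered = 0
        cur_s, cur_e = intervals[0]
        for s, e in intervals[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
        frac = covered / len(ref_seq)
        if frac > best[1] or (frac == best[1] and top > best[2]):
            best = (ref_id, frac, top)
    return best


def _single_frame_orf_coverage(
    seq: str, span: tuple[int, int], refs: dict[str, str], which: str
) -> tuple[str | None, float, tuple[int, int] | None]:
    """Coverage of the best reference by the translation of one intact ORF.

    Returns (ref_id, coverage, aligned_nt_span).  The aligned span is the
    reference-matching footprint mapped back to nucleotides, which matters
    when a truncated upstream ORF reads in-frame into the next one and the
    raw ORF call spans both.
    """
    prot = translate_orf(seq, _OrfView(*span))
    best = (None, 0.0, None)
    for ref_id, ref_seq in refs.items():
        if which not in ref_id:
            continue
        # steep gap costs: payload divergence is substitution-like, and cheap
        # gap extension would let the alignment bridge into unrelated sequence
        aln = local_align_protein(prot, ref_seq, gap_open=-11.0, gap_extend=-8.0)
        if aln.score < 60.0 or not aln.spans_a:
            continue
        covered = sum(e - s for s, e in aln.spans_b) / len(ref_seq)
        if covered > best[1]:
            nt_span = (span[0] + 3 * aln.spans_a[0][0], span[0] + 3 * aln.spans_a[-1][1])
            best = (ref_id, covered, nt_span)
    return best


@dataclass
class _OrfView:
    start: int
    end: int
    strand: str = "+"


def classify_orf_composition(
    model: IStronModel,
    orf_calls: list,
    *,
    genome: GenomeRecord,
    refs: dict[str, str] | None = None,
) -> tuple[str, dict]:
    """Assign the element's ORF composition from reference alignments.

    intact: a single-frame ORF covering >= 80% of the best reference;
    delta (truncated): reference coverage in [20%, 80%); phi (frameshifted):
    >= 80% coverage across reading-frame fragments but no intact single-frame
    ORF; absent otherwise.  Returns (composition, detail) where detail maps
    'orfA'/'orfB' to (state, ref_id, span).
    """
    refs = refs or load_reference_orfs()
    seq = genome.sequence
    s, e = model.istron_start, model.istron_end

    detail: dict[str, tuple] = {}

    # --- ORF B: prefer an intact single-frame ORF call
    orf_b_state, orf_b_span, orf_b_ref = "absent", None, None
    candidates = [o for o in orf_calls if o.strand == "+" and s < o.start and o.end <= e]
    best_intact = (None, 0.0, None)
    for o in candidates:
        ref_id, cov, nt_span = _single_frame_orf_coverage(seq, (o.start, o.end), refs, "ORFB")
        if ref_id and cov > best_intact[1]:
            best_intact = (ref_id, cov, nt_span)
    if best_intact[0] and best_intact[1] >= DELTA_THRESHOLD:
        orf_b_state, orf_b_ref, orf_b_span = "intact", best_intact[0], best_intact[2]
    else:
        ref_id, cov, _ = _ref_coverage(seq[s:e], refs, "ORFB")
        if ref_id and cov >= DELTA_THRESHOLD and best_intact[0] is None:
            orf_b_state, orf_b_ref = "frameshifted", ref_id
        elif ref_id and cov >= PRESENCE_THRESHOLD:
            orf_b_state, orf_b_ref = "truncated", ref_id
            orf_b_span = best_intact[2]

    # --- ORF A: fragment coverage over the region 5' of ORF B
    a_end = orf_b_span[0] if orf_b_span else e
    region = seq[s + 30 : a_end]
    orf_a_state, orf_a_ref, orf_a_span = "absent", None, None
    if len(region) >= 90:
        best_single = (None, 0.0, None)
        for o in candidates:
            if orf_b_span and o.start >= orf_b_span[0]:
                continue
            ref_id, cov, nt_span = _single_frame_orf_coverage(seq, (o.start, o.end), refs, "ORFA")
            if ref_id and cov > best_single[1]:
                best_single = (ref_id, cov, nt_span)
        ref_id, cov, _ = _ref_coverage(region, refs, "ORFA")
        if best_single[0] and best_single[1] >= DELTA_THRESHOLD:
            orf_a_state, orf_a_ref, orf_a_span = "intact", best_single[0], best_single[2]
        elif ref_id and cov >= DELTA_THRESHOLD:
            orf_a_state, orf_a_ref = "frameshifted", ref_id
        elif ref_id and cov >= PRESENCE_THRESHOLD:
            orf_a_state, orf_a_ref = "truncated", ref_id

    detail["orfA"] = (orf_a_state, orf_a_ref, orf_a_span)
    detail["orfB"] = (orf_b_state, orf_b_ref, orf_b_span)

    if orf_b_state == "absent":
        composition = "no_ORF"
    elif orf_a_state == "absent":
        composition = "dORF_B_only" if orf_b_state == "truncated" else "ORF_B_only"
    elif orf_a_state == "intact":
        composition = "ORF_A+ORF_B"
    elif orf_a_state == "frameshifted":
        composition = "phiORF_A+ORF_B"
    else:
        composition = "dORF_A+ORF_B"
    return composition, detail


def is_family_label(detail: dict) -> str | None:
    """Best-hit IS-family assignment from the composition detail."""
    for key in ("orfA", "orfB"):
        state, ref_id, _ = detail.get(key, ("absent", None, None))
        if ref_id:
            return "IS200/IS605" if ref_id.startswith("IS200_IS605") else "IS607"
    return None


# ---------------------------------------------------------------------------
# TSD check
# ---------------------------------------------------------------------------

def check_no_tsd(model: IStronModel, genome: GenomeRecord) -> bool:
    """True when the bases immediately 3' of the element differ from the
    target-site motif (IStrons never duplicate their target site)."""
    if model.target_site is None:
        return True
    motif = model.target_site[0]
    k = len(motif)
    flank = genome.sequence[model.istron_end : model.istron_end + k]
    if len(flank) < k:
        if "tsd-check-truncated" not in model.flags:
            model.flags.append("tsd-check-truncated")
        return True
    return flank != motif


# ---------------------------------------------------------------------------
# Boundary resolution
# ---------------------------------------------------------------------------

@dataclass
class Boundaries:
    istron_start: int
    istron_end: int


def _match_counts(a: np.ndarray, b: np.ndarray) -> int:
    return int((a == b).sum())


def _encode_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _homolog_breakpoints(
    g: str, A: int, homolog: str, identity_floor: float, max_len: int
) -> tuple[int, float] | None:
    """3' breakpoint from one homolog, anchored at candidate start ``A``.

    Stage 1 finds the 5'-flank alignment offset (no-indel divergence model)
    by matching homolog prefixes against the genome ending at ``A``; stage 2
    slides the homolog's remaining 3' flank along the genome downstream of
    ``A`` and places the boundary at the best match.  Returns (istron_end,
    identity) or None when the homolog does not reach the identity floor.
    """
    h = _encode_bytes(homolog)
    gb = _encode_bytes(g)
    n_h = len(h)
    L5max = min(n_h - 40, A)
    probe = 60
    if L5max < probe or A < probe:
        return None
    target = gb[A - probe : A]
    windows = np.lib.stride_tricks.sliding_window_view(h[: L5max], probe)
    scores = (windows == target).sum(axis=1)
    k_candidates = [int(i) + probe for i in np.flatnonzero(scores >= int(0.75 * probe))]
    best5 = None
    for k in k_candidates:
        m = _match_counts(h[:k], gb[A - k : A])
        if m / k >= identity_floor and (best5 is None or m - 0.4 * k > best5[1]):
            best5 = (k, m - 0.4 * k, m / k)
    if best5 is None:
        return None
    k5 = best5[0]
    f3 = h[k5:]
    w = min(len(f3), 200)
    if w < 40:
        return None
    lo = A + MIN_ISTRON_NT
    hi = min(len(gb) - w, A + max_len)
    if hi <= lo:
        return None
    g_windows = np.lib.stride_tricks.sliding_window_view(gb[lo : hi + w], w)
    scores3 = (g_windows == f3[:w]).sum(axis=1)
    b_rel = int(np.argmax(scores3))
    if scores3[b_rel] / w < identity_floor:
        return None
    identity = (best5[1] + 0.4 * k5 + float(scores3[b_rel])) / (k5 + w)
    return lo + b_rel, identity


def _gaac_end_positions(region: str) -> list[int]:
    """End coordinates of every GAAC-family motif occurrence in a region."""
    from .grammar import GAAC_MOTIFS

    ends = []
    for motif in GAAC_MOTIFS:
        i = region.find(motif)
        while i >= 0:
            ends.append(i + len(motif))
            i = region.find(motif, i + 1)
    ends.sort()
    return ends


def _near_any(sorted_positions: list[int], pos: int, slack: int) -> bool:
    from bisect import bisect_left

    i = bisect_left(sorted_positions, pos - slack)
    return i < len(sorted_positions) and sorted_positions[i] <= pos + slack


def _gaac_abuts(region: str, arm5_start: int, slack: int = 6) -> bool:
    """True when a GAAC-family motif ends within ``slack`` nt of the stem's
    5' arm start (in real elements the motif directly precedes the 5' IR)."""
    from .grammar import GAAC_MOTIFS

    lo = max(0, arm5_start - 6 - slack)
    window = region[lo : arm5_start + slack + 6]
    for motif in GAAC_MOTIFS:
        i = window.find(motif)
        while i >= 0:
            end = lo + i + len(motif)
            if abs(end - arm5_start) <= slack:
                return True
            i = window.find(motif, i + 1)
    return False


def _best_homolog_end(
    g: str, A: int, homologs, identity_floor: float
) -> tuple[int, float] | None:
    """Best (istron_end, identity) over all homolog witnesses for anchor A."""
    best = None
    for hom in homologs:
        res = _homolog_breakpoints(g, A, hom.sequence, identity_floor, MAX_ISTRON_NT)
        if res and (best is None or res[1] > best[1]):
            best = res
    return best


def _terminus_end(
    region: str, arm3_end: int, motifs: list[str], tail_slack: int = TERMINUS_TAIL_SLACK
) -> tuple[int, str] | None:
    """Smallest element end near arm3_end whose final bases are a known
    terminus motif.  The unpaired 3'-arm tail may be up to ``tail_slack``;
    the motif may also overlap the arm by a few bases, because accidental
    complementarity can extend the detected stem into the terminus itself."""
    best = None
    for motif in motifs:
        m = len(motif)
        for t in range(-min(4, m), tail_slack + 1):
            e = arm3_end + m + t
            if e > len(region):
                break
            if e - m >= 0 and region[e - m : e] == motif:
                if best is None or e < best[0]:
                    best = (e, motif)
                break
    return best


def resolve_boundaries(
    candidate: IntronCandidate,
    orf: MobileORF | None,
    known_ends: dict[str, str] | None = None,
    homologs: list[GenomeRecord] = (),
    *,
    genome: GenomeRecord,
    identity_floor: float = 0.75,
    require_homolog: bool = False,
) -> tuple[Boundaries, frozenset] | None:
    """Fix element boundaries by the three methods; homolog alignment wins.

    Returns None when no method succeeds, when the resolved 3' end falls
    upstream of the mobile gene (independent intron + IS), or when the span
    is outside the plausible element size range.  A homolog below the
    identity floor makes method (ii) abstain rather than fail.

    The structural route (i)+(iii) demands a stem whose 5' arm abuts a
    GAAC-family motif and whose 3' arm is followed by a known terminus; the
    bare AG variant target site is too unspecific to anchor a structure-only
    call, so variant elements need the homolog witness.
    """
    known_ends = known_ends or TERMINI
    g = genome.sequence
    if candidate.window is not None:
        if candidate.window.strand != "+":
            raise ValueError("resolve_boundaries expects forward-oriented windows")
        A = candidate.window.to_genome(candidate.intron_start)
    else:
        A = candidate.intron_start

    evidence: set[str] = set()
    best = _best_homolog_end(g, A, homologs, identity_floor)
    end_ii = best[0] if best else None

    groups = {grp for _, grp in candidate.site_hypotheses}
    motifs = sorted({known_ends[grp] for grp in groups if grp in known_ends}, key=len, reverse=True)
    struct_motifs = sorted(
        {known_ends[grp] for grp in groups - {"B-variant"} if grp in known_ends},
        key=len, reverse=True,
    )
    region = g[A : min(len(g), A + MAX_ISTRON_NT)]
    orf_rel = (orf.start - A, orf.end - A) if orf else None

    # The structural route is anchored: the candidate must carry its own GAAC
    # motif with the IGS close to the splice site, the stem's 5' arm must abut
    # a GAAC motif at a plausible ribozyme-core distance from the intron
    # start, and the 3' arm must be followed by a group-consistent terminus.
    end_i3 = None
    structurally_anchored = (
        candidate.gaac_span is not None
        and candidate.p1 is not None
        and candidate.p1.igs_span[0] <= 8
        and struct_motifs
    )
    if structurally_anchored:
        gaac_ends = _gaac_end_positions(region)
        stems = [
            h for h in enumerate_stems(region, min_stem_bp=6, max_loop_nt=2500)
            if (orf_rel is None or (h.arm5[1] <= orf_rel[0] and h.arm3[0] >= orf_rel[1]))
            and 80 <= h.arm5[0] <= 600
            and _near_any(gaac_ends, h.arm5[0], 6)
        ]
        # the element's own IR stem sits flush: terminus directly after the
        # 3' arm and GAAC directly before the 5' arm; prefer the tightest fit
        best13 = None
        for stem in stems:
            hit = _terminus_end(region, stem.arm3[1], struct_motifs)
            if hit is None:
                continue
            tail = abs(hit[0] - len(hit[1]) - stem.arm3[1])
            gap = min(abs(e - stem.arm5[0]) for e in gaac_ends)
            key = (tail, gap, -stem.stem_length_bp, stem.arm5[0])
            if best13 is None or key < best13[0]:
                best13 = (key, hit[0])
        if best13 is not None:
            end_i3 = A + best13[1]
    end_i = None
    if end_i3 is None and orf_rel is not None and motifs:
        for motif in motifs:
            i = region.find(motif, orf_rel[1])
            if i >= 0 and (end_i is None or i + len(motif) < end_i):
                end_i = i + len(motif)
        if end_i is not None:
            end_i += A

    if end_ii is not None:
        end = end_ii
        evidence.add("homolog_alignment")
        if end_i3 == end:
            evidence.update({"known_ends", "structural_enclosure"})
        elif end_i == end:
            evidence.add("known_ends")
    elif end_i3 is not None:
        end = end_i3
        evidence.update({"known_ends", "structural_enclosure"})
    elif end_i is not None:
        end = end_i
        evidence.add("known_ends")
    else:
        return None

    if require_homolog and "homolog_alignment" not in evidence:
        return None
    length = end - A
    if not (MIN_ISTRON_NT <= length <= MAX_ISTRON_NT):
        return None
    if orf is not None:
        if end <= orf.start:
            return None  # intron 3' end upstream of the mobile gene
        if orf.end > end:
            return None  # mobile ORF not enclosed by the element
    return Boundaries(A, end), frozenset(evidence)


# ---------------------------------------------------------------------------
# Full calling pipeline
# ---------------------------------------------------------------------------

def _annotate_model(
    genome: GenomeRecord,
    bounds: Boundaries,
    candidate: IntronCandidate,
    evidence: frozenset,
    refs: dict[str, str],
    strand: str = "+",
) -> IStronModel:
    g = genome.sequence
    s, e = bounds.istron_start, bounds.istron_end
    seq = g[s:e]
    term = match_terminus(seq)
    hyps = detect_target_site(g[max(0, s - 6) : s])
    site = None
    if hyps:
        preferred = [h for h in hyps if TERMINI[h[1]] == term] or hyps
        motif = preferred[0][0]
        site = (motif, (s - len(motif), s))

    model = IStronModel(
        name="",
        genome_id=genome.id,
        strand=strand,
        exon5_end=s,
        istron_start=s,
        istron_end=e,
        target_site=site,
        group="unclassified",
        terminus_motif=term,
        boundary_evidence=evidence,
        score=candidate.score,
        sequence=seq,
    )
    model.p1 = annotate_p1(g[max(0, s - 8) : s], seq[:24]) if s >= 8 else None

    orf_calls = [o for o in find_orfs(seq, min_length_nt=201) if o.strand == "+"]
    orf_calls = [_OrfView(o.start + s, o.end + s) for o in orf_calls]

    # IR stem: prefer stems whose 3' arm abuts the terminus
    stems = enumerate_stems(seq, min_stem_bp=6, max_loop_nt=2500)
    term_len = len(term) if term else 3
    anchored = [
        h for h in stems
        if len(seq) - term_len - TERMINUS_TAIL_SLACK <= h.arm3[1] <= len(seq) - term_len
    ]
    pool = anchored or stems
    if pool:
        model.ir_stem = min(pool, key=lambda h: (-h.stem_length_bp, h.loop_length, h.arm5[0]))
    if model.ir_stem is not None:
        model.dr = find_drs(seq, model.ir_stem) if model.ir_stem else None

    composition, detail = classify_orf_composition(model, orf_calls, genome=genome, refs=refs)
    model.orf_composition = composition
    model.is_family = is_family_label(detail)
    a_state, _, a_span = detail["orfA"]
    b_state, _, b_span = detail["orfB"]
    model.orf_a = ((a_span or (0, 0)), a_state) if a_state != "absent" else None
    model.orf_b = ((b_span or (0, 0)), b_state) if b_state != "absent" else None

    model.tsd_absent = check_no_tsd(model, genome)
    group, flags = classify_group(model)
    model.group = group
    model.flags.extend(flags)
    return model


def _calls_overlap(a: IStronModel, b: IStronModel) -> bool:
    if a.genome_id != b.genome_id:
        return False
    inter = min(a.istron_end, b.istron_end) - max(a.istron_start, b.istron_start)
    shorter = min(a.istron_end - a.istron_start, b.istron_end - b.istron_start)
    return inter > 0.5 * shorter


def _call_strength(m: IStronModel) -> tuple:
    return ("homolog_alignment" in m.boundary_evidence, len(m.boundary_evidence), m.score)


def _add_call(calls: list[IStronModel], model: IStronModel) -> None:
    """Add a call, resolving overlaps in favour of the better-evidenced one."""
    rivals = [c for c in calls if _calls_overlap(model, c)]
    if not rivals:
        calls.append(model)
        return
    if all(_call_strength(model) > _call_strength(c) for c in rivals):
        for c in rivals:
            calls.remove(c)
        calls.append(model)


def _call_forward(
    genome: GenomeRecord,
    refs: dict[str, str],
    homologs: list[GenomeRecord],
    *,
    genome_wide: bool,
    strand_label: str,
) -> list[IStronModel]:
    calls: list[IStronModel] = []
    g = genome.sequence
    mobile = screen_mobile_orfs(genome, refs)
    # longest first: a full ORF B window resolves its element before windows
    # anchored on short fragments of a degenerated ORF A get a chance
    mobile.sort(key=lambda o: (-(o.end - o.start), o.start))
    for orf in mobile:
        if orf.strand != "+":
            continue
        if any(c.istron_start <= orf.start < c.istron_end for c in calls):
            continue  # this mobile ORF is already part of a call
        window = extract_upstream(genome, orf)
        cands = scan_intron_signature(window)[:12]
        # stage 1: prefer the candidate whose anchor maximises the homolog
        # alignment identity -- a shifted anchor always scores lower
        winner = None
        best_ident = 0.0
        for cand in cands:
            A = window.to_genome(cand.intron_start)
            hit = _best_homolog_end(g, A, homologs, identity_floor=0.75)
            if hit and hit[1] > best_ident:
                winner, best_ident = cand, hit[1]
        ordered = ([winner] if winner else []) or cands
        for cand in ordered:
            resolved = resolve_boundaries(cand, orf, None, homologs, genome=genome)
            if resolved is None:
                continue
            if resolved[1] == frozenset({"known_ends"}):
                continue  # a lone end-motif match is not enough to call
            model = _annotate_model(genome, resolved[0], cand, resolved[1], refs, strand_label)
            _add_call(calls, model)
            break
    if genome_wide and homologs:
        # ORF-less elements carry no mobile gene; scan the whole record and
        # accept only candidates with a homolog witness, best identity first
        witnessed = []
        for cand in scan_intron_signature(genome.sequence, require_gaac=True):
            A = cand.intron_start
            if any(c.istron_start - 200 <= A < c.istron_end for c in calls):
                continue
            hit = _best_homolog_end(g, A, homologs, identity_floor=0.75)
            if hit:
                witnessed.append((hit[1], cand))
        witnessed.sort(key=lambda t: -t[0])
        for _, cand in witnessed:
            resolved = resolve_boundaries(
                cand, None, None, homologs, genome=genome, require_homolog=True
            )
            if resolved is None:
                continue
            model = _annotate_model(genome, resolved[0], cand, resolved[1], refs, strand_label)
            _add_call(calls, model)
    return calls


def call_istrons(
    genome: GenomeRecord,
    refs: dict[str, str] | None = None,
    homologs: list[GenomeRecord] = (),
    both_strands: bool = True,
    genome_wide: bool = True,
) -> list[IStronModel]:
    """Run the full screen -> scan -> resolve -> annotate pipeline on a record.

    Minus-strand elements are handled by flipping the record (and homologs),
    re-running the forward pipeline and mapping coordinates back.  Calls at
    identical coordinates are deduplicated with a logged warning; overlapping
    calls keep the better-supported one.
    """
    refs = refs or load_reference_orfs()
    homologs = list(homologs)
    calls = _call_forward(genome, refs, homologs, genome_wide=genome_wide, strand_label="+")
    if both_strands:
        flipped = flip_record(genome)
        flipped_homs = [flip_record(h) for h in homologs]
        n = len(genome.sequence)
        for m in _call_forward(flipped, refs, flipped_homs, genome_wide=genome_wide, strand_label="-"):
            mapped = IStronModel(
                name=m.name,
                genome_id=genome.id,
                strand="-",
                exon5_end=n - m.istron_end,
                istron_start=n - m.istron_end,
                istron_end=n - m.istron_start,
                target_site=m.target_site,
                group=m.group,
                terminus_motif=m.terminus_motif,
                p1=m.p1,
                ir_stem=m.ir_stem,
                dr=m.dr,
                orf_a=m.orf_a,
                orf_b=m.orf_b,
                orf_composition=m.orf_composition,
                is_family=m.is_family,
                boundary_evidence=m.boundary_evidence,
                tsd_absent=m.tsd_absent,
                flags=list(m.flags),
                score=m.score,
                sequence=m.sequence,
            )
            _add_call(calls, mapped)
    deduped: list[IStronModel] = []
    for m in sorted(calls, key=lambda c: (c.istron_start, c.istron_end)):
        dup = next(
            (o for o in deduped
             if (o.istron_start, o.istron_end) == (m.istron_start, m.istron_end)),
            None,
        )
        if dup is not None:
            logger.warning(
                "duplicate call at %s:%d-%d dropped", m.genome_id, m.istron_start, m.istron_end
            )
            continue
        deduped.append(m)
    return deduped
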