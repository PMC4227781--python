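"""Shared sequence vocabulary for IStron detection.

IStrons are chimeric mobile elements: a self-splicing group I intron (structural
class IA2) fused at its 3' end to an IS200/IS605- or IS607-family insertion
sequence.  The two major element groups are recognised by a small, conserved
motif grammar at the DNA level:

* group A elements sit immediately downstream of a T-rich pentanucleotide
  (TTGAT, ATTAT or TTTAT) and end with TCAG;
* group B elements sit downstream of a GG-ending site (AGGG, TGGG, GAGG) and
  end with CGG; a minor variant inserts after AG and ends with CAG;
* in all elements the IS component sits downstream of a GAAC-family motif
  (GAACGA, GAACAA, GAACAC, GAATAA or GAATAT at the DNA level);
* the intron begins with a stop-codon triplet (TAA/TAG/TGA), so an in-frame
  intragenic insertion creates a stop codon at the insertion point.

Everything here is plain data plus a few base-pairing helpers; the modules that
consume it (screening, structure annotation, calling, simulation) import from
this single place so generator and classifier stay self-consistent.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Alphabet helpers
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA_ALPHABET = frozenset("ACGTN")
RNA_ALPHABET = frozenset("ACGU")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA convention; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def as_dna(seq: str) -> str:
    """Uppercase and read U as T."""
    return seq.upper().replace("U", "T")


def as_rna(seq: str) -> str:
    """Uppercase and read T as U (RNA view used in structure output)."""
    return seq.upper().replace("T", "U")


_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}


def is_wc(a: str, b: str) -> bool:
    return (a, b) in _WC


def is_wobble(a: str, b: str) -> bool:
    """U-G (T-G at DNA level) wobble, either orientation."""
    return (a, b) in _GU


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    return (a, b) in _WC or (allow_gu and (a, b) in _GU)


def is_au_pair(a: str, b: str) -> bool:
    """A-U pair (either orientation); G-U wobbles count as non-AU."""
    return (a == "A" and b == "T") or (a == "T" and b == "A")


# ---------------------------------------------------------------------------
# IStron motif grammar (DNA level)
# ---------------------------------------------------------------------------

GROUP_A_TARGET_SITES: tuple[str, ...] = ("TTGAT", "ATTAT", "TTTAT")
GROUP_B_TARGET_SITES: tuple[str, ...] = ("AGGG", "TGGG", "GAGG")
GROUP_B_VARIANT_TARGET_SITE: str = "AG"

#: (motif, group) pairs ordered longest-first so suffix matching prefers the
#: most specific hypothesis.
TARGET_SITE_TABLE: tuple[tuple[str, str], ...] = (
    tuple((m, "A") for m in GROUP_A_TARGET_SITES)
    + tuple((m, "B") for m in GROUP_B_TARGET_SITES)
    + ((GROUP_B_VARIANT_TARGET_SITE, "B-variant"),)
)

#: 3' terminus of the element per group.
TERMINI: dict[str, str] = {"A": "TCAG", "B": "CGG", "B-variant": "CAG"}

#: GAAC-family motif directly upstream of the IS component (downstream of the
#: intron's P9.2 subdomain).
GAAC_MOTIFS: tuple[str, ...] = ("GAACGA", "GAACAA", "GAACAC", "GAATAA", "GAATAT")

STOP_TRIPLETS: tuple[str, ...] = ("TAA", "TAG", "TGA")
START_CODONS: tuple[str, ...] = ("ATG", "GTG", "TTG")

#: The BcISt1 direct repeat: 15 nt of the 21-nt 5' IR arm, repeated on the 3'
#: side immediately upstream of the 3' IR arm in group B elements.
BCIST1_DR: str = "TAAATTTGATTGAAT"

GROUPS: tuple[str, ...] = ("A", "B", "B-variant")


def major_group(group: str) -> str:
    """Collapse the B-variant label onto its major group."""
    return "B" if group == "B-variant" else group


def match_target_site(five_flank: str) -> list[tuple[str, str]]:
    """All (motif, group) hypotheses whose motif is a suffix of the flank."""
    flank = as_dna(five_flank)
    return [(m, g) for m, g in TARGET_SITE_TABLE if flank.endswith(m)]


def match_terminus(seq_end: str) -> str | None:
    """Longest known 3'-terminus motif matching the end of a sequence."""
    s = as_dna(seq_end)
    for motif in sorted(set(TERMINI.values()), key=len, reverse=True):
        if s.endswith(motif):
            return motif
    return None
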