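"""Mobile-ORF screening and upstream-window extraction.

The survey strategy for finding IStrons without prior sequence knowledge is to
locate genes with mobility-related functions (transposases, recombinases,
resolvases, ...) and inspect the 2 kb of sequence upstream of each for a group
I intron.  Two evidence paths retain an ORF as "mobile":

* keyword — an overlapping gene annotation whose product label contains one of
  the mobility keywords (whole-word, case-insensitive);
* similarity — a local protein alignment against a bundled reference set of
  IS-family ORFs scoring at least ``min_score`` and covering at least half of
  the shorter of query and reference (the 50% coverage homology rule).

The reference set shipped with the package is a synthetic stand-in for
IS200/IS605- and IS607-family ORF A/B proteins (see
``data/reference_orfs_synthetic.faa``); any protein FASTA can be substituted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .grammar import START_CODONS, STOP_TRIPLETS, revcomp
from .records import GenomeRecord, read_protein_fasta

#: Annotation keywords marking DNA-mobility functions.
MOBILITY_KEYWORDS: tuple[str, ...] = (
    "IS element",
    "excision",
    "excisionase",
    "insertase",
    "insertion",
    "integrase",
    "integrate",
    "integrative",
    "integration",
    "inversion",
    "invertase",
    "mobile",
    "recombinase",
    "recombination",
    "resolution",
    "resolvase",
    "transposable",
    "transposase",
    "transposition",
    "transposon",
)

DEFAULT_MIN_SCORE = 60.0
DEFAULT_MIN_ALIGNED_FRACTION = 0.5
DEFAULT_MIN_ORF_NT = 150
DEFAULT_UPSTREAM_NT = 2000
_MAX_N_RUN = 10


@dataclass
class OrfSpan:
    """A maximal open reading frame in genome coordinates (stop included)."""

    start: int
    end: int
    strand: str

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class MobileORF:
    """An ORF retained by the mobility screen."""

    genome_id: str
    start: int
    end: int
    strand: str
    protein: str
    evidence: str


@dataclass
class UpstreamWindow:
    """Window 5' of a mobile ORF, oriented so the ORF lies downstream."""

    genome_id: str
    orf: MobileORF
    start: int
    end: int
    sequence: str
    strand: str

    def to_genome(self, pos: int) -> int:
        """Map a window-sequence position to a genome coordinate."""
        if self.strand == "+":
            return self.start + pos
        return self.end - 1 - pos


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

def _longest_n_run(seq: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c == "N" else 0
        best = max(best, run)
    return best


def _scan_strand(seq: str, min_length_nt: int):
    """Maximal ORFs on the given (forward-read) sequence, local coordinates."""
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon in STOP_TRIPLETS:
                if start is not None and i + 3 - start >= min_length_nt:
                    yield (start, i + 3)
                start = None
            elif start is None and codon in START_CODONS:
                start = i


def find_orfs(sequence: str, min_length_nt: int = DEFAULT_MIN_ORF_NT) -> list[OrfSpan]:
    """All maximal ORFs on both strands, sorted by start coordinate.

    Start codons ATG/GTG/TTG, stop TAA/TAG/TGA; the stop codon is included in
    the span, so span lengths are multiples of 3.  "Maximal" means the first
    start codon after the previous in-frame stop.  ORFs spanning an N run
    longer than 10 are skipped.
    """
    if min_length_nt < 6 or min_length_nt % 3:
        raise ValueError("min_length_nt must be >= 6 and a multiple of 3")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters: {sorted(bad)}")
    n = len(seq)
    out = []
    for s, e in _scan_strand(seq, min_length_nt):
        if _longest_n_run(seq[s:e]) <= _MAX_N_RUN:
            out.append(OrfSpan(s, e, "+"))
    rc = revcomp(seq)
    for s, e in _scan_strand(rc, min_length_nt):
        if _longest_n_run(rc[s:e]) <= _MAX_N_RUN:
            out.append(OrfSpan(n - e, n - s, "-"))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def translate_orf(genome_seq: str, orf: OrfSpan) -> str:
    nt = genome_seq[orf.start : orf.end]
    if orf.strand == "-":
        nt = revcomp(nt)
    prot = str(Seq(nt).translate())
    return prot[:-1] if prot.endswith("*") else prot


# ---------------------------------------------------------------------------
# Local protein alignment
# ---------------------------------------------------------------------------

@dataclass
class LocalAlignment:
    score: float
    spans_a: list[tuple[int, int]]
    spans_b: list[tuple[int, int]]
    aligned_fraction: float


def _make_aligner(matrix=None, gap_open: float = -11.0, gap_extend: float = -1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = (
        substitution_matrices.load("BLOSUM62") if matrix is None else matrix
    )
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


_ALIGNER_CACHE: dict[tuple[float, float], Align.PairwiseAligner] = {}


def _default_aligner(gap_open: float, gap_extend: float):
    key = (gap_open, gap_extend)
    if key not in _ALIGNER_CACHE:
        _ALIGNER_CACHE[key] = _make_aligner(None, gap_open, gap_extend)
    return _ALIGNER_CACHE[key]


def local_align_protein(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment under affine gaps.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  Residues not
    in the matrix alphabet are scored through the matrix's X wildcard row.
    ``aligned_fraction`` is the number of aligned residue pairs divided by the
    length of the shorter sequence.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if matrix is None:
        aligner = _default_aligner(gap_open, gap_extend)
    else:
        aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    qa = "".join(c if c in alphabet else "X" for c in a.upper())
    qb = "".join(c if c in alphabet else "X" for c in b.upper())
    score = aligner.score(qa, qb)
    if score <= 0:
        return LocalAlignment(0.0, [], [], 0.0)
    aln = next(iter(aligner.align(qa, qb)))
    blocks_a, blocks_b = aln.aligned
    aligned_len = int(sum(e - s for s, e in blocks_a))
    return LocalAlignment(
        score=float(score),
        spans_a=[(int(s), int(e)) for s, e in blocks_a],
        spans_b=[(int(s), int(e)) for s, e in blocks_b],
        aligned_fraction=aligned_len / min(len(a), len(b)),
    )


# ---------------------------------------------------------------------------
# Reference set and screening
# ---------------------------------------------------------------------------

def load_reference_orfs() -> dict[str, str]:
    """The bundled synthetic IS-family ORF reference proteins."""
    path = resources.files("istronkit.data") / "reference_orfs_synthetic.faa"
    with resources.as_file(path) as p:
        return read_protein_fasta(p)


def _keyword_regexes(keyword_table) -> list[tuple[str, re.Pattern]]:
    return [
        (kw, re.compile(r"(?<!\w)" + re.escape(kw) + r"(?!\w)", re.IGNORECASE))
        for kw in keyword_table
    ]


def screen_mobile_orfs(
    genome: GenomeRecord,
    refs: dict[str, str] | None = None,
    keyword_table=MOBILITY_KEYWORDS,
    min_score: float = DEFAULT_MIN_SCORE,
    min_aligned_fraction: float = DEFAULT_MIN_ALIGNED_FRACTION,
    min_orf_length: int = DEFAULT_MIN_ORF_NT,
) -> list[MobileORF]:
    """Retain ORFs with mobility-keyword annotation or reference similarity.

    An ORF is kept when (a) a same-strand overlapping gene annotation's
    product label contains a mobility keyword, or (b) its best local alignment
    against the reference proteins reaches ``min_score`` and covers at least
    ``min_aligned_fraction`` of the shorter of query and reference.
    """
    if refs is None:
        refs = load_reference_orfs()
    if not refs:
        raise ValueError("reference protein set must be non-empty")
    patterns = _keyword_regexes(keyword_table)
    out: list[MobileORF] = []
    for orf in find_orfs(genome.sequence, min_orf_length):
        prot = translate_orf(genome.sequence, orf)
        if "*" in prot:
            continue
        evidence = None
        for gene in genome.genes:
            if gene.strand != orf.strand or gene.end <= orf.start or gene.start >= orf.end:
                continue
            for kw, pat in patterns:
                if pat.search(gene.product_label):
                    evidence = f"keyword:{kw}"
                    break
            if evidence:
                break
        if evidence is None:
            best = None
            for ref_id, ref_seq in refs.items():
                aln = local_align_protein(prot, ref_seq)
                if best is None or aln.score > best[1].score:
                    best = (ref_id, aln)
            if best is not None:
                ref_id, aln = best
                if aln.score >= min_score and aln.aligned_fraction >= min_aligned_fraction:
                    evidence = f"similarity:{ref_id},{aln.score:.1f},{aln.aligned_fraction:.3f}"
        if evidence:
            out.append(MobileORF(genome.id, orf.start, orf.end, orf.strand, prot, evidence))
    return out


def extract_upstream(
    genome: GenomeRecord, orf: MobileORF, window_nt: int = DEFAULT_UPSTREAM_NT
) -> UpstreamWindow:
    """At most ``window_nt`` bases 5' of the ORF start on the ORF's strand.

    For minus-strand ORFs the genomic span 3' of the ORF (in forward
    coordinates) is returned reverse-complemented, so the window always reads
    5'->3' into the ORF.  Truncated silently at contig edges.
    """
    if window_nt <= 0:
        raise ValueError("window_nt must be positive")
    n = len(genome.sequence)
    if orf.strand == "+":
        start, end = max(0, orf.start - window_nt), orf.start
        seq = genome.sequence[start:end]
    else:
        start, end = orf.end, min(n, orf.end + window_nt)
        seq = revcomp(genome.sequence[start:end])
    return UpstreamWindow(genome.id, orf, start, end, seq, orf.strand)
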