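"""Synthetic Firmicutes-like genomes with embedded IStrons and exact ground truth.

The generator emits genomes containing group A / group B (and B-variant)
IStrons built from the element grammar the survey detects: a target-site
motif written into the host immediately 5' of the insertion point, an intron
starting with a stop-codon triplet whose head carries the IGS complementary
to the 5'-exon tail (with the single U-G wobble in the group-appropriate
position), a GAAC-family motif in front of the IS component, inverted-repeat
arms enclosing the ORF region (short and balanced for group A, long and
AU-rich for group B), the group-B direct repeat immediately upstream of the
3' IR arm, and the group-specific 3' terminus.  ORF payloads are derived
from the bundled reference proteins at a configurable amino-acid identity so
the similarity screen can recover them.

Degeneration modes mirror the ORF-composition classes observed in real
elements: truncated ORF A, frameshifted (length-preserving) ORF A, ORF B
only, and the ORF-less "emetic" variant that retains only the DR + 3' IR
stem-forming sequence.

Every embedding returns a :class:`SyntheticTruth` with exact coordinates, and
each locus can be paired with an IStron-less homolog (flanks excised and
point-mutated) for the homolog-alignment boundary method.  All sampling flows
from integer seeds; identical config + seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .caller import name_istron
from .grammar import (
    BCIST1_DR,
    GAAC_MOTIFS,
    GROUP_A_TARGET_SITES,
    GROUP_B_TARGET_SITES,
    GROUP_B_VARIANT_TARGET_SITE,
    STOP_TRIPLETS,
    TERMINI,
    revcomp,
)
from .records import Gene, GenomeRecord, Gff3Feature, write_gff3
from .screen import load_reference_orfs
from .structure import annotate_p1


class ConfigurationError(ValueError):
    """A generator parameter is outside its documented range."""


class PlacementError(ValueError):
    """No feasible insertion point for an embedding."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_SPECIES: tuple[tuple[str, str], ...] = (
    ("Bacillus", "simulans"),
    ("Clostridium", "fictum"),
    ("Enterococcus", "exemplaris"),
    ("Fusobacterium", "syntheticum"),
    ("Lysinibacillus", "modelii"),
    ("Selenomonas", "artificialis"),
)

_BENIGN_PRODUCTS = (
    "alcohol dehydrogenase",
    "drug transporter",
    "quinone oxidoreductase",
    "DNA helicase",
    "transcriptional regulator",
    "hypothetical protein",
    "metal transporter",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic survey.

    Defaults encode the survey-scale conditions the pipeline is validated
    against: 20 genomes of 30 kb, 1-4 element copies each, 58% intragenic
    insertions of which 54% are in-frame, group-B IR stems of 15-34 bp with
    >=80% AU pairs, group-A stems of 6-10 bp with balanced composition, IGS
    lengths of 4-6 nt, and homologous IStron-less loci at 3% divergence.
    """

    genome_length: int = 30_000
    n_genomes: int = 20
    n_elements: int = 6
    copies_range: tuple[int, int] = (1, 4)
    group_weights: dict = field(
        default_factory=lambda: {"A": 0.5, "B": 0.4, "B-variant": 0.1}
    )
    mode_weights: dict = field(
        default_factory=lambda: {
            "intact": 0.40,
            "delta_orfA": 0.25,
            "phi_orfA": 0.15,
            "orfB_only": 0.10,
            "orfless_emetic": 0.10,
        }
    )
    intragenic_fraction: float = 0.58
    inframe_fraction: float = 0.54
    gc: float = 0.35
    core_len_range: tuple[int, int] = (150, 260)
    orf_a_identity: float = 0.75
    orf_b_identity: float = 0.70
    orf_truncation: float = 0.60
    stem_a_choices: tuple[int, ...] = (6, 8, 10)
    stem_b_range: tuple[int, int] = (15, 34)
    au_fraction_range: tuple[float, float] = (0.85, 0.95)
    igs_range: tuple[int, int] = (4, 6)
    dr_length: int = 15
    orf_spacer: int = 6
    dr_spacer: int = 3
    homolog_flank: int = 600
    homolog_divergence: float = 0.03
    copy_divergence: float = 0.02
    species: tuple = _DEFAULT_SPECIES

    def validate(self) -> None:
        if not (4 <= self.igs_range[0] <= self.igs_range[1] <= 6):
            raise ConfigurationError("igs_range must lie within [4, 6]")
        if not (0.0 <= self.gc <= 1.0):
            raise ConfigurationError("gc must be in [0, 1]")
        if not (0.8 <= self.au_fraction_range[0] <= self.au_fraction_range[1] <= 1.0):
            raise ConfigurationError("au_fraction_range must lie within [0.8, 1.0]")
        if not (15 <= self.stem_b_range[0] <= self.stem_b_range[1] <= 34):
            raise ConfigurationError("stem_b_range must lie within [15, 34]")
        if any(s < 6 or s > 10 or s % 2 for s in self.stem_a_choices):
            raise ConfigurationError("stem_a_choices must be even values in [6, 10]")
        if self.dr_length < 8 or self.dr_length > self.stem_b_range[0]:
            raise ConfigurationError("dr_length must be in [8, min group-B stem]")
        if not (0.0 <= self.homolog_divergence <= 0.2):
            raise ConfigurationError("homolog_divergence must be in [0, 0.2]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("copies_range", "core_len_range", "stem_b_range", "igs_range",
                    "au_fraction_range", "stem_a_choices"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "species" in data:
            data["species"] = tuple(tuple(x) for x in data["species"])
        return cls(**data)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass
class IStronTemplate:
    group: str
    target_site_motif: str
    intron_start_motif: str
    igs_length: int
    p1_topology: str
    gaac_motif: str
    ir5: str
    ir3: str
    dr: str
    orf_a_state: str = "intact"
    orf_b_state: str = "intact"
    terminus_motif: str = ""
    stem_length_bp: int = 0
    stem_au_fraction: float = 0.0


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=p)) if n else ""


def _build_arm_b(rng: np.random.Generator, config: GeneratorConfig) -> tuple[str, float]:
    """A group-B 5' IR arm: AU-rich, with any CG pairs kept out of the DR
    portion where possible, and a guaranteed non-AT base immediately 5' of the
    DR so the direct repeat has a crisp left edge."""
    lo, hi = config.stem_b_range
    length = int(rng.integers(lo, hi + 1))
    frac = rng.uniform(*config.au_fraction_range)
    n_au = int(round(length * frac))
    n_cg = length - n_au
    if length > config.dr_length:
        n_cg = max(n_cg, 1)
        n_au = length - n_cg
    bases = []
    cg_zone = max(0, length - config.dr_length)  # indices outside the DR
    forced_c = cg_zone - 1  # left edge marker for the DR
    cg_positions = set()
    if cg_zone:
        cg_positions.add(forced_c)
        extra = min(n_cg - 1, cg_zone - 1)
        if extra > 0:
            cg_positions.update(
                int(i) for i in rng.choice(cg_zone - 1, size=extra, replace=False)
            )
        spill = n_cg - len(cg_positions)
        if spill > 0:
            cg_positions.update(
                cg_zone + int(i)
                for i in rng.choice(config.dr_length, size=spill, replace=False)
            )
    else:
        cg_positions.update(int(i) for i in rng.choice(length, size=n_cg, replace=False))
    for i in range(length):
        if i in cg_positions:
            bases.append("C" if (i == forced_c or rng.random() < 0.5) else "G")
        else:
            bases.append("A" if rng.random() < 0.5 else "T")
    arm = "".join(bases)
    au = sum(1 for b in arm if b in "AT")
    return arm, au / length


def _build_arm_a(rng: np.random.Generator, config: GeneratorConfig) -> tuple[str, float]:
    """A group-A 5' IR arm: short, equal numbers of CG and AU pairs."""
    length = int(rng.choice(config.stem_a_choices))
    kinds = ["AT"] * (length // 2) + ["CG"] * (length // 2)
    rng.shuffle(kinds)
    arm = "".join(
        ("A" if rng.random() < 0.5 else "T") if k == "AT" else ("C" if rng.random() < 0.5 else "G")
        for k in kinds
    )
    return arm, (length // 2) / length


def build_istron_template(
    group: str, params: GeneratorConfig | None = None, seed: int = 0
) -> IStronTemplate:
    """Sample a group-consistent IStron template; deterministic given seed."""
    if group not in ("A", "B", "B-variant"):
        raise ConfigurationError(f"unknown group {group!r}")
    config = params or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    igs = int(rng.integers(config.igs_range[0], config.igs_range[1] + 1))
    start = str(rng.choice(STOP_TRIPLETS))
    gaac = str(rng.choice(GAAC_MOTIFS))
    if group == "A":
        site = str(rng.choice(GROUP_A_TARGET_SITES))
        arm, au = _build_arm_a(rng, config)
        dr = ""
        topology = "embedded-wobble"
    else:
        site = (
            GROUP_B_VARIANT_TARGET_SITE
            if group == "B-variant"
            else str(rng.choice(GROUP_B_TARGET_SITES))
        )
        arm, au = _build_arm_b(rng, config)
        dr = arm[-config.dr_length :]
        topology = "loop-adjacent-shifted"
    return IStronTemplate(
        group=group,
        target_site_motif=site,
        intron_start_motif=start,
        igs_length=igs,
        p1_topology=topology,
        gaac_motif=gaac,
        ir5=arm,
        ir3=revcomp(arm),
        dr=dr,
        terminus_motif=TERMINI[group],
        stem_length_bp=len(arm),
        stem_au_fraction=au,
    )


def bcist1_like_template(seed: int = 0, params: GeneratorConfig | None = None) -> IStronTemplate:
    """A BcISt1-style group-B template: 21-nt 5' IR arm whose 3'-proximal 15 nt
    are the printed direct repeat TAAATTTGATTGAAT."""
    config = params or GeneratorConfig()
    rng = np.random.default_rng(seed)
    pad = "".join("A" if rng.random() < 0.5 else "T" for _ in range(5)) + "C"
    arm = pad + BCIST1_DR
    template = build_istron_template("B", config, seed)
    au = sum(1 for b in arm if b in "AT") / len(arm)
    return dataclasses.replace(
        template,
        target_site_motif="AGGG",
        ir5=arm,
        ir3=revcomp(arm),
        dr=BCIST1_DR,
        stem_length_bp=len(arm),
        stem_au_fraction=au,
    )


_DEGRADE_MODES = ("delta_orfA", "phi_orfA", "orfB_only", "orfless_emetic")


def degrade_element(template: IStronTemplate, mode: str) -> IStronTemplate:
    """Apply one of the observed ORF degeneration modes to a template.

    ``orfless_emetic`` marks both ORFs absent; at assembly the ORF region and
    the 5' IR arm are dropped and only the DR + 3' IR stem-forming sequence
    (plus the intron) is retained, as in the ORF-less emetic-strain variants.
    """
    if mode == "delta_orfA":
        return dataclasses.replace(template, orf_a_state="truncated")
    if mode == "phi_orfA":
        return dataclasses.replace(template, orf_a_state="frameshifted")
    if mode == "orfB_only":
        return dataclasses.replace(template, orf_a_state="absent")
    if mode == "orfless_emetic":
        return dataclasses.replace(template, orf_a_state="absent", orf_b_state="absent")
    raise ConfigurationError(f"unknown degeneration mode {mode!r}; expected one of {_DEGRADE_MODES}")


# ---------------------------------------------------------------------------
# ORF payloads
# ---------------------------------------------------------------------------

_CODONS_BY_AA: dict[str, list[str]] = {}


def _codons_by_aa() -> dict[str, list[str]]:
    if not _CODONS_BY_AA:
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[11].forward_table
        for codon, aa in table.items():
            _CODONS_BY_AA.setdefault(aa, []).append(codon)
        for aa in _CODONS_BY_AA:
            _CODONS_BY_AA[aa].sort()
    return _CODONS_BY_AA


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def back_translate(protein: str, identity: float, rng: np.random.Generator) -> str:
    """Back-translate a reference protein at the given amino-acid identity.

    The first codon is forced to ATG and a stop codon is appended, so an
    intact payload of ``n`` residues is ``3 * (n + 1)`` nt with no internal
    stop.
    """
    codons = _codons_by_aa()
    out = ["ATG"]
    for aa in protein[1:]:
        if rng.random() >= identity:
            aa = _AA20[int(rng.integers(len(_AA20)))]
        out.append(codons[aa][int(rng.integers(len(codons[aa])))])
    out.append(str(rng.choice(STOP_TRIPLETS)))
    return "".join(out)


def _frameshift(nt: str, rng: np.random.Generator) -> str:
    """Length-preserving frameshift: one deletion at ~1/3, one insertion at
    ~2/3, with an in-frame stop guaranteed inside the shifted segment."""
    n = len(nt)
    d = (n // 3) // 3 * 3 + 1
    ins = (2 * n // 3) // 3 * 3 + 1
    shifted = nt[:d] + nt[d + 1 : ins] + str(rng.choice(list("ACGT"))) + nt[ins:]
    assert len(shifted) == n
    has_stop = any(
        shifted[i : i + 3] in STOP_TRIPLETS for i in range(d + 3 - (d % 3), ins - 3, 3)
    )
    if not has_stop:
        mid = ((d + ins) // 2) // 3 * 3
        shifted = shifted[:mid] + "TAA" + shifted[mid + 3 :]
    return shifted


def _ref_ids(group: str) -> tuple[str, str]:
    fam = "IS200_IS605" if group == "A" else "IS607"
    return f"{fam}_ORFA|synthetic", f"{fam}_ORFB|synthetic"


@dataclass
class ElementBody:
    """The locus-independent parts of one element, shared by its copies."""

    core_shared: str
    spacer1: str
    spacer2: str
    spacer_dr: str
    orf_a_intact: str
    orf_b_intact: str


def build_element_body(
    template: IStronTemplate,
    seed: int,
    config: GeneratorConfig | None = None,
    refs: dict[str, str] | None = None,
) -> ElementBody:
    config = config or GeneratorConfig()
    refs = refs or load_reference_orfs()
    rng = np.random.default_rng(seed)
    core_len = int(rng.integers(*config.core_len_range))
    p1_region = 3 + 1 + (template.igs_length + 1) + 1
    shared_len = max(0, core_len - p1_region - 16)
    ref_a, ref_b = _ref_ids(template.group)
    return ElementBody(
        core_shared=_random_seq(rng, shared_len, config.gc),
        spacer1=_random_seq(rng, config.orf_spacer, config.gc),
        spacer2=_random_seq(rng, config.orf_spacer, config.gc),
        spacer_dr=_random_seq(rng, config.dr_spacer, config.gc),
        orf_a_intact=back_translate(refs[ref_a], config.orf_a_identity, rng),
        orf_b_intact=back_translate(refs[ref_b], config.orf_b_identity, rng),
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class IStronFeatures:
    """Feature spans relative to the IStron start (0-based half-open)."""

    length: int
    igs_span: tuple[int, int]
    gaac_span: tuple[int, int]
    ir5_span: tuple[int, int] | None
    ir3_span: tuple[int, int]
    dr5_span: tuple[int, int] | None
    dr3_span: tuple[int, int] | None
    orf_a_span: tuple[int, int] | None
    orf_b_span: tuple[int, int] | None
    terminus_span: tuple[int, int]


def assemble_istron(
    template: IStronTemplate,
    exon_tail: str,
    seed: int | np.random.Generator = 0,
    config: GeneratorConfig | None = None,
    body: ElementBody | None = None,
    refs: dict[str, str] | None = None,
) -> tuple[str, IStronFeatures]:
    """Build the concrete IStron sequence to be inserted after ``exon_tail``.

    The IGS is constructed as the antiparallel complement of the splice
    strand (last ``igs_length`` exon bases + the first intron base) with the
    wobble G substituted at the group-appropriate position, so the element is
    only fully defined once its insertion site is known.  A short stretch of
    interior filler next to the P1 region is resampled until the P1 annotator
    recovers the template's topology, which keeps generator and classifier
    self-consistent.
    """
    config = config or GeneratorConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if body is None:
        body_seed = int(rng.integers(0, 2**31 - 1))
        body = build_element_body(template, body_seed, config, refs)

    a = template.igs_length
    if len(exon_tail) < max(a, 8):
        raise PlacementError("exon tail too short for IGS construction")
    exon_tail = exon_tail.upper()
    strand = exon_tail[-a:] + template.intron_start_motif[0]
    k = a + 1
    igs = list(revcomp(strand))
    if template.p1_topology == "embedded-wobble":
        if strand[a - 1] != "T":
            raise PlacementError("embedded-wobble topology requires a U-ending 5' exon")
        igs[1] = "G"  # partner of the last exon base
    else:
        igs[0] = "G"  # partner of the first intron base (the shifted U)
    igs = "".join(igs)

    p1_region = template.intron_start_motif + "A" + igs + "A"
    head_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
    for _ in range(80):
        head_filler = _random_seq(head_rng, 16, config.gc)
        head = (p1_region + head_filler + body.core_shared)[:24]
        ann = annotate_p1(exon_tail[-8:], head)
        if ann.topology == template.p1_topology:
            break
    else:  # pragma: no cover - bounded rejection nearly never exhausts
        raise PlacementError("could not realise a self-consistent P1 register")

    core = p1_region + head_filler + body.core_shared
    igs_span = (len(template.intron_start_motif) + 1, len(template.intron_start_motif) + 1 + k)

    emetic = template.orf_a_state == "absent" and template.orf_b_state == "absent"
    segs: list[tuple[str, str]] = [("core", core), ("gaac", template.gaac_motif)]
    if emetic:
        segs += [
            ("dr3", template.dr or template.ir5[-config.dr_length :]),
            ("spacer_dr", body.spacer_dr),
            ("ir3", template.ir3),
        ]
    else:
        segs += [("ir5", template.ir5), ("spacer1", body.spacer1)]
        if template.orf_a_state != "absent":
            orf_a = body.orf_a_intact
            if template.orf_a_state == "truncated":
                orf_a = orf_a[: int(len(orf_a) * config.orf_truncation) // 3 * 3]
            elif template.orf_a_state == "frameshifted":
                orf_a = _frameshift(orf_a, np.random.default_rng(int(rng.integers(0, 2**31 - 1))))
            segs += [("orfA", orf_a), ("spacer2", body.spacer2)]
        if template.orf_b_state != "absent":
            orf_b = body.orf_b_intact
            if template.orf_b_state == "truncated":
                orf_b = orf_b[: int(len(orf_b) * config.orf_truncation) // 3 * 3]
            segs += [("orfB", orf_b)]
        if template.dr:
            segs += [("dr3", template.dr), ("spacer_dr", body.spacer_dr)]
        segs += [("ir3", template.ir3)]
    segs += [("terminus", template.terminus_motif)]

    spans: dict[str, tuple[int, int]] = {}
    cursor = 0
    parts = []
    for name, seq_part in segs:
        spans[name] = (cursor, cursor + len(seq_part))
        parts.append(seq_part)
        cursor += len(seq_part)
    istron = "".join(parts)

    ir5_span = spans.get("ir5")
    dr3_span = spans.get("dr3")
    dr5_span = None
    if template.dr and ir5_span is not None:
        dr5_span = (ir5_span[1] - len(template.dr), ir5_span[1])
    feats = IStronFeatures(
        length=len(istron),
        igs_span=igs_span,
        gaac_span=spans["gaac"],
        ir5_span=ir5_span,
        ir3_span=spans["ir3"],
        dr5_span=dr5_span,
        dr3_span=dr3_span,
        orf_a_span=spans.get("orfA"),
        orf_b_span=spans.get("orfB"),
        terminus_span=spans["terminus"],
    )
    return istron, feats


# ---------------------------------------------------------------------------
# Ground truth and embedding
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTruth:
    element_name: str
    genome_id: str
    exon5_end: int
    istron_start: int
    istron_end: int
    target_site_motif: str
    target_site_span: tuple[int, int]
    group: str
    igs_length: int
    p1_topology: str
    gaac_span: tuple[int, int]
    ir5_span: tuple[int, int] | None
    ir3_span: tuple[int, int]
    dr5_span: tuple[int, int] | None
    dr3_span: tuple[int, int] | None
    orf_a_span: tuple[int, int] | None
    orf_a_state: str
    orf_b_span: tuple[int, int] | None
    orf_b_state: str
    terminus_motif: str
    terminus_span: tuple[int, int]
    context: str
    host_gene_index: int | None
    in_frame: bool | None
    istron_sequence: str
    homolog_record_id: str | None = None

    @property
    def mode(self) -> str:
        if self.orf_a_state == "absent" and self.orf_b_state == "absent":
            return "orfless_emetic"
        if self.orf_a_state == "absent":
            return "orfB_only"
        if self.orf_a_state == "truncated":
            return "delta_orfA"
        if self.orf_a_state == "frameshifted":
            return "phi_orfA"
        return "intact"


def _shift(span: tuple[int, int] | None, offset: int) -> tuple[int, int] | None:
    return None if span is None else (span[0] + offset, span[1] + offset)


def embed_istron(
    genome: GenomeRecord,
    template: IStronTemplate,
    host_gene_index: int | None,
    in_frame: bool,
    seed: int,
    config: GeneratorConfig | None = None,
    body: ElementBody | None = None,
    element_name: str = "element",
    refs: dict[str, str] | None = None,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Insert one IStron into a genome and return the exact ground truth.

    The target-site motif is written into the host immediately 5' of the
    insertion point; the target site is never duplicated on the 3' side (the
    first 3'-flank base is repointed if the host happens to repeat the
    motif).  With ``in_frame`` the insertion offset within the host ORF is a
    multiple of 3, so the intron's stop-codon start triplet lands in the host
    reading frame.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    seq = genome.sequence
    margin = 160
    if host_gene_index is None:
        spans = _intergenic_spans(genome, margin)
        if not spans:
            raise PlacementError(f"no intergenic span with {margin} nt margin in {genome.id}")
        s, e = spans[int(rng.integers(len(spans)))]
        pos = int(rng.integers(s, e))
        in_frame_flag = None
        context = "intergenic"
    else:
        gene = genome.genes[host_gene_index]
        if gene.end - gene.start < 2 * margin + 30:
            raise PlacementError(
                f"gene {host_gene_index} of {genome.id} too short to accept an insertion"
            )
        offset = int(rng.integers(margin, gene.end - gene.start - margin))
        if gene.strand == "+":
            if in_frame:
                offset -= offset % 3
            elif offset % 3 == 0:
                offset += 1
            pos = gene.start + offset
        else:
            if in_frame:
                offset -= offset % 3
            elif offset % 3 == 0:
                offset += 1
            pos = gene.end - offset
        in_frame_flag = bool(in_frame)
        context = "intragenic"

    motif = template.target_site_motif
    klen = len(motif)
    if seq[pos - klen : pos] != motif:
        seq = seq[:pos - klen] + motif + seq[pos:]
    exon_tail = seq[pos - 8 : pos]
    istron, feats = assemble_istron(template, exon_tail, rng, config, body, refs)

    new_seq = seq[:pos] + istron + seq[pos:]
    # no target-site duplication on the 3' side
    flank3 = new_seq[pos + len(istron) : pos + len(istron) + klen]
    if flank3 == motif:
        i = pos + len(istron)
        repl = "C" if new_seq[i] != "C" else "A"
        new_seq = new_seq[:i] + repl + new_seq[i + 1 :]

    genes = []
    for g in genome.genes:
        if g.start >= pos:
            genes.append(Gene(g.start + len(istron), g.end + len(istron), g.strand, g.frame, g.product_label))
        elif g.end > pos:
            genes.append(Gene(g.start, g.end + len(istron), g.strand, g.frame, g.product_label))
        else:
            genes.append(g)
    out = GenomeRecord(genome.id, new_seq, genes, genome.organism)

    truth = SyntheticTruth(
        element_name=element_name,
        genome_id=genome.id,
        exon5_end=pos,
        istron_start=pos,
        istron_end=pos + len(istron),
        target_site_motif=motif,
        target_site_span=(pos - klen, pos),
        group=template.group,
        igs_length=template.igs_length,
        p1_topology=template.p1_topology,
        gaac_span=_shift(feats.gaac_span, pos),
        ir5_span=_shift(feats.ir5_span, pos),
        ir3_span=_shift(feats.ir3_span, pos),
        dr5_span=_shift(feats.dr5_span, pos),
        dr3_span=_shift(feats.dr3_span, pos),
        orf_a_span=_shift(feats.orf_a_span, pos),
        orf_a_state=template.orf_a_state,
        orf_b_span=_shift(feats.orf_b_span, pos),
        orf_b_state=template.orf_b_state,
        terminus_motif=template.terminus_motif,
        terminus_span=_shift(feats.terminus_span, pos),
        context=context,
        host_gene_index=host_gene_index,
        in_frame=in_frame_flag,
        istron_sequence=istron,
    )
    return out, truth


def _intergenic_spans(genome: GenomeRecord, margin: int) -> list[tuple[int, int]]:
    n = len(genome.sequence)
    edges = [margin]
    for g in sorted(genome.genes, key=lambda g: g.start):
        edges.extend([g.start - margin, g.end + margin])
    edges.append(n - margin)
    spans = []
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s > 10:
            spans.append((s, e))
    return spans


def make_istronless_homolog(
    genome: GenomeRecord,
    truth: SyntheticTruth,
    divergence: float,
    seed: int = 0,
    flank_nt: int = 600,
) -> GenomeRecord:
    """The paired IStron-less locus: element excised, flanks point-mutated.

    The divergence model is uniform point substitution only (no indels), so
    the insertion breakpoint in the homolog is unambiguous.
    """
    if not (0.0 <= divergence <= 0.2):
        raise ConfigurationError("divergence must be in [0, 0.2]")
    g = genome.sequence
    f5 = g[max(0, truth.istron_start - flank_nt) : truth.istron_start]
    f3 = g[truth.istron_end : truth.istron_end + flank_nt]
    rng = np.random.default_rng(seed)
    seq = _point_mutate(f5 + f3, divergence, rng)
    hid = f"{truth.element_name}|{genome.id}|homolog"
    return GenomeRecord(hid, seq, [], genome.organism)


def _point_mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    alphabet = "ACGT"
    for i in hits:
        old = out[i]
        choices = [c for c in alphabet if c != old]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def _mutate_copy(body: ElementBody, rate: float, rng: np.random.Generator) -> ElementBody:
    """Per-copy divergence confined to positions that cannot break the element
    grammar: interior filler and spacers (free substitution) and ORF wobble
    positions (codon third bases, never creating or destroying stops)."""

    def wobble_mutate(nt: str) -> str:
        out = list(nt)
        for c in range(1, len(nt) // 3 - 1):
            if rng.random() < rate * 3:
                i = 3 * c + 2
                for _ in range(3):
                    cand = "ACGT"[int(rng.integers(4))]
                    trial = out[3 * c] + out[3 * c + 1] + cand
                    if trial not in STOP_TRIPLETS:
                        out[i] = cand
                        break
        return "".join(out)

    return ElementBody(
        core_shared=_point_mutate(body.core_shared, rate, rng),
        spacer1=_point_mutate(body.spacer1, rate, rng),
        spacer2=_point_mutate(body.spacer2, rate, rng),
        spacer_dr=body.spacer_dr,
        orf_a_intact=wobble_mutate(body.orf_a_intact),
        orf_b_intact=wobble_mutate(body.orf_b_intact),
    )


# ---------------------------------------------------------------------------
# Host genomes and the survey simulation
# ---------------------------------------------------------------------------

def make_host_genome(
    genome_id: str,
    organism: str,
    seed: int,
    config: GeneratorConfig | None = None,
    decoy_keyword_gene: bool = False,
) -> GenomeRecord:
    """A random Firmicutes-like background with annotated protein-coding genes."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    seq = list(_random_seq(rng, config.genome_length, config.gc))
    genes: list[Gene] = []
    cursor = 400
    codons = _codons_by_aa()
    while cursor + 2600 < config.genome_length:
        n_codons = int(rng.integers(300, 700))
        aa = "".join(_AA20[int(i)] for i in rng.integers(0, len(_AA20), n_codons))
        coding = "ATG" + "".join(
            codons[a][int(rng.integers(len(codons[a])))] for a in aa
        ) + str(rng.choice(STOP_TRIPLETS))
        strand = "+" if rng.random() < 0.75 else "-"
        written = coding if strand == "+" else revcomp(coding)
        start, end = cursor, cursor + len(coding)
        seq[start:end] = list(written)
        if decoy_keyword_gene and not genes:
            label = "putative transposase"
        else:
            label = _BENIGN_PRODUCTS[int(rng.integers(len(_BENIGN_PRODUCTS)))]
        genes.append(Gene(start, end, strand, 0, label))
        cursor = end + int(rng.integers(400, 900))
    return GenomeRecord(genome_id, "".join(seq), genes, organism)


@dataclass
class SurveySimulation:
    config: GeneratorConfig
    genomes: list[GenomeRecord]
    truths: list[SyntheticTruth]
    homologs: list[GenomeRecord]
    templates: dict[str, IStronTemplate]


def _weighted_choice(rng: np.random.Generator, weights: dict) -> str:
    keys = sorted(weights)
    p = np.array([weights[key] for key in keys], dtype=float)
    p /= p.sum()
    return keys[int(rng.choice(len(keys), p=p))]


def simulate_survey_genomes(
    config: GeneratorConfig | None = None, seed: int = 0
) -> SurveySimulation:
    """The full study set: genomes with embedded elements plus paired homologs.

    Each species carries one element family (species never mix element
    groups); each genome receives 1-4 copies of its species' element with
    per-copy degeneration modes, insertion contexts (intragenic at the
    configured fraction, in-frame at the configured fraction of those) and
    small per-copy divergence.  Every copy gets a paired IStron-less homolog.
    """
    config = config or GeneratorConfig()
    config.validate()
    refs = load_reference_orfs()
    rng = np.random.default_rng(seed)

    # one element family per species
    species = list(config.species)
    designs = []
    for e in range(config.n_elements):
        genus, sp = species[e % len(species)]
        group = _weighted_choice(rng, config.group_weights)
        tseed = int(rng.integers(0, 2**31 - 1))
        template = build_istron_template(group, config, tseed)
        body = build_element_body(template, int(rng.integers(0, 2**31 - 1)), config, refs)
        name = name_istron(genus, sp, e // len(species) + 1)
        designs.append((name, genus, sp, template, body))

    genomes: list[GenomeRecord] = []
    truths: list[SyntheticTruth] = []
    homologs: list[GenomeRecord] = []
    templates: dict[str, IStronTemplate] = {}
    for gi in range(config.n_genomes):
        name, genus, sp, template, body = designs[gi % len(designs)]
        organism = f"{genus} {sp}"
        gid = f"{genus[:2].lower()}{sp[:2].lower()}_strain{gi + 1:03d}"
        genome = make_host_genome(
            gid, organism, int(rng.integers(0, 2**31 - 1)), config,
            decoy_keyword_gene=(gi % 5 == 0),
        )
        n_copies = int(rng.integers(config.copies_range[0], config.copies_range[1] + 1))
        placed = 0
        attempts = 0
        while placed < n_copies and attempts < 4 * n_copies + 8:
            attempts += 1
            mode = _weighted_choice(rng, config.mode_weights)
            copy_template = template if mode == "intact" else degrade_element(template, mode)
            copy_body = _mutate_copy(body, config.copy_divergence, rng)
            intragenic = rng.random() < config.intragenic_fraction
            host_index = None
            if intragenic:
                candidates = _embeddable_genes(genome, truths_in=gid, truths=truths)
                if candidates:
                    host_index = candidates[int(rng.integers(len(candidates)))]
                else:
                    intragenic = False
            in_frame = bool(rng.random() < config.inframe_fraction) if intragenic else False
            cname = f"{name}_copy{placed + 1}"
            try:
                trial_genome, truth = embed_istron(
                    genome, copy_template, host_index, in_frame,
                    int(rng.integers(0, 2**31 - 1)), config, copy_body, cname, refs,
                )
            except PlacementError:
                continue
            if _too_close(truth, truths, gid, 3000):
                continue  # rejected placements must not touch the genome
            genome = trial_genome
            # embedding upstream of an existing element shifts its coordinates
            delta = truth.istron_end - truth.istron_start
            for t in truths:
                if t.genome_id == gid and t.istron_start >= truth.istron_end:
                    _shift_truth(t, delta)
            hom = make_istronless_homolog(
                genome, truth, config.homolog_divergence,
                int(rng.integers(0, 2**31 - 1)), config.homolog_flank,
            )
            truth.homolog_record_id = hom.id
            truths.append(truth)
            homologs.append(hom)
            templates[cname] = copy_template
            placed += 1
        genomes.append(genome)
    return SurveySimulation(config, genomes, truths, homologs, templates)


def _embeddable_genes(genome: GenomeRecord, truths_in: str, truths: list[SyntheticTruth]) -> list[int]:
    used = [
        (t.istron_start, t.istron_end) for t in truths if t.genome_id == truths_in
    ]
    out = []
    for i, g in enumerate(genome.genes):
        if g.strand != "+" or g.end - g.start < 360:
            continue
        if any(s < g.end and g.start < e for s, e in used):
            continue
        out.append(i)
    return out


def _shift_truth(t: SyntheticTruth, delta: int) -> None:
    t.exon5_end += delta
    t.istron_start += delta
    t.istron_end += delta
    for name in ("target_site_span", "gaac_span", "ir5_span", "ir3_span",
                 "dr5_span", "dr3_span", "orf_a_span", "orf_b_span", "terminus_span"):
        setattr(t, name, _shift(getattr(t, name), delta))


def _too_close(truth: SyntheticTruth, truths: list[SyntheticTruth], gid: str, gap: int) -> bool:
    for t in truths:
        if t.genome_id != gid:
            continue
        if truth.istron_start < t.istron_end + gap and t.istron_start < truth.istron_end + gap:
            return True
    return False


# ---------------------------------------------------------------------------
# Fixture helpers for structural parameter recovery
# ---------------------------------------------------------------------------

def simulate_locus(
    group_or_template: str | IStronTemplate,
    seed: int,
    config: GeneratorConfig | None = None,
    mode: str = "intact",
) -> tuple[GenomeRecord, SyntheticTruth]:
    """One small host locus with a single embedded element (plus truth)."""
    config = config or GeneratorConfig()
    small = dataclasses.replace(config, genome_length=6000)
    rng = np.random.default_rng(seed)
    if isinstance(group_or_template, IStronTemplate):
        template = group_or_template
    else:
        template = build_istron_template(group_or_template, config, int(rng.integers(0, 2**31 - 1)))
    if mode != "intact":
        template = degrade_element(template, mode)
    genome = make_host_genome(f"locus_{seed}", "Synthetic locus", int(rng.integers(0, 2**31 - 1)), small)
    host = next((i for i, g in enumerate(genome.genes) if g.strand == "+" and g.end - g.start > 600), None)
    return embed_istron(
        genome, template, host, True, int(rng.integers(0, 2**31 - 1)), config,
        element_name=f"fixture_{seed}",
    )


def make_element_fixture(
    group_or_template: str | IStronTemplate,
    seed: int,
    config: GeneratorConfig | None = None,
    mode: str = "intact",
) -> tuple[str, str, IStronFeatures, IStronTemplate]:
    """A standalone element fixture: (exon_tail, istron, features, template).

    Lighter than :func:`simulate_locus` (no host genome); the exon tail is a
    random AT-rich context ending with the template's target-site motif.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    if isinstance(group_or_template, IStronTemplate):
        template = group_or_template
    else:
        template = build_istron_template(group_or_template, config, int(rng.integers(0, 2**31 - 1)))
    if mode != "intact":
        template = degrade_element(template, mode)
    tail = _random_seq(rng, 12, config.gc)
    exon_tail = tail[: -len(template.target_site_motif)] + template.target_site_motif
    istron, feats = assemble_istron(template, exon_tail, rng, config)
    return exon_tail, istron, feats, template


def element_ir_region(istron: str, feats: IStronFeatures, mask_interior: bool = True) -> str:
    """The element's IR region with the ORF-coding interior masked to N."""
    start = feats.ir5_span[0] if feats.ir5_span else feats.dr3_span[0]
    end = feats.ir3_span[1]
    region = istron[start:end]
    if mask_interior and feats.ir5_span:
        a = feats.ir5_span[1] - start
        b = feats.ir3_span[0] - start
        region = region[:a] + "N" * (b - a) + region[b:]
    return region


def extract_ir_region(genome: GenomeRecord, truth: SyntheticTruth, mask_interior: bool = True) -> str:
    """The IR region of an element with the ORF-coding interior masked to N,
    mirroring the ORFs-removed view used for folding the intron structure."""
    start = truth.ir5_span[0] if truth.ir5_span else truth.dr3_span[0]
    end = truth.ir3_span[1]
    region = genome.sequence[start:end]
    if mask_interior and truth.ir5_span:
        a = truth.ir5_span[1] - start
        b = truth.ir3_span[0] - start
        region = region[:a] + "N" * (b - a) + region[b:]
    return region


def exon_intron_views(
    genome: GenomeRecord, truth: SyntheticTruth, exon_context: int = 8, head_context: int = 24
) -> tuple[str, str]:
    """(5'-exon tail, intron head) around the 5' splice junction."""
    p = truth.istron_start
    return genome.sequence[p - exon_context : p], genome.sequence[p : p + head_context]


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def truth_gff3_features(truths: Iterable[SyntheticTruth], flank: int = 600) -> list[Gff3Feature]:
    feats: list[Gff3Feature] = []
    for t in truths:
        base = {"ID": t.element_name, "group": t.group, "mode": t.mode}
        feats.append(Gff3Feature(t.genome_id, "istron", t.istron_start, t.istron_end, attributes=base))
        feats.append(
            Gff3Feature(t.genome_id, "exon5", max(0, t.istron_start - flank), t.istron_start,
                        attributes={"Parent": t.element_name})
        )
        feats.append(
            Gff3Feature(t.genome_id, "exon3", t.istron_end, t.istron_end + flank,
                        attributes={"Parent": t.element_name})
        )
        feats.append(
            Gff3Feature(t.genome_id, "target_site", *t.target_site_span,
                        attributes={"Parent": t.element_name, "motif": t.target_site_motif})
        )
        for ftype, span in (
            ("orfA", t.orf_a_span),
            ("orfB", t.orf_b_span),
            ("ir5", t.ir5_span),
            ("ir3", t.ir3_span),
            ("dr5", t.dr5_span),
            ("dr3", t.dr3_span),
        ):
            if span is not None:
                feats.append(Gff3Feature(t.genome_id, ftype, *span, attributes={"Parent": t.element_name}))
    return feats


def write_truth_gff3(truths: Iterable[SyntheticTruth], path: str | Path) -> None:
    write_gff3(truth_gff3_features(truths), path)


def write_truth_tsv(truths: Iterable[SyntheticTruth], path: str | Path) -> None:
    import pandas as pd

    from .records import dataclass_to_row

    rows = []
    for t in truths:
        row = dataclass_to_row(t)
        row.pop("istron_sequence", None)
        row["mode"] = t.mode
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
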