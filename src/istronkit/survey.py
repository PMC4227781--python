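"""Survey aggregation: copy clustering, insertion context, splice products,
report tables.

Strains of one species usually carry highly similar copies (>93% nucleotide
identity over the element length) of a single element, so copies are grouped
into elements by single-linkage clustering on pairwise global identity.
Insertion-context statistics mirror the survey reporting convention: the
percentage of intragenic insertions is computed over insertion sites with
gene predictions available, and the in-frame percentage over the intragenic
subset.  Splice products are reconstructed in silico: ligated exons, the
full-length circle junction (element 3' terminus joined to its 5' start) and
partial circles missing leading/trailing element bases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .caller import IStronModel, name_istron
from .records import GenomeRecord, Gene, Gff3Feature, write_gff3
from .grammar import STOP_TRIPLETS, major_group

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Global identity
# ---------------------------------------------------------------------------

_S1 = 1 << 32  # score field weight
_S2 = 1 << 16  # matches field weight
_CMAX = 60_000  # column budget (cols are subtracted from this)


def global_identity(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
) -> float:
    """Identity of the optimal global alignment: matches / alignment columns.

    The alignment maximises (score, matches, -columns) lexicographically so
    the reported identity is deterministic among co-optimal alignments.
    Linear gap cost (``gap`` per gapped column).  Implemented as a packed
    int64 dynamic programme; sequences up to ~6 kb.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if len(a) + len(b) > _CMAX // 4:
        raise ValueError("sequences too long for packed-identity alignment")
    av = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bv = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    n, m = len(av), len(bv)

    gap_delta = gap * _S1 - 1
    diag_match = match * _S1 + _S2 - 1
    diag_mismatch = mismatch * _S1 - 1

    prev = np.empty(m + 1, dtype=np.int64)
    prev[0] = _CMAX
    prev[1:] = _CMAX + gap_delta * np.arange(1, m + 1, dtype=np.int64)
    gcost = -gap_delta
    for i in range(1, n + 1):
        eq = bv == av[i - 1]
        diag = prev[:-1] + np.where(eq, diag_match, diag_mismatch)
        up = prev[1:] + gap_delta
        base = np.maximum(diag, up)
        cur = np.empty(m + 1, dtype=np.int64)
        cur[0] = _CMAX + gap_delta * i
        # left moves: cur[j] = max over k <= j of base-ish[k] - gcost*(j-k)
        t = np.empty(m + 1, dtype=np.int64)
        t[0] = cur[0]
        t[1:] = base
        t = t + gcost * np.arange(m + 1, dtype=np.int64)
        np.maximum.accumulate(t, out=t)
        cur[1:] = (t - gcost * np.arange(m + 1, dtype=np.int64))[1:]
        prev = cur
    packed = int(prev[m])
    low = packed % _S1
    matches = low // _S2
    cols = _CMAX - (low % _S2)
    return matches / cols


# ---------------------------------------------------------------------------
# Copy clustering
# ---------------------------------------------------------------------------

@dataclass
class ElementCluster:
    name: str
    members: list[str]
    identity: pd.DataFrame
    representative: str  # sequence of the longest copy


def cluster_copies(
    calls: list[IStronModel],
    threshold: float = 0.93,
    *,
    organisms: dict[str, tuple[str, str]] | None = None,
    genome_order: list[str] | None = None,
) -> list[ElementCluster]:
    """Single-linkage clustering of calls on pairwise global identity.

    Clusters are named per the element nomenclature with indices ordered by
    first-seen genome (then coordinate), so permuting the input yields the
    same clusters and names.  ``organisms`` maps genome_id -> (genus,
    species); unknown genomes are named under a generic synthetic binomial.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    calls = sorted(calls, key=lambda c: (c.genome_id, c.istron_start, c.istron_end))
    ncalls = len(calls)
    parent = list(range(ncalls))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    idmat = np.eye(ncalls)
    for i in range(ncalls):
        for j in range(i + 1, ncalls):
            la, lb = len(calls[i].sequence), len(calls[j].sequence)
            if min(la, lb) / max(la, lb) < threshold:
                ident = 0.0
            else:
                ident = global_identity(calls[i].sequence, calls[j].sequence)
            idmat[i, j] = idmat[j, i] = ident
            if ident >= threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(ncalls):
        groups.setdefault(find(i), []).append(i)

    if genome_order is None:
        genome_order = sorted({c.genome_id for c in calls})
    order_rank = {gid: r for r, gid in enumerate(genome_order)}

    def cluster_key(members: list[int]):
        first = min(
            (order_rank.get(calls[i].genome_id, len(order_rank)), calls[i].istron_start)
            for i in members
        )
        return first

    clusters = []
    per_species_index: dict[tuple[str, str], int] = {}
    for members in sorted(groups.values(), key=cluster_key):
        rep = max(members, key=lambda i: len(calls[i].sequence))
        gid = calls[min(members, key=lambda i: (order_rank.get(calls[i].genome_id, 0), calls[i].istron_start))].genome_id
        genus, species = (organisms or {}).get(gid, ("Synthetic", "organism"))
        key = (genus, species)
        per_species_index[key] = per_species_index.get(key, 0) + 1
        name = name_istron(genus, species, per_species_index[key])
        ids = [f"{calls[i].genome_id}:{calls[i].istron_start}-{calls[i].istron_end}" for i in members]
        sub = pd.DataFrame(
            idmat[np.ix_(members, members)], index=ids, columns=ids
        )
        clusters.append(
            ElementCluster(name=name, members=ids, identity=sub, representative=calls[rep].sequence)
        )
    return clusters


# ---------------------------------------------------------------------------
# Insertion context
# ---------------------------------------------------------------------------

@dataclass
class InsertionContext:
    call_id: str
    context: str  # intragenic | intergenic
    host_gene: Gene | None
    in_frame: bool | None
    stop_created: bool | None


def insertion_context(call: IStronModel, genes: list[Gene], genome: GenomeRecord | None = None) -> InsertionContext:
    """Intragenic/intergenic context of a call, with the in-frame test.

    The frame origin is the annotated gene start on its own strand (gene end
    for minus-strand genes); in_frame is defined only for intragenic calls.
    ``stop_created`` is true when the insertion is in-frame and the element's
    first triplet read on the gene strand is a stop codon.
    """
    call_id = f"{call.genome_id}:{call.istron_start}-{call.istron_end}"
    host = None
    for g in genes:
        if g.contains(call.istron_start):
            if host is None or (g.end - g.start) < (host.end - host.start):
                host = g
    if host is None:
        return InsertionContext(call_id, "intergenic", None, None, None)
    if host.strand == "+":
        offset = call.istron_start - host.start
        first = call.sequence[:3]
    else:
        offset = host.end - call.istron_end
        from .grammar import revcomp

        first = revcomp(call.sequence[-3:])
    in_frame = offset % 3 == 0
    stop_created = bool(in_frame and first in STOP_TRIPLETS)
    return InsertionContext(call_id, "intragenic", host, in_frame, stop_created)


# ---------------------------------------------------------------------------
# Splice products
# ---------------------------------------------------------------------------

@dataclass
class SpliceProducts:
    ligated_exons: str
    full_circle_junction: str
    partial_circles: list[tuple[int, int, str]]
    junction_window: int


def simulate_splicing(
    locus: str,
    call: IStronModel,
    partial_offsets: list[tuple[int, int]] = (),
    junction_window: int = 30,
) -> SpliceProducts:
    """Reconstruct ligated exons and circle junctions for one locus.

    The full circle junction is the last ``w`` element bases joined to the
    first ``w``; a partial circle missing ``o5`` leading and ``o3`` trailing
    bases contributes the surviving part of that same junction region, so its
    junction is exactly ``o5 + o3`` shorter than the full one.  ``w`` widens
    automatically to cover the largest requested offset.
    """
    s, e = call.istron_start, call.istron_end
    if not (0 <= s < e <= len(locus)):
        raise ValueError("call boundaries outside the locus")
    exon5, istron, exon3 = locus[:s], locus[s:e], locus[e:]
    assert len(exon5) + len(istron) + len(exon3) == len(locus)
    w = max(junction_window, max((max(o5, o3) + 1 for o5, o3 in partial_offsets), default=0))
    w = min(w, len(istron) // 2)
    full = istron[-w:] + istron[:w]
    partials = []
    for o5, o3 in partial_offsets:
        junction = istron[len(istron) - w : len(istron) - o3] + istron[o5:w]
        partials.append((o5, o3, junction))
    return SpliceProducts(
        ligated_exons=exon5 + exon3,
        full_circle_junction=full,
        partial_circles=partials,
        junction_window=w,
    )


# ---------------------------------------------------------------------------
# Survey report
# ---------------------------------------------------------------------------

@dataclass
class SurveySummary:
    n_calls: int
    n_full_length: int
    n_partial: int
    n_clusters: int
    pct_intragenic: float | None
    pct_in_frame: float | None


def write_survey(
    calls: list[IStronModel],
    clusters: list[ElementCluster],
    contexts: list[InsertionContext],
    out_dir: str | Path,
    *,
    organisms: dict[str, tuple[str, str]] | None = None,
) -> SurveySummary:
    """Emit the survey outputs: an element table, per-call GFF3, summary
    counts and a run log.  Duplicate calls at identical coordinates are
    dropped with a warning."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    seen = set()
    unique_calls = []
    for c in calls:
        key = (c.genome_id, c.istron_start, c.istron_end)
        if key in seen:
            logger.warning("duplicate call %s deduplicated in survey", key)
            continue
        seen.add(key)
        unique_calls.append(c)

    call_by_id = {
        f"{c.genome_id}:{c.istron_start}-{c.istron_end}": c for c in unique_calls
    }

    rows = []
    for cl in clusters:
        members = [call_by_id[m] for m in cl.members if m in call_by_id]
        if not members:
            continue
        per_strain: dict[str, int] = {}
        for m in members:
            per_strain[m.genome_id] = per_strain.get(m.genome_id, 0) + 1
        copies = "-".join(
            map(str, sorted({min(per_strain.values()), max(per_strain.values())}))
        )
        first = members[0]
        gid = first.genome_id
        genus, species = (organisms or {}).get(gid, ("Synthetic", "organism"))
        rows.append(
            {
                "element": cl.name,
                "species": f"{genus} {species}",
                "size_bp": len(cl.representative),
                "copies_per_strain": copies,
                "intron_class": "IA2",
                "orf_composition": first.orf_composition,
                "is_family": first.is_family or "unassigned",
                "target_site": first.target_site[0] if first.target_site else "",
                "terminus": first.terminus_motif or "",
                "group": major_group(first.group) if first.group != "unclassified" else "unclassified",
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "element", "species", "size_bp", "copies_per_strain", "intron_class",
            "orf_composition", "is_family", "target_site", "terminus", "group",
        ],
    )
    table.to_csv(out / "elements.tsv", sep="\t", index=False)

    feats = []
    for c in unique_calls:
        attrs = {
            "ID": f"{c.genome_id}:{c.istron_start}-{c.istron_end}",
            "group": c.group,
            "orf_composition": c.orf_composition,
            "evidence": "|".join(sorted(c.boundary_evidence)),
        }
        feats.append(
            Gff3Feature(c.genome_id, "istron", c.istron_start, c.istron_end, c.strand, attributes=attrs)
        )
    write_gff3(feats, out / "calls.gff3")

    n_truncated = sum(1 for c in unique_calls if "tsd-check-truncated" in c.flags)
    ctx = [x for x in contexts if x.call_id in call_by_id]
    intragenic = [x for x in ctx if x.context == "intragenic"]
    in_frame = [x for x in intragenic if x.in_frame]
    pct_intra = 100.0 * len(intragenic) / len(ctx) if ctx else None
    pct_frame = 100.0 * len(in_frame) / len(intragenic) if intragenic else None
    summary = SurveySummary(
        n_calls=len(unique_calls),
        n_full_length=len(unique_calls) - n_truncated,
        n_partial=n_truncated,
        n_clusters=len([r for r in rows]),
        pct_intragenic=pct_intra,
        pct_in_frame=pct_frame,
    )
    with open(out / "summary.txt", "w") as fh:
        fh.write(f"calls\t{summary.n_calls}\n")
        fh.write(f"full_length\t{summary.n_full_length}\n")
        fh.write(f"partial\t{summary.n_partial}\n")
        fh.write(f"elements\t{summary.n_clusters}\n")
        fh.write(
            f"pct_intragenic\t{'' if pct_intra is None else f'{pct_intra:.1f}'}\n"
        )
        fh.write(
            f"pct_in_frame\t{'' if pct_frame is None else f'{pct_frame:.1f}'}\n"
        )
    return summary
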