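# Methods

`istronkit` detects and annotates IStrons — chimeric mobile elements made of
a self-splicing group I intron (structural class IA2) fused at its 3' end to
an IS200/IS605- or IS607-family insertion sequence — and ships a synthetic
genome generator that provides exact ground truth for every pipeline stage.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not show.

## The element model

An IStron is modelled as a contiguous genomic span with the following
grammar, shared between the generator and the detectors:

```
5'exon | [target site] | intron core (stop triplet, P1/IGS, filler, GAAC) |
         5' IR arm | ORF A | ORF B | (group B: 3' DR) | 3' IR arm | terminus | 3'exon
```

* **Target site.** Group A elements insert immediately downstream of a
  T-rich pentanucleotide (TTGAT, ATTAT or TTTAT); group B elements after a
  GG-ending site (AGGG, TGGG, GAGG); one variant inserts after AG.  The
  site is never duplicated on the 3' side (no TSD).
* **5' splice junction / P1.** The last 4–6 nt of the 5' exon pair with the
  internal guide sequence (IGS) near the intron start, with a single U–G
  wobble.  In group A the exon ends with U and the wobble is embedded in
  the IGS stem (canonical pairs on both sides).  In group B the exon ends
  with G; the U that follows the target site is the *first intron base*,
  the wobble sits one bp past the splice junction and is followed by an
  internal loop ("loop-adjacent-shifted").
* **Intron start.** The first intron triplet is a stop codon (TAA/TAG/TGA),
  so an in-frame intragenic insertion creates a stop at the insertion
  point.
* **GAAC motif.** The IS component sits downstream of the intron's P9.2
  region after one of GAACGA, GAACAA, GAACAC, GAATAA, GAATAT (DNA level).
* **IR stem.** Inverted-repeat arms enclosing the ORF region: 15–34 bp with
  >80% A–U pairs in group B; 6–10 bp with equal numbers of C–G and A–U
  pairs in group A.
* **Direct repeat (group B).** The 3'-proximal 15 nt of the 5' IR arm are
  directly repeated immediately upstream of the 3' IR arm; the BcISt1-style
  repeat is TAAATTTGATTGAAT (15 of the 21-nt arm).
* **Terminus.** TCAG (group A), CGG (group B), CAG (variant) are the final
  element bases.
* **ORFs.** ORF A (a tyrosine recombinase in IS200/IS605-family elements, a
  serine recombinase in IS607-family elements) and the shared-ancestry
  ORF B.  Degeneration modes mirror observed element states: ΔORF A
  (truncated), ΦORF A (full-length but frameshifted), ORF B only, and the
  ORF-less "emetic" variant that retains only the DR + 3' IR stem-forming
  sequence.

## Detection pipeline

1. **Mobile-ORF screen** (`screen`).  All maximal ORFs (start ATG/GTG/TTG,
   stop TAA/TAG/TGA, default ≥150 nt — a declared convention, the minimum
   screened gene length is not fixed by the survey protocol) are retained
   when an overlapping annotation carries a DNA-mobility keyword
   (whole-word, case-insensitive) or when a Smith–Waterman alignment
   against the bundled reference ORFs scores ≥60 with ≥50% coverage of the
   shorter sequence (the homology coverage rule).  The raw-score threshold
   of 60 replaces a BLAST e-value cutoff, which is meaningless without a
   database size; the flag is exposed.
2. **Upstream windows.**  2 kb of sequence 5' of each mobile ORF, oriented
   so the ORF is downstream.
3. **Signature scan** (`structure.scan_intron_signature`).  Candidate
   intron starts require a target-site motif directly 5' of a stop triplet
   and a valid P1 register (≥4 nt IGS pairing including exactly one U–G
   wobble, in one of the two recognised wobble topologies); a GAAC-family
   motif downstream is weighted evidence (+2), a group-consistent terminus
   motif +1, IGS length contributes its value.  Whether the GAAC motif is
   strictly required in all elements is unknown, so the scanner treats it
   as weighted rather than mandatory; the caller's structure-only route
   does require it.
4. **Boundary resolution** (`caller.resolve_boundaries`), three methods:
   * *(i) known ends* — terminus motifs (TCAG/CGG/CAG) downstream of the
     mobile ORF;
   * *(ii) homolog alignment* — a no-indel breakpoint fit of an
     IStron-less homologous locus: the 5'-flank offset is found by probing
     the 60 bases ending at the candidate start, then the homolog's
     remaining 3' flank is slid along the genome; both sides must reach
     75% identity, otherwise the method abstains;
   * *(iii) structural enclosure* — an IR stem whose arms flank the mobile
     ORF, whose 5' arm abuts a GAAC motif (±6 nt) at a plausible
     ribozyme-core distance (80–600 nt from the intron start) and whose 3'
     arm is followed (within 24 nt, overlap of up to 4 nt allowed for
     stems extended by accidental complementarity) by a known terminus.
     Stems are ranked by tightness of fit (terminus tail, then GAAC gap,
     then length).
   When methods disagree on the 3' boundary, (ii) wins, then (i), then
   (iii) — the homolog is the only method with an external witness.  A
   candidate whose resolved 3' end falls upstream of the mobile gene is an
   independent intron + IS pair and is rejected, as are spans outside
   100–2600 nt (the plausible element size range).  Within each window all
   candidate anchors are tried and the one maximising the homolog
   alignment identity wins: a shifted anchor always scores lower because
   the shifted bases mismatch the flank.  A lone end-motif match (evidence
   = known ends only) never suffices to call.  Elements with no ORFs are
   found by a genome-wide scan but require the homolog witness, and the
   bare AG variant target site is too unspecific for structure-only
   calling, so variant elements also need a homolog.  Known-ends-only and
   structure-only decisions err on the side of not calling; this is the
   main reason the structure-only route recovers ~95% rather than 100% of
   elements (see validation).
5. **Annotation.**  Group assignment uses target site + terminus only
   (A: T-rich site + TCAG; B: GG-ending + CGG; variant: AG + CAG); P1
   topology and IR-stem statistics are corroborating flags because real
   group B includes one exception to the P1 pattern.  ORF composition is
   classified from reference coverage: *intact* = a single-frame ORF
   covering ≥80% of the best reference; *Δ (truncated)* = coverage in
   [20%, 80%); *Φ (frameshifted)* = ≥80% coverage across reading-frame
   fragments with no intact single-frame ORF; the 80% threshold is a
   package convention ("truncated" is not quantified in the survey
   literature).  These classification alignments use steep gap costs
   (open −11, extend −8) because payload divergence is substitution-like
   and cheap gap extension lets a local alignment bridge into unrelated
   sequence and inflate coverage; the screening alignments keep BLAST-like
   −11/−1.  The IS family label is the best-hit reference family.  The DR
   annotator reports the longest exact common substring (≥8 nt) between
   the 5' IR arm and the 40 nt upstream of the 3' arm; a mismatch-tolerant
   mode exists behind a flag but is off by default since the repeats vary
   from strongly to weakly similar in real elements.
6. **Survey** (`survey`).  Copies cluster into elements by single-linkage
   on pairwise global identity ≥0.93 (the ">93% identity" copy rule;
   single linkage because highly similar copies group transitively across
   strains).  Insertion context: intragenic when the element start lies in
   a gene; in-frame when the offset from the gene's frame origin (gene
   start on its own strand) is ≡0 mod 3; the in-frame percentage is
   reported over intragenic insertions with gene predictions available.
   Splice products: ligated exons (exon5+exon3), the full circle junction
   (last w + first w element bases, default w=30) and partial circles
   missing leading/trailing bases.  The junction window widens
   automatically to cover the largest requested offset so that a partial
   circle's junction is exactly o5+o3 shorter than the full one; with a
   fixed 30-nt window the stated 42- and 71-base offsets could not shift
   the junction length by their full amount.

## Structural primitives

* **P1 annotation** maximises the exon-side pairing length within [4, 6];
  the duplex strand is the exon tail plus 0–2 leading intron bases, paired
  antiparallel against an IGS window in the intron head (minimum 3-nt
  loop).  Only registers whose single wobble is embedded or at the shift-1
  loop-adjacent position are valid P1 configurations; anything else is
  reported `absent`.
* **Constrained folding** is Nussinov-style base-pair maximisation
  (Watson–Crick + G·U, minimum loop 3) with forced pairs and forbidden
  spans; ties prefer the lexicographically smallest sorted pair list,
  which makes results exactly reproducible.  Contradictory constraints
  raise an error naming the pairs.  This deliberately replaces
  thermodynamic folding: covariance-model scores and free-energy
  parameters are not re-derivable from the element grammar, and the
  detection task only needs the conserved anchors.
* **IR stems** are maximal ungapped complementary runs on anti-diagonals of
  the pairing matrix (G·U allowed, counted as non-AU in the AU fraction;
  N never pairs), found by a vectorised run-length recurrence.  Scoring is
  stem length, ties by smaller loop then smaller 5'-arm start.  Bulged
  stems are deferred; observed stems are near-contiguous.  The default
  maximum loop is 2500 nt because the loop encloses the ORF region.
  For parameter-recovery runs the ORF-coding interior of the IR region is
  masked to N, mirroring the ORFs-removed view used when folding intron
  structures.
* **Alignment kernels.**  Local protein alignment is Smith–Waterman with
  affine gaps (a gap of length L costs open + (L−1)·extend) over BLOSUM62,
  delegated to `Bio.Align.PairwiseAligner`.  Global nucleotide identity is
  matches / alignment columns of the optimal global alignment (match +1,
  mismatch −1, linear gap −2); among co-optimal alignments the one
  maximising (score, matches, −columns) lexicographically is used, making
  the identity deterministic — implemented as a packed-int64 dynamic
  programme.

## The synthetic generator

The generator's defaults are the study conditions used for validation:
20 genomes of 30 kb (GC 0.35, Firmicutes-like), six element families (one
per species; species never mix groups, matching the observed pattern), 1–4
copies per genome separated by ≥3 kb, group weights A/B/variant =
0.5/0.4/0.1, degeneration mode weights intact/ΔORF A/ΦORF A/ORF B-only/
ORF-less = 0.40/0.25/0.15/0.10/0.10 (ΔORF A being the most common observed
state), 58% intragenic insertions of which 54% are in-frame (the survey's
reported fractions), intron core filler of 150–260 nt (anchors only are
specified by the element grammar; interior realism is not attempted), ORF
payloads back-translated from the bundled reference proteins at 75% (ORF A)
and 70% (ORF B) amino-acid identity, element copies diverged at 2% on
grammar-safe positions (filler and codon third bases, never creating or
destroying stops), and paired IStron-less homologs with 600-nt flanks at 3%
divergence.  The homolog divergence model is substitution-only so the
insertion breakpoint is unambiguous, which keeps the homolog-method test
exact.  ORF A/B lengths default to 453/1200 nt, placing full elements at
~1.8–2.1 kb and all generated elements inside the observed 0.48–2.6 kb size
range.  Truncation keeps the first 60% of an ORF; the frameshift mode
deletes one base at ~1/3 and inserts one at ~2/3 (length-preserving) and
guarantees an in-frame stop inside the shifted segment, since a frameshift
that never hits a stop is indistinguishable from an intact ORF at the
sequence level.  All coordinates are 0-based half-open; elements are
embedded on the forward strand, and record flipping provides the
reverse-complement mode used for strand-invariance tests.

The bundled reference ORFs are synthetic stand-ins (fixed-seed sequences
with realistic amino-acid composition, labelled `synthetic` in the FASTA),
not curated IS-family proteins.  Consequently the similarity screen and
IS-family labels are validated for internal consistency, not against real
IS diversity.  The DR/IR motifs are assigned to the element interior as a
labelled convention; whether they belong to the intron or the IS component
is unknown.

After assembling an intron head the generator verifies that the P1
annotator recovers the template's topology and resamples a short stretch of
interior filler otherwise (bounded, seeded rejection): random filler can
occasionally create a spurious higher-scoring P1 register, and the
generator's contract is that every emitted element validates against the
classifier's rules.

What passing the synthetic suite does **not** show: recovery of real
IStrons from GenBank-scale data (no covariance-model search, no BLAST
databases), robustness to assembly gaps/indel-divergent homologs (the
breakpoint fit assumes substitution-only divergence), bulged IR stems, or
elements on plasmids/phages with unusual flanking composition.

## Validation results computed by the tests

The test suite regenerates the default study set and verifies: exact
boundary recovery and generator-mode ORF compositions for 100% of elements
when paired homologs are supplied, with no false calls and no target-site
duplication; ≥95% exact boundaries for ORF-bearing elements from the
structure-and-ends methods alone; group-B stem recovery at ≥15 bp and ≥80%
AU; group-A stems ≥6 bp; IGS pairings ≥4 nt; and exact agreement of the
alignment/folding kernels with brute-force oracles on small inputs
(alignments ≤8 residues, foldings ≤12 nt).  Problem sizes (20 genomes of
30 kb; 50 fixtures per structural panel; 1000 alignment pairs; 500 folding
strings) are the package's chosen validation scale.

## Known limitations

* Boundary method (ii) assumes no indels between locus and homolog flanks.
* The ungapped stem finder merges coaxial stems separated by a single
  non-pairing base into separate runs; a real bulged arm would be reported
  as its longest ungapped segment.
* ORF-less and AG-variant elements are only called with a homolog witness.
* ΔORF B alone is classified like the other degenerate states; no distinct
  boundary treatment is applied.
* `global_identity` accepts sequences up to ~6 kb (packed-field budget);
  element-length inputs are far below this.
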