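# Methods

This note documents the models, parameters and design choices behind
`synmend`, and states what the synthetic test substrate does and does not
demonstrate about real data.

## Coordinate model

Sequences are circular by default. Coordinates are 0-based half-open
internally and GFF3 1-based inclusive on disk. A feature spanning the origin
of a circular genome is stored with `end > length` and serialized with the
GFF3 circular-genome convention (`end` beyond the landmark length,
`Is_circular=true` on the region line). Degenerate IUPAC bases are rejected
at load: every downstream stage (k-mer seeding, primer uniqueness, Tm) is
defined over A/C/G/T only.

All comparisons happen in the *dnaA frame*: each genome is
reverse-complemented if its unique dnaA gene (identified by product text,
case-insensitively matching "chromosomal replication initiator" or "dnaA",
with a locus-tag override) lies on the minus strand, then rotated so dnaA
starts at base 0. Normalization is idempotent and content-preserving, which
the test suite asserts directly.

rRNA operons are counted as maximal runs of rRNA genes with inter-gene gaps
≤ `operon_gap_bp` = 1,000 bp. The value is a convention, not biology: real
16S–23S spacers are a few hundred bp, and distinct operons in bacterial
chromosomes are tens of kbp apart, so any threshold in that wide valley
yields the same grouping.

## Ortholog anchoring and the consensus gene order

Anchoring is reciprocal-best-hit (RBH) pairing of translated CDS (bacterial
code, table 11). A 5-mer set Jaccard prefilter (≥ 0.5) proposes candidates;
a hit qualifies at global edit-distance identity ≥ 70 % between proteins
within a 70 % length ratio; only mutual, *unambiguous* bests are kept — a tie
for the best hit (identical paralogs, i.e. transposase copies) drops the gene
from anchoring entirely. This is deliberate: dispersed identical repeats
cannot be ordered reliably and are exactly the elements a misassembly moves.
The first panel genome serves as the anchoring reference and names the
ortholog groups; the reference is mapped through the same RBH machinery
(against itself), so its duplicate genes drop out symmetrically.

Each genome is reduced to its signed gene order: anchored CDS in coordinate
order, signed by strand agreement with the reference. The consensus is a
majority vote over signed adjacencies of the panel profiles (an adjacency and
its reverse-reading are one object). The consensus *sequence* is chained from
the dnaA group along each group's majority successor; where no successor
reaches majority — a gene missing from part of the panel — the plurality
successor keeps the backbone connected. Gene presence/absence is thereby
excluded from order comparison rather than penalized, since it is not a
synteny violation. Per-group expected start coordinates (the median of panel
dnaA-frame starts) are recorded alongside.

## Violation detection

The query profile is split into maximal blocks that are internally collinear
with the consensus (same direction, consecutive consensus indices, circular).
A single defect produces a characteristic block pattern; several defects
compose. Blocks are then explained greedily, smallest (fewest genes) first:

* a direction-flipped block whose un-flipped placement would restore both
  flanking adjacencies is an **inversion** (repaired virtually in place);
* a block whose removal makes its neighbors consensus-adjacent is a
  **translocation** (virtually re-inserted at its consensus home).

Adjacent collinear blocks are merged after each repair; the loop ends when
one block — the consensus arrangement — remains. Preferring the smaller
block resolves the inherent ambiguity of a translocation (moving the 19-gene
fragment or the 500-gene complement both explain the data) by parsimony,
which also matches the repeat-flank evidence.

**Intervals and breakpoints.** A translocation's interval is the span from
its first to its last anchored feature; its displacement is the observed
start of the first block gene minus that group's consensus-expected start
(positive = downstream). An inversion's breakpoints are first snapped to the
inner boundaries of repeat-family members inside the breakpoint regions, then
refined at single-base resolution against the panel: the exact breakpoint is
where the query stops agreeing with the per-position majority base of the
panel (the refinement is only accepted within 50 bp of the repeat-boundary
estimate, since it presumes locally agreeing coordinate frames). When a
breakpoint lies within identical repeat copies its position is identifiable
only up to the repeat unit; the reported interval is the one whose correction
reproduces the consensus layout with one full repeat copy on each side.

A violation is flagged **low-confidence** when either junction has no
repeat-family member boundary within `flank_window_bp` = 5,000 bp. The
window operationalizes "immediately adjacent to the repeat"; low-confidence
violations are reported but excluded from correction plans unless forced.

Repeat families themselves come from exact 31-mer seeding (2-bit rolling
encodings, both strands; k-mers occurring > 64 times are treated as
low-complexity noise) followed by ungapped X-drop extension (match +1,
mismatch −3, drop 30) and union-find merging of members overlapping ≥ 50 %
of the shorter. Defaults `min_len_bp` = 500 and `min_identity` = 0.95 catch
transposase genes (~1 kbp) and rRNA operons (~5 kbp) while ignoring short
dispersed repeats; gapped and tandem repeats are out of scope because the
repeats that mediate finished-genome misassemblies are near-exact. On
genomes ≤ 100 kbp the finder is checked against an independent exact-match
oracle with ±5 bp boundary tolerance.

## Rearrangement operations

`move(start, end, dest)` and `invert(start, end)` are length-preserving
permutations of positions applied by splicing; features are remapped through
the same permutation (inverted features flip strand), and a feature
straddling a cut site aborts the operation — the cuts this pipeline proposes
fall in intergenic repeat boundaries, so a straddler signals a bad plan.
Ops in a plan must affect disjoint regions and are applied in listed order,
with later ops re-resolved through each applied op's coordinate map (manual
edit semantics, no simultaneity). Every move composes with its inverse to
the identity and invert is self-inverse; the suite asserts both on random
ops, plus census invariance under any plan.

Verification after correction checks equal length, equal census, identical
locus sets, and byte-identical extracted sequence per locus — layout may
change, content may not.

## Validation-primer design

Each correction op defines seams (three for a move: both ends of the restored
fragment and the healed excision; two for an inversion), and each seam is
paired with the nearest repeat-family member within the flank window. The
amplicon for a junction must span the junction *and* the entire adjacent
repeat unit — a product contained in one repeat copy would not validate the
join — so primers are sought in the windows (default 2,000 bp) immediately
outside the spanned region, wholly outside every repeat member.

Constraints (re-verified independently in the tests): melting temperature in
[54, 56] °C; amplicon ≤ 10,000 bp; 3′-terminal 15-mer occurring exactly once
in the genome over both strands (the operationalization of "no significant
binding outside the intended priming sites"; full thermodynamic off-target
scanning is out of scope); longest self-complementary run < 8 and hairpin
stem < 6 with loop ≥ 3 by exact-complementarity dynamic programming (ΔG
folding out of scope); primer length 18–30 nt. Exactly two accepted pairs
per junction, ranked by Tm mismatch then amplicon length, with no primer
reuse between the pairs; infeasibility raises an error naming the dominant
failing constraint.

Tm is nearest-neighbor thermodynamics with the unified duplex parameter set
(Allawi & SantaLucia ΔH/ΔS tables, terminal initiation terms, symmetry
correction), the entropic salt correction 0.368·(N−1)·ln[Na⁺] at 50 mM
monovalent salt, and 1 µM primer in excess over template — the validation
PCR's own conditions. The parameter set is declared in every design table.
The suite cross-checks the implementation against an independent
nearest-neighbor implementation to < 0.05 °C, and evaluates the published
SAFR-032 validation primers (selected by Primer3 under its own undisclosed
defaults) as a documented tolerance check at ±2 °C around the window — under
the declared model they fall at 52.1–55.2 °C.

## Annotation reconciliation

Loci of two annotation versions are matched on the (stop coordinate, strand)
key — the stop is the stable end of a prokaryotic CDS, and the disagreements
this module targets are alternative starts. Matched loci with equal starts
are `identical`; for differing loci a third annotation arbitrates:
arbiter = new → `adopt_new`; arbiter = original → `retain_original`; arbiter
missing or matching neither → `default_new_ambiguous` (the new annotation is
kept for consistency, flagged ambiguous). Decisions are pure functions of
coordinates, order-independent, and symmetric under version relabeling.
Unmatched loci become the omitted list (original-only) and the new-gene list
(new-only). Non-coding RNAs and riboswitches bypass the vote and are carried
over from the original annotation.

Homology rules (all four thresholds are config keys; they are this package's
own operationalization of what the original study did by manual alignment
inspection):

* **pseudogene adjudication** — valid gene if the translated product covers
  ≥ 90 % of some panel protein at ≥ 50 % identity with no internal stop
  (this is the split-gene rescue: a product matching only the N-half of a
  bifunctional reference but all of a single-domain family member is valid);
  pseudogene on an internal in-frame stop, or best homolog coverage < 60 %
  (substantial deletion) without any full-length alternative match;
* **reinstatement** — an omitted locus is kept iff some panel protein
  matches at ≥ 50 % identity over ≥ 70 % of the length.

Identity is matches / alignment columns under global alignment with match
+1, mismatch −1, gap −2 (declared in output metadata); a 5-mer prefilter
limits alignments to plausible homologs. The final census enforces the
ledger arithmetic: differing = adopt_new + retain_original + ambiguous, and
retained pseudogenes = confirmed shared + confirmed extras.

## The synthetic substrate

The generator emulates a congeneric strain panel at finished-assembly level:

* one ancestral chromosome (default 1.8 Mbp, 1,800 CDS, 72 tRNA, 7 rRNA
  operons of 5 kbp, one identical transposase pair, GC ≈ 41 %, intergenic
  gaps 50–300 bp, homopolymer runs capped at 8);
* panel strains that share the ancestral layout with per-site substitutions
  in coding sequence (1 %/site, start/stop preserved, no new internal
  stops); repeat units mutate once per strain and are stamped at every site,
  so copies stay identical *within* a genome. Strains are emitted rotated to
  random origins and, half the time, reverse-complemented, so normalization
  is actually exercised;
* a query derived from the unmutated ancestor by planted ops: a fragment of
  19 CDS + 1 tRNA + 1 rRNA operon (the operon inside the fragment, near its
  end) bounded by operon copies and moved exactly 522,000 bp downstream over
  them, and an exactly 11,000 bp segment of 13 CDS + 1 tRNA between the two
  identical transposases, inverted. The generator refuses moves or
  inversions that are not repeat-bounded. The segment's end base is kept
  non-complementary to its start base so the planted breakpoints are not
  ambiguous by a 1 bp shift;
* annotation fixtures in which reconciliation categories are realized purely
  by start coordinates (three in-frame ATGs at codon offsets 0/3/6, a
  Shine-Dalgarno-like AGGAGG planted upstream except for "neither" cases),
  and a pseudogene ledger realized purely by sequence content (planted
  internal stops, 40 % truncations, split-gene constructions) with its
  homolog panel.

**What this does not exercise.** Divergence is substitution-only — no
indels, no gene gain/loss, no genuinely rearranged panel members — so panel
genomes share the ancestral coordinate system and consensus-expected
positions are exact; on real strains the expected start is a median over
genuinely different coordinates and displacement estimates inherit kbp-scale
noise. Repeat copies are identical within a genome (the 98 %-identity case
is exercised separately in the repeat-finder tests, not end-to-end).
Transposases are present in all panel strains, although in the motivating
study they were query-specific; this is harmless here because identical
duplicates drop out of anchoring either way. Start-codon fixtures plant
clean ATG alternatives; real ambiguous starts involve GTG/TTG and RBS
context that the reconciler deliberately does not model. Passing on this
substrate therefore demonstrates the correctness of the comparative logic,
the coordinate arithmetic and the rule systems — not robustness to
assembly-level noise sources the generator does not contain.

## Problem sizes and numerical choices

The default scenario (1.8 Mbp × 6 genomes) runs detection + correction in
under a minute on one CPU; the test suite uses compact scenarios (120–150
kbp, 100–140 genes, 2–3 strains) for per-module checks and runs the default
scale once in the acceptance tests, alongside 100 seeded single-op
end-to-end replicates at the compact scale. Seeds are mandatory everywhere;
there is no wall-clock entropy. Ties are broken deterministically (smallest
block first, then coordinate order; leftmost repeat member; lexicographic
pair ranking), so every artifact is byte-reproducible from (config, seed).

Known limitations beyond the generator's scope: no rearrangement-distance
machinery (single misplaced blocks, not minimal DCJ scenarios, are the
target); gapped repeats and scaffolding gaps are not modeled; the
annotation reconciler trusts its inputs' reading frames and does not re-call
genes.
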