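"""Ortholog anchoring, consensus signed gene order, and violation detection.

The comparison frame is the signed gene order: each genome, rotated to start
at *dnaA* on the plus strand, is reduced to its sequence of anchored
protein-coding genes with a sign recording the strand relative to the
consensus.  Anchoring is reciprocal-best-hit pairing of translated CDS against
a reference genome of the panel; genes without an unambiguous reciprocal best
hit (duplicated transposases above all) stay unanchored and take no part in
order comparison.

A *violation* is a maximal run of query genes that is internally collinear
with the consensus but misplaced as a whole: uniformly sign-flipped in place
(an inversion) or relocated (a translocation).  Violations whose breakpoints
are not near a long-repeat family member are reported but flagged
low-confidence — repeat flanks are the signature of a misassembly rather than
a true rearrangement.
"""

from __future__ import annotations

import collections
import json
import statistics
from dataclasses import dataclass, field

from . import _align
from .genome_model import AnnotatedGenome, GenomeModelError, translate_cds
from .repeat_finder import RepeatFamily

__all__ = [
    "AnchorMap",
    "GeneOrderProfile",
    "ConsensusOrder",
    "Violation",
    "LowOverlapError",
    "build_anchor_map",
    "assign_ortholog_groups",
    "build_profile",
    "consensus_order",
    "detect_violations",
]

ANCHOR_MIN_IDENTITY = 0.70
ANCHOR_MIN_LENGTH_RATIO = 0.70
ANCHOR_MIN_JACCARD = 0.50
FLANK_WINDOW_BP = 5_000


class LowOverlapError(GenomeModelError):
    """Profiles share too few ortholog groups to form a consensus."""


@dataclass
class AnchorMap:
    genome_a: str
    genome_b: str
    pairs: list[tuple[str, str, float]]  # (locus_a, locus_b, identity)
    coverage: float  # fraction of A's CDS anchored

    def as_dict_a_to_b(self) -> dict[str, str]:
        return {a: b for a, b, _ in self.pairs}


@dataclass
class GeneOrderProfile:
    genome_id: str
    entries: list  # list of _ProfileEntry in genome order, starting at dnaA


@dataclass(frozen=True)
class _ProfileEntry:
    group: str
    sign: int  # +1 / -1: strand relative to the reference gene's strand
    start: int
    end: int
    locus_tag: str


@dataclass
class ConsensusOrder:
    groups: list[str]  # circular order, starting at the dnaA group
    signs: dict[str, int]
    adjacency_support: dict[tuple, int]
    expected_start: dict[str, int]  # median dnaA-frame start per group
    panel_size: int

    @property
    def position(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.groups)}


@dataclass
class Violation:
    violation_id: str
    kind: str  # translocation | inversion
    query_interval: tuple[int, int]
    fragment_gene_counts: tuple[int, int, int]  # (n_CDS, n_tRNA, n_rRNA_operons)
    length_bp: int
    displacement_bp: int | None  # translocation only; + = downstream
    expected_start: int | None
    flank_families: tuple[str | None, str | None]
    support: int
    low_confidence: bool
    n_anchored_genes: int = 0

    def as_dict(self) -> dict:
        return {
            "violation_id": self.violation_id,
            "kind": self.kind,
            "query_start": self.query_interval[0] + 1,  # 1-based in reports
            "query_end": self.query_interval[1],
            "n_cds": self.fragment_gene_counts[0],
            "n_trna": self.fragment_gene_counts[1],
            "n_rrna_operons": self.fragment_gene_counts[2],
            "length_bp": self.length_bp,
            "displacement_bp": self.displacement_bp,
            "flank_families": list(self.flank_families),
            "support": self.support,
            "low_confidence": self.low_confidence,
        }


def violations_to_json(violations: list[Violation]) -> str:
    return json.dumps([v.as_dict() for v in violations], indent=2)


def violations_to_tsv(violations: list[Violation]) -> str:
    cols = [
        "violation_id", "kind", "query_start", "query_end", "n_cds", "n_trna",
        "n_rrna_operons", "length_bp", "displacement_bp", "support", "low_confidence",
    ]
    lines = ["\t".join(cols)]
    for v in violations:
        d = v.as_dict()
        lines.append("\t".join(str(d[c]) for c in cols))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------

def _proteomes(genome: AnnotatedGenome) -> dict[str, str]:
    prots = {}
    for f in genome.features:
        if f.ftype != "CDS":
            continue
        p = translate_cds(genome, f.locus_tag)
        if len(p) >= 30:
            prots[f.locus_tag] = p
    return prots


def _best_hits(prots_a, prots_b, prefilter_b):
    """Best partner in B for each protein of A; ambiguous ties dropped."""
    best = {}
    for tag_a, pa in prots_a.items():
        cands = prefilter_b.candidates(pa, top=4, min_jaccard=ANCHOR_MIN_JACCARD)
        scored = []
        for tag_b, _j in cands:
            pb = prots_b[tag_b]
            if min(len(pa), len(pb)) / max(len(pa), len(pb)) < ANCHOR_MIN_LENGTH_RATIO:
                continue
            ident = _align.global_identity(pa, pb)
            if ident >= ANCHOR_MIN_IDENTITY:
                scored.append((ident, tag_b))
        if not scored:
            continue
        scored.sort(reverse=True)
        if len(scored) > 1 and scored[0][0] - scored[1][0] < 1e-9:
            continue  # duplicated gene: no unambiguous ortholog
        best[tag_a] = (scored[0][1], scored[0][0])
    return best


def build_anchor_map(genome_a: AnnotatedGenome, genome_b: AnnotatedGenome) -> AnchorMap:
    """Reciprocal-best-hit CDS pairing by protein similarity.

    A 5-mer Jaccard prefilter proposes candidates; global edit-distance
    identity >= 70 % over proteins within a 70 % length ratio qualifies a hit;
    only mutual unambiguous bests are kept.
    """
    prots_a = _proteomes(genome_a)
    prots_b = _proteomes(genome_b)
    pf_a = _align.KmerPrefilter(prots_a)
    pf_b = _align.KmerPrefilter(prots_b)
    ab = _best_hits(prots_a, prots_b, pf_b)
    ba = _best_hits(prots_b, prots_a, pf_a)
    pairs = []
    for tag_a, (tag_b, ident) in ab.items():
        back = ba.get(tag_b)
        if back and back[0] == tag_a:
            pairs.append((tag_a, tag_b, round(ident, 4)))
    coverage = len(pairs) / max(len(prots_a), 1)
    return AnchorMap(genome_a.genome_id, genome_b.genome_id, sorted(pairs), coverage)


def assign_ortholog_groups(
    genome: AnnotatedGenome, reference: AnnotatedGenome, anchor_map: AnchorMap | None = None
) -> dict[str, str]:
    """Map each anchorable CDS of ``genome`` to a group named after its
    reference locus."""
    if anchor_map is None:
        anchor_map = build_anchor_map(genome, reference)
    return anchor_map.as_dict_a_to_b()


def build_profile(
    genome: AnnotatedGenome,
    groups: dict[str, str],
    ref_strands: dict[str, str],
) -> GeneOrderProfile:
    """Signed gene-order profile of a dnaA-normalized genome."""
    entries = []
    for f in genome.features:
        if f.ftype != "CDS" or f.locus_tag not in groups:
            continue
        group = groups[f.locus_tag]
        sign = 1 if f.strand == ref_strands[group] else -1
        entries.append(_ProfileEntry(group, sign, f.start, f.end, f.locus_tag))
    entries.sort(key=lambda e: e.start)
    return GeneOrderProfile(genome.genome_id, entries)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _canonical_adjacency(g1, s1, g2, s2):
    a = (g1, s1, g2, s2)
    b = (g2, -s2, g1, -s1)
    return min(a, b)


def consensus_order(profiles: list[GeneOrderProfile], dnaA_group: str) -> ConsensusOrder:
    """Majority vote over signed adjacencies of the panel profiles.

    The consensus sequence is chained from the dnaA group along each group's
    majority successor.  Groups absent from a genome simply contribute no
    adjacencies there (gene presence/absence is not an order violation).
    """
    if len(profiles) < 2:
        raise GenomeModelError("consensus needs at least 2 profiles")
    group_sets = [frozenset(e.group for e in p.entries) for p in profiles]
    universe = frozenset.union(*group_sets)
    for gs in group_sets:
        if len(gs & group_sets[0]) < 0.5 * min(len(gs), len(group_sets[0])):
            raise LowOverlapError("profiles share fewer than half of their groups")

    adjacency_votes: collections.Counter = collections.Counter()
    successor_votes: dict[tuple[str, int], collections.Counter] = collections.defaultdict(
        collections.Counter
    )
    starts: dict[str, list[int]] = collections.defaultdict(list)
    sign_votes: dict[str, collections.Counter] = collections.defaultdict(collections.Counter)
    for p in profiles:
        ents = p.entries
        n = len(ents)
        for e in ents:
            starts[e.group].append(e.start)
            sign_votes[e.group][e.sign] += 1
        for i in range(n):
            a, b = ents[i], ents[(i + 1) % n]
            adjacency_votes[_canonical_adjacency(a.group, a.sign, b.group, b.sign)] += 1
            successor_votes[(a.group, a.sign)][(b.group, b.sign)] += 1
            successor_votes[(b.group, -b.sign)][(a.group, -a.sign)] += 1

    majority = len(profiles) // 2 + 1
    # chain the consensus from dnaA along majority successors; where no
    # successor reaches majority (a gene missing from some genomes), the
    # plurality successor keeps the backbone connected
    order = [dnaA_group]
    signs = {dnaA_group: 1}
    seen = {dnaA_group}
    cur = (dnaA_group, 1)
    while True:
        votes = successor_votes.get(cur)
        if not votes:
            break
        nxt = None
        for (g, sgn), count in votes.most_common():
            if g not in seen:
                nxt = (g, sgn, count)
                break
        if nxt is None:
            break
        nxt_group, nxt_sign, _count = nxt
        order.append(nxt_group)
        signs[nxt_group] = nxt_sign
        seen.add(nxt_group)
        cur = (nxt_group, nxt_sign)

    expected = {g: int(statistics.median(v)) for g, v in starts.items()}
    return ConsensusOrder(
        groups=order,
        signs=signs,
        adjacency_support=dict(adjacency_votes),
        expected_start=expected,
        panel_size=len(profiles),
    )


# ---------------------------------------------------------------------------
# violation detection
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    entries: list  # profile entries in query order
    dirn: int  # +1 collinear forward, -1 traversed against consensus
    pos_first: int  # consensus index of the first entry
    pos_last: int  # consensus index of the last entry
    gidx: tuple[int, int]  # global index range in the query profile (inclusive)

    @property
    def size(self) -> int:
        return len(self.entries)


def _collinear(pos, n, e1, e2, csign):
    d1 = e1.sign * csign[e1.group]
    d2 = e2.sign * csign[e2.group]
    if d1 != d2:
        return False
    step = (pos[e2.group] - pos[e1.group]) % n
    return step == (1 if d1 == 1 else n - 1)


def _split_blocks(entries, pos, n, csign):
    breaks = []
    m = len(entries)
    for i in range(m):
        if not _collinear(pos, n, entries[i], entries[(i + 1) % m], csign):
            breaks.append(i)
    if not breaks:
        return []
    blocks = []
    for bi, brk in enumerate(breaks):
        start = (breaks[bi - 1] + 1) % m
        idxs = []
        j = start
        while True:
            idxs.append(j)
            if j == brk:
                break
            j = (j + 1) % m
        ents = [entries[j] for j in idxs]
        d = ents[0].sign * csign[ents[0].group]
        blocks.append(
            _Block(ents, d, pos[ents[0].group], pos[ents[-1].group], (idxs[0], idxs[-1]))
        )
    blocks.sort(key=lambda b: b.gidx[0])
    return blocks


def _would_adjoin(b1: _Block, b2: _Block, n: int) -> bool:
    """Would b2 follow b1 collinearly in the consensus circle?"""
    if b1.dirn != b2.dirn:
        return False
    if b1.dirn == 1:
        return (b2.pos_first - b1.pos_last) % n == 1
    return (b1.pos_last - b2.pos_first) % n == 1


def _flip(b: _Block) -> _Block:
    return _Block(list(reversed(b.entries)), -b.dirn, b.pos_last, b.pos_first, b.gidx)


def detect_violations(
    query_profile: GeneOrderProfile,
    consensus: ConsensusOrder,
    repeat_families: list[RepeatFamily],
    query_genome: AnnotatedGenome,
    panel_genomes: list[AnnotatedGenome] | None = None,
    flank_window_bp: int = FLANK_WINDOW_BP,
    max_rounds: int = 50,
) -> list[Violation]:
    """Report maximal misplaced consensus-collinear runs of the query.

    The query profile is split into blocks at broken consensus adjacencies.
    Blocks are then greedily explained, smallest first: a sign-flipped block
    whose un-flipped placement restores both flanking adjacencies is an
    inversion; a block whose removal makes its neighbors adjacent is a
    translocation and is virtually re-inserted at its consensus home.  The
    loop ends when one block (the consensus arrangement) remains.
    """
    pos = consensus.position
    n = len(consensus.groups)
    csign = consensus.signs
    entries = [e for e in query_profile.entries if e.group in pos]
    if len(entries) < 2:
        return []
    blocks = _split_blocks(entries, pos, n, csign)
    if not blocks:
        return []

    violations = []
    vid = 0
    work = list(blocks)
    for _ in range(max_rounds):
        if len(work) <= 1:
            break
        m = len(work)
        candidates = []  # (gene count, index, kind)
        for i, b in enumerate(work):
            left, right = work[(i - 1) % m], work[(i + 1) % m]
            if b.dirn == -1:
                bf = _flip(b)
                if _would_adjoin(left, bf, n) and _would_adjoin(bf, right, n):
                    candidates.append((b.size, i, "inversion"))
                    continue
            if _would_adjoin(left, right, n) or m == 2:
                candidates.append((b.size, i, "translocation"))
        if not candidates:
            break
        candidates.sort()
        _, i, kind = candidates[0]
        b = work[i]
        violations.append((kind, b))
        if kind == "inversion":
            work[i] = _flip(b)
        else:
            work.pop(i)
            # re-insert at the consensus home if it exists in the current order
            placed = False
            for j in range(len(work)):
                nxt = work[(j + 1) % len(work)]
                if _would_adjoin(work[j], b, n) and _would_adjoin(b, nxt, n):
                    work.insert(j + 1, b)
                    placed = True
                    break
            if not placed and len(work) >= 1:
                for j in range(len(work)):
                    if _would_adjoin(work[j], b, n):
                        work.insert(j + 1, b)
                        break
        # merge adjacent collinear blocks
        def merge2(a: _Block, c: _Block) -> _Block:
            return _Block(
                a.entries + c.entries, a.dirn, a.pos_first, c.pos_last,
                (a.gidx[0], c.gidx[1]),
            )

        merged = [work[0]]
        for blk in work[1:]:
            if _would_adjoin(merged[-1], blk, n):
                merged.append(merge2(merged.pop(), blk))
            else:
                merged.append(blk)
        if len(merged) > 1 and _would_adjoin(merged[-1], merged[0], n):
            first = merged.pop(0)
            merged.append(merge2(merged.pop(), first))
        work = merged

    out = []
    for kind, b in violations:
        out.append(
            _violation_record(
                f"V{vid:03d}", kind, b, entries, consensus, repeat_families,
                query_genome, panel_genomes, flank_window_bp,
            )
        )
        vid += 1
    out.sort(key=lambda v: v.query_interval)
    return out


# -- violation coordinates, junctions, counts --------------------------------

def _nearest_boundary_dist(families, point):
    best = None
    for fam in families:
        for mem in fam.members:
            for bnd in (mem.start, mem.end):
                d = abs(point - bnd)
                if best is None or d < best[0]:
                    best = (d, fam.family_id)
    return best if best else (None, None)


def _majority_base(panel_seqs: list[str], j: int) -> str | None:
    bases = [s[j] for s in panel_seqs if 0 <= j < len(s)]
    if not bases:
        return None
    cnt = collections.Counter(bases).most_common()
    if len(cnt) > 1 and cnt[0][1] == cnt[1][1]:
        return None
    return cnt[0][0]


def _refine_breakpoint(qseq, panel_seqs, approx, side, window=400):
    """Exact breakpoint: where the query stops agreeing with the panel majority.

    ``side`` 'left': last position before divergence (scan rightwards);
    'right': first position after divergence resumes agreement (scan leftwards).
    """
    lo = max(approx - window, 0)
    hi = min(approx + window, len(qseq))
    if side == "left":
        for j in range(lo, hi):
            m = _majority_base(panel_seqs, j)
            if m is not None and qseq[j] != m:
                return j
        return approx
    for j in range(hi - 1, lo - 1, -1):
        m = _majority_base(panel_seqs, j)
        if m is not None and qseq[j] != m:
            return j + 1
    return approx


def _violation_record(
    vid, kind, block, entries, consensus, families, query_genome, panel_genomes,
    flank_window_bp,
):
    m = len(entries)
    first, last = block.entries[0], block.entries[-1]
    prev_e = entries[(block.gidx[0] - 1) % m]
    next_e = entries[(block.gidx[1] + 1) % m]

    jl, jr = first.start, last.end
    if kind == "inversion":
        # snap to the inner boundaries of flanking repeat members, then refine
        # against the panel's local consensus sequence
        left_cands = [
            mem.end
            for fam in families for mem in fam.members
            if prev_e.end <= mem.end <= first.start
        ]
        right_cands = [
            mem.start
            for fam in families for mem in fam.members
            if last.end <= mem.start <= next_e.start
        ]
        if left_cands:
            jl = max(left_cands)
        if right_cands:
            jr = min(right_cands)
        if panel_genomes:
            # only trust the sequence-level refinement if it stays close to the
            # repeat-boundary estimate (the local coordinate frames must agree)
            pseqs = [g.sequence for g in panel_genomes]
            jl_ref = _refine_breakpoint(query_genome.sequence, pseqs, jl, "left")
            jr_ref = _refine_breakpoint(query_genome.sequence, pseqs, jr, "right")
            if abs(jl_ref - jl) <= 50:
                jl = jl_ref
            if abs(jr_ref - jr) <= 50:
                jr = jr_ref

    # fragment content: features fully inside the interval
    n_cds = n_trna = 0
    rrna = []
    for f in query_genome.features:
        if f.start >= jl and f.end <= jr:
            if f.ftype == "CDS":
                n_cds += 1
            elif f.ftype == "tRNA":
                n_trna += 1
            elif f.ftype == "rRNA":
                rrna.append((f.start, f.end))
    rrna.sort()
    n_operons = 0
    if rrna:
        n_operons = 1
        for (s0, e0), (s1, e1) in zip(rrna, rrna[1:]):
            if s1 - e0 > 1000:
                n_operons += 1

    displacement = None
    expected = None
    if kind == "translocation":
        expected = consensus.expected_start.get(first.group)
        if expected is not None:
            displacement = first.start - expected

    dl, fam_l = _nearest_boundary_dist(families, jl)
    dr, fam_r = _nearest_boundary_dist(families, jr)
    low_conf = not (
        dl is not None and dl <= flank_window_bp and dr is not None and dr <= flank_window_bp
    )

    support = consensus.panel_size
    return Violation(
        violation_id=vid,
        kind=kind,
        query_interval=(jl, jr),
        fragment_gene_counts=(n_cds, n_trna, n_operons),
        length_bp=jr - jl,
        displacement_bp=displacement,
        expected_start=expected,
        flank_families=(fam_l, fam_r),
        support=support,
        low_confidence=low_conf,
        n_anchored_genes=len(block.entries),
    )
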