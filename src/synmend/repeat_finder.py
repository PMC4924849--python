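"""Detection of long near-identical repeat families.

Long repeats — rRNA operons and mobile-element (transposase) genes above all —
are the sequence signature at which bacterial assemblies go wrong: a join made
across the wrong copy of a repeat relocates or inverts everything between the
copies.  This module finds such repeats with exact k-mer seeding followed by
ungapped X-drop extension, merges the matches into families, and classifies
each family by what it overlaps in the annotation.

Gapped or highly diverged repeats are out of scope: the repeats that mediate
misassemblies in finished genomes are near-exact.
"""

from __future__ import annotations

import collections
import itertools
from dataclasses import dataclass

import numpy as np

from .genome_model import AnnotatedGenome, GenomeModelError, reverse_complement

__all__ = [
    "RepeatFamily",
    "RepeatMember",
    "find_long_repeats",
    "classify_repeats",
    "members_near",
]

DEFAULT_MIN_LEN = 500
DEFAULT_MIN_IDENTITY = 0.95
SEED_K = 31


@dataclass(frozen=True, order=True)
class RepeatMember:
    start: int
    end: int
    strand: str  # '+' or '-' relative to the family's reference copy

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatFamily:
    family_id: str
    members: list[RepeatMember]
    unit_length_bp: int
    pairwise_identity: float
    repeat_class: str = "other"  # rRNA_operon | transposase | other

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise GenomeModelError("a repeat family needs >= 2 members")
        self.members.sort()


# ---------------------------------------------------------------------------
# seeding and extension
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

#: k-mers occurring more often than this are treated as low-complexity noise
MAX_KMER_OCCURRENCES = 64


def _kmer_ints(seq: str, k: int):
    """Rolling 2-bit encodings of every k-mer, forward and reverse-complement."""
    codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.uint64)
    n = len(seq)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for t in range(k):
        fwd = (fwd << np.uint64(2)) | codes[t : m + t]
        rev = (rev << np.uint64(2)) | (np.uint64(3) - codes[k - 1 - t : m + k - 1 - t])
    return fwd, rev


def _seed_pairs(seq: str, k: int, min_len: int):
    """Pairs of positions sharing a k-mer, grouped by orientation and diagonal.

    Same-orientation hits extend along the diagonal ``j - i``; opposite-strand
    hits (the k-mer at ``i`` equals the reverse complement of the one at ``j``)
    extend along the anti-diagonal ``i + j``.
    """
    fwd, rev = _kmer_ints(seq, k)
    m = len(fwd)
    vals = np.concatenate([fwd, rev])
    pos = np.concatenate([np.arange(m), np.arange(m)])
    is_rc = np.concatenate([np.zeros(m, dtype=bool), np.ones(m, dtype=bool)])
    order = np.argsort(vals, kind="stable")
    vals, pos, is_rc = vals[order], pos[order], is_rc[order]
    boundaries = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(vals)]])

    fwd_hits: dict[int, list[int]] = collections.defaultdict(list)
    rc_hits: dict[int, list[int]] = collections.defaultdict(list)
    min_sep = max(min_len // 2, k)
    for s, e in zip(starts, ends):
        if e - s < 2 or e - s > MAX_KMER_OCCURRENCES:
            continue
        ppos = pos[s:e]
        prc = is_rc[s:e]
        f_positions = ppos[~prc]
        r_positions = ppos[prc]
        for a, b in itertools.combinations(sorted(int(x) for x in f_positions), 2):
            if b - a >= min_sep:
                fwd_hits[b - a].append(a)
        for a in f_positions:
            for b in r_positions:
                a, b = int(a), int(b)
                if a < b and b - a >= min_sep:
                    rc_hits[a + b + k].append(a)
    return fwd_hits, rc_hits


def _merge_seed_runs(starts: list[int], k: int, max_gap: int = 400):
    """Merge sorted seed starts on one diagonal into candidate runs."""
    starts = sorted(set(starts))
    runs = []
    run_start = prev = starts[0]
    for s in starts[1:]:
        if s - prev <= max_gap:
            prev = s
        else:
            runs.append((run_start, prev + k))
            run_start = prev = s
    runs.append((run_start, prev + k))
    return runs


def _extend_pair(seq_a: str, seq_b: str, a0: int, a1: int, b0: int, xdrop: int = 30):
    """Ungapped extension of an aligned pair; returns (a0, a1, b0, identity).

    ``seq_b`` is the (possibly reverse-complemented) frame in which the second
    copy runs parallel to the first; ``b0`` is the partner coordinate of
    ``a0`` in that frame.  Match +1, mismatch -3, trimmed at the best score.
    """
    n, m = len(seq_a), len(seq_b)

    def run(direction: int):
        best = 0
        best_off = 0
        score = 0
        off = 0
        while True:
            if direction > 0:
                ia, ib = a1 + off, b0 + (a1 - a0) + off
            else:
                ia, ib = a0 - 1 - off, b0 - 1 - off
            if ia < 0 or ib < 0 or ia >= n or ib >= m:
                break
            score += 1 if seq_a[ia] == seq_b[ib] else -3
            off += 1
            if score > best:
                best, best_off = score, off
            if score < best - xdrop:
                break
        return best_off

    right = run(+1)
    left = run(-1)
    na0, na1, nb0 = a0 - left, a1 + right, b0 - left
    matches = sum(1 for i in range(na1 - na0) if seq_a[na0 + i] == seq_b[nb0 + i])
    ident = matches / (na1 - na0) if na1 > na0 else 0.0
    return na0, na1, nb0, ident


def find_long_repeats(
    genome: AnnotatedGenome,
    min_len_bp: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    k: int = SEED_K,
) -> list[RepeatFamily]:
    """Find families of near-identical repeats >= ``min_len_bp`` at >= ``min_identity``.

    Both orientations are detected; an inverted copy is reported with
    strand ``'-'``.
    """
    if min_len_bp < 50:
        raise GenomeModelError("min_len_bp must be >= 50")
    if not (0.8 < min_identity <= 1.0):
        raise GenomeModelError("min_identity must be in (0.8, 1.0]")
    seq = genome.sequence
    if len(seq) < min_len_bp:
        raise GenomeModelError("genome shorter than min_len_bp")
    rc_seq = reverse_complement(seq)
    n = len(seq)

    fwd_hits, rev_hits = _seed_pairs(seq, k, min_len_bp)

    pair_hits = []  # (intervalA, intervalB, strand, identity)
    for diag, starts in fwd_hits.items():
        for r0, r1 in _merge_seed_runs(starts, k):
            a0, a1, b0, ident = _extend_pair(seq, seq, r0, r1, r0 + diag)
            if a1 - a0 >= min_len_bp and ident >= min_identity:
                if b0 >= a1:  # keep only non-overlapping copy pairs
                    pair_hits.append(((a0, a1), (b0, b0 + (a1 - a0)), "+", ident))
    for anti, starts in rev_hits.items():
        # partner of forward position i is rc-frame position n - (anti - i) ...
        # in rc coordinates: the k-mer at i pairs with rc position n - i - anti + ... ;
        # using rc_index = n - (j + k) for genome j, and j = anti - i - k:
        for r0, r1 in _merge_seed_runs(starts, k):
            b0 = n - (anti - r0)
            a0, a1, nb0, ident = _extend_pair(seq, rc_seq, r0, r1, b0)
            if a1 - a0 >= min_len_bp and ident >= min_identity:
                # map the rc-frame interval back to genome coordinates
                gb0 = n - (nb0 + (a1 - a0))
                gb1 = n - nb0
                if gb0 >= a1 or a0 >= gb1:
                    first, second = sorted([(a0, a1), (gb0, gb1)])
                    pair_hits.append((first, second, "-", ident))

    return _families_from_pairs(pair_hits, min_len_bp)


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    shorter = max(1, min(a[1] - a[0], b[1] - b[0]))
    return inter / shorter


def _families_from_pairs(pair_hits, min_len_bp) -> list[RepeatFamily]:
    """Union-find over member intervals: overlapping (>=50 % of the shorter)
    intervals are the same member; members linked by a pair hit are one family."""
    members: list[list] = []  # [start, end, strand ('+' unless only seen inverted)]

    def find_member(iv, strand):
        for idx, m in enumerate(members):
            if _overlap_frac(iv, (m[0], m[1])) >= 0.5:
                m[0] = min(m[0], iv[0])
                m[1] = max(m[1], iv[1])
                if strand == "-":
                    m[2] = "-"
                return idx
        members.append([iv[0], iv[1], strand])
        return len(members) - 1

    parent = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent[find(x)] = find(y)

    pair_ident: dict[int, float] = {}
    for iv_a, iv_b, strand, ident in sorted(pair_hits):
        ia = find_member(iv_a, "+")
        ib = find_member(iv_b, strand)
        union(ia, ib)
        root = find(ia)
        pair_ident[root] = min(pair_ident.get(root, 1.0), ident)

    groups: dict[int, list[int]] = collections.defaultdict(list)
    for idx in range(len(members)):
        groups[find(idx)].append(idx)

    families = []
    fam_n = 0
    for root, idxs in sorted(groups.items(), key=lambda kv: min(members[i][0] for i in kv[1])):
        if len(idxs) < 2:
            continue
        mems = [
            RepeatMember(members[i][0], members[i][1], members[i][2]) for i in idxs
        ]
        lens = sorted(m.length for m in mems)
        unit = lens[len(lens) // 2]
        if unit < min_len_bp:
            continue
        ident = min(
            pair_ident.get(find(i), 1.0) for i in idxs
        )
        families.append(
            RepeatFamily(
                family_id=f"rep{fam_n:03d}",
                members=mems,
                unit_length_bp=unit,
                pairwise_identity=round(ident, 4),
            )
        )
        fam_n += 1
    return families


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_repeats(
    families: list[RepeatFamily], genome: AnnotatedGenome
) -> list[RepeatFamily]:
    """Label each family by annotation overlap of its members.

    ``rRNA_operon`` if >= 50 % of the unit overlaps rRNA genes, ``transposase``
    if >= 50 % overlaps CDS whose product mentions a transposase, else
    ``other``.
    """
    rrna = [(f.start, f.end) for f in genome.features if f.ftype == "rRNA"]
    tpase = [
        (f.start, f.end)
        for f in genome.features
        if f.ftype == "CDS" and "transposase" in f.product.lower()
    ]

    def covered(member: RepeatMember, intervals) -> int:
        return sum(
            max(0, min(member.end, e) - max(member.start, s)) for s, e in intervals
        )

    for fam in families:
        r_cov = sum(covered(m, rrna) for m in fam.members)
        t_cov = sum(covered(m, tpase) for m in fam.members)
        total = sum(m.length for m in fam.members)
        if total and r_cov / total >= 0.5:
            fam.repeat_class = "rRNA_operon"
        elif total and t_cov / total >= 0.5:
            fam.repeat_class = "transposase"
        else:
            fam.repeat_class = "other"
    return families


def members_near(
    families: list[RepeatFamily], position: int, window: int
) -> list[tuple[RepeatFamily, RepeatMember, int]]:
    """All family members whose boundary lies within ``window`` of ``position``."""
    out = []
    for fam in families:
        for m in fam.members:
            if m.start - window <= position <= m.end + window:
                dist = 0 if m.start <= position <= m.end else min(
                    abs(position - m.start), abs(position - m.end)
                )
                out.append((fam, m, dist))
    out.sort(key=lambda t: t[2])
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def repeats_to_bed(families: list[RepeatFamily], genome_id: str) -> str:
    lines = []
    for fam in families:
        score = int(round(fam.pairwise_identity * 1000))
        for m in fam.members:
            strand = m.strand if m.strand in "+-" else "+"
            lines.append(
                f"{genome_id}\t{m.start}\t{m.end}\t{fam.family_id}\t{score}\t{strand}"
            )
    return "\n".join(lines) + ("\n" if lines else "")


def repeats_to_tsv(families: list[RepeatFamily]) -> str:
    lines = ["family_id\trepeat_class\tunit_length_bp\tidentity\tstart\tend\tstrand"]
    for fam in families:
        for m in fam.members:
            lines.append(
                f"{fam.family_id}\t{fam.repeat_class}\t{fam.unit_length_bp}\t"
                f"{fam.pairwise_identity}\t{m.start}\t{m.end}\t{m.strand}"
            )
    return "\n".join(lines) + "\n"
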