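"""Internal alignment helpers: k-mer prefilters, edit-distance identity,
and scored global alignment statistics.

Protein identity for ortholog anchoring uses edit distance (edlib), which for
congeneric strains (a few percent divergence, rare indels) is an excellent
proxy for alignment identity and keeps panel-scale scans fast.  The slower
scored global alignment (match +1 / mismatch -1 / gap -2) backs the
reconciliation rules, where per-homolog coverage matters.
"""

from __future__ import annotations

import collections

import edlib
from Bio import Align

__all__ = [
    "kmer_set",
    "KmerPrefilter",
    "global_identity",
    "GlobalAlignmentStats",
    "align_stats",
]


def kmer_set(s: str, k: int = 5) -> frozenset:
    return frozenset(s[i : i + k] for i in range(len(s) - k + 1))


class KmerPrefilter:
    """Inverted 5-mer index over a protein collection; returns candidates
    ranked by shared k-mer count."""

    def __init__(self, proteins: dict[str, str], k: int = 5):
        self.k = k
        self.sets = {name: kmer_set(p, k) for name, p in proteins.items()}
        self.index: dict[str, list[str]] = collections.defaultdict(list)
        for name, kset in self.sets.items():
            for kmer in kset:
                self.index[kmer].append(name)

    def candidates(self, protein: str, top: int = 5, min_jaccard: float = 0.0):
        qset = kmer_set(protein, self.k)
        counts: collections.Counter = collections.Counter()
        for kmer in qset:
            for name in self.index.get(kmer, ()):
                counts[name] += 1
        out = []
        for name, shared in counts.most_common(top * 3):
            union = len(qset | self.sets[name])
            j = shared / union if union else 0.0
            if j >= min_jaccard:
                out.append((name, j))
        out.sort(key=lambda t: -t[1])
        return out[:top]


def global_identity(a: str, b: str) -> float:
    """Identity under global edit distance: 1 - dist / max(len)."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


class GlobalAlignmentStats:
    __slots__ = ("identity", "coverage_of_b", "matches", "columns")

    def __init__(self, identity, coverage_of_b, matches, columns):
        self.identity = identity
        self.coverage_of_b = coverage_of_b
        self.matches = matches
        self.columns = columns


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2


def align_stats(query: str, subject: str) -> GlobalAlignmentStats:
    """Global alignment statistics of ``query`` against homolog ``subject``.

    ``identity`` is matches / aligned columns; ``coverage_of_b`` is the
    fraction of the subject's residues aligned to query residues.
    """
    if not query or not subject:
        return GlobalAlignmentStats(0.0, 0.0, 0, 0)
    aln = _aligner.align(query, subject)[0]
    matches = 0
    covered_b = 0
    for (qs, qe), (ss, se) in zip(*aln.aligned):
        covered_b += se - ss
        qseg = query[qs:qe]
        sseg = subject[ss:se]
        matches += sum(1 for x, y in zip(qseg, sseg) if x == y)
    columns = aln.length  # alignment columns, gaps included
    return GlobalAlignmentStats(
        identity=matches / columns if columns else 0.0,
        coverage_of_b=covered_b / len(subject),
        matches=matches,
        columns=columns,
    )
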