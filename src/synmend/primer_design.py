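"""Validation-primer design for corrected repeat-flanked junctions.

A corrected junction can only be validated by a PCR product that reads across
the entire repeat unit: primers must sit in unique sequence immediately
adjacent to the repeat copies, and the amplicon spans repeat plus junction.
Selection criteria follow the validation scheme of the SAFR-032 genome update:
melting temperature within 54–56 °C, amplicon at most 10,000 bp, no predicted
binding outside the intended sites, no significant self-structure, and exactly
two accepted pairs per junction.

Melting temperatures come from nearest-neighbor thermodynamics with the
unified duplex parameter set (Allawi & SantaLucia), 50 mM monovalent salt and
1 µM primer concentration (the amplification conditions of the validation
PCR); the parameter set is declared in the output metadata so the Tm window is
auditable.
"""

from __future__ import annotations

import collections
import json
import math
from dataclasses import dataclass, field

import numpy as np

from .genome_model import AnnotatedGenome, GenomeModelError, reverse_complement
from .rearrangement import CorrectionPlan
from .repeat_finder import _CODE, RepeatFamily, _kmer_ints, find_long_repeats

__all__ = [
    "PrimerCandidate",
    "AmpliconDesign",
    "PrimerConstraints",
    "PrimerDesignError",
    "InfeasiblePrimerError",
    "melting_temperature",
    "TM_PARAMETERS",
    "KmerUniqueness",
    "enumerate_candidates",
    "design_junction_amplicons",
    "design_validation_primers",
    "junctions_from_plan",
    "self_dimer_run",
    "hairpin_stem",
]


class PrimerDesignError(GenomeModelError):
    pass


class InfeasiblePrimerError(PrimerDesignError):
    """Fewer than the required number of feasible primer pairs exist."""


# ---------------------------------------------------------------------------
# nearest-neighbor melting temperature
# ---------------------------------------------------------------------------

# Unified nearest-neighbor duplex parameters (Allawi & SantaLucia):
# ΔH in kcal/mol, ΔS in cal/(mol·K), 5'→3' top-strand dinucleotides.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_SYM = (0.0, -1.4)
_R = 1.9872  # gas constant, cal/(mol·K)

#: declared Tm model parameters (emitted with every design table)
TM_PARAMETERS = {
    "nn_table": "unified (Allawi & SantaLucia)",
    "monovalent_mM": 50.0,
    "primer_nM": 1000.0,
    "salt_correction": "SantaLucia 1998 entropic, 0.368*(N-1)*ln[Na+]",
}


def melting_temperature(
    sequence: str, primer_nM: float = 1000.0, monovalent_mM: float = 50.0
) -> float:
    """Nearest-neighbor duplex Tm in °C for a primer against its template.

    Tm = ΔH / (ΔS + ΔS_salt + R·ln C) − 273.15 with the primer in excess over
    template (the PCR situation), C the primer concentration, and the entropic
    salt correction 0.368·(N−1)·ln[Na⁺].  Self-complementary primers take the
    symmetry term.
    """
    seq = sequence.upper()
    if len(seq) < 8:
        raise PrimerDesignError("primer shorter than 8 nt")
    if set(seq) - set("ACGT"):
        raise PrimerDesignError(f"bad primer alphabet in {sequence!r}")
    dh, ds = 0.0, 0.0
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s
    for terminal in (seq[0], seq[-1]):
        h, s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += h
        ds += s
    if seq == reverse_complement(seq):
        dh += _SYM[0]
        ds += _SYM[1]
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mM / 1000.0)
    conc = primer_nM * 1e-9
    return (dh * 1000.0) / (ds + _R * math.log(conc)) - 273.15


# ---------------------------------------------------------------------------
# structure heuristics
# ---------------------------------------------------------------------------

def self_dimer_run(seq: str) -> int:
    """Longest self-complementary run (dimerization seed): the longest
    substring of the primer whose reverse complement is also a substring.

    Equivalent to the longest common substring of the primer and its reverse
    complement, computed by dynamic programming.
    """
    rc = reverse_complement(seq)
    n = len(seq)
    best = 0
    prev = [0] * (n + 1)
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        ci = seq[i - 1]
        for j in range(1, n + 1):
            if ci == rc[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest intramolecular stem with a loop of at least ``min_loop`` nt.

    A stem of length t pairs positions (i..i+t-1) with (j-t+1..j) as Watson
    Crick complements; the enclosed loop j - i - 2t + 1 must be >= min_loop.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    n = len(seq)
    best = 0
    # run[i][j]: consecutive complementary pairs starting at (i, j) inward
    run = [[0] * n for _ in range(n)]
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            if comp[seq[i]] == seq[j]:
                inner = run[i + 1][j - 1] if i + 1 < j - 1 else 0
                run[i][j] = 1 + inner
                t_geo = (j - i + 1 - min_loop) // 2
                t = min(run[i][j], max(t_geo, 0))
                if t > best:
                    best = t
    return best


# ---------------------------------------------------------------------------
# genome-wide 3' uniqueness
# ---------------------------------------------------------------------------

class KmerUniqueness:
    """Occurrence counts of 15-mers over both strands of a genome."""

    K = 15

    def __init__(self, sequence: str):
        fwd, rev = _kmer_ints(sequence, self.K)
        vals = np.concatenate([fwd, rev])
        self._values, self._counts = np.unique(vals, return_counts=True)

    def _encode(self, kmer: str) -> int:
        code = 0
        for b in kmer:
            code = (code << 2) | int(_CODE[ord(b)])
        return code

    def occurrences(self, kmer: str) -> int:
        if len(kmer) != self.K or set(kmer) - set("ACGT"):
            raise PrimerDesignError(f"need a {self.K}-mer over ACGT")
        code = self._encode(kmer)
        i = int(np.searchsorted(self._values, code))
        if i < len(self._values) and int(self._values[i]) == code:
            return int(self._counts[i])
        return 0

    def is_unique(self, kmer: str) -> bool:
        return self.occurrences(kmer) == 1


# ---------------------------------------------------------------------------
# candidates and designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str
    position: int  # 0-based start of the binding site on the genome
    strand: str  # '+' forward primer, '-' reverse primer
    tm_celsius: float
    unique_3prime: bool
    self_dimer_run: int
    hairpin_stem: int

    @property
    def binding_interval(self) -> tuple[int, int]:
        return (self.position, self.position + len(self.sequence))


@dataclass(frozen=True)
class PrimerConstraints:
    tm_min: float = 54.0
    tm_max: float = 56.0
    max_amplicon_bp: int = 10_000
    max_self_dimer_run: int = 7  # accepted iff run < 8
    max_hairpin_stem: int = 5  # accepted iff stem < 6
    require_unique_3prime: bool = True
    length_min: int = 18
    length_max: int = 30
    pairs_per_junction: int = 2
    #: pairing considers only this many candidates per side, nearest the
    #: spanned region first (keeps amplicons short and pairing tractable)
    max_candidates_per_side: int = 250


@dataclass
class Junction:
    junction_id: str
    position: int
    repeat_interval: tuple[int, int]  # the adjacent repeat unit the amplicon must span
    provenance: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(self.position, self.repeat_interval[0]),
            max(self.position, self.repeat_interval[1]),
        )


@dataclass
class AmpliconDesign:
    junction_id: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_interval: tuple[int, int]
    amplicon_length_bp: int
    tm_parameters: dict = field(default_factory=lambda: dict(TM_PARAMETERS))

    def as_dict(self) -> dict:
        return {
            "junction_id": self.junction_id,
            "forward_seq": self.forward.sequence,
            "forward_pos": self.forward.position + 1,
            "forward_tm": round(self.forward.tm_celsius, 2),
            "reverse_seq": self.reverse.sequence,
            "reverse_pos": self.reverse.position + 1,
            "reverse_tm": round(self.reverse.tm_celsius, 2),
            "amplicon_start": self.amplicon_interval[0] + 1,
            "amplicon_end": self.amplicon_interval[1],
            "amplicon_length_bp": self.amplicon_length_bp,
        }


def _in_any(interval: tuple[int, int], families: list[RepeatFamily]) -> bool:
    a, b = interval
    for fam in families:
        for m in fam.members:
            if a < m.end and m.start < b:
                return True
    return False


def enumerate_candidates(
    genome: AnnotatedGenome,
    junction: Junction,
    side: str,
    uniqueness: KmerUniqueness,
    families: list[RepeatFamily],
    search_window_bp: int = 2_000,
    constraints: PrimerConstraints | None = None,
) -> list[PrimerCandidate]:
    """Primer candidates on one side of a junction's spanned region.

    ``side`` 'left' yields forward (+) primers upstream of the span; 'right'
    yields reverse (−) primers downstream.  Candidates must lie wholly outside
    every repeat-family member and carry a genome-unique 3'-terminal 15-mer.
    """
    c = constraints or PrimerConstraints()
    seq = genome.sequence
    span = junction.span
    out = []
    if side == "left":
        lo, hi = max(span[0] - search_window_bp, 0), span[0]
    elif side == "right":
        lo, hi = span[1], min(span[1] + search_window_bp, len(seq))
    else:
        raise PrimerDesignError("side must be 'left' or 'right'")
    if hi - lo < c.length_min:
        raise InfeasiblePrimerError(
            f"{junction.junction_id}: no candidate space on the {side} side "
            "(repeats abut the junction)"
        )
    window = seq[lo:hi]
    # thermodynamic prefix sums over the window: the Tm of any sub-site falls
    # out of stacked dinucleotide sums plus terminal initiation terms
    w = len(window)
    ph = [0.0] * w
    ps = [0.0] * w
    for i in range(w - 1):
        h, s = _NN[window[i : i + 2]]
        ph[i + 1] = ph[i] + h
        ps[i + 1] = ps[i] + s
    salt = math.log(50.0 / 1000.0)
    ln_c = _R * math.log(1000.0 * 1e-9)
    for start in range(w - c.length_min + 1):
        for length in range(c.length_min, c.length_max + 1):
            end = start + length
            if end > w:
                break
            g_start, g_end = lo + start, lo + end
            if _in_any((g_start, g_end), families):
                continue
            dh = ph[end - 1] - ph[start]
            ds = ps[end - 1] - ps[start]
            for terminal in (window[start], window[end - 1]):
                ih, isv = _INIT_GC if terminal in "GC" else _INIT_AT
                dh += ih
                ds += isv
            ds += 0.368 * (length - 1) * salt
            tm = (dh * 1000.0) / (ds + ln_c) - 273.15
            if not (c.tm_min <= tm <= c.tm_max):
                continue
            site = window[start:end]
            primer = site if side == "left" else reverse_complement(site)
            tm = melting_temperature(primer)  # exact, incl. symmetry term
            if not (c.tm_min <= tm <= c.tm_max):
                continue
            three_prime = primer[-KmerUniqueness.K :]
            out.append(
                PrimerCandidate(
                    sequence=primer,
                    position=g_start,
                    strand="+" if side == "left" else "-",
                    tm_celsius=tm,
                    unique_3prime=uniqueness.is_unique(three_prime),
                    self_dimer_run=self_dimer_run(primer),
                    hairpin_stem=hairpin_stem(primer),
                )
            )
    return out


def design_junction_amplicons(
    genome: AnnotatedGenome,
    junction: Junction,
    families: list[RepeatFamily],
    uniqueness: KmerUniqueness | None = None,
    constraints: PrimerConstraints | None = None,
    search_window_bp: int = 2_000,
) -> list[AmpliconDesign]:
    """Exactly ``pairs_per_junction`` accepted primer pairs for one junction.

    Pairs are ranked by Tm mismatch, then amplicon length; the second pair
    must not reuse either primer of the first.  Raises
    :class:`InfeasiblePrimerError` (naming the dominant failing constraint)
    when too few pairs survive.
    """
    c = constraints or PrimerConstraints()
    if uniqueness is None:
        uniqueness = KmerUniqueness(genome.sequence)
    fails: collections.Counter = collections.Counter()

    def acceptable(p: PrimerCandidate) -> bool:
        ok = True
        if c.require_unique_3prime and not p.unique_3prime:
            fails["off_target_binding"] += 1
            ok = False
        if p.self_dimer_run > c.max_self_dimer_run:
            fails["self_dimer"] += 1
            ok = False
        if p.hairpin_stem > c.max_hairpin_stem:
            fails["hairpin"] += 1
            ok = False
        return ok

    fwd = [
        p
        for p in enumerate_candidates(
            genome, junction, "left", uniqueness, families, search_window_bp, c
        )
        if acceptable(p)
    ]
    rev = [
        p
        for p in enumerate_candidates(
            genome, junction, "right", uniqueness, families, search_window_bp, c
        )
        if acceptable(p)
    ]
    # nearest the spanned region first: forward primers end near span[0],
    # reverse primers start near span[1]
    fwd.sort(key=lambda p: (junction.span[0] - (p.position + len(p.sequence)), p.position))
    rev.sort(key=lambda p: (p.position - junction.span[1], p.position))
    fwd = fwd[: c.max_candidates_per_side]
    rev = rev[: c.max_candidates_per_side]
    scored = []
    for f in fwd:
        for r in rev:
            length = (r.position + len(r.sequence)) - f.position
            if length > c.max_amplicon_bp:
                fails["amplicon_too_long"] += 1
                continue
            scored.append((abs(f.tm_celsius - r.tm_celsius), length, f, r))
    scored.sort(key=lambda t: (t[0], t[1], t[2].position, t[3].position))

    chosen: list[AmpliconDesign] = []
    used: set[tuple[int, str]] = set()
    for dtm, length, f, r in scored:
        fk, rk = (f.position, f.sequence), (r.position, r.sequence)
        if fk in used or rk in used:
            continue
        chosen.append(
            AmpliconDesign(
                junction_id=junction.junction_id,
                forward=f,
                reverse=r,
                amplicon_interval=(f.position, r.position + len(r.sequence)),
                amplicon_length_bp=length,
            )
        )
        used.add(fk)
        used.add(rk)
        if len(chosen) == c.pairs_per_junction:
            return chosen
    dominant = fails.most_common(1)[0][0] if fails else "tm_window"
    raise InfeasiblePrimerError(
        f"{junction.junction_id}: only {len(chosen)} feasible pair(s); "
        f"dominant failing constraint: {dominant}"
    )


# ---------------------------------------------------------------------------
# junctions of a correction plan
# ---------------------------------------------------------------------------

def junctions_from_plan(
    plan: CorrectionPlan,
    corrected: AnnotatedGenome,
    families: list[RepeatFamily] | None = None,
    flank_window_bp: int = 5_000,
) -> list[Junction]:
    """Junction points of the corrected genome, each paired with the repeat
    unit its amplicon must read across.

    A ``move`` creates three seams (both ends of the restored fragment and
    the healed excision site); an ``invert`` creates two.
    """
    if families is None:
        families = find_long_repeats(corrected)
    out = []
    seam_positions: list[tuple[str, int]] = []
    for op in plan.ops:
        # seams in the coordinates right after this op; ops of a valid plan
        # act on disjoint regions, so these survive the rest of the plan
        if op.kind == "move":
            s, e, d = op.start, op.end, op.dest
            if d < s:
                seams = [d, d + (e - s), e]
            else:
                seams = [s, s + (d - e), d]
            name = "move"
        else:
            seams = [op.start, op.end]
            name = "inv"
        for k, pos in enumerate(seams):
            seam_positions.append((f"{name}_{op.provenance or 'op'}_{k}", pos))
    for jid, pos in seam_positions:
        near = []
        for fam in families:
            for mem in fam.members:
                dist = 0 if mem.start <= pos <= mem.end else min(
                    abs(pos - mem.start), abs(pos - mem.end)
                )
                near.append((dist, fam.family_id, (mem.start, mem.end)))
        if not near:
            continue
        near.sort()
        dist, fam_id, interval = near[0]
        if dist > flank_window_bp:
            continue
        out.append(Junction(junction_id=jid, position=pos, repeat_interval=interval))
    return out


def design_validation_primers(
    corrected: AnnotatedGenome,
    plan: CorrectionPlan,
    constraints: PrimerConstraints | None = None,
    search_window_bp: int = 2_000,
) -> list[AmpliconDesign]:
    """Design all validation amplicons for a corrected genome."""
    families = find_long_repeats(corrected)
    junctions = junctions_from_plan(plan, corrected, families)
    uniqueness = KmerUniqueness(corrected.sequence)
    designs = []
    for j in junctions:
        designs.extend(
            design_junction_amplicons(
                corrected, j, families, uniqueness, constraints, search_window_bp
            )
        )
    return designs


def designs_to_tsv(designs: list[AmpliconDesign]) -> str:
    cols = [
        "junction_id", "forward_seq", "forward_pos", "forward_tm",
        "reverse_seq", "reverse_pos", "reverse_tm", "amplicon_length_bp",
    ]
    lines = ["\t".join(cols)]
    for d in designs:
        row = d.as_dict()
        lines.append("\t".join(str(row[c]) for c in cols))
    lines.append("# tm_model: " + json.dumps(TM_PARAMETERS))
    return "\n".join(lines) + "\n"


def designs_to_fasta(designs: list[AmpliconDesign]) -> str:
    lines = []
    for i, d in enumerate(designs):
        lines.append(f">{d.junction_id}_pair{i}_fwd\n{d.forward.sequence}")
        lines.append(f">{d.junction_id}_pair{i}_rev\n{d.reverse.sequence}")
    return "\n".join(lines) + ("\n" if lines else "")
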