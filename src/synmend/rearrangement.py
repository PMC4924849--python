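"""Executable genome rearrangement operations and correction plans.

A correction plan is an ordered list of ``move`` / ``invert`` operations on a
genome.  Every operation is a length-preserving permutation of positions:

* ``move``  — excise ``[start, end)`` and re-insert it so its first base lands
  at ``dest`` (given in the coordinates of the genome *before* the op).
* ``invert`` — reverse-complement ``[start, end)`` in place.

Features are remapped through the same permutation; a feature that straddles a
cut site aborts the operation (the corrections this package proposes cut in
intergenic repeat boundaries, so a straddling feature signals a bad plan).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .genome_model import (
    AnnotatedGenome,
    Census,
    GenomeModelError,
    census,
    extract_feature_sequence,
    reverse_complement,
)

__all__ = [
    "RearrangementOp",
    "CorrectionPlan",
    "RearrangementError",
    "StraddlingFeatureError",
    "ConflictingViolationsError",
    "apply_op",
    "apply_plan",
    "invert_op",
    "plan_corrections",
    "verify_correction",
    "VerificationReport",
]


class RearrangementError(GenomeModelError):
    pass


class StraddlingFeatureError(RearrangementError):
    """A feature crosses a cut site of an operation."""


class ConflictingViolationsError(RearrangementError):
    """Requested operations overlap and cannot be applied sequentially."""


@dataclass(frozen=True)
class RearrangementOp:
    kind: str  # "move" | "invert"
    start: int
    end: int
    dest: int | None = None  # move only; landing coordinate of the fragment start
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("move", "invert"):
            raise RearrangementError(f"unknown op kind {self.kind!r}")
        if self.end <= self.start:
            raise RearrangementError(f"empty interval [{self.start}, {self.end})")
        if self.kind == "move":
            if self.dest is None:
                raise RearrangementError("move requires a destination")
            if self.start <= self.dest < self.end or self.dest == self.start:
                raise RearrangementError("move destination inside source interval")
        elif self.dest is not None:
            raise RearrangementError("invert takes no destination")

    @property
    def length(self) -> int:
        return self.end - self.start

    def affected_interval(self) -> tuple[int, int]:
        if self.kind == "invert":
            return (self.start, self.end)
        if self.dest < self.start:
            return (self.dest, self.end)
        return (self.start, self.dest)

    def map_position(self, p: int) -> int:
        """Image of position ``p`` under this op."""
        s, e, d = self.start, self.end, self.dest
        if self.kind == "invert":
            if s <= p < e:
                return s + (e - 1 - p)
            return p
        if d < s:  # fragment moves upstream
            if s <= p < e:
                return p - (s - d)
            if d <= p < s:
                return p + (e - s)
            return p
        # fragment moves downstream; it lands so that its first base sits at
        # d - (e - s) ... == dest semantics: seq[:s] + seq[e:d] + seq[s:e] + seq[d:]
        if s <= p < e:
            return p + (d - e)
        if e <= p < d:
            return p - (e - s)
        return p

    def map_interval(self, a: int, b: int) -> tuple[int, int]:
        """Image of half-open ``[a, b)``; raises if it straddles a cut site."""
        cuts = sorted({self.start, self.end} | ({self.dest} if self.dest is not None else set()))
        for c in cuts:
            if a < c < b:
                raise StraddlingFeatureError(f"interval [{a}, {b}) straddles cut at {c}")
        if self.kind == "invert" and self.start <= a < self.end:
            return (self.start + (self.end - b), self.start + (self.end - a))
        na = self.map_position(a) if a < b else a
        return (na, na + (b - a))

    def as_dict(self) -> dict:
        d = {"kind": self.kind, "start": self.start, "end": self.end, "provenance": self.provenance}
        if self.dest is not None:
            d["dest"] = self.dest
        return d


def invert_op(op: RearrangementOp) -> RearrangementOp:
    """The operation undoing ``op`` (in the coordinates after ``op``)."""
    if op.kind == "invert":
        return op
    s, e, d = op.start, op.end, op.dest
    length = e - s
    if d < s:
        # fragment now occupies [d, d+length); send it back after the block
        # that originally preceded it, i.e. to land at s again
        return RearrangementOp("move", d, d + length, dest=e, provenance=op.provenance)
    new_start = s + (d - e)
    return RearrangementOp("move", new_start, new_start + length, dest=s, provenance=op.provenance)


@dataclass
class CorrectionPlan:
    ops: list[RearrangementOp] = field(default_factory=list)
    expected_length_bp: int | None = None

    def __post_init__(self) -> None:
        ivs = sorted(op.affected_interval() for op in self.ops)
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ConflictingViolationsError(
                    f"operations overlap: [{a0},{b0}) and [{a1},{b1})"
                )

    def to_json(self) -> str:
        return json.dumps(
            {
                "expected_length_bp": self.expected_length_bp,
                "ops": [op.as_dict() for op in self.ops],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrectionPlan":
        d = json.loads(text)
        ops = [
            RearrangementOp(
                kind=o["kind"],
                start=o["start"],
                end=o["end"],
                dest=o.get("dest"),
                provenance=o.get("provenance", ""),
            )
            for o in d["ops"]
        ]
        return cls(ops=ops, expected_length_bp=d.get("expected_length_bp"))


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def _splice(seq: str, op: RearrangementOp) -> str:
    s, e, d = op.start, op.end, op.dest
    if op.kind == "invert":
        return seq[:s] + reverse_complement(seq[s:e]) + seq[e:]
    if d < s:
        return seq[:d] + seq[s:e] + seq[d:s] + seq[e:]
    return seq[:s] + seq[e:d] + seq[s:e] + seq[d:]


def apply_op(genome: AnnotatedGenome, op: RearrangementOp) -> AnnotatedGenome:
    n = len(genome.sequence)
    hi = max(op.end, op.dest if op.dest is not None else 0)
    if hi > n or op.start < 0:
        raise RearrangementError(f"op outside genome bounds: {op}")
    seq = _splice(genome.sequence, op)
    flip = {"+": "-", "-": "+", ".": "."}
    feats = []
    for f in genome.features:
        if f.end > n:
            raise StraddlingFeatureError(
                f"{f.locus_tag}: origin-wrapping features cannot cross rearrangement ops"
            )
        try:
            a, b = op.map_interval(f.start, f.end)
        except StraddlingFeatureError as exc:
            raise StraddlingFeatureError(f"{f.locus_tag}: {exc}") from exc
        strand = f.strand
        if op.kind == "invert" and op.start <= f.start < op.end:
            strand = flip[strand]
        feats.append(replace(f, start=a, end=b, strand=strand))
    return AnnotatedGenome(genome.genome_id, seq, circular=genome.circular, features=feats)


def _shift_through(op_applied: RearrangementOp, op: RearrangementOp) -> RearrangementOp:
    """Re-express ``op`` in the coordinates produced by ``op_applied``."""
    a, b = op_applied.map_interval(op.start, op.end)
    dest = None
    if op.dest is not None:
        dest = op_applied.map_position(op.dest)
    return RearrangementOp(op.kind, a, b, dest=dest, provenance=op.provenance)


def apply_plan(genome: AnnotatedGenome, plan: CorrectionPlan) -> AnnotatedGenome:
    """Apply ops in order, re-resolving coordinates of later ops after each."""
    g = genome
    pending = list(plan.ops)
    while pending:
        op = pending.pop(0)
        g = apply_op(g, op)
        pending = [_shift_through(op, rest) for rest in pending]
    if plan.expected_length_bp is not None and len(g.sequence) != plan.expected_length_bp:
        raise RearrangementError(
            f"length changed: {len(g.sequence)} != {plan.expected_length_bp}"
        )
    return g


# ---------------------------------------------------------------------------
# planning from detected violations
# ---------------------------------------------------------------------------

def plan_corrections(violations, include_low_confidence: bool = False) -> CorrectionPlan:
    """Turn detected violations into an executable plan.

    Translocations become ``move`` ops restoring the consensus placement;
    inversions become ``invert`` ops.  Low-confidence violations (those not
    flanked by repeats) are excluded unless forced.
    """
    ops = []
    total_len = None
    for v in violations:
        if getattr(v, "low_confidence", False) and not include_low_confidence:
            continue
        if v.kind == "translocation":
            ops.append(
                RearrangementOp(
                    "move",
                    v.query_interval[0],
                    v.query_interval[1],
                    dest=v.expected_start,
                    provenance=v.violation_id,
                )
            )
        elif v.kind == "inversion":
            ops.append(
                RearrangementOp(
                    "invert",
                    v.query_interval[0],
                    v.query_interval[1],
                    provenance=v.violation_id,
                )
            )
        else:
            raise RearrangementError(f"unknown violation kind {v.kind!r}")
    ops.sort(key=lambda op: op.affected_interval())
    return CorrectionPlan(ops=ops, expected_length_bp=total_len)


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

@dataclass
class VerificationReport:
    length_equal: bool
    census_equal: bool
    locus_sets_equal: bool
    changed_loci: list[str]
    missing_loci: list[str]
    extra_loci: list[str]
    census_before: Census = None
    census_after: Census = None

    @property
    def passed(self) -> bool:
        return (
            self.length_equal
            and self.census_equal
            and self.locus_sets_equal
            and not self.changed_loci
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "length_equal": self.length_equal,
                "census_equal": self.census_equal,
                "locus_sets_equal": self.locus_sets_equal,
                "changed_loci": self.changed_loci,
                "missing_loci": self.missing_loci,
                "extra_loci": self.extra_loci,
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [f"verification: {'PASS' if self.passed else 'FAIL'}"]
        lines.append(f"  length equal: {self.length_equal}")
        lines.append(f"  census equal: {self.census_equal}")
        lines.append(f"  locus sets equal: {self.locus_sets_equal}")
        if self.changed_loci:
            lines.append(f"  changed loci ({len(self.changed_loci)}): "
                         + ", ".join(self.changed_loci[:20]))
        return "\n".join(lines) + "\n"


def verify_correction(before: AnnotatedGenome, after: AnnotatedGenome) -> VerificationReport:
    """Content-preservation check: a rearrangement changes layout, never genes."""
    cb, ca = census(before), census(after)
    loci_b = {f.locus_tag for f in before.features}
    loci_a = {f.locus_tag for f in after.features}
    changed = []
    for tag in sorted(loci_b & loci_a):
        if extract_feature_sequence(before, tag) != extract_feature_sequence(after, tag):
            changed.append(tag)
    return VerificationReport(
        length_equal=len(before.sequence) == len(after.sequence),
        census_equal=cb.as_dict() == ca.as_dict(),
        locus_sets_equal=loci_b == loci_a,
        changed_loci=changed,
        missing_loci=sorted(loci_b - loci_a),
        extra_loci=sorted(loci_a - loci_b),
        census_before=cb,
        census_after=ca,
    )
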