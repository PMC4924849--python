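"""Core data types and I/O for annotated circular bacterial genomes.

The unit of data throughout the package is the :class:`AnnotatedGenome`: a
single circular (or linear) nucleotide sequence plus an ordered, strand-aware
feature table.  Coordinates are 0-based half-open internally and converted to
the GFF3 1-based inclusive convention only on disk.

A second concern of this module is coordinate normalization: related bacterial
chromosomes are compared in a common frame whose origin is the first base of
the replication-initiator gene *dnaA* on the plus strand.  Genomes deposited in
reverse-complement orientation are flipped before rotation.
"""

from __future__ import annotations

import collections
import json
import re
import urllib.parse
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq

import gffutils

__all__ = [
    "Feature",
    "AnnotatedGenome",
    "Census",
    "GenomeModelError",
    "MultiRecordFastaError",
    "AmbiguousBaseError",
    "FeatureOutOfBoundsError",
    "DuplicateLocusTagError",
    "UnknownLocusTagError",
    "DnaAAnchorError",
    "load_annotated_genome",
    "save_annotated_genome",
    "normalize_to_dnaA",
    "rotate_genome",
    "reverse_complement_genome",
    "extract_feature_sequence",
    "census",
    "reverse_complement",
]

FEATURE_TYPES = frozenset(
    {"CDS", "tRNA", "rRNA", "tmRNA", "ncRNA", "riboswitch", "repeat_region", "pseudogene"}
)

#: default maximum gap (bp) between consecutive rRNA genes of one operon
OPERON_GAP_BP = 1000

_DNAA_PRODUCT_RE = re.compile(r"chromosomal replication initiat|\bdnaA\b", re.IGNORECASE)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class GenomeModelError(Exception):
    """Base class for genome-model errors."""


class MultiRecordFastaError(GenomeModelError):
    """FASTA file did not contain exactly one record."""


class AmbiguousBaseError(GenomeModelError):
    """Sequence contains bases outside the A/C/G/T alphabet."""


class FeatureOutOfBoundsError(GenomeModelError):
    """A feature interval does not fit the sequence."""


class DuplicateLocusTagError(GenomeModelError):
    """Two features share a locus tag."""


class UnknownLocusTagError(GenomeModelError, KeyError):
    """Requested locus tag is not present in the genome."""


class DnaAAnchorError(GenomeModelError):
    """Zero or multiple dnaA features; the genome cannot be anchored."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Feature:
    """One annotated interval.

    ``start``/``end`` are 0-based half-open.  On a circular genome a feature
    spanning the origin is stored with ``end > genome length`` (the interval
    wraps).  ``strand`` is ``'+'`` or ``'-'`` (``'.'`` allowed for
    ``repeat_region``).
    """

    locus_tag: str
    ftype: str
    start: int
    end: int
    strand: str
    product: str = ""
    ortholog_group: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise GenomeModelError(f"unknown feature type {self.ftype!r}")
        if self.start < 0 or self.end <= self.start:
            raise FeatureOutOfBoundsError(
                f"{self.locus_tag}: bad interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-") and not (
            self.strand == "." and self.ftype == "repeat_region"
        ):
            raise GenomeModelError(f"{self.locus_tag}: bad strand {self.strand!r}")


@dataclass
class AnnotatedGenome:
    genome_id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if not self.sequence:
            raise GenomeModelError(f"{self.genome_id}: empty sequence")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise AmbiguousBaseError(
                f"{self.genome_id}: non-ACGT bases {sorted(bad)!r}"
            )
        n = len(self.sequence)
        seen: set[str] = set()
        for f in self.features:
            if f.locus_tag in seen:
                raise DuplicateLocusTagError(f.locus_tag)
            seen.add(f.locus_tag)
            limit = 2 * n if self.circular else n
            if f.start >= n or f.end > limit:
                raise FeatureOutOfBoundsError(
                    f"{f.locus_tag}: [{f.start}, {f.end}) outside genome of {n} bp"
                )
        self.features.sort(key=lambda f: (f.start, f.end, f.locus_tag))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def feature_index(self) -> dict[str, Feature]:
        return {f.locus_tag: f for f in self.features}

    def get(self, locus_tag: str) -> Feature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise UnknownLocusTagError(locus_tag)

    def copy(self) -> "AnnotatedGenome":
        return AnnotatedGenome(
            genome_id=self.genome_id,
            sequence=self.sequence,
            circular=self.circular,
            features=[replace(f) for f in self.features],
        )


@dataclass
class Census:
    counts: dict[str, int]
    rrna_operon_count: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_dict(self) -> dict:
        d = dict(sorted(self.counts.items()))
        d["rrna_operon_count"] = self.rrna_operon_count
        return d

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def to_tsv(self) -> str:
        lines = ["ftype\tcount"]
        lines += [f"{k}\t{v}" for k, v in sorted(self.counts.items())]
        lines.append(f"rrna_operon\t{self.rrna_operon_count}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_annotated_genome(fasta_path, gff3_path, circular: bool = True) -> AnnotatedGenome:
    """Read a single-record FASTA plus its GFF3 feature table.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise MultiRecordFastaError(
            f"{fasta_path}: expected exactly one record, found {len(records)}"
        )
    rec = records[0]
    sequence = str(rec.seq).upper()

    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    features = []
    for gf in db.all_features():
        if gf.featuretype == "region":
            continue
        if gf.seqid != rec.id:
            raise GenomeModelError(
                f"{gff3_path}: seqid {gf.seqid!r} does not match FASTA id {rec.id!r}"
            )
        locus = gf.attributes.get("locus_tag", gf.attributes.get("ID", [gf.id]))[0]
        product = urllib.parse.unquote(gf.attributes.get("product", [""])[0])
        group = gf.attributes.get("ortholog_group", [None])[0]
        features.append(
            Feature(
                locus_tag=locus,
                ftype=gf.featuretype,
                start=gf.start - 1,
                end=gf.end,
                strand=gf.strand if gf.strand in ("+", "-") else ".",
                product=product,
                ortholog_group=group,
            )
        )
    return AnnotatedGenome(rec.id, sequence, circular=circular, features=features)


def save_annotated_genome(genome: AnnotatedGenome, fasta_path, gff3_path) -> None:
    """Write FASTA (70-column wrap) and GFF3 with locus_tag/product attributes.

    Origin-spanning features of circular genomes are written with
    ``end > sequence length`` per the GFF3 circular-genome convention, with
    ``Is_circular=true`` on the region line.
    """
    with open(fasta_path, "w") as fh:
        fh.write(f">{genome.genome_id}\n")
        seq = genome.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")

    n = len(genome.sequence)
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.genome_id} 1 {n}\n")
        circ = ";Is_circular=true" if genome.circular else ""
        fh.write(
            f"{genome.genome_id}\tsynmend\tregion\t1\t{n}\t.\t+\t.\t"
            f"ID=region0{circ}\n"
        )
        for f in genome.features:
            attrs = f"ID={f.locus_tag};locus_tag={f.locus_tag}"
            if f.product:
                attrs += f";product={urllib.parse.quote(f.product, safe=' ')}"
            if f.ortholog_group:
                attrs += f";ortholog_group={f.ortholog_group}"
            fh.write(
                f"{genome.genome_id}\tsynmend\t{f.ftype}\t{f.start + 1}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------

def rotate_genome(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Rotate a circular genome so that current position ``offset`` becomes 0."""
    if not genome.circular:
        raise GenomeModelError("cannot rotate a linear genome")
    n = len(genome.sequence)
    offset %= n
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        start = (f.start - offset) % n
        feats.append(replace(f, start=start, end=start + f.length))
    return AnnotatedGenome(genome.genome_id, seq, circular=True, features=feats)


def reverse_complement_genome(genome: AnnotatedGenome) -> AnnotatedGenome:
    n = len(genome.sequence)
    seq = reverse_complement(genome.sequence)
    flip = {"+": "-", "-": "+", ".": "."}
    feats = []
    for f in genome.features:
        start = (n - f.end) % n
        feats.append(replace(f, start=start, end=start + f.length, strand=flip[f.strand]))
    return AnnotatedGenome(genome.genome_id, seq, circular=genome.circular, features=feats)


def find_dnaA(genome: AnnotatedGenome, locus_tag: str | None = None) -> Feature:
    """Locate the unique dnaA feature, by product text or explicit locus tag."""
    if locus_tag is not None:
        return genome.get(locus_tag)
    hits = [
        f
        for f in genome.features
        if f.ftype in ("CDS", "pseudogene") and _DNAA_PRODUCT_RE.search(f.product)
    ]
    if len(hits) != 1:
        raise DnaAAnchorError(
            f"{genome.genome_id}: found {len(hits)} dnaA candidates, need exactly 1"
        )
    return hits[0]


def normalize_to_dnaA(genome: AnnotatedGenome, locus_tag: str | None = None) -> AnnotatedGenome:
    """Rotate (and if needed reverse-complement) so dnaA starts at base 0, plus strand."""
    if not genome.circular:
        raise GenomeModelError("dnaA normalization requires a circular genome")
    dnaA = find_dnaA(genome, locus_tag)
    g = genome
    if dnaA.strand == "-":
        g = reverse_complement_genome(g)
        dnaA = find_dnaA(g, locus_tag if locus_tag else None)
    if dnaA.start == 0:
        return g
    return rotate_genome(g, dnaA.start)


def extract_feature_sequence(genome: AnnotatedGenome, locus_tag: str) -> str:
    """Strand-aware feature sequence; supports origin-wrapping intervals."""
    f = genome.get(locus_tag)
    n = len(genome.sequence)
    if f.end <= n:
        seq = genome.sequence[f.start : f.end]
    else:
        if not genome.circular:
            raise FeatureOutOfBoundsError(f.locus_tag)
        seq = genome.sequence[f.start :] + genome.sequence[: f.end - n]
    if f.strand == "-":
        seq = reverse_complement(seq)
    return seq


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def _group_operons(intervals: list[tuple[int, int]], gap: int, circular: bool, n: int) -> int:
    """Count maximal runs of rRNA genes with inter-gene gaps <= ``gap``."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    groups = 1
    for (s0, e0), (s1, e1) in zip(intervals, intervals[1:]):
        if s1 - e0 > gap:
            groups += 1
    if circular and groups > 1:
        # first and last runs may join across the origin
        first_start = intervals[0][0]
        last_end = intervals[-1][1]
        if (first_start + n) - last_end <= gap:
            groups -= 1
    return groups


def census(genome: AnnotatedGenome, operon_gap_bp: int = OPERON_GAP_BP) -> Census:
    counts = collections.Counter(f.ftype for f in genome.features)
    rrna = [(f.start, f.end) for f in genome.features if f.ftype == "rRNA"]
    operons = _group_operons(rrna, operon_gap_bp, genome.circular, len(genome.sequence))
    return Census(counts=dict(counts), rrna_operon_count=operons)


def translate_cds(genome: AnnotatedGenome, locus_tag: str) -> str:
    """Translate a CDS with the bacterial code (table 11), without the stop."""
    nt = extract_feature_sequence(genome, locus_tag)
    prot = str(Seq(nt).translate(table=11))
    return prot[:-1] if prot.endswith("*") else prot
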