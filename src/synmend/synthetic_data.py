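"""Seeded generators for the test substrate of the pipeline.

Real inputs for this kind of analysis are a finished query genome and a panel
of related finished genomes.  This module emulates that situation for a
*B. pumilus*-like chromosome:

* a panel of strains sharing one dnaA-anchored gene order, whose coding
  sequences diverge by random substitutions (1 %/site by default) so that
  ortholog anchoring is non-trivial;
* seven identical-copy rRNA operon repeats and a pair of identical transposase
  genes — the repeat classes that flank real misassemblies;
* a misassembled query derived from the ancestral genome by two planted
  repeat-flanked defects: a fragment of 19 protein genes, 1 tRNA and 1 rRNA
  operon relocated 522 kbp downstream over rRNA-operon copies, and an
  11,000 bp inversion of 13 protein genes and 1 tRNA between the transposase
  pair;
* three-way annotation fixtures and a pseudogene ledger with planted category
  counts, realized purely by coordinates / sequence content (never labels).

Divergence between strains is substitution-only (no indels), so all panel
genomes share the ancestral coordinate system; the methods note discusses what
this simplification does and does not exercise.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import (
    AnnotatedGenome,
    Feature,
    GenomeModelError,
    reverse_complement,
    reverse_complement_genome,
    rotate_genome,
)
from .rearrangement import RearrangementOp, apply_op

__all__ = [
    "PanelConfig",
    "FragmentSpec",
    "InversionSpec",
    "PlantedTruth",
    "Layout",
    "AncestralCatalog",
    "Scenario",
    "InfeasibleConfigError",
    "NotRepeatFlankedError",
    "generate_strain_panel",
    "plant_misassembly",
    "generate_scenario",
    "generate_annotation_fixture",
    "generate_pseudogene_ledger",
    "AnnotationFixture",
    "PseudogeneFixture",
    "PseudogeneLocus",
]


class InfeasibleConfigError(GenomeModelError):
    """Planted elements do not fit the requested genome."""


class NotRepeatFlankedError(GenomeModelError):
    """A requested rearrangement is not bounded by repeat copies."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentSpec:
    """Composition of the fragment to be translocated (defaults: the study's)."""

    n_cds: int = 19
    n_trna: int = 1
    with_operon: bool = True
    displacement_bp: int = 522_000


@dataclass(frozen=True)
class InversionSpec:
    """Composition of the segment to be inverted between the transposase pair."""

    n_cds: int = 13
    n_trna: int = 1
    length_bp: int = 11_000


@dataclass(frozen=True)
class PanelConfig:
    seed: int
    n_strains: int = 5
    genome_length_bp: int = 1_800_000
    n_genes: int = 1800
    n_rrna_operons: int = 7
    rrna_operon_length_bp: int = 5_000
    n_transposase_pairs: int = 1
    n_trna: int = 72
    cds_substitution_rate: float = 0.01
    operon_substitution_rate: float = 0.002
    randomize_origin: bool = True

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise InfeasibleConfigError("panel needs at least 2 strains")
        if self.n_transposase_pairs < 1:
            raise InfeasibleConfigError("need at least one transposase pair")


@dataclass
class Layout:
    """Ground-truth landmarks of the ancestral genome (coordinates 0-based)."""

    fragment_interval: tuple[int, int]  # [s, e): first to last fragment feature
    insertion_point: int  # d: end of the downstream operon copy, d - e = displacement
    inversion_interval: tuple[int, int]  # exactly between the transposase pair
    operon_sites: list[int] = field(default_factory=list)  # unit start coords
    transposase_sites: list[int] = field(default_factory=list)
    rotation_candidates: list[int] = field(default_factory=list)  # safe gap midpoints


@dataclass
class AncestralCatalog:
    """Ground-truth gene catalog shared by the panel."""

    true_genome: AnnotatedGenome
    layout: Layout
    groups: dict[str, str]  # ortholog group -> product
    frag_spec: FragmentSpec = None
    inv_spec: InversionSpec = None


@dataclass
class PlantedTruth:
    true_genome: AnnotatedGenome
    planted_ops: list[RearrangementOp]
    planted_displacement_bp: int
    planted_inversion_length_bp: int


@dataclass
class Scenario:
    config: PanelConfig
    panel: list[AnnotatedGenome]
    truth: PlantedTruth
    query: AnnotatedGenome
    catalog: AncestralCatalog


# ---------------------------------------------------------------------------
# low-level sequence sampling
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# B. pumilus-like base composition, GC ~ 41 %
_BASE_P = np.array([0.295, 0.205, 0.205, 0.295])
_STOPS = {"TAA", "TAG", "TGA"}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    arr = rng.choice(_BASES, size=n, p=_BASE_P)
    s = arr.tobytes().decode()
    return _break_runs(s, rng)


def _break_runs(s: str, rng: np.random.Generator, maxrun: int = 8) -> str:
    """Cap homopolymer runs so spurious low-complexity repeats never arise."""
    out = list(s)
    run = 1
    for i in range(1, len(out)):
        if out[i] == out[i - 1]:
            run += 1
            if run > maxrun:
                choices = [b for b in "ACGT" if b != out[i]]
                out[i] = choices[rng.integers(len(choices))]
                run = 1
        else:
            run = 1
    return "".join(out)


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop; length (n_codons+2)*3."""
    body = []
    while len(body) < n_codons:
        chunk = rng.choice(_BASES, size=3 * (n_codons - len(body)), p=_BASE_P)
        s = chunk.tobytes().decode()
        for i in range(0, len(s), 3):
            cod = s[i : i + 3]
            if cod not in _STOPS:
                body.append(cod)
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return "ATG" + "".join(body) + stop


def _mutate_cds(nt: str, rng: np.random.Generator, rate: float) -> str:
    """Substitute ~rate per site, preserving start/stop and avoiding new stops."""
    n = len(nt)
    k = rng.binomial(max(n - 6, 0), rate)
    if k == 0:
        return nt
    out = list(nt)
    positions = rng.choice(np.arange(3, n - 3), size=k, replace=False)
    for p in sorted(int(x) for x in positions):
        old = out[p]
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(3)]
        out[p] = new
        c0 = (p // 3) * 3
        if "".join(out[c0 : c0 + 3]) in _STOPS:
            out[p] = old  # would create an internal stop: revert
    return "".join(out)


_TRNA_CORE = None


def _trna_seq(rng: np.random.Generator) -> str:
    # one conserved 76-nt "tRNA" per run of the generator family
    return _random_seq(rng, 76)


# ---------------------------------------------------------------------------
# ancestral genome construction
# ---------------------------------------------------------------------------

class _Builder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.cursor = 0
        self.features: list[Feature] = []
        self.gap_mids: list[int] = []

    def add_seq(self, s: str) -> int:
        start = self.cursor
        self.parts.append(s)
        self.cursor += len(s)
        return start

    def add_gap(self, s: str, record: bool = False) -> None:
        if record and len(s) >= 20:
            self.gap_mids.append(self.cursor + len(s) // 2)
        self.add_seq(s)

    def pad_to(self, target: int, rng: np.random.Generator, what: str) -> None:
        if self.cursor > target:
            raise InfeasibleConfigError(
                f"layout overshoot before {what}: cursor {self.cursor} > {target}"
            )
        if self.cursor < target:
            self.add_seq(_random_seq(rng, target - self.cursor))

    def add_feature(self, locus, ftype, start, length, strand, product, group=None):
        self.features.append(
            Feature(locus, ftype, start, start + length, strand, product, group)
        )


def _make_operon_unit(rng: np.random.Generator, unit_len: int):
    """One rRNA operon repeat unit: 16S + 23S + 5S at fixed offsets."""
    if unit_len < 4900:
        raise InfeasibleConfigError("rRNA operon unit must be >= 4900 bp")
    seq16, seq23, seq5 = (
        _random_seq(rng, 1538),
        _random_seq(rng, 2900),
        _random_seq(rng, 116),
    )
    lead = _random_seq(rng, 60)
    sp1 = _random_seq(rng, 190)
    sp2 = _random_seq(rng, 90)
    tail_len = unit_len - (60 + 1538 + 190 + 2900 + 90 + 116)
    if tail_len < 0:
        raise InfeasibleConfigError("rRNA operon unit too short for its genes")
    tail = _random_seq(rng, tail_len)
    unit = lead + seq16 + sp1 + seq23 + sp2 + seq5 + tail
    gene_offsets = [
        (60, 1538, "16S ribosomal RNA"),
        (60 + 1538 + 190, 2900, "23S ribosomal RNA"),
        (60 + 1538 + 190 + 2900 + 90, 116, "5S ribosomal RNA"),
    ]
    return unit, gene_offsets


def _build_ancestor(
    config: PanelConfig, frag_spec: FragmentSpec, inv_spec: InversionSpec,
    rng: np.random.Generator,
):
    L = config.genome_length_bp
    unit_len = config.rrna_operon_length_bp
    disp = frag_spec.displacement_bp

    operon_unit, operon_genes = _make_operon_unit(rng, unit_len)
    tp_len_codons = 330
    transposase_unit = _random_cds(rng, tp_len_codons)  # 996 bp
    tp_len = len(transposase_unit)
    trna_unit = _trna_seq(rng)

    # -- gene length budget -------------------------------------------------
    n_extra_tp = 2 * (config.n_transposase_pairs - 1)
    n_bg = config.n_genes - 1 - frag_spec.n_cds - inv_spec.n_cds - 2 - n_extra_tp
    if n_bg < 10:
        raise InfeasibleConfigError("n_genes too small for the planted elements")
    n_op = config.n_rrna_operons
    if n_op < 3:
        raise InfeasibleConfigError("need at least 3 rRNA operons (two flanks + one in the fragment)")

    fixed_bp = (
        n_op * unit_len
        + inv_spec.length_bp
        + (2 + n_extra_tp) * tp_len
        + config.n_trna * 76
        + 1344  # dnaA
    )
    mean_gap = 175
    avail = L - fixed_bp - mean_gap * (n_bg + config.n_trna + n_op + 8)
    mean_cds = avail * 0.97 / max(n_bg + frag_spec.n_cds, 1)
    mean_codons = int(np.clip(mean_cds / 3, 80, 1200))
    bg_codons = rng.integers(
        max(int(mean_codons * 0.7), 60), int(mean_codons * 1.3) + 1, size=n_bg
    )
    frag_codons = rng.integers(
        max(int(mean_codons * 0.7), 60), int(mean_codons * 1.3) + 1, size=frag_spec.n_cds
    )
    # inversion genes must fit inside length_bp with their spacers
    inv_budget = inv_spec.length_bp - inv_spec.n_trna * 76 - 120 * (inv_spec.n_cds + inv_spec.n_trna + 1)
    inv_mean = inv_budget // max(inv_spec.n_cds, 1)
    if inv_mean < 200:
        raise InfeasibleConfigError("inversion too short for its gene content")
    inv_codons = rng.integers(
        max(int(inv_mean * 0.6 / 3), 40), max(int(inv_mean * 0.9 / 3), 41), size=inv_spec.n_cds
    )

    b = _Builder()
    gene_i = 0
    group_products: dict[str, str] = {}
    cds_sites: list[tuple[int, int, str]] = []  # (start, length, strand) of mutable CDS
    operon_sites: list[int] = []
    transposase_sites: list[int] = []
    trna_sites: list[int] = []

    def tag(i: int) -> str:
        return f"ANC_{i:05d}"

    def emit_cds(n_codons: int, product="hypothetical protein", strand=None, mutable=True):
        nonlocal gene_i
        if strand is None:
            strand = "+" if rng.random() < 0.5 else "-"
        nt = _random_cds(rng, int(n_codons))
        if strand == "-":
            body = reverse_complement(nt)
        else:
            body = nt
        start = b.add_seq(body)
        group = f"og{gene_i:05d}"
        b.add_feature(tag(gene_i), "CDS", start, len(body), strand, product, group)
        group_products[group] = product
        if mutable:
            cds_sites.append((start, len(body), strand))
        gene_i += 1
        return start

    def emit_gap(lo=50, hi=300, record=False):
        b.add_gap(_random_seq(rng, int(rng.integers(lo, hi + 1))), record=record)

    def emit_trna():
        nonlocal gene_i
        strand = "+" if rng.random() < 0.5 else "-"
        body = trna_unit if strand == "+" else reverse_complement(trna_unit)
        start = b.add_seq(body)
        group = f"og{gene_i:05d}"
        b.add_feature(tag(gene_i), "tRNA", start, 76, strand, "tRNA", group)
        group_products[group] = "tRNA"
        trna_sites.append(start)
        gene_i += 1

    def emit_operon():
        nonlocal gene_i
        start = b.add_seq(operon_unit)
        operon_sites.append(start)
        for off, glen, prod in operon_genes:
            group = f"og{gene_i:05d}"
            b.add_feature(tag(gene_i), "rRNA", start + off, glen, "+", prod, group)
            group_products[group] = prod
            gene_i += 1
        return start

    def emit_transposase():
        nonlocal gene_i
        start = b.add_seq(transposase_unit)
        transposase_sites.append(start)
        b.add_feature(
            tag(gene_i), "CDS", start, tp_len, "+", "IS256 family transposase", None
        )
        gene_i += 1
        return start

    # landmark positions ----------------------------------------------------
    oa_end = max(int(round(L / 12)), 4 * unit_len)

    bg_left = list(bg_codons)
    trna_every = max(n_bg // max(config.n_trna - frag_spec.n_trna - inv_spec.n_trna, 1), 1)
    trna_left = config.n_trna - frag_spec.n_trna - inv_spec.n_trna
    emitted_bg = 0

    def emit_background_until(limit: int, margin: int = 400):
        nonlocal emitted_bg, trna_left
        while bg_left:
            need = int(bg_left[0]) * 3 + 6 + 300 + margin
            if b.cursor + need > limit:
                break
            emit_gap(record=True)
            emit_cds(bg_left.pop(0))
            emitted_bg += 1
            if trna_left > 0 and emitted_bg % trna_every == 0:
                emit_gap()
                emit_trna()
                trna_left -= 1

    # dnaA at position 0, plus strand
    emit_cds(446, product="chromosomal replication initiator protein DnaA",
             strand="+", mutable=True)

    # phase A: background up to the upstream flanking operon O_a
    emit_background_until(oa_end - unit_len - 350)
    b.pad_to(oa_end - unit_len, rng, "flanking operon (upstream)")
    emit_operon()  # O_a ends exactly at oa_end

    # the translocatable fragment: first feature starts at s = oa_end,
    # last feature ends at e; its own operon copy sits before the last two CDS
    s = b.cursor
    frag_list = list(frag_codons)
    op_before_idx = max(len(frag_list) - 2, 1) if frag_spec.with_operon else None
    trna_idx = len(frag_list) // 2
    for i, codons in enumerate(frag_list):
        if i > 0:
            emit_gap(50, 150)
        if frag_spec.n_trna and i == trna_idx:
            emit_trna()
            emit_gap(50, 150)
        if op_before_idx is not None and i == op_before_idx:
            emit_operon()
            emit_gap(50, 150)
        emit_cds(codons)
    e = b.cursor
    frag_interval = (s, e)

    # phase B: background and mid operons until the downstream flank O_b,
    # whose unit ends exactly at d = e + displacement
    d = e + disp
    tail_margin = max(int(round(L * 0.05)), 6 * unit_len)
    if d + unit_len + tail_margin > L:
        raise InfeasibleConfigError(
            f"displacement {disp} does not fit genome of {L} bp"
        )
    n_extra_ops = n_op - (3 if frag_spec.with_operon else 2)
    mid_span = (d - unit_len) - e
    n_mid = min(n_extra_ops, max(mid_span // 250_000, 0))
    mid_targets = [e + int(mid_span * (i + 1) / (n_mid + 1)) for i in range(n_mid)]
    for t in mid_targets:
        emit_background_until(t - unit_len - 350)
        b.pad_to(t - unit_len, rng, "mid operon")
        emit_operon()
    emit_background_until(d - unit_len - 350)
    b.pad_to(d - unit_len, rng, "flanking operon (downstream)")
    emit_operon()
    assert b.cursor == d

    # phase C: background until the transposase-flanked invertible segment
    iv0 = max(int(round(L * 0.55)), d + max(int(round(L * 0.02)), 5_000))
    if iv0 + inv_spec.length_bp + tp_len + max(int(round(L * 0.03)), 2 * unit_len) > L:
        raise InfeasibleConfigError("inversion segment does not fit the genome")
    emit_background_until(iv0 - tp_len - 350)
    b.pad_to(iv0 - tp_len, rng, "left transposase")
    emit_transposase()
    assert b.cursor == iv0

    # the invertible segment occupies exactly [iv0, iv0 + length_bp)
    inv_list = list(inv_codons)
    first_gap = _random_seq(rng, int(rng.integers(60, 121)))
    b.add_seq(first_gap)
    for i, codons in enumerate(inv_list):
        if i > 0:
            emit_gap(60, 120)
        if inv_spec.n_trna and i == len(inv_list) // 2:
            emit_trna()
            emit_gap(60, 120)
        emit_cds(codons)
    pad_len = iv0 + inv_spec.length_bp - b.cursor
    if pad_len <= 0:
        raise InfeasibleConfigError("inversion content exceeds its planted length")
    pad = _random_seq(rng, pad_len)
    # keep the segment's end base non-complementary to its start base, so the
    # inversion breakpoints are not ambiguous by a 1 bp shift
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if pad[-1] == comp[first_gap[0]]:
        alt = [x for x in "ACGT" if x != comp[first_gap[0]]]
        prev = pad[-2] if pad_len > 1 else ""
        alt = [x for x in alt if x != prev] or alt
        pad = pad[:-1] + alt[int(rng.integers(len(alt)))]
    b.add_seq(pad)
    inversion_interval = (iv0, iv0 + inv_spec.length_bp)
    emit_transposase()

    # extra transposase pairs (dispersed identical copies)
    for _ in range(config.n_transposase_pairs - 1):
        emit_gap(400, 900)
        emit_transposase()
        emit_gap(400, 900)
        emit_transposase()

    # phase D: remaining operons spread over the tail, then remaining genes
    n_tail_ops = n_op - len(operon_sites)
    tail_lo = b.cursor + max(int(round(L * 0.005)), 2_000)
    tail_hi = L - max(int(round(L * 0.015)), 5_000)
    if n_tail_ops > 0:
        if tail_hi - tail_lo < n_tail_ops * (unit_len + max(int(round(L * 0.01)), 4_000)):
            raise InfeasibleConfigError("no room for the remaining rRNA operons")
        targets = [
            tail_lo + int((tail_hi - tail_lo) * (i + 1) / (n_tail_ops + 1))
            for i in range(n_tail_ops)
        ]
        for t in targets:
            emit_background_until(t - unit_len - 350)
            b.pad_to(t - unit_len, rng, "tail operon")
            emit_operon()
    emit_background_until(L - 400)
    # any leftover genes keep the census honest even if they push past target
    while bg_left:
        emit_gap(record=True)
        emit_cds(bg_left.pop(0))
    while trna_left > 0:
        emit_gap()
        emit_trna()
        trna_left -= 1
    if b.cursor < L:
        b.add_gap(_random_seq(rng, L - b.cursor), record=True)

    genome = AnnotatedGenome(
        "ancestor", "".join(b.parts), circular=True, features=b.features
    )
    layout = Layout(
        fragment_interval=frag_interval,
        insertion_point=d,
        inversion_interval=inversion_interval,
        operon_sites=operon_sites,
        transposase_sites=transposase_sites,
        rotation_candidates=[m for m in b.gap_mids if m > inversion_interval[1] + tp_len],
    )
    internal = {
        "cds_sites": cds_sites,
        "operon_unit_len": unit_len,
        "tp_len": tp_len,
    }
    return genome, layout, group_products, internal


# ---------------------------------------------------------------------------
# strain derivation
# ---------------------------------------------------------------------------

def _derive_strain(
    ancestor: AnnotatedGenome,
    layout: Layout,
    internal: dict,
    config: PanelConfig,
    strain_id: str,
    rng: np.random.Generator,
) -> AnnotatedGenome:
    seq = bytearray(ancestor.sequence, "ascii")

    # per-gene substitutions (protein-coding, non-repeat)
    for start, length, strand in internal["cds_sites"]:
        nt = ancestor.sequence[start : start + length]
        if strand == "-":
            nt = reverse_complement(nt)
        nt = _mutate_cds(nt, rng, config.cds_substitution_rate)
        if strand == "-":
            nt = reverse_complement(nt)
        seq[start : start + length] = nt.encode()

    # repeats mutate once per strain and are stamped at every site, so copies
    # stay identical within the strain
    unit_len = internal["operon_unit_len"]
    op0 = layout.operon_sites[0]
    unit = ancestor.sequence[op0 : op0 + unit_len]
    unit = _mutate_repeat(unit, rng, config.operon_substitution_rate)
    for site in layout.operon_sites:
        seq[site : site + unit_len] = unit.encode()
    tp_len = internal["tp_len"]
    tp0 = layout.transposase_sites[0]
    tp_unit = ancestor.sequence[tp0 : tp0 + tp_len]
    tp_unit = _mutate_cds(tp_unit, rng, config.operon_substitution_rate)
    for site in layout.transposase_sites:
        seq[site : site + tp_len] = tp_unit.encode()

    feats = []
    for f in ancestor.features:
        feats.append(
            Feature(
                f"{strain_id}_{f.locus_tag.split('_', 1)[1]}",
                f.ftype, f.start, f.end, f.strand, f.product, f.ortholog_group,
            )
        )
    g = AnnotatedGenome(strain_id, seq.decode(), circular=True, features=feats)
    if config.randomize_origin and layout.rotation_candidates:
        off = int(
            layout.rotation_candidates[rng.integers(len(layout.rotation_candidates))]
        )
        g = rotate_genome(g, off)
        if rng.random() < 0.5:
            g = reverse_complement_genome(g)
    return g


def _mutate_repeat(unit: str, rng: np.random.Generator, rate: float) -> str:
    n = len(unit)
    k = rng.binomial(n, rate)
    if k == 0:
        return unit
    out = list(unit)
    for p in rng.choice(n, size=k, replace=False):
        choices = [c for c in "ACGT" if c != out[p]]
        out[p] = choices[rng.integers(3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_strain_panel(
    config: PanelConfig,
    frag_spec: FragmentSpec | None = None,
    inv_spec: InversionSpec | None = None,
):
    """Generate the strain panel plus the ancestral gene catalog.

    Returns ``(strains, catalog)``; the catalog carries the ancestral genome,
    the planted layout landmarks and the ortholog-group truth used by tests.
    """
    frag_spec = frag_spec or FragmentSpec()
    inv_spec = inv_spec or InversionSpec()
    rng = np.random.default_rng(config.seed)
    ancestor, layout, groups, internal = _build_ancestor(config, frag_spec, inv_spec, rng)
    strains = []
    for i in range(config.n_strains):
        strain_rng = np.random.default_rng([config.seed, 1000 + i])
        strains.append(
            _derive_strain(ancestor, layout, internal, config, f"S{i:02d}", strain_rng)
        )
    catalog = AncestralCatalog(
        true_genome=ancestor, layout=layout, groups=groups,
        frag_spec=frag_spec, inv_spec=inv_spec,
    )
    return strains, catalog


def _longest_shared_flank(seq: str, a: int, b: int, limit: int = 20_000) -> int:
    """Length of the longest identical stretch ending at positions a and b."""
    k = 0
    while k < limit and a - k - 1 >= 0 and b - k - 1 >= 0 and seq[a - k - 1] == seq[b - k - 1]:
        k += 1
    return k


def _longest_shared_right(seq: str, a: int, b: int, limit: int = 20_000) -> int:
    k = 0
    n = len(seq)
    while k < limit and a + k < n and b + k < n and seq[a + k] == seq[b + k]:
        k += 1
    return k


def plant_misassembly(
    genome: AnnotatedGenome,
    displacement_bp: int,
    moved_fragment_interval: tuple[int, int] | None,
    inversion_interval: tuple[int, int] | None,
    seed: int,
    min_flank_bp: int = 300,
    randomize_origin: bool = False,
) -> tuple[AnnotatedGenome, PlantedTruth]:
    """Plant a repeat-flanked translocation and/or inversion into ``genome``.

    The translocated interval must begin at a repeat boundary whose copy also
    ends at the insertion point (``interval end + displacement``); the inverted
    interval must be bounded by identical same-orientation repeat copies.  The
    misassembled query and the exact ops that produced it are returned.
    """
    rng = np.random.default_rng(seed)
    ops: list[RearrangementOp] = []
    seq = genome.sequence
    if moved_fragment_interval is not None:
        s, e = moved_fragment_interval
        d = e + displacement_bp
        if d > len(seq):
            raise InfeasibleConfigError("displacement exceeds genome length")
        flank = _longest_shared_flank(seq, s, d)
        if flank < min_flank_bp:
            raise NotRepeatFlankedError(
                f"translocation source/destination share only a {flank} bp flank "
                f"(< {min_flank_bp}); refusing a non-repeat-mediated move"
            )
        ops.append(RearrangementOp("move", s, e, dest=d, provenance="planted_move"))
    if inversion_interval is not None:
        a, bnd = inversion_interval
        # identical same-orientation copies must bound the segment:
        # the stretch ending at a equals the stretch starting at bnd
        k = _shared_flank_pair(seq, a, bnd)
        if k < min_flank_bp:
            raise NotRepeatFlankedError(
                f"inversion bounded by only a {k} bp identical flank (< {min_flank_bp})"
            )
        ops.append(RearrangementOp("invert", a, bnd, provenance="planted_inversion"))

    query = genome.copy()
    query.genome_id = genome.genome_id + "_misassembled"
    for op in ops:
        query = apply_op(query, op)
    truth = PlantedTruth(
        true_genome=genome,
        planted_ops=ops,
        planted_displacement_bp=displacement_bp if moved_fragment_interval else 0,
        planted_inversion_length_bp=(
            inversion_interval[1] - inversion_interval[0] if inversion_interval else 0
        ),
    )
    return query, truth


def _shared_flank_pair(seq: str, a: int, b: int, limit: int = 20_000) -> int:
    """Longest k with seq[a-k:a] == seq[b:b+k] (same-orientation bounding copies).

    This is the longest suffix of the sequence ending at ``a`` that is also a
    prefix of the sequence starting at ``b``, found with a KMP failure table.
    """
    right = seq[b : min(b + limit, len(seq))]
    left = seq[max(0, a - limit) : a]
    if not right or not left:
        return 0
    s = right + "\x00" + left
    fail = [0] * len(s)
    for i in range(1, len(s)):
        j = fail[i - 1]
        while j and s[i] != s[j]:
            j = fail[j - 1]
        if s[i] == s[j]:
            j += 1
        fail[i] = j
    return fail[-1]


def generate_scenario(
    config: PanelConfig,
    frag_spec: FragmentSpec | None = None,
    inv_spec: InversionSpec | None = None,
) -> Scenario:
    """Panel + ancestral truth + misassembled query, all from one seed."""
    frag_spec = frag_spec or FragmentSpec()
    inv_spec = inv_spec or InversionSpec()
    strains, catalog = generate_strain_panel(config, frag_spec, inv_spec)
    layout = catalog.layout
    truth_genome = catalog.true_genome.copy()
    truth_genome.genome_id = "query_truth"
    query, truth = plant_misassembly(
        truth_genome,
        frag_spec.displacement_bp,
        layout.fragment_interval,
        layout.inversion_interval,
        seed=int(np.random.default_rng([config.seed, 7]).integers(2**31)),
    )
    query.genome_id = "query"
    if config.randomize_origin and layout.rotation_candidates:
        qrng = np.random.default_rng([config.seed, 11])
        # rotate at a safe intergenic point downstream of all planted regions
        off = int(layout.rotation_candidates[qrng.integers(len(layout.rotation_candidates))])
        query = rotate_genome(query, off)
    return Scenario(config=config, panel=strains, truth=truth, query=query, catalog=catalog)


# ---------------------------------------------------------------------------
# annotation reconciliation fixtures
# ---------------------------------------------------------------------------

@dataclass
class AnnotationFixture:
    original: AnnotatedGenome
    new: AnnotatedGenome
    arbiter: AnnotatedGenome
    truth_categories: dict[str, str]  # locus key -> planted category (tests only)
    homolog_panel: list[tuple[str, str]]  # (name, protein) for reinstatement


_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA2CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, 20, size=n))


def _backtranslate(prot: str) -> str:
    return "".join(_AA2CODON[a] for a in prot)


def generate_annotation_fixture(
    case_counts: tuple[int, int, int, int, int],
    seed: int,
    n_new_genes: int = 0,
) -> AnnotationFixture:
    """Three annotation versions of one synthetic genome.

    ``case_counts`` is ``(n_arbiter_supports_new, n_arbiter_supports_original,
    n_arbiter_supports_neither, n_identical, n_omitted_from_new)``.  Category
    identity is realized only through start coordinates on shared
    (stop, strand) loci — the emitted annotations carry no labels.
    """
    n_new_sup, n_orig_sup, n_neither, n_identical, n_omitted = case_counts
    rng = np.random.default_rng(seed)
    total = n_new_sup + n_orig_sup + n_neither + n_identical + n_omitted + n_new_genes

    cats = (
        ["supports_new"] * n_new_sup
        + ["supports_original"] * n_orig_sup
        + ["supports_neither"] * n_neither
        + ["identical"] * n_identical
        + ["omitted"] * n_omitted
        + ["new_gene"] * n_new_genes
    )
    rng.shuffle(cats)

    parts: list[str] = []
    cursor = 0
    orig_feats: list[Feature] = []
    new_feats: list[Feature] = []
    arb_feats: list[Feature] = []
    truth: dict[str, str] = {}
    panel: list[tuple[str, str]] = []

    for i, cat in enumerate(cats):
        gap = int(rng.integers(60, 200))
        sd_needed = cat != "supports_neither"
        gseq = _random_seq(rng, gap)
        if sd_needed and gap > 20:
            # a Shine-Dalgarno-like motif upstream of the outermost start
            pos = gap - 10 - int(rng.integers(0, 4))
            gseq = gseq[:pos] + "AGGAGG" + gseq[pos + 6 :]
        parts.append(gseq)
        cursor += len(gseq)

        body_codons = int(rng.integers(60, 160))
        prot = _random_protein(rng, body_codons)
        link1 = _random_protein(rng, 2)
        link2 = _random_protein(rng, 2)
        # three in-frame alternative starts at codon offsets 0, 3 and 6
        full_prot = "M" + link1 + "M" + link2 + "M" + prot
        gene = _backtranslate(full_prot) + "TAA"
        strand = "+" if rng.random() < 0.5 else "-"
        placed = gene if strand == "+" else reverse_complement(gene)
        start = cursor
        parts.append(placed)
        cursor += len(placed)
        glen = len(gene)

        # start-coordinate variants, in gene-local codon offsets
        offsets = [0, 9, 18]
        rng.shuffle(offsets)
        if cat == "identical":
            o_orig = o_new = o_arb = offsets[0]
        elif cat == "supports_new":
            o_orig, o_new = offsets[0], offsets[1]
            o_arb = o_new
        elif cat == "supports_original":
            o_orig, o_new = offsets[0], offsets[1]
            o_arb = o_orig
        elif cat == "supports_neither":
            o_orig, o_new, o_arb = offsets[0], offsets[1], offsets[2]
        else:  # omitted / new_gene: single coherent start
            o_orig = o_new = o_arb = offsets[0]

        def interval(off: int) -> tuple[int, int]:
            if strand == "+":
                return (start + off, start + glen)
            return (start, start + glen - off)

        tag = f"L{i:05d}"

        def feat(off: int) -> Feature:
            a, bnd = interval(off)
            return Feature(tag, "CDS", a, bnd, strand, "hypothetical protein")

        if cat == "omitted":
            orig_feats.append(feat(o_orig))
            arb_feats.append(feat(o_arb))
            panel.append((f"hom_{tag}", full_prot))
        elif cat == "new_gene":
            new_feats.append(feat(o_new))
        else:
            orig_feats.append(feat(o_orig))
            new_feats.append(feat(o_new))
            arb_feats.append(feat(o_arb))
        truth[tag] = cat

    parts.append(_random_seq(rng, 200))
    seq = "".join(parts)
    mk = lambda gid, feats: AnnotatedGenome(
        gid, seq, circular=False,
        features=[Feature(f.locus_tag, f.ftype, f.start, f.end, f.strand, f.product)
                  for f in feats],
    )
    return AnnotationFixture(
        original=mk("fixture", orig_feats),
        new=mk("fixture", new_feats),
        arbiter=mk("fixture", arb_feats),
        truth_categories=truth,
        homolog_panel=panel,
    )


# ---------------------------------------------------------------------------
# pseudogene ledger fixture
# ---------------------------------------------------------------------------

@dataclass
class PseudogeneLocus:
    locus_tag: str
    flagged_by: str  # "both" | "new_only"
    nucleotide: str  # the annotated coding interval, plus-strand
    truth_kind: str  # tests only: shared | extra_truncated | extra_split


@dataclass
class PseudogeneFixture:
    cases: list[PseudogeneLocus]
    homolog_panel: list[tuple[str, str]]


def generate_pseudogene_ledger(
    n_shared: int, n_extra_truncated: int, n_extra_split_gene: int, seed: int
) -> PseudogeneFixture:
    """Pseudogene adjudication substrate with a homolog protein panel.

    * shared cases carry an internal in-frame stop (agreed pseudogenes);
    * extra_truncated cases retain < 60 % of their only homolog (or carry an
      internal stop) — genuinely defective;
    * extra_split cases fully match a shorter single-domain homolog family
      although they cover only half of a bifunctional reference — valid genes.
    """
    rng = np.random.default_rng(seed)
    cases: list[PseudogeneLocus] = []
    panel: list[tuple[str, str]] = []

    for i in range(n_shared):
        prot = "M" + _random_protein(rng, int(rng.integers(200, 350)))
        panel.append((f"ref_shared_{i:03d}", prot))
        nt = _backtranslate(prot)
        stop_at = int(rng.integers(len(prot) // 3, 2 * len(prot) // 3)) * 3
        nt = nt[:stop_at] + "TAA" + nt[stop_at + 3 :]
        cases.append(PseudogeneLocus(f"PSE_S{i:03d}", "both", nt + "TAA", "shared"))

    for i in range(n_extra_truncated):
        prot = "M" + _random_protein(rng, int(rng.integers(250, 400)))
        panel.append((f"ref_trunc_{i:03d}", prot))
        if i % 2 == 0:
            keep = int(len(prot) * 0.4)
            nt = _backtranslate(prot[:keep]) + "TAA"
        else:
            nt = _backtranslate(prot)
            stop_at = int(len(prot) * 0.4) * 3
            nt = nt[:stop_at] + "TGA" + nt[stop_at + 3 :] + "TAA"
        cases.append(PseudogeneLocus(f"PSE_T{i:03d}", "new_only", nt, "extra_truncated"))

    for i in range(n_extra_split_gene):
        # bifunctional reference = domain1 + domain2; the query encodes an
        # intact single-domain protein matching a standalone family member
        d1 = "M" + _random_protein(rng, int(rng.integers(180, 240)))
        d2 = _random_protein(rng, int(rng.integers(250, 320)))
        panel.append((f"ref_bifunctional_{i:03d}", d1 + d2))
        panel.append((f"ref_single_domain_{i:03d}", d1))
        cases.append(
            PseudogeneLocus(
                f"PSE_X{i:03d}", "new_only", _backtranslate(d1) + "TAA", "extra_split"
            )
        )
    return PseudogeneFixture(cases=cases, homolog_panel=panel)
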