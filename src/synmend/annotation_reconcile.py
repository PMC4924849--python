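"""Three-way annotation reconciliation, pseudogene adjudication and census.

When a genome is re-annotated, most disagreements between the old and the new
annotation are alternative start codons on otherwise identical ORFs.  The
reconciliation strategy here mirrors the manual curation of the SAFR-032
update: loci are matched by their (stop codon, strand) key, since the stop is
the stable end of a prokaryotic CDS; a third, independent annotation
arbitrates each differing start; starts supported by neither annotation are
left as the new annotation has them, marked ambiguous.  Genes omitted by the
re-annotation are reinstated when homology supports them, and pseudogene
calls are adjudicated against a homolog protein panel, including the
split-gene rescue: a locus that looks truncated against a bifunctional
reference but fully matches a single-domain homolog family is a valid gene.
"""

from __future__ import annotations

import collections
import json
from dataclasses import dataclass

from Bio.Seq import Seq

from ._align import KmerPrefilter, align_stats, global_identity
from .genome_model import (
    AnnotatedGenome,
    Census,
    GenomeModelError,
    census as genome_census,
    extract_feature_sequence,
)

__all__ = [
    "AnnotationCase",
    "ReconciliationDecision",
    "PseudogeneCase",
    "ReconcileError",
    "LedgerArithmeticError",
    "pair_annotation_cases",
    "resolve_start_codon",
    "resolve_all",
    "adjudicate_pseudogene",
    "adjudicate_ledger",
    "reinstate_omitted_genes",
    "final_census",
    "HomologyThresholds",
]


class ReconcileError(GenomeModelError):
    pass


class LedgerArithmeticError(ReconcileError):
    """Reconciliation counts do not add up."""


@dataclass(frozen=True)
class HomologyThresholds:
    """Config keys for every homology rule; fractions in [0, 1].

    * ``rescue_coverage`` / ``rescue_identity`` — full-length match to an
      alternative (e.g. single-domain) family member that rescues a
      pseudogene call;
    * ``truncation_coverage`` — best homolog coverage below this means a
      substantial deletion;
    * ``reinstate_identity`` / ``reinstate_length`` — evidence required to
      reinstate an omitted gene.
    """

    rescue_coverage: float = 0.90
    rescue_identity: float = 0.50
    truncation_coverage: float = 0.60
    reinstate_identity: float = 0.50
    reinstate_length: float = 0.70


# ---------------------------------------------------------------------------
# case pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationCase:
    key: tuple[int, str]  # (stop coordinate, strand)
    locus_original: str | None
    locus_new: str | None
    start_original: int | None
    start_new: int | None

    @property
    def differing(self) -> bool:
        return (
            self.start_original is not None
            and self.start_new is not None
            and self.start_original != self.start_new
        )


def _bio_key(f) -> tuple[int, str]:
    """(stop, strand): the coordinate of the stop-codon end of the CDS."""
    stop = f.end if f.strand == "+" else f.start
    return (stop, f.strand)


def _bio_start(f) -> int:
    return f.start if f.strand == "+" else f.end


def pair_annotation_cases(
    original: AnnotatedGenome, new: AnnotatedGenome
) -> tuple[list[AnnotationCase], list[str], list[str]]:
    """Match CDS loci of two annotation versions on (stop, strand).

    Returns (cases for matched loci, loci omitted from the new annotation,
    loci newly introduced by it).
    """
    if len(original.sequence) != len(new.sequence):
        raise ReconcileError("annotations refer to sequences of different length")
    omap = {_bio_key(f): f for f in original.features if f.ftype == "CDS"}
    nmap = {_bio_key(f): f for f in new.features if f.ftype == "CDS"}
    cases = []
    for key in sorted(set(omap) & set(nmap), key=lambda k: (k[0], k[1])):
        fo, fn = omap[key], nmap[key]
        cases.append(
            AnnotationCase(
                key=key,
                locus_original=fo.locus_tag,
                locus_new=fn.locus_tag,
                start_original=_bio_start(fo),
                start_new=_bio_start(fn),
            )
        )
    omitted = sorted(omap[k].locus_tag for k in set(omap) - set(nmap))
    new_genes = sorted(nmap[k].locus_tag for k in set(nmap) - set(omap))
    return cases, omitted, new_genes


# ---------------------------------------------------------------------------
# start-codon arbitration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReconciliationDecision:
    case: AnnotationCase
    chosen_start: int
    rule_applied: str  # identical | adopt_new | retain_original | default_new_ambiguous
    ambiguous: bool


def resolve_start_codon(
    case: AnnotationCase, arbiter: AnnotatedGenome | None
) -> ReconciliationDecision:
    """Arbitrate one matched locus.

    The arbiter's start equal to the new (resp. original) start adopts that
    version; an arbiter that is missing or supports neither start leaves the
    new annotation in place, flagged ambiguous.
    """
    if case.start_original is None or case.start_new is None:
        raise ReconcileError("resolve_start_codon needs a locus present in both versions")
    if case.start_original == case.start_new:
        return ReconciliationDecision(case, case.start_new, "identical", False)
    arb_start = None
    if arbiter is not None:
        amap = getattr(arbiter, "_synmend_key_cache", None)
        if amap is None:
            amap = {_bio_key(f): _bio_start(f) for f in arbiter.features if f.ftype == "CDS"}
            arbiter._synmend_key_cache = amap
        arb_start = amap.get(case.key)
    if arb_start == case.start_new:
        return ReconciliationDecision(case, case.start_new, "adopt_new", False)
    if arb_start == case.start_original:
        return ReconciliationDecision(case, case.start_original, "retain_original", False)
    return ReconciliationDecision(case, case.start_new, "default_new_ambiguous", True)


def resolve_all(
    cases: list[AnnotationCase], arbiter: AnnotatedGenome | None
) -> list[ReconciliationDecision]:
    return [resolve_start_codon(c, arbiter) for c in cases]


# ---------------------------------------------------------------------------
# pseudogene adjudication
# ---------------------------------------------------------------------------

@dataclass
class PseudogeneCase:
    locus_tag: str
    flagged_by: str  # both | new_only | original_only
    best_homolog_coverage: float
    has_internal_stop: bool
    full_length_match_to_alternative_family: bool
    verdict: str  # pseudogene | valid_gene


def _translate_frame0(nt: str) -> str:
    nt = nt[: len(nt) - len(nt) % 3]
    prot = str(Seq(nt).translate(table=11))
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def adjudicate_pseudogene(
    locus_tag: str,
    nucleotide: str,
    flagged_by: str,
    homolog_panel: list[tuple[str, str]],
    thresholds: HomologyThresholds | None = None,
    prefilter: KmerPrefilter | None = None,
) -> PseudogeneCase:
    """Verdict for one pseudogene candidate against the homolog panel.

    valid_gene — the translated product covers >= 90 % of some panel protein
    at >= 50 % identity with no internal stop (the split-gene rescue, and the
    trivial intact-gene case).  pseudogene — an internal in-frame stop, or
    best homolog coverage below 60 % (a substantial deletion) without any
    full-length alternative match.
    """
    th = thresholds or HomologyThresholds()
    if not homolog_panel:
        raise ReconcileError("empty homolog panel")
    prot = _translate_frame0(nucleotide)
    has_stop = "*" in prot
    query = prot.split("*")[0] if has_stop else prot

    panel = dict(homolog_panel)
    if prefilter is None:
        prefilter = KmerPrefilter(panel)
    names = [n for n, _ in prefilter.candidates(query, top=5)] or list(panel)[:5]
    best_cov = 0.0
    full_match = False
    for name in names:
        st = align_stats(query, panel[name])
        best_cov = max(best_cov, st.coverage_of_b)
        if st.coverage_of_b >= th.rescue_coverage and st.identity >= th.rescue_identity:
            full_match = True

    if has_stop:
        verdict = "pseudogene"
    elif full_match:
        verdict = "valid_gene"
    elif best_cov < th.truncation_coverage:
        verdict = "pseudogene"
    else:
        verdict = "valid_gene"
    return PseudogeneCase(
        locus_tag=locus_tag,
        flagged_by=flagged_by,
        best_homolog_coverage=round(best_cov, 4),
        has_internal_stop=has_stop,
        full_length_match_to_alternative_family=full_match,
        verdict=verdict,
    )


def adjudicate_ledger(fixture_cases, homolog_panel, thresholds=None) -> list[PseudogeneCase]:
    """Adjudicate a whole pseudogene ledger (shared + extra candidates)."""
    pf = KmerPrefilter(dict(homolog_panel))
    return [
        adjudicate_pseudogene(
            c.locus_tag, c.nucleotide, c.flagged_by, homolog_panel, thresholds, pf
        )
        for c in fixture_cases
    ]


# ---------------------------------------------------------------------------
# omitted-gene reinstatement
# ---------------------------------------------------------------------------

def reinstate_omitted_genes(
    omitted: list[tuple[str, str]],
    homolog_panel: list[tuple[str, str]],
    thresholds: HomologyThresholds | None = None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Keep omitted loci with homology support; drop the rest with a reason.

    ``omitted`` is (locus_tag, protein sequence).  A locus is kept iff some
    panel protein matches at >= 50 % identity over >= 70 % of the length.
    """
    th = thresholds or HomologyThresholds()
    panel = dict(homolog_panel)
    pf = KmerPrefilter(panel) if panel else None
    kept, dropped = [], []
    for tag, prot in omitted:
        if not prot:
            dropped.append((tag, "empty_product"))
            continue
        names = [n for n, _ in pf.candidates(prot, top=5)] if pf else []
        ok = False
        for name in names:
            ref = panel[name]
            if min(len(prot), len(ref)) / max(len(prot), len(ref)) < th.reinstate_length:
                continue
            if global_identity(prot, ref) >= th.reinstate_identity:
                ok = True
                break
        if ok:
            kept.append(tag)
        else:
            dropped.append((tag, "no_homology_support"))
    return kept, dropped


# ---------------------------------------------------------------------------
# final census and ledger arithmetic
# ---------------------------------------------------------------------------

def final_census(
    genome: AnnotatedGenome,
    decisions: list[ReconciliationDecision],
    pseudo_cases: list[PseudogeneCase] | None = None,
    n_shared_pseudogenes: int | None = None,
) -> dict:
    """Census plus reconciliation ledger, with the arithmetic enforced:
    differing = adopt_new + retain_original + ambiguous, and retained
    pseudogenes = shared + confirmed extras."""
    cen = genome_census(genome)
    rules = collections.Counter(d.rule_applied for d in decisions)
    differing = sum(1 for d in decisions if d.case.differing)
    resolved = (
        rules.get("adopt_new", 0)
        + rules.get("retain_original", 0)
        + rules.get("default_new_ambiguous", 0)
    )
    if differing != resolved:
        raise LedgerArithmeticError(
            f"differing loci {differing} != resolved decisions {resolved}"
        )
    out = {
        "census": cen.as_dict(),
        "start_codon_ledger": {
            "identical": rules.get("identical", 0),
            "differing": differing,
            "adopt_new": rules.get("adopt_new", 0),
            "retain_original": rules.get("retain_original", 0),
            "default_new_ambiguous": rules.get("default_new_ambiguous", 0),
        },
    }
    if pseudo_cases is not None:
        retained = sum(1 for c in pseudo_cases if c.verdict == "pseudogene")
        shared = sum(1 for c in pseudo_cases if c.flagged_by == "both")
        extras_confirmed = sum(
            1
            for c in pseudo_cases
            if c.flagged_by != "both" and c.verdict == "pseudogene"
        )
        if n_shared_pseudogenes is not None and shared != n_shared_pseudogenes:
            raise LedgerArithmeticError(
                f"shared pseudogenes {shared} != declared {n_shared_pseudogenes}"
            )
        shared_confirmed = sum(
            1 for c in pseudo_cases if c.flagged_by == "both" and c.verdict == "pseudogene"
        )
        if retained != shared_confirmed + extras_confirmed:
            raise LedgerArithmeticError("pseudogene ledger does not add up")
        out["pseudogene_ledger"] = {
            "candidates": len(pseudo_cases),
            "shared": shared,
            "extras_confirmed": extras_confirmed,
            "rescued_valid_genes": sum(
                1 for c in pseudo_cases if c.verdict == "valid_gene"
            ),
            "retained": retained,
        }
    return out


def decisions_to_tsv(decisions: list[ReconciliationDecision]) -> str:
    lines = ["locus_original\tlocus_new\tstop\tstrand\tstart_original\tstart_new\tchosen_start\trule\tambiguous"]
    for d in decisions:
        c = d.case
        lines.append(
            f"{c.locus_original}\t{c.locus_new}\t{c.key[0]}\t{c.key[1]}\t"
            f"{c.start_original}\t{c.start_new}\t{d.chosen_start}\t{d.rule_applied}\t"
            f"{str(d.ambiguous).lower()}"
        )
    return "\n".join(lines) + "\n"


def pseudogene_ledger_to_tsv(cases: list[PseudogeneCase]) -> str:
    lines = ["locus_tag\tflagged_by\tbest_homolog_coverage\thas_internal_stop\tfull_length_alt_match\tverdict"]
    for c in cases:
        lines.append(
            f"{c.locus_tag}\t{c.flagged_by}\t{c.best_homolog_coverage}\t"
            f"{str(c.has_internal_stop).lower()}\t"
            f"{str(c.full_length_match_to_alternative_family).lower()}\t{c.verdict}"
        )
    return "\n".join(lines) + "\n"
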