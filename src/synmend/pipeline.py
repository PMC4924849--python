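"""End-to-end orchestration: normalize → anchor → consensus → detect →
correct → verify → design primers.

This is the library-level composition used by the command-line interface, the
test-suite and the reproduction script.  Every stage is an ordinary function
of the per-stage modules; this module only wires them together and collects a
machine-readable run report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import primer_design, repeat_finder, synteny
from .genome_model import AnnotatedGenome, census, find_dnaA, normalize_to_dnaA
from .rearrangement import (
    CorrectionPlan,
    VerificationReport,
    apply_plan,
    plan_corrections,
    verify_correction,
)

__all__ = ["DetectionResult", "detect_misassemblies", "correct_genome", "run_scenario_pipeline"]


@dataclass
class DetectionResult:
    query: AnnotatedGenome  # dnaA-normalized query
    panel: list[AnnotatedGenome]  # dnaA-normalized panel
    consensus: synteny.ConsensusOrder
    repeat_families: list[repeat_finder.RepeatFamily]
    violations: list[synteny.Violation]
    anchor_coverage: float


def detect_misassemblies(
    query: AnnotatedGenome,
    panel: list[AnnotatedGenome],
    min_repeat_len: int = repeat_finder.DEFAULT_MIN_LEN,
    min_repeat_identity: float = repeat_finder.DEFAULT_MIN_IDENTITY,
    flank_window_bp: int = synteny.FLANK_WINDOW_BP,
) -> DetectionResult:
    """Full detection stage against a panel of related genomes.

    The first panel genome serves as the anchoring reference; its loci name
    the ortholog groups.  All genomes are brought into the dnaA frame first.
    """
    if len(panel) < 2:
        raise ValueError("need a panel of at least 2 genomes")
    nq = normalize_to_dnaA(query)
    npanel = [normalize_to_dnaA(g) for g in panel]
    ref = npanel[0]
    ref_strands = {f.locus_tag: f.strand for f in ref.features if f.ftype == "CDS"}
    dnaA_group = find_dnaA(ref).locus_tag

    profiles = []
    for g in npanel:
        # the reference maps onto itself through the same reciprocal-best
        # machinery, so its ambiguous duplicates (transposase copies) drop out
        # of the profile exactly as they do for every other genome
        groups = synteny.assign_ortholog_groups(g, ref)
        profiles.append(synteny.build_profile(g, groups, ref_strands))

    cons = synteny.consensus_order(profiles, dnaA_group)

    qmap = synteny.build_anchor_map(nq, ref)
    qgroups = qmap.as_dict_a_to_b()
    qprofile = synteny.build_profile(nq, qgroups, ref_strands)

    fams = repeat_finder.classify_repeats(
        repeat_finder.find_long_repeats(nq, min_repeat_len, min_repeat_identity), nq
    )
    violations = synteny.detect_violations(
        qprofile, cons, fams, nq, panel_genomes=npanel, flank_window_bp=flank_window_bp
    )
    return DetectionResult(
        query=nq,
        panel=npanel,
        consensus=cons,
        repeat_families=fams,
        violations=violations,
        anchor_coverage=qmap.coverage,
    )


def correct_genome(
    detection: DetectionResult, include_low_confidence: bool = False
) -> tuple[CorrectionPlan, AnnotatedGenome, VerificationReport]:
    plan = plan_corrections(detection.violations, include_low_confidence)
    corrected = apply_plan(detection.query, plan)
    corrected.genome_id = detection.query.genome_id + "_corrected"
    report = verify_correction(detection.query, corrected)
    return plan, corrected, report


def run_scenario_pipeline(
    query: AnnotatedGenome,
    panel: list[AnnotatedGenome],
    design_primers: bool = True,
    primer_constraints: "primer_design.PrimerConstraints | None" = None,
) -> dict:
    """Detection + correction + verification + primer design; returns the run
    report as a JSON-serializable dict (artifacts are the caller's concern)."""
    det = detect_misassemblies(query, panel)
    plan, corrected, verification = correct_genome(det)
    report = {
        "n_violations": len(det.violations),
        "violations": [v.as_dict() for v in det.violations],
        "anchor_coverage": round(det.anchor_coverage, 4),
        "plan": [op.as_dict() for op in plan.ops],
        "verification_passed": verification.passed,
        "census_after": census(corrected).as_dict(),
    }
    if design_primers and plan.ops:
        designs = primer_design.design_validation_primers(
            corrected, plan, constraints=primer_constraints
        )
        report["amplicons"] = [d.as_dict() for d in designs]
    return report
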