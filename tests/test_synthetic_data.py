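"""Generators: determinism, planted-truth consistency, fixture categories."""

import numpy as np
import pytest
from Bio.Seq import Seq

from synmend.genome_model import census, normalize_to_dnaA
from synmend.rearrangement import apply_op
from synmend.synthetic_data import (
    FragmentSpec,
    InfeasibleConfigError,
    InversionSpec,
    NotRepeatFlankedError,
    PanelConfig,
    generate_annotation_fixture,
    generate_pseudogene_ledger,
    generate_scenario,
    generate_strain_panel,
    plant_misassembly,
)

from conftest import SMALL_FRAG, SMALL_INV, SMALL_PANEL


class TestPanelGenerator:
    def test_same_seed_is_byte_identical(self):
        cfg = PanelConfig(seed=42, **SMALL_PANEL)
        a, _ = generate_strain_panel(cfg, SMALL_FRAG, SMALL_INV)
        b, _ = generate_strain_panel(cfg, SMALL_FRAG, SMALL_INV)
        for ga, gb in zip(a, b):
            assert ga.sequence == gb.sequence
            assert [
                (f.locus_tag, f.start, f.end, f.strand) for f in ga.features
            ] == [(f.locus_tag, f.start, f.end, f.strand) for f in gb.features]

    def test_census_matches_config(self, small_scenario):
        cfg = small_scenario.config
        for g in small_scenario.panel + [small_scenario.catalog.true_genome]:
            cen = census(g)
            assert cen.counts["CDS"] == cfg.n_genes
            assert cen.counts["rRNA"] == 3 * cfg.n_rrna_operons
            assert cen.rrna_operon_count == cfg.n_rrna_operons
            assert cen.counts["tRNA"] == cfg.n_trna

    def test_strains_share_truth_ortholog_pairing(self, small_scenario):
        truth = normalize_to_dnaA(small_scenario.catalog.true_genome)
        for strain in small_scenario.panel:
            ns = normalize_to_dnaA(strain)
            by_group_s = {
                f.ortholog_group: (f.start, f.end, f.strand)
                for f in ns.features if f.ortholog_group
            }
            by_group_t = {
                f.ortholog_group: (f.start, f.end, f.strand)
                for f in truth.features if f.ortholog_group
            }
            assert by_group_s == by_group_t  # substitution-only divergence

    def test_repeat_copies_identical_within_strain(self, small_scenario):
        lay = small_scenario.catalog.layout
        unit = small_scenario.config.rrna_operon_length_bp
        for g in small_scenario.panel:
            ns = normalize_to_dnaA(g)
            units = {ns.sequence[s : s + unit] for s in lay.operon_sites}
            assert len(units) == 1

    def test_strains_diverge_from_truth(self, small_scenario):
        truth = normalize_to_dnaA(small_scenario.catalog.true_genome)
        ns = normalize_to_dnaA(small_scenario.panel[0])
        mismatches = sum(
            1 for a, b in zip(truth.sequence, ns.sequence) if a != b
        )
        # ~1 %/site over coding sequence; well above zero, below 2 %
        assert 0.001 < mismatches / len(truth.sequence) < 0.02

    def test_infeasible_config_rejected(self):
        with pytest.raises(InfeasibleConfigError):
            generate_strain_panel(
                PanelConfig(seed=1, n_strains=2, genome_length_bp=200_000, n_genes=100),
                FragmentSpec(displacement_bp=522_000),
                InversionSpec(),
            )


class TestPlantMisassembly:
    def test_planted_ops_reproduce_query(self, small_scenario):
        g = small_scenario.truth.true_genome.copy()
        for op in small_scenario.truth.planted_ops:
            g = apply_op(g, op)
        assert (
            normalize_to_dnaA(g).sequence
            == normalize_to_dnaA(small_scenario.query).sequence
        )

    def test_zero_op_spec_returns_identical_genome(self, small_scenario):
        truth = small_scenario.catalog.true_genome
        q, planted = plant_misassembly(truth, 0, None, None, seed=3)
        assert q.sequence == truth.sequence
        assert planted.planted_ops == []

    def test_inverse_ops_restore_truth_exactly(self, small_scenario):
        from synmend.rearrangement import invert_op

        truth = small_scenario.truth.true_genome
        g = truth.copy()
        ops = small_scenario.truth.planted_ops
        for op in ops:
            g = apply_op(g, op)
        for op in reversed(ops):
            g = apply_op(g, invert_op(op))
        assert g.sequence == truth.sequence

    def test_census_invariant_under_planting(self, small_scenario):
        assert (
            census(small_scenario.query).as_dict()
            == census(small_scenario.catalog.true_genome).as_dict()
        )

    def test_non_repeat_flanked_move_refused(self, small_scenario):
        truth = small_scenario.catalog.true_genome
        # an arbitrary interval not bounded by repeat copies
        with pytest.raises(NotRepeatFlankedError):
            plant_misassembly(truth, 20_000, (1_000, 6_000), None, seed=5)


class TestAnnotationFixture:
    def test_counts_are_realized_by_coordinates(self, annotation_fixture_small):
        fx = annotation_fixture_small
        omap = {f.locus_tag: f for f in fx.original.features}
        nmap = {f.locus_tag: f for f in fx.new.features}
        amap = {f.locus_tag: f for f in fx.arbiter.features}
        import collections

        derived = collections.Counter()
        for tag, cat in fx.truth_categories.items():
            if cat == "omitted":
                assert tag in omap and tag not in nmap
                derived["omitted"] += 1
                continue
            if cat == "new_gene":
                assert tag in nmap and tag not in omap
                derived["new_gene"] += 1
                continue
            fo, fn, fa = omap[tag], nmap[tag], amap[tag]
            so = fo.start if fo.strand == "+" else fo.end
            sn = fn.start if fn.strand == "+" else fn.end
            sa = fa.start if fa.strand == "+" else fa.end
            if so == sn:
                derived["identical"] += 1
            elif sa == sn:
                derived["supports_new"] += 1
            elif sa == so:
                derived["supports_original"] += 1
            else:
                derived["supports_neither"] += 1
        assert derived["supports_new"] == 12
        assert derived["supports_original"] == 7
        assert derived["supports_neither"] == 4
        assert derived["identical"] == 30
        assert derived["omitted"] == 9

    def test_all_annotated_starts_are_atg(self, annotation_fixture_small):
        fx = annotation_fixture_small
        from synmend.genome_model import extract_feature_sequence

        for version in (fx.original, fx.new, fx.arbiter):
            for f in version.features:
                assert extract_feature_sequence(version, f.locus_tag)[:3] == "ATG"

    def test_deterministic(self):
        a = generate_annotation_fixture((3, 2, 1, 5, 2), seed=9)
        b = generate_annotation_fixture((3, 2, 1, 5, 2), seed=9)
        assert a.original.sequence == b.original.sequence
        assert [
            (f.locus_tag, f.start, f.end) for f in a.new.features
        ] == [(f.locus_tag, f.start, f.end) for f in b.new.features]


class TestPseudogeneFixture:
    def test_truncated_loci_fail_six_frame_intact_scan(self, pseudogene_fixture_small):
        """Independent oracle: no reading frame of a genuinely defective locus
        yields a stop-free ORF covering most of its homolog."""
        fx = pseudogene_fixture_small
        panel = dict(fx.homolog_panel)
        for case in fx.cases:
            if case.truth_kind != "extra_truncated":
                continue
            ref = panel[f"ref_trunc_{case.locus_tag[-3:]}"]
            ref_words = {ref[i : i + 15] for i in range(len(ref) - 14)}
            nt = case.nucleotide
            best_homologous_orf = 0
            for frame_seq in (nt, str(Seq(nt).reverse_complement())):
                for off in range(3):
                    sub = frame_seq[off:]
                    sub = sub[: len(sub) - len(sub) % 3]
                    prot = str(Seq(sub).translate(table=11))
                    for stretch in prot.split("*"):
                        # only stop-free stretches that actually resemble the
                        # homolog count as a candidate intact product
                        if any(
                            stretch[i : i + 15] in ref_words
                            for i in range(0, max(len(stretch) - 14, 0), 5)
                        ):
                            best_homologous_orf = max(best_homologous_orf, len(stretch))
            assert best_homologous_orf < 0.9 * len(ref)

    def test_shared_cases_have_internal_stop(self, pseudogene_fixture_small):
        for case in pseudogene_fixture_small.cases:
            if case.truth_kind == "shared":
                nt = case.nucleotide
                body = nt[: len(nt) - 3]
                prot = str(Seq(body[: len(body) - len(body) % 3]).translate(table=11))
                assert "*" in prot

    def test_empty_ledger(self):
        fx = generate_pseudogene_ledger(0, 0, 0, seed=1)
        assert fx.cases == [] and fx.homolog_panel == []
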