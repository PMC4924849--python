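"""Reconciliation rules, symmetry/order-independence, pseudogene adjudication."""

import collections
import random

import pytest

from synmend.annotation_reconcile import (
    AnnotationCase,
    HomologyThresholds,
    LedgerArithmeticError,
    ReconcileError,
    adjudicate_ledger,
    adjudicate_pseudogene,
    final_census,
    pair_annotation_cases,
    reinstate_omitted_genes,
    resolve_all,
    resolve_start_codon,
)
from synmend.genome_model import AnnotatedGenome, Feature, translate_cds
from synmend.synthetic_data import generate_annotation_fixture


def _case(orig, new, key=(500, "+")):
    return AnnotationCase(key, "lo", "ln", orig, new)


def _arbiter_with(start, key=(500, "+")):
    stop, strand = key
    if strand == "+":
        f = Feature("a", "CDS", start, stop, "+")
    else:
        f = Feature("a", "CDS", stop, start, "-")
    seq = "ACGT" * 200
    return AnnotatedGenome("fixture", seq, circular=False, features=[f])


class TestResolveStartCodon:
    @pytest.mark.parametrize(
        "orig,new,arb,rule,ambiguous",
        [
            (100, 91, 91, "adopt_new", False),
            (100, 91, 100, "retain_original", False),
            (100, 91, 85, "default_new_ambiguous", True),
            (100, 100, 100, "identical", False),
        ],
    )
    def test_rule_table(self, orig, new, arb, rule, ambiguous):
        decision = resolve_start_codon(_case(orig, new), _arbiter_with(arb))
        assert decision.rule_applied == rule
        assert decision.ambiguous is ambiguous

    def test_missing_arbiter_defaults_to_new(self):
        decision = resolve_start_codon(_case(100, 91), None)
        assert decision.rule_applied == "default_new_ambiguous"
        assert decision.chosen_start == 91

    def test_category_symmetric_under_version_swap(self, annotation_fixture_small):
        fx = annotation_fixture_small
        cases, _, _ = pair_annotation_cases(fx.original, fx.new)
        swapped, _, _ = pair_annotation_cases(fx.new, fx.original)
        rules = collections.Counter(
            d.rule_applied for d in resolve_all(cases, fx.arbiter)
        )
        rules_sw = collections.Counter(
            d.rule_applied for d in resolve_all(swapped, fx.arbiter)
        )
        assert rules["adopt_new"] == rules_sw["retain_original"]
        assert rules["retain_original"] == rules_sw["adopt_new"]
        assert rules["default_new_ambiguous"] == rules_sw["default_new_ambiguous"]
        assert rules["identical"] == rules_sw["identical"]

    def test_order_independence(self, annotation_fixture_small):
        fx = annotation_fixture_small
        cases, _, _ = pair_annotation_cases(fx.original, fx.new)
        shuffled = list(cases)
        random.Random(99).shuffle(shuffled)
        a = {d.case.key: d.rule_applied for d in resolve_all(cases, fx.arbiter)}
        b = {d.case.key: d.rule_applied for d in resolve_all(shuffled, fx.arbiter)}
        assert a == b


class TestPairing:
    def test_identical_annotations_all_identical(self, annotation_fixture_small):
        fx = annotation_fixture_small
        cases, omitted, new_genes = pair_annotation_cases(fx.original, fx.original)
        assert omitted == [] and new_genes == []
        assert all(not c.differing for c in cases)

    def test_fixture_counts_recovered(self, annotation_fixture_small):
        fx = annotation_fixture_small
        cases, omitted, new_genes = pair_annotation_cases(fx.original, fx.new)
        decisions = resolve_all(cases, fx.arbiter)
        rules = collections.Counter(d.rule_applied for d in decisions)
        assert sum(1 for c in cases if c.differing) == 12 + 7 + 4
        assert rules["adopt_new"] == 12
        assert rules["retain_original"] == 7
        assert rules["default_new_ambiguous"] == 4
        assert rules["identical"] == 30
        assert len(omitted) == 9

    def test_empty_annotation(self, annotation_fixture_small):
        fx = annotation_fixture_small
        empty = AnnotatedGenome(
            "fixture", fx.original.sequence, circular=False, features=[]
        )
        cases, omitted, new_genes = pair_annotation_cases(fx.original, empty)
        assert cases == [] and new_genes == []
        assert len(omitted) == len(
            [f for f in fx.original.features if f.ftype == "CDS"]
        )

    def test_different_sequence_lengths_rejected(self, annotation_fixture_small):
        fx = annotation_fixture_small
        other = AnnotatedGenome("x", "ACGT" * 100, circular=False, features=[])
        with pytest.raises(ReconcileError):
            pair_annotation_cases(fx.original, other)


class TestPseudogeneAdjudication:
    def test_fixture_verdicts_match_planted_kinds(self, pseudogene_fixture_small):
        fx = pseudogene_fixture_small
        results = adjudicate_ledger(fx.cases, fx.homolog_panel)
        for case, res in zip(fx.cases, results):
            expected = "valid_gene" if case.truth_kind == "extra_split" else "pseudogene"
            assert res.verdict == expected, case.locus_tag

    def test_split_gene_rescue_fields(self, pseudogene_fixture_small):
        fx = pseudogene_fixture_small
        results = adjudicate_ledger(fx.cases, fx.homolog_panel)
        for case, res in zip(fx.cases, results):
            if case.truth_kind == "extra_split":
                assert res.full_length_match_to_alternative_family
                assert not res.has_internal_stop

    def test_intact_full_length_gene_is_valid(self):
        panel = [("ref", "MKVLATTTTGWWAELRNDKKEQVV" * 10)]
        nt_panel_gene = "".join(
            {
                "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "G": "GGT",
                "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT", "Q": "CAA",
                "R": "CGT", "T": "ACT", "V": "GTT", "W": "TGG",
            }[a]
            for a in panel[0][1]
        ) + "TAA"
        res = adjudicate_pseudogene("x", nt_panel_gene, "new_only", panel)
        assert res.verdict == "valid_gene"
        assert res.best_homolog_coverage > 0.99

    def test_internal_stop_is_pseudogene(self):
        panel = [("ref", "MKVLATTTTGWWAELRNDKKEQVV" * 10)]
        body = "ATGAAAGTT" * 50
        nt = body[:90] + "TAA" + body[93:] + "TAA"
        res = adjudicate_pseudogene("x", nt, "new_only", panel)
        assert res.verdict == "pseudogene"
        assert res.has_internal_stop

    def test_empty_panel_rejected(self):
        with pytest.raises(ReconcileError):
            adjudicate_pseudogene("x", "ATGAAATAA", "both", [])


class TestReinstatement:
    def test_identical_protein_is_kept(self):
        prot = "MKVLATTTTGWWAELRNDKKEQVV" * 6
        kept, dropped = reinstate_omitted_genes(
            [("locus", prot)], [("hom", prot)]
        )
        assert kept == ["locus"] and dropped == []

    def test_random_protein_is_dropped(self, pseudogene_fixture_small):
        import numpy as np

        rng = np.random.default_rng(77)
        junk = "".join("ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, 150))
        kept, dropped = reinstate_omitted_genes(
            [("junk", junk)], pseudogene_fixture_small.homolog_panel
        )
        assert kept == []
        assert dropped[0][1] == "no_homology_support"

    def test_fixture_omitted_genes_all_reinstated(self, annotation_fixture_small):
        fx = annotation_fixture_small
        _, omitted, _ = pair_annotation_cases(fx.original, fx.new)
        prots = [(tag, translate_cds(fx.original, tag)) for tag in omitted]
        kept, dropped = reinstate_omitted_genes(prots, fx.homolog_panel)
        assert sorted(kept) == sorted(omitted)

    def test_empty_omitted_list(self):
        kept, dropped = reinstate_omitted_genes([], [("h", "MKVL" * 20)])
        assert kept == [] and dropped == []


class TestFinalCensus:
    def test_ledger_arithmetic(self, annotation_fixture_small, pseudogene_fixture_small):
        fx = annotation_fixture_small
        cases, _, _ = pair_annotation_cases(fx.original, fx.new)
        decisions = resolve_all(cases, fx.arbiter)
        pseudo = adjudicate_ledger(
            pseudogene_fixture_small.cases, pseudogene_fixture_small.homolog_panel
        )
        out = final_census(fx.new, decisions, pseudo, n_shared_pseudogenes=5)
        led = out["start_codon_ledger"]
        assert led["differing"] == (
            led["adopt_new"] + led["retain_original"] + led["default_new_ambiguous"]
        )
        pg = out["pseudogene_ledger"]
        assert pg["retained"] == 5 + 3  # shared + confirmed truncated extras
        assert pg["rescued_valid_genes"] == 4

    def test_declared_shared_count_enforced(
        self, annotation_fixture_small, pseudogene_fixture_small
    ):
        fx = annotation_fixture_small
        cases, _, _ = pair_annotation_cases(fx.original, fx.new)
        decisions = resolve_all(cases, fx.arbiter)
        pseudo = adjudicate_ledger(
            pseudogene_fixture_small.cases, pseudogene_fixture_small.homolog_panel
        )
        with pytest.raises(LedgerArithmeticError):
            final_census(fx.new, decisions, pseudo, n_shared_pseudogenes=6)

    def test_empty_annotation_census(self):
        g = AnnotatedGenome("e", "ACGTACGT", circular=False, features=[])
        out = final_census(g, [])
        assert out["census"]["rrna_operon_count"] == 0
        assert out["start_codon_ledger"]["differing"] == 0
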