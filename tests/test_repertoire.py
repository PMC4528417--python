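"""Clonal clustering, evaluation table semantics and repertoire summaries."""

import numpy as np
import pytest

from vdjplace.classify import RearrangementCall
from vdjplace.dregion import DCall
from vdjplace.mapping import JunctionSpec
from vdjplace.repertoire import (
    aggregate_clone_support,
    cluster_by_shared_rearrangement,
    credible_set_sizes,
    evaluate_assignments,
    summarize_repertoire,
)


def make_call(read_id, best_v, best_j, credible=None, d=None, cdr3_len=12,
              productive=True, support=0.9):
    credible = credible if credible is not None else [(best_v, best_j, support)]
    junction = JunctionSpec(
        nucleotides="ACG" * cdr3_len, amino_acids="", cdr3_interior="X" * cdr3_len,
        cdr3_length=cdr3_len, terminating_rule="J-motif", start=0, end=0,
    )
    d_call = DCall(alleles=[(d, "forward", 40.0)]) if d else DCall()
    return RearrangementCall(
        read_id=read_id, best_v=best_v, best_j=best_j,
        v_support=support, j_support=support, rearrangement_support=support,
        credible_set=credible, d_call=d_call, junction=junction,
        productive=productive, orientation="+", mapping_score=100.0,
    )


class TestClustering:
    def test_shared_pair_joins_two_reads(self):
        a = make_call("a", "IGHV1-2*01", "IGHJ4*02")
        b = make_call(
            "b", "IGHV1-3*01", "IGHJ4*02",
            credible=[("IGHV1-2*01", "IGHJ4*02", 0.5),
                      ("IGHV1-3*01", "IGHJ4*02", 0.5)],
        )
        g = cluster_by_shared_rearrangement([a, b])
        assert g.graph.has_edge("a", "b")
        assert g.components == [{"a", "b"}]

    def test_disjoint_credible_sets_stay_singletons(self):
        calls = [
            make_call("a", "IGHV1-1*01", "IGHJ1*01"),
            make_call("b", "IGHV2-1*01", "IGHJ2*01"),
            make_call("c", "IGHV3-1*01", "IGHJ1*01"),  # same J, different V
        ]
        g = cluster_by_shared_rearrangement(calls)
        assert g.n_components == 3

    def test_clustering_is_order_invariant(self, rng):
        calls = []
        for k in range(12):
            pair = (f"IGHV{k % 3 + 1}-1*01", "IGHJ1*01")
            calls.append(make_call(f"r{k}", *pair))
        base = cluster_by_shared_rearrangement(calls).components
        for _ in range(3):
            perm = [calls[i] for i in rng.permutation(len(calls))]
            assert cluster_by_shared_rearrangement(perm).components == base

    def test_transitive_sharing_merges_chains(self):
        # a~b share P1, b~c share P2: one component of three
        a = make_call("a", "IGHV1-1*01", "IGHJ1*01")
        b = make_call("b", "IGHV1-1*01", "IGHJ1*01",
                      credible=[("IGHV1-1*01", "IGHJ1*01", 0.5),
                                ("IGHV1-2*01", "IGHJ1*01", 0.5)])
        c = make_call("c", "IGHV1-2*01", "IGHJ1*01")
        g = cluster_by_shared_rearrangement([a, b, c])
        assert g.components == [{"a", "b", "c"}]


class TestCloneSupport:
    def test_single_read_reports_its_own_credible_set(self):
        call = make_call("a", "IGHV1-1*01", "IGHJ1*01", support=0.8)
        df = aggregate_clone_support([call])
        assert df.iloc[0]["mean_support"] == pytest.approx(0.8)

    def test_mean_support_averages_over_all_reads(self):
        a = make_call("a", "IGHV1-1*01", "IGHJ1*01",
                      credible=[("IGHV1-1*01", "IGHJ1*01", 0.6)])
        b = make_call("b", "IGHV1-1*01", "IGHJ1*01",
                      credible=[("IGHV1-1*01", "IGHJ1*01", 0.2)])
        df = aggregate_clone_support([a, b])
        row = df[(df.v == "IGHV1-1*01") & (df.j == "IGHJ1*01")].iloc[0]
        assert row["mean_support"] == pytest.approx(0.4)
        assert row["best_count"] == 2

    def test_true_pair_dominates_when_best_everywhere(self):
        calls = [
            make_call(f"r{k}", "IGHV2-1*01", "IGHJ1*01",
                      credible=[("IGHV2-1*01", "IGHJ1*01", 0.7),
                                ("IGHV2-2*01", "IGHJ1*01", 0.2)])
            for k in range(5)
        ]
        df = aggregate_clone_support(calls)
        assert (df.iloc[0]["v"], df.iloc[0]["j"]) == ("IGHV2-1*01", "IGHJ1*01")
        assert df.iloc[0]["mean_support"] > df.iloc[1]["mean_support"]


def truth_for(calls, v=None, d="IGHD1-1*01", j=None):
    return {
        c.read_id: {
            "v": v or c.best_v, "d": d, "j": j or c.best_j,
        }
        for c in calls
    }


class TestEvaluation:
    def test_all_correct_gives_clean_rows(self):
        calls = [make_call(f"r{k}", "IGHV1-1*01", "IGHJ1*01", d="IGHD1-1*01")
                 for k in range(4)]
        table = evaluate_assignments(calls, truth_for(calls)).table
        for region in ("V", "D", "J"):
            assert table.loc[region, "correct_top"] == 100.0
            assert table.loc[region, "wrong"] == 0.0
            assert table.loc[region, "no_assignment"] == 0.0

    def test_wrong_allele_right_gene_counts_wrong_not_wrong_gene(self):
        calls = [make_call(f"r{k}", "IGHV1-1*01", "IGHJ1*01", d="IGHD1-1*01")
                 for k in range(4)]
        truth = truth_for(calls)
        truth["r0"]["v"] = "IGHV1-1*02"  # same gene, different allele
        table = evaluate_assignments(calls, truth).table
        assert table.loc["V", "wrong"] == 25.0
        assert table.loc["V", "wrong_gene"] == 0.0

    def test_synonymous_alleles_count_correct(self):
        calls = [make_call("r0", "IGHV1-1*01", "IGHJ1*01", d="IGHD1-1*01")]
        truth = {"r0": {"v": "IGHV1-1*03", "d": "IGHD1-1*01", "j": "IGHJ1*01"}}
        synonyms = {"IGHV1-1*03": "IGHV1-1*01"}
        table = evaluate_assignments(calls, truth, synonyms).table
        assert table.loc["V", "correct_top"] == 100.0

    def test_ancestral_gene_label_tallied_separately(self):
        calls = [make_call("r0", "IGHV1-1", "IGHJ1*01", d="IGHD1-1*01")]
        table = evaluate_assignments(calls, truth_for(
            calls, v="IGHV1-1*02")).table
        assert table.loc["V", "ancestral"] == 100.0
        assert table.loc["V", "wrong"] == 0.0

    def test_correct_in_credible_counted_when_outweighed(self):
        calls = [make_call(
            "r0", "IGHV1-2*01", "IGHJ1*01", d="IGHD1-1*01",
            credible=[("IGHV1-2*01", "IGHJ1*01", 0.6),
                      ("IGHV1-1*01", "IGHJ1*01", 0.4)],
        )]
        table = evaluate_assignments(
            calls, truth_for(calls, v="IGHV1-1*01")).table
        assert table.loc["V", "correct_in_credible"] == 100.0
        assert table.loc["V", "correct"] == 100.0
        assert table.loc["V", "correct_top"] == 0.0

    def test_rows_sum_to_one_hundred(self, rng):
        calls = []
        vs = ["IGHV1-1*01", "IGHV1-1", "IGHV2-1*01"]
        for k in range(20):
            calls.append(make_call(
                f"r{k}", vs[rng.integers(0, 3)], "IGHJ1*01",
                d="IGHD1-1*01" if rng.random() < 0.7 else None,
            ))
        table = evaluate_assignments(
            calls, truth_for(calls, v="IGHV1-1*01")).table
        sums = (
            table["correct"] + table["ancestral"] + table["wrong"]
            + table["no_assignment"]
        )
        assert np.allclose(sums, 100.0, atol=0.01)

    def test_missing_truth_record_is_an_error(self):
        calls = [make_call("mystery", "IGHV1-1*01", "IGHJ1*01")]
        with pytest.raises(ValueError, match="mystery"):
            evaluate_assignments(calls, {})

    def test_unmappable_reads_count_as_no_assignment(self):
        calls = [make_call("r0", "IGHV1-1*01", "IGHJ1*01", d="IGHD1-1*01")]
        truth = truth_for(calls)
        truth["lost"] = {"v": "IGHV1-1*01", "d": "IGHD1-1*01", "j": "IGHJ1*01"}
        table = evaluate_assignments(calls, truth).table
        assert table.loc["V", "no_assignment"] == 50.0


class TestSummary:
    def test_uniform_calls_have_unit_frequency_at_every_level(self):
        calls = [make_call(f"r{k}", "IGHV3-2*01", "IGHJ2*02")
                 for k in range(5)]
        s = summarize_repertoire(calls)
        assert s["v"]["family"]["IGHV3"] == pytest.approx(1.0)
        assert s["v"]["gene"]["IGHV3-2"] == pytest.approx(1.0)
        assert s["v"]["allele"]["IGHV3-2*01"] == pytest.approx(1.0)
        assert s["productive_fraction"] == 1.0

    def test_mixed_composition_recovers_constructed_proportions(self):
        calls = (
            [make_call(f"a{k}", "IGHV1-1*01", "IGHJ1*01") for k in range(3)]
            + [make_call(f"b{k}", "IGHV1-2*01", "IGHJ1*01") for k in range(1)]
        )
        s = summarize_repertoire(calls)
        assert s["v"]["allele"]["IGHV1-1*01"] == pytest.approx(0.75)
        assert s["v"]["allele"]["IGHV1-2*01"] == pytest.approx(0.25)
        assert s["v"]["family"]["IGHV1"] == pytest.approx(1.0)

    def test_family_frequency_dominates_member_genes(self):
        calls = (
            [make_call(f"a{k}", "IGHV1-1*01", "IGHJ1*01") for k in range(3)]
            + [make_call(f"b{k}", "IGHV1-2*01", "IGHJ1*01") for k in range(2)]
            + [make_call(f"c{k}", "IGHV2-1*01", "IGHJ1*01") for k in range(1)]
        )
        s = summarize_repertoire(calls)
        for fam, freq in s["v"]["family"].items():
            member_max = max(
                (f for g, f in s["v"]["gene"].items()
                 if g.startswith(fam + "-")),
                default=0.0,
            )
            assert freq >= member_max - 1e-12

    def test_cdr3_histogram_counts_lengths(self):
        calls = [make_call(f"r{k}", "IGHV1-1*01", "IGHJ1*01", cdr3_len=10 + k % 2)
                 for k in range(6)]
        s = summarize_repertoire(calls)
        assert s["cdr3_length_histogram"] == {"10": 3, "11": 3}

    def test_credible_set_sizes_count_distinct_region_labels(self):
        call = make_call(
            "r0", "IGHV1-1*01", "IGHJ1*01",
            credible=[("IGHV1-1*01", "IGHJ1*01", 0.5),
                      ("IGHV1-1*01", "IGHJ1*02", 0.3),
                      ("IGHV1-2*01", "IGHJ1*01", 0.2)],
        )
        assert credible_set_sizes([call], "V")[0] == 2
        assert credible_set_sizes([call], "J")[0] == 2
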