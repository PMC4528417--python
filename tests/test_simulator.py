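"""Repertoire simulator: rearrangements, retention filters, S5F mutation."""

import numpy as np
import pytest
from scipy import stats

from vdjplace.simulate import (
    RearrangementParams,
    S5FModel,
    _inverse_gene_weights,
    geometric_lengths,
    passes_filters,
    s5f_mutate,
    simulate_clones,
    simulate_rearrangement,
    simulate_repertoire,
    simulate_simple,
)


def degenerate_params():
    zero = np.zeros(3)
    zero[0] = 1.0
    return RearrangementParams(
        del_v3=zero, del_d5=zero, del_d3=zero, del_j5=zero,
        n1_len=zero, n2_len=zero,
    )


class TestSimple:
    def test_cartesian_product_of_primary_alleles(self, small_bundle):
        reads = simulate_simple(small_bundle)
        expected = (
            len(small_bundle.primary_v)
            * len(small_bundle.primary_d)
            * len(small_bundle.primary_j)
        )
        assert len(reads) == expected
        assert len({r.read_id for r in reads}) == expected

    def test_each_read_starts_with_its_v_allele(self, small_bundle):
        for r in simulate_simple(small_bundle)[:20]:
            v = small_bundle.v_alignment.ungapped(r.truth.true_v)
            assert r.sequence.startswith(v)
            j = small_bundle.j_alignment.ungapped(r.truth.true_j)
            assert r.sequence.endswith(j)


class TestRealistic:
    def test_degenerate_distributions_reduce_to_concatenation(
        self, small_bundle
    ):
        rng = np.random.default_rng(0)
        sim = simulate_rearrangement(small_bundle, degenerate_params(), rng)
        assert sim is not None
        t = sim.truth
        v = small_bundle.v_alignment.ungapped(t.true_v)
        d = small_bundle.d_forward()[t.true_d]
        j = small_bundle.j_alignment.ungapped(t.true_j)
        assert sim.sequence == v + d + j
        assert (t.del_v3, t.del_d5, t.del_d3, t.del_j5) == (0, 0, 0, 0)
        assert t.n1 == t.n2 == ""

    def test_unmutated_read_reassembles_from_truth(self, bundle):
        rng = np.random.default_rng(1)
        for _ in range(10):
            sim = simulate_rearrangement(bundle, RearrangementParams(), rng)
            t = sim.truth
            v = bundle.v_alignment.ungapped(t.true_v)
            d = bundle.d_forward()[t.true_d]
            j = bundle.j_alignment.ungapped(t.true_j)
            rebuilt = (
                v[: len(v) - t.del_v3] + t.n1
                + d[t.del_d5: len(d) - t.del_d3 or None] + t.n2
                + j[t.del_j5:]
            )
            assert sim.sequence == rebuilt

    def test_every_emitted_read_passes_retention_filters(self, bundle):
        reads = simulate_repertoire(bundle, RearrangementParams(), 15, 0,
                                    seed=3)
        for r in reads:
            assert passes_filters(r.sequence, RearrangementParams().cdr3_regex)

    def test_inverse_weights_make_genes_equiprobable(self):
        names = [
            "IGHD1-1*01", "IGHD1-1*02", "IGHD1-1*03", "IGHD1-1*04",
            "IGHD2-2*01",
        ]
        w = _inverse_gene_weights(names)
        assert np.isclose(w[:4].sum(), 0.5)
        assert np.isclose(w[4], 0.5)
        # binomial check on seeded draws: gene 2 hit ~half the time
        rng = np.random.default_rng(5)
        draws = rng.choice(len(names), size=10_000, p=w)
        frac_gene2 = np.mean(draws == 4)
        se = np.sqrt(0.5 * 0.5 / 10_000)
        assert abs(frac_gene2 - 0.5) < 3 * se

    def test_seeded_determinism(self, bundle):
        a = simulate_repertoire(bundle, RearrangementParams(), 8, 10, seed=7)
        b = simulate_repertoire(bundle, RearrangementParams(), 8, 10, seed=7)
        assert [(r.read_id, r.sequence) for r in a] == [
            (r.read_id, r.sequence) for r in b
        ]
        c = simulate_repertoire(bundle, RearrangementParams(), 8, 10, seed=8)
        assert [r.sequence for r in a] != [r.sequence for r in c]

    def test_malformed_distribution_rejected_at_load(self):
        with pytest.raises(ValueError, match="probability"):
            RearrangementParams(del_v3=np.array([0.5, 0.4]))

    def test_geometric_lengths_have_requested_mean(self):
        probs = geometric_lengths(2.0, max_len=60)
        assert np.isclose(probs.sum(), 1.0)
        assert np.isclose(np.arange(61) @ probs, 2.0, atol=0.05)


class TestS5F:
    def test_zero_mutations_is_identity(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
        assert s5f_mutate(seq, 0, S5FModel.uniform(), rng) == seq

    def test_hamming_distance_exactly_n_mut(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        out = s5f_mutate(seq, 40, S5FModel.uniform(), rng)
        assert sum(a != b for a, b in zip(seq, out)) == 40

    def test_terminal_two_positions_never_mutated(self, rng):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 30))
        for _ in range(50):
            out = s5f_mutate(seq, 10, S5FModel.uniform(), rng)
            assert out[:2] == seq[:2] and out[-2:] == seq[-2:]

    def test_uniform_model_spreads_positions_uniformly(self):
        rng = np.random.default_rng(0)
        L = 200
        seq = "A" * L
        counts = np.zeros(L)
        n_reads = 300
        for _ in range(n_reads):
            out = s5f_mutate(seq, 20, S5FModel.uniform(), rng)
            counts += np.frombuffer(out.encode(), dtype=np.uint8) != ord("A")
        assert counts[:2].sum() == 0 and counts[-2:].sum() == 0
        interior = counts[2:-2]
        chi2 = ((interior - interior.mean()) ** 2 / interior.mean()).sum()
        # generous chi-square bound: reject only gross non-uniformity
        assert chi2 < stats.chi2.ppf(0.999, df=len(interior) - 1)

    def test_hot_fivemer_attracts_first_mutation(self):
        rng = np.random.default_rng(1)
        seq = "A" * 20 + "ACGTA" + "A" * 20  # unique central 5-mer at 20..25
        model = S5FModel(
            mutability={"ACGTA": 1.0},
            substitution={},
        )
        # missing 5-mers get mutability 0 -> the hot centre must be chosen
        hits = 0
        for _ in range(200):
            out = s5f_mutate(seq, 1, model, rng)
            diff = [i for i, (a, b) in enumerate(zip(seq, out)) if a != b]
            hits += diff == [22]
        assert hits == 200

    def test_all_zero_mutability_is_an_error(self, rng):
        model = S5FModel(mutability={"AAAAA": 0.0}, substitution={})
        with pytest.raises(ValueError, match="mutability"):
            s5f_mutate("CCCCCCCCCC", 1, model, rng)

    def test_substitution_profile_must_normalise(self):
        with pytest.raises(ValueError, match="sums to"):
            S5FModel(mutability={}, substitution={"AAAAA": {"C": 0.5}})


class TestClones:
    def test_clone_counts_and_shared_truth(self, bundle):
        reads = simulate_clones(bundle, RearrangementParams(), n_clones=3,
                                clone_size=5, n_mut=10, seed=2)
        assert len(reads) == 15
        clone_ids = {r.truth.clone_id for r in reads}
        assert len(clone_ids) == 3
        for cid in clone_ids:
            members = [r for r in reads if r.truth.clone_id == cid]
            assert len({(m.truth.true_v, m.truth.true_d, m.truth.true_j)
                        for m in members}) == 1

    def test_within_clone_hamming_bounded_by_twice_mutation_load(self, bundle):
        n_mut = 12
        reads = simulate_clones(bundle, RearrangementParams(), n_clones=2,
                                clone_size=4, n_mut=n_mut, seed=4)
        by_clone = {}
        for r in reads:
            by_clone.setdefault(r.truth.clone_id, []).append(r.sequence)
        for seqs in by_clone.values():
            for a in seqs:
                for b in seqs:
                    assert sum(x != y for x, y in zip(a, b)) <= 2 * n_mut

    def test_single_member_clone_degenerates_to_plain_simulation(self, bundle):
        reads = simulate_clones(bundle, RearrangementParams(), n_clones=2,
                                clone_size=1, n_mut=5, seed=6)
        assert len(reads) == 2
        for r in reads:
            assert r.truth.n_mutations == 5
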