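"""Homology mapping, region segmentation and junction extraction.

The alignment route is checked against a hand-written affine-gap local DP
oracle, and segmentation against constructed reads whose coordinates are
known exactly.
"""

import numpy as np
import pytest

from vdjplace.mapping import (
    MappingEngine,
    codon_align_query,
    dinucleotide_shuffle,
    segment_regions,
)
from vdjplace.reference import reverse_complement


def affine_local_dp(a: str, b: str, match=5.0, mismatch=-4.0,
                    gap_open=-10.0, gap_extend=-1.0) -> float:
    """Brute-force Gotoh local alignment score (independent oracle)."""
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)  # gap in b
    Y = np.full((n + 1, m + 1), NEG)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1],
                                       Y[i - 1, j - 1]))
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
            best = max(best, M[i, j])
    return best


@pytest.fixture(scope="module")
def engine(bundle):
    return MappingEngine(bundle)


def simple_read(bundle, v="IGHV1-1*01", d="IGHD1-1*01", j="IGHJ1*01"):
    return (
        bundle.v_alignment.ungapped(v)
        + bundle.d_alleles[d]["sequence"]
        + bundle.j_alignment.ungapped(j)
    )


class TestAlignment:
    def test_self_alignment_scores_full_identity(self, engine):
        t = engine.templates[1]
        m = codon_align_query(t.seq, t)
        assert m.score == 5.0 * len(t.seq)
        assert m.orientation == "+"
        assert all(c >= 0 for c in m.qcols)

    def test_reverse_complement_scores_identically(self, engine):
        t = engine.templates[1]
        m = codon_align_query(reverse_complement(t.seq), t)
        assert m.score == 5.0 * len(t.seq)
        assert m.orientation == "-"

    def test_internal_deletion_matches_dp_oracle(self, engine, rng):
        t = engine.templates[1]
        q = t.seq[:90] + t.seq[93:180]  # one internal 3-nt deletion
        m = codon_align_query(q, t)
        assert m.score == affine_local_dp(t.seq, q)
        # the deletion is reproduced: columns jump by 3 at the gap
        cols = [c for c in m.qcols if c >= 0]
        diffs = np.diff(cols)
        assert np.sum(diffs == 4) == 1  # one 3-column jump (+1 step)

    @pytest.mark.parametrize("seed", range(4))
    def test_random_pairs_match_dp_oracle(self, engine, seed):
        rng = np.random.default_rng(seed)
        t = engine.templates[2]
        q = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        m = codon_align_query(q, t, both_strands=False)
        assert m.score == affine_local_dp(t.seq, q)


class TestBestMapping:
    def test_unmutated_read_selects_its_own_template(self, engine, bundle):
        m = engine.best_mapping(simple_read(bundle, "IGHV3-2*01", j="IGHJ2*01"))
        assert m.template.v_name == "IGHV3-2*01"
        assert m.template.j_name == "IGHJ2*01"

    def test_random_sequence_is_unmappable(self, engine, rng):
        rand = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        assert engine.best_mapping(rand) is None

    def test_mutated_reads_keep_parent_template(self, engine, bundle, rng):
        # ~10% random substitutions must rarely change the chosen template
        ok = 0
        trials = 20
        for _ in range(trials):
            read = list(simple_read(bundle, "IGHV2-3*01", j="IGHJ3*01"))
            idx = rng.choice(len(read), round(0.1 * len(read)), replace=False)
            for i in idx:
                read[i] = "ACGT"[int(rng.integers(0, 4))]
            m = engine.best_mapping("".join(read))
            if m and m.template.v_name == "IGHV2-3*01" \
                    and m.template.j_name == "IGHJ3*01":
                ok += 1
        assert ok >= int(0.95 * trials)

    def test_dinucleotide_shuffle_preserves_composition(self, rng):
        seq = "ACGTACGGTTACGATCGATCGGGTACT"
        shuf = dinucleotide_shuffle(seq, rng)
        count = lambda s: sorted((s[i:i + 2]) for i in range(len(s) - 1))
        assert sorted(shuf) == sorted(seq)
        assert count(shuf) == count(seq)


class TestSegmentation:
    def test_full_length_read_recovers_all_regions(self, engine, bundle):
        m = engine.best_mapping(simple_read(bundle))
        rm = segment_regions(m, bundle)
        bounds = bundle.v_alignment.boundaries
        # IGHV1-1*01 has no alignment gaps: columns equal query coordinates
        for name, (a, b) in bounds.items():
            assert rm.regions[name] == (a, b)
        v_len = len(bundle.v_alignment.ungapped("IGHV1-1*01"))
        assert rm.regions["junction"][0] == v_len - 3  # Cys codon start

    def test_truncation_before_fr2_drops_leading_regions(self, engine, bundle):
        read = simple_read(bundle)
        start = bundle.v_alignment.boundaries["FR2"][0] + 6
        m = engine.best_mapping(read[start:])
        rm = segment_regions(m, bundle)
        assert "FR1" not in rm.regions
        assert "CDR1" not in rm.regions
        assert "FR3" in rm.regions

    def test_insertion_in_cdr1_shifts_downstream_regions(self, engine, bundle):
        read = simple_read(bundle)
        at = bundle.v_alignment.boundaries["CDR1"][0] + 9
        inserted = read[:at] + "GGG" + read[at:]
        m0 = segment_regions(engine.best_mapping(read), bundle)
        m1 = segment_regions(engine.best_mapping(inserted), bundle)
        for name in ("FR2", "CDR2", "FR3"):
            a0, b0 = m0.regions[name]
            assert m1.regions[name] == (a0 + 3, b0 + 3)
        assert m1.regions["FR1"] == m0.regions["FR1"]

    def test_strand_invariant_region_maps(self, engine, bundle, rng):
        read = list(simple_read(bundle, "IGHV4-1*01", j="IGHJ2*01"))
        idx = rng.choice(len(read), 20, replace=False)
        for i in idx:
            read[i] = "ACGT"[int(rng.integers(0, 4))]
        read = "".join(read)
        fwd = segment_regions(engine.best_mapping(read), bundle)
        rev = segment_regions(
            engine.best_mapping(reverse_complement(read)), bundle
        )
        assert fwd.regions == rev.regions
        assert fwd.productive == rev.productive


class TestJunction:
    def _read_with_junction(self, bundle, insert="GCGAGAGATTAC"):
        # Cys codon | insert | full J (motif WGQG at J codon 7)
        v = bundle.v_alignment.ungapped("IGHV1-1*01")
        j = bundle.j_alignment.ungapped("IGHJ1*01")
        return v + insert + j

    def test_in_frame_junction_terminates_at_motif(self, engine, bundle):
        read = self._read_with_junction(bundle)
        rm = segment_regions(engine.best_mapping(read), bundle)
        assert rm.junction is not None
        assert rm.junction.terminating_rule == "J-motif"
        v_len = len(bundle.v_alignment.ungapped("IGHV1-1*01"))
        # junction = Cys codon + insert + 7 J head codons, motif excluded
        assert rm.junction.start == v_len - 3
        assert rm.junction.end == v_len + 12 + 21
        assert rm.junction.nucleotides == read[v_len - 3: v_len + 33]
        assert (rm.junction.end - rm.junction.start) % 3 == 0
        assert rm.productive

    def test_mutated_motif_falls_back_to_conserved_trp_column(
        self, engine, bundle
    ):
        read = self._read_with_junction(bundle)
        v_len = len(bundle.v_alignment.ungapped("IGHV1-1*01"))
        motif_start = v_len + 12 + 21
        assert read[motif_start:motif_start + 3] == "TGG"
        mutated = read[:motif_start] + "TTG" + read[motif_start + 3:]  # W->L
        rm = segment_regions(engine.best_mapping(mutated), bundle)
        assert rm.junction.terminating_rule == "conserved-Trp-fallback"
        assert rm.junction.end == motif_start

    def test_stop_codon_makes_read_unproductive(self, engine, bundle):
        read = self._read_with_junction(bundle, insert="GCGTAAGATTAC")
        rm = segment_regions(engine.best_mapping(read), bundle)
        assert rm.stop_codon_found
        assert not rm.productive
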