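"""Pileup, consensus calling, MSA assembly, p-distances and NJ trees."""
import numpy as np
import pandas as pd
import pytest

from strainshare import (AlignmentRecord, ConsensusSequence, PipelineConfig,
                         SGBSkipped, build_msa, call_consensus, filter_profiles,
                         nj_tree, normalized_patristic, pairwise_pdistance,
                         pileup, random_sequence, total_branch_length)
from strainshare.dna import BASES, decode, encode
from strainshare.profiling import StrainMSA

from conftest import brute_force_patristic, random_tree


def _read(start, bases, mapq=60, identity=1.0, ref="ref"):
    return AlignmentRecord("r", ref, start, len(bases), mapq, identity, "+", bases)


class TestPileup:
    def test_single_perfect_read(self, config):
        bases = "A" * 100
        pile = pileup([_read(0, bases)], 200, config)
        assert (pile.depth[:100] == 1).all() and (pile.depth[100:] == 0).all()
        assert pile.counts[:100, 0].sum() == 100

    @pytest.mark.parametrize("kwargs", [
        dict(mapq=20),                    # below mapq 30
        dict(identity=0.9),               # below 97% identity
    ])
    def test_filtered_reads_excluded_entirely(self, config, kwargs):
        pile = pileup([_read(0, "A" * 100, **kwargs)], 200, config)
        assert pile.depth.sum() == 0 and pile.n_reads_filtered == 1

    def test_short_alignment_excluded(self, config):
        pile = pileup([_read(0, "A" * 29)], 200, config)
        assert pile.depth.sum() == 0

    def test_n_and_gap_calls_contribute_nothing(self, config):
        pile = pileup([_read(0, "AN-" + "C" * 27)], 100, config)
        assert pile.depth[1] == 0 and pile.depth[2] == 0 and pile.depth[0] == 1

    def test_random_reads_match_exhaustive_tally(self, config):
        rng = np.random.default_rng(8)
        ref_len = 300
        records = []
        for _ in range(100):
            start = int(rng.integers(0, ref_len - 40))
            length = int(rng.integers(30, min(60, ref_len - start)))
            bases = decode(rng.integers(0, 6, size=length, dtype=np.uint8))
            records.append(_read(start, bases, mapq=int(rng.integers(0, 61)),
                                 identity=float(rng.uniform(0.9, 1.0))))
        pile = pileup(records, ref_len, config)
        oracle = np.zeros((ref_len, 4), dtype=int)
        for r in records:
            if r.mapq < 30 or r.identity_frac < 0.97 or r.aligned_len_nt < 30:
                continue
            for offset, ch in enumerate(r.bases):
                if ch in "ACGT":
                    oracle[r.ref_start + offset, "ACGT".index(ch)] += 1
        assert np.array_equal(pile.counts, oracle)


class TestConsensus:
    @staticmethod
    def _counts(rows):
        return np.array(rows, dtype=np.int32)

    @pytest.mark.parametrize("row,expected", [
        ([10, 0, 0, 0], "A"),   # clean call
        ([3, 2, 0, 0], "N"),    # 60% dominant < 80%
        ([4, 0, 0, 0], "N"),    # depth 4 < 5
        ([4, 1, 0, 0], "A"),    # exactly 80% dominant at depth 5 passes
        ([5, 0, 0, 0], "A"),    # depth exactly 5 passes
    ])
    def test_boundary_rules(self, config, row, expected):
        cons = call_consensus(self._counts([row]), config=config)
        assert cons.sequence == expected

    def test_called_fraction(self, config):
        counts = self._counts([[10, 0, 0, 0], [2, 2, 0, 0], [0, 0, 9, 0], [0, 0, 0, 0]])
        cons = call_consensus(counts, config=config)
        assert cons.sequence == "ANGN" and cons.called_frac == pytest.approx(0.5)

    def test_matches_brute_force_on_random_pileups(self, config):
        rng = np.random.default_rng(9)
        for _ in range(50):
            counts = rng.integers(0, 12, size=(40, 4)).astype(np.int32)
            cons = call_consensus(counts, config=config)
            for pos in range(40):
                row = counts[pos]
                depth = row.sum()
                best = int(np.argmax(row))
                if depth >= 5 and row[best] / depth >= 0.8:
                    assert cons.sequence[pos] == "ACGT"[best]
                else:
                    assert cons.sequence[pos] == "N"


class TestFilterProfiles:
    @staticmethod
    def _table(present):
        return pd.DataFrame(present).astype(float)

    def test_marker_in_too_few_samples_dropped(self, config):
        table = pd.DataFrame(1.0, index=[f"s{i}" for i in range(6)],
                             columns=[f"m{j}" for j in range(12)])
        table.loc["s0":"s1", "m0"] = 0.0  # m0 present in only 4 of 6
        samples, markers = filter_profiles(table, config)
        assert "m0" not in markers and len(samples) == 6

    def test_sample_with_too_few_markers_dropped(self, config):
        table = pd.DataFrame(1.0, index=[f"s{i}" for i in range(6)],
                             columns=[f"m{j}" for j in range(12)])
        table.loc["s0", "m0":"m2"] = 0.0  # s0 left with 9 markers
        samples, markers = filter_profiles(table, config)
        assert "s0" not in samples and len(markers) == 12

    def test_single_pass_markers_first(self, config):
        # after dropping a marker, a sample falls below 10 — markers are NOT
        # re-evaluated against the reduced sample set
        table = pd.DataFrame(1.0, index=[f"s{i}" for i in range(6)],
                             columns=[f"m{j}" for j in range(11)])
        table.loc["s0":"s1", "m0"] = 0.0   # m0 in 4 samples -> dropped
        table.loc["s2", "m1"] = 0.0        # s2 then has 9 of 10 -> dropped
        samples, markers = filter_profiles(table, config)
        assert markers == [f"m{j}" for j in range(1, 11)]
        assert samples == ["s0", "s1", "s3", "s4", "s5"]

    def test_too_few_samples_skips_sgb(self, config):
        table = pd.DataFrame(1.0, index=["s0", "s1", "s2"],
                             columns=[f"m{j}" for j in range(12)])
        with pytest.raises(SGBSkipped):
            filter_profiles(table, config)


class TestBuildMSA:
    @staticmethod
    def _msa(rows, config, markers=("m0",)):
        samples = [f"s{i}" for i in range(len(rows))]
        lengths = {m: len(rows[0]) // len(markers) for m in markers}
        consensus = {}
        for s, row in zip(samples, rows):
            consensus[s] = {}
            pos = 0
            for m in markers:
                consensus[s][m] = ConsensusSequence(s, m, row[pos:pos + lengths[m]], 1.0)
                pos += lengths[m]
        return build_msa(consensus, samples, list(markers), lengths, config=config)

    def test_no_missing_no_columns_dropped(self, config):
        msa = self._msa(["ACGT", "ACGT", "ACGT"], config)
        assert msa.retained.all()

    def test_majority_missing_column_dropped(self, config):
        rows = ["ACGT", "NCGT", "NCGT", "NCGT", "ACGT"]  # col0: 3/5 N = 60%
        msa = self._msa(rows, config)
        assert not msa.retained[0] and msa.retained[1:].all()

    def test_exactly_half_missing_retained(self, config):
        rows = ["ACGT", "NCGT", "NCGT", "ACGT"]  # col0: 2/4 = 50%, strict >
        msa = self._msa(rows, config)
        assert msa.retained.all()

    def test_missing_marker_padded_with_n(self, config):
        consensus = {"s0": {"m0": ConsensusSequence("s0", "m0", "ACGT", 1.0)}, "s1": {}}
        msa = build_msa(consensus, ["s0", "s1"], ["m0"], {"m0": 4}, config=config)
        assert decode(msa.matrix[1]) == "NNNN"


class TestPDistance:
    @staticmethod
    def _msa_from_strings(rows):
        matrix = np.vstack([encode(r) for r in rows])
        return StrainMSA("S", [f"s{i}" for i in range(len(rows))], matrix,
                         np.ones(matrix.shape[1], dtype=bool), [])

    def test_identical_rows_zero(self):
        cfg = PipelineConfig(min_overlap_cols=1)
        D = pairwise_pdistance(self._msa_from_strings(["ACGT", "ACGT"]), cfg)
        assert D[0, 1] == 0.0

    def test_single_difference(self):
        cfg = PipelineConfig(min_overlap_cols=1)
        D = pairwise_pdistance(self._msa_from_strings(["AAAA", "AAAT"]), cfg)
        assert D[0, 1] == pytest.approx(0.25)

    def test_uncalled_positions_excluded(self):
        cfg = PipelineConfig(min_overlap_cols=1)
        D = pairwise_pdistance(self._msa_from_strings(["AANA", "AANT"]), cfg)
        assert D[0, 1] == pytest.approx(1 / 3)

    def test_insufficient_overlap_flagged_nan(self):
        cfg = PipelineConfig(min_overlap_cols=4)
        D = pairwise_pdistance(self._msa_from_strings(["AANN", "NNAA"]), cfg)
        assert np.isnan(D[0, 1])

    def test_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(10)
        rows = [decode(rng.integers(0, 5, size=60, dtype=np.uint8)) for _ in range(6)]
        cfg = PipelineConfig(min_overlap_cols=1)
        D = pairwise_pdistance(self._msa_from_strings(rows), cfg)
        for i in range(6):
            for j in range(i + 1, 6):
                pairs = [(a, b) for a, b in zip(rows[i], rows[j])
                         if a in "ACGT" and b in "ACGT"]
                expect = (sum(a != b for a, b in pairs) / len(pairs)) if pairs else np.nan
                if np.isnan(D[i, j]):
                    assert not pairs
                else:
                    assert D[i, j] == pytest.approx(expect)


class TestTrees:
    def test_two_taxa_single_edge(self):
        tree = nj_tree(np.array([[0.0, 0.4], [0.4, 0.0]]), ["a", "b"])
        assert total_branch_length(tree) == pytest.approx(0.4)
        _, P = normalized_patristic(tree)
        assert P[0, 1] == pytest.approx(1.0)

    def test_additive_four_taxon_matrix_reproduced(self):
        # additive construction: ((a:1,b:2):0.5,(c:3,d:4))
        D = np.array([[0.0, 3.0, 4.5, 5.5],
                      [3.0, 0.0, 5.5, 6.5],
                      [4.5, 5.5, 0.0, 7.0],
                      [5.5, 6.5, 7.0, 0.0]])
        ids = ["a", "b", "c", "d"]
        tree = nj_tree(D, ids)
        names, P = brute_force_patristic(tree)
        order = [names.index(i) for i in ids]
        assert np.allclose(P[np.ix_(order, order)], D, atol=1e-9)

    def test_star_like_equidistant(self):
        d = 0.6
        D = np.full((3, 3), d)
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(D, ["a", "b", "c"])
        for tip in tree.tips():
            assert tip.length == pytest.approx(d / 2)

    def test_incomplete_matrix_rejected(self):
        D = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="incomplete"):
            nj_tree(D, ["a", "b"])

    def test_normalized_patristic_three_leaf_star(self):
        D = np.full((3, 3), 2.0)
        np.fill_diagonal(D, 0.0)
        tree = nj_tree(D, ["a", "b", "c"])
        _, P = normalized_patristic(tree)
        off_diag = P[~np.eye(3, dtype=bool)]
        assert np.allclose(off_diag, 2.0 / 3.0)

    def test_normalized_patristic_matches_path_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            tree = random_tree(int(rng.integers(4, 12)), rng)
            total = total_branch_length(tree)
            names_o, D_o = brute_force_patristic(tree)
            ids, P = normalized_patristic(tree)
            order = [names_o.index(i) for i in ids]
            assert np.allclose(P, D_o[np.ix_(order, order)] / total, atol=1e-12)
            assert P.max() <= 1.0 and np.allclose(np.diag(P), 0.0)

    def test_zero_length_tree_rejected(self):
        from skbio import TreeNode

        tree = TreeNode.read(["(a:0.0,b:0.0);"])
        with pytest.raises(ValueError, match="zero total branch length"):
            normalized_patristic(tree)
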