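"""Genome binning: sketching, Mash distances, clustering, taxonomy."""
import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from strainshare import (GenomeBin, GenomeRecord, MinHashSketch, PipelineConfig,
                         assign_genome, average_linkage_cluster, build_hierarchy,
                         estimate_jaccard, exclude_small_usgbs, filter_mag_quality,
                         mash_distance, mutate_sequence, pairwise_mash_matrix,
                         random_sequence, sketch_genome)
from strainshare.binning import _canonical_kmer_codes, vote_taxonomy
from strainshare.dna import revcomp


def _mag(gid, completeness, contamination, seqs=None):
    return GenomeRecord(genome_id=gid, sequences=seqs or ["ACGT" * 100],
                        source="mag", completeness_pct=completeness,
                        contamination_pct=contamination)


class TestQualityFilter:
    @pytest.mark.parametrize("completeness,contamination,expected", [
        (60, 3, True),
        (50, 3, False),   # strict >50
        (90, 5, False),   # strict <5
        (50.1, 4.9, True),
    ])
    def test_strict_boundaries(self, config, completeness, contamination, expected):
        assert filter_mag_quality(_mag("g", completeness, contamination), config) is expected

    def test_missing_quality_rejected(self, config):
        g = GenomeRecord("g", ["ACGT" * 100], source="mag")
        with pytest.raises(ValueError, match="completeness"):
            filter_mag_quality(g, config)


class TestSketch:
    def test_identical_genomes_identical_sketches(self):
        seq = random_sequence(5000, np.random.default_rng(0))
        a = sketch_genome([seq], genome_id="a")
        b = sketch_genome([seq], genome_id="b")
        assert np.array_equal(a.hashes, b.hashes)

    def test_reverse_complement_invariant(self):
        seq = random_sequence(5000, np.random.default_rng(1))
        a = sketch_genome([seq], genome_id="a")
        b = sketch_genome([revcomp(seq)], genome_id="b")
        assert np.array_equal(a.hashes, b.hashes)

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError, match="shorter than k"):
            sketch_genome(["ACGT"], genome_id="tiny")

    def test_jaccard_estimate_close_to_exact(self):
        # oracle: exact Jaccard over the full canonical k-mer sets
        rng = np.random.default_rng(2)
        a_seq = random_sequence(50_000, rng)
        b_seq = mutate_sequence(a_seq, 0.01, 3)
        k = 21
        a_set = set(_canonical_kmer_codes(a_seq, k).tolist())
        b_set = set(_canonical_kmer_codes(b_seq, k).tolist())
        exact = len(a_set & b_set) / len(a_set | b_set)
        estimate = estimate_jaccard(sketch_genome([a_seq], k=k, s=1000, genome_id="a"),
                                    sketch_genome([b_seq], k=k, s=1000, genome_id="b"))
        assert abs(estimate - exact) < 0.05


class TestMashDistance:
    @staticmethod
    def _sketch_pair(n_shared, n_total, k=21):
        # fabricate hash sets with an exact bottom-s Jaccard
        a = MinHashSketch("a", k, n_total, np.arange(n_total, dtype=np.uint64))
        b_hashes = np.concatenate([
            np.arange(n_shared, dtype=np.uint64),
            np.arange(10_000, 10_000 + n_total - n_shared, dtype=np.uint64)])
        b = MinHashSketch("b", k, n_total, np.sort(b_hashes))
        return a, b

    def test_identity_gives_zero(self):
        a, b = self._sketch_pair(1000, 1000)
        assert mash_distance(a, b) == 0.0

    def test_zero_jaccard_caps_at_one(self):
        a, b = self._sketch_pair(0, 1000)
        assert mash_distance(a, b) == 1.0

    def test_closed_form_value(self):
        # j=0.9, k=21 -> -(1/21) ln(1.8/1.9) = 0.00257...
        a, b = self._sketch_pair(900, 1000)
        assert estimate_jaccard(a, b) == pytest.approx(0.9)
        assert mash_distance(a, b) == pytest.approx(-np.log(1.8 / 1.9) / 21, abs=1e-5)

    def test_symmetry_and_k_mismatch(self):
        a, b = self._sketch_pair(500, 1000)
        assert mash_distance(a, b) == mash_distance(b, a)
        c = MinHashSketch("c", 15, 1000, np.arange(1000, dtype=np.uint64))
        with pytest.raises(ValueError, match="different k"):
            mash_distance(a, c)


def brute_force_average_linkage(D, threshold):
    """Naive oracle: rescan all cluster pairs each step, merge the smallest
    strictly-below-threshold linkage, smallest-index tie-break."""
    n = len(D)
    clusters = [[i] for i in range(n)]
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = np.mean([D[i][j] for i in clusters[x] for j in clusters[y]])
                key = (d, min(clusters[x]), min(clusters[y]))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (d, _, _), x, y = best
        if d >= threshold:
            break
        clusters[x] = sorted(clusters[x] + clusters[y])
        del clusters[y]
    labels = [0] * n
    for c in clusters:
        for i in c:
            labels[i] = min(c)
    return labels


class TestAverageLinkage:
    def test_all_below_threshold_one_bin(self):
        D = np.full((5, 5), 0.01)
        np.fill_diagonal(D, 0.0)
        assert len(set(average_linkage_cluster(D, 0.05))) == 1

    def test_all_above_threshold_singletons(self):
        D = np.full((5, 5), 0.2)
        np.fill_diagonal(D, 0.0)
        assert len(set(average_linkage_cluster(D, 0.05))) == 5

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 0.1], [0.2, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            average_linkage_cluster(D, 0.05)

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(10)
        for trial in range(100):
            n = int(rng.integers(2, 13))
            D = rng.uniform(0, 1, size=(n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            threshold = float(rng.uniform(0.1, 0.9))
            assert average_linkage_cluster(D, threshold) == \
                brute_force_average_linkage(D.tolist(), threshold), f"trial {trial}"

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            D = rng.uniform(0, 1, size=(n, n))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0.0)
            t = float(rng.uniform(0.2, 0.8))
            ours = average_linkage_cluster(D, t)
            # scipy cuts at height <= t; emulate strict < with a nudge
            sp = fcluster(linkage(squareform(D), method="average"),
                          t=t - 1e-12, criterion="distance")
            ours_sets = {frozenset(np.flatnonzero(np.array(ours) == l)) for l in set(ours)}
            sp_sets = {frozenset(np.flatnonzero(sp == l)) for l in set(sp)}
            assert ours_sets == sp_sets


class TestAssignAndHierarchy:
    @staticmethod
    def _planted(rng, n_sgbs=3, members=4, within=0.005, center_div=0.04, length=20_000):
        ancestor = random_sequence(length, rng)
        genomes = []
        for s in range(n_sgbs):
            center = mutate_sequence(ancestor, center_div, rng)
            for m in range(members):
                seq = mutate_sequence(center, within, rng)
                genomes.append(GenomeRecord(f"S{s}_g{m}", [seq], source="mag",
                                            completeness_pct=90.0, contamination_pct=1.0))
        return genomes

    def test_assignment_below_and_above_threshold(self, config):
        rng = np.random.default_rng(12)
        base = random_sequence(20_000, rng)
        members = [mutate_sequence(base, 0.005, rng) for _ in range(3)]
        sketches = {f"m{i}": sketch_genome([s], genome_id=f"m{i}")
                    for i, s in enumerate(members)}
        bin_ = GenomeBin("SGB0001", "sgb", list(sketches))
        near = sketch_genome([mutate_sequence(base, 0.02, rng)], genome_id="near")
        far = sketch_genome([mutate_sequence(base, 0.09, rng)], genome_id="far")
        assert assign_genome(near, [bin_], sketches, config.sgb_threshold) == "SGB0001"
        assert assign_genome(far, [bin_], sketches, config.sgb_threshold) is None
        assert assign_genome(near, [], sketches, config.sgb_threshold) is None

    def test_tied_assignment_prefers_lexicographic_bin(self, config):
        rng = np.random.default_rng(13)
        base = random_sequence(10_000, rng)
        sk = {"g1": sketch_genome([base], genome_id="g1"),
              "g2": sketch_genome([base], genome_id="g2")}
        bins = [GenomeBin("SGB0002", "sgb", ["g2"]), GenomeBin("SGB0001", "sgb", ["g1"])]
        query = sketch_genome([mutate_sequence(base, 0.01, rng)], genome_id="q")
        assert assign_genome(query, bins, sk, 0.05) == "SGB0001"

    def test_planted_three_sgbs_recovered(self, config):
        rng = np.random.default_rng(14)
        genomes = self._planted(rng)
        hierarchy = build_hierarchy(genomes, config)
        planted = {g.genome_id: g.genome_id.split("_")[0] for g in genomes}
        recovered = dict(zip(hierarchy.assignments["genome_id"],
                             hierarchy.assignments["sgb_id"]))
        assert len(set(recovered.values())) == 3
        # same planted label <-> same recovered bin
        for a in planted:
            for b in planted:
                assert (planted[a] == planted[b]) == (recovered[a] == recovered[b])

    def test_nesting_refinement(self, config):
        rng = np.random.default_rng(15)
        genomes = self._planted(rng, n_sgbs=4, members=3)
        hierarchy = build_hierarchy(genomes, config)
        df = hierarchy.assignments
        assert df.groupby("sgb_id")["ggb_id"].nunique().max() == 1
        assert df.groupby("ggb_id")["fgb_id"].nunique().max() == 1

    def test_close_sgbs_share_ggb(self, config):
        rng = np.random.default_rng(16)
        base = random_sequence(20_000, rng)
        center_a = mutate_sequence(base, 0.0, rng)
        center_b = mutate_sequence(base, 0.05, rng)  # pairwise ~0.05..0.10 < 0.15
        genomes = []
        for tag, center in (("a", center_a), ("b", center_b)):
            for m in range(3):
                genomes.append(GenomeRecord(f"{tag}{m}", [mutate_sequence(center, 0.003, rng)],
                                            source="mag", completeness_pct=80.0,
                                            contamination_pct=1.0))
        hierarchy = build_hierarchy(genomes, config)
        df = hierarchy.assignments
        assert df["sgb_id"].nunique() == 2
        assert df["ggb_id"].nunique() == 1

    def test_single_genome_chain(self, config):
        g = GenomeRecord("solo", [random_sequence(5000, np.random.default_rng(0))],
                         source="mag", completeness_pct=90.0, contamination_pct=0.5)
        hierarchy = build_hierarchy([g], config)
        row = hierarchy.assignments.iloc[0]
        assert row["sgb_id"] == "SGB0001" and row["ggb_id"] == "GGB0001"
        assert row["fgb_id"] == "FGB0001"


class TestTaxonomy:
    @staticmethod
    def _tax(species, genus="G", family="Fam"):
        return ("Bacteria", "P", "C", "O", family, genus, species)

    @staticmethod
    def _hierarchy_with_refs(rng, ref_taxes, include_refless_sgb=False):
        from strainshare import build_hierarchy

        base = random_sequence(15_000, rng)
        genomes = []
        for i, tax in enumerate(ref_taxes):
            genomes.append(GenomeRecord(f"ref{i}", [mutate_sequence(base, 0.004, rng)],
                                        source="reference", taxonomy=tax))
        genomes.append(GenomeRecord("mag0", [mutate_sequence(base, 0.004, rng)],
                                    source="mag", completeness_pct=90.0,
                                    contamination_pct=1.0))
        if include_refless_sgb:
            far = mutate_sequence(base, 0.08, rng)  # own SGB, same GGB
            genomes.append(GenomeRecord("lone", [far], source="mag",
                                        completeness_pct=90.0, contamination_pct=1.0))
        return build_hierarchy(genomes, PipelineConfig())

    def test_majority_vote_species(self):
        rng = np.random.default_rng(20)
        hierarchy = self._hierarchy_with_refs(
            rng, [self._tax("X"), self._tax("X"), self._tax("Y")])
        (sgb,) = hierarchy.bins["sgb"].values()
        assert sgb.known and sgb.taxonomy[-1] == "X"
        assert sgb.deepest_rank == "species"

    def test_usgb_falls_back_to_genus_from_ggb(self):
        rng = np.random.default_rng(21)
        hierarchy = self._hierarchy_with_refs(
            rng, [self._tax("X"), self._tax("X")], include_refless_sgb=True)
        usgbs = [b for b in hierarchy.bins["sgb"].values() if not b.known]
        assert len(usgbs) == 1
        assert usgbs[0].taxonomy[5] == "G" and usgbs[0].taxonomy[6] == ""
        assert usgbs[0].deepest_rank == "genus"

    def test_vote_tie_backs_off_to_shared_rank(self):
        rng = np.random.default_rng(22)
        hierarchy = self._hierarchy_with_refs(
            rng, [self._tax("X", genus="G"), self._tax("Y", genus="G")])
        (sgb,) = hierarchy.bins["sgb"].values()
        assert sgb.taxonomy[6] == "" and sgb.taxonomy[5] == "G"
        assert sgb.deepest_rank == "genus"

    def test_no_references_anywhere_unclassified(self):
        g = GenomeRecord("m", [random_sequence(6000, np.random.default_rng(0))],
                         source="mag", completeness_pct=90.0, contamination_pct=1.0)
        hierarchy = build_hierarchy([g], PipelineConfig())
        (sgb,) = hierarchy.bins["sgb"].values()
        assert sgb.taxonomy == ("unclassified",) * 7 and not sgb.known


class TestExcludeSmallUSGBs:
    @pytest.mark.parametrize("n_members,known,kept", [
        (4, False, False),
        (5, False, True),
        (1, True, True),
    ])
    def test_rules(self, config, n_members, known, kept):
        bin_ = GenomeBin("SGB0001", "sgb", [f"g{i}" for i in range(n_members)], known=known)
        out = exclude_small_usgbs({"SGB0001": bin_}, config)
        assert ("SGB0001" in out) is kept
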