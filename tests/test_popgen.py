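"""Evaluation statistics: dissimilarity, NJ, PCA, AMOVA/PhiPT, LD r²."""

import itertools

import numpy as np
import pandas as pd
import pytest

from snppanel import popgen
from snppanel.containers import MISSING
from conftest import make_matrix


# --------------------------------------------------------------------------
# Independent oracles
# --------------------------------------------------------------------------

def brute_force_amova_ss(dosage, labels):
    """Explicit double-loop SS computation from raw dosages (complete data)."""
    n = len(labels)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d2[i, j] = sum((dosage[i, l] - dosage[j, l]) ** 2
                           for l in range(dosage.shape[1]))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d2[i, j]
    ss_total /= n
    ss_within = 0.0
    for g in sorted(set(labels)):
        idx = [i for i, lab in enumerate(labels) if lab == g]
        acc = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                acc += d2[idx[a], idx[b]]
        ss_within += acc / len(idx)
    return ss_total, ss_within


def four_point_topology(d, ids):
    """Pick the 4-taxon split minimising the sum of cherry distances."""
    a, b, c, e = ids
    sums = {
        frozenset([frozenset([a, b]), frozenset([c, e])]): d[a][b] + d[c][e],
        frozenset([frozenset([a, c]), frozenset([b, e])]): d[a][c] + d[b][e],
        frozenset([frozenset([a, e]), frozenset([b, c])]): d[a][e] + d[b][c],
    }
    return min(sums, key=sums.get)


def newick_cherries(newick, ids):
    """The split a 4-taxon unrooted tree induces, via pairwise path lengths."""
    import io
    import skbio

    tree = skbio.TreeNode.read(io.StringIO(newick))
    dm = tree.tip_tip_distances()
    # the true cherry pair has the smallest sum of within-pair distances
    best = min(
        (frozenset([frozenset(p), frozenset(set(ids) - set(p))])
         for p in itertools.combinations(ids, 2)),
        key=lambda split: sum(dm[tuple(sorted(pair))[0], tuple(sorted(pair))[1]]
                              for pair in split),
    )
    return best


# --------------------------------------------------------------------------
# Simple-matching dissimilarity
# --------------------------------------------------------------------------

class TestSimpleMatching:
    def test_identical_samples_zero(self):
        m = make_matrix([[1, 1], [2, 2], [0, 0]])
        d = popgen.simple_matching_dissimilarity(m)
        assert d.d[0, 1] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "col,d_exp,d2_exp",
        [([0, 2], 1.0, 4.0), ([0, 1], 0.5, 1.0), ([1, 1], 0.0, 0.0)],
    )
    def test_single_locus_hand_values(self, col, d_exp, d2_exp):
        m = make_matrix([col])
        dist = popgen.simple_matching_dissimilarity(m)
        assert dist.d[0, 1] == pytest.approx(d_exp)
        assert dist.d2[0, 1] == pytest.approx(d2_exp)

    def test_pairwise_complete_and_rescaling(self):
        # locus 2 incomplete: d over locus 1 only; d2 rescaled 2/1
        m = make_matrix([[0, 2], [1, MISSING]])
        dist = popgen.simple_matching_dissimilarity(m)
        assert dist.n_complete[0, 1] == 1
        assert dist.d[0, 1] == pytest.approx(1.0)
        assert dist.d2[0, 1] == pytest.approx(4.0 * 2 / 1)

    def test_zero_complete_pair_warns(self):
        m = make_matrix([[0, MISSING], [MISSING, 2]])
        with pytest.warns(UserWarning, match="zero complete"):
            dist = popgen.simple_matching_dissimilarity(m)
        assert np.isnan(dist.d[0, 1])

    def test_symmetry_and_zero_diagonal(self, two_pool_dataset):
        dist = popgen.simple_matching_dissimilarity(two_pool_dataset.matrix)
        assert np.allclose(dist.d, dist.d.T)
        assert np.allclose(np.diag(dist.d), 0.0)
        tri = dist.d[np.triu_indices(len(dist.ids), 1)]
        assert np.nanmin(tri) >= 0.0 and np.nanmax(tri) <= 1.0


class TestDissimilarityBins:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.0, "low"), (0.25, "low"), (0.3, "medium"), (0.50, "medium"),
         (0.55, "high"), (1.0, "high")],
    )
    def test_boundaries(self, d, expected):
        assert popgen.classify_dissimilarity(d) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            popgen.classify_dissimilarity(1.2)


class TestTopPairs:
    def _toy(self):
        # B1-R1 maximally dissimilar; B1-B2 nearly identical
        m = make_matrix(
            [[0, 0, 1, 2], [0, 0, 1, 2], [2, 2, 1, 0]],
            samples=["B1", "B2", "R2", "R1"],
            groups={"B1": "B", "B2": "B", "R1": "R", "R2": "R"},
        )
        return popgen.simple_matching_dissimilarity(m), m.groups

    def test_between_groups_ranks_cross_pair_first(self):
        dist, groups = self._toy()
        out = popgen.top_dissimilar_pairs(dist, groups, "between_groups", 0.5)
        assert len(out) >= 1
        assert {out.iloc[0].sample_1, out.iloc[0].sample_2} == {"B1", "R1"}
        assert out.iloc[0].dissimilarity == pytest.approx(1.0)

    def test_threshold_above_max_gives_empty(self):
        dist, groups = self._toy()
        out = popgen.top_dissimilar_pairs(dist, groups, "within_group", 0.99)
        assert out.empty

    def test_ties_break_lexicographically(self):
        dist, groups = self._toy()
        out = popgen.top_dissimilar_pairs(dist, groups, "between_groups", 0.0)
        tied = out[np.isclose(out.dissimilarity, out.dissimilarity.iloc[0])]
        pairs = list(zip(tied.sample_1, tied.sample_2))
        assert pairs == sorted(pairs)

    def test_unknown_mode_rejected(self):
        dist, groups = self._toy()
        with pytest.raises(ValueError, match="mode"):
            popgen.top_dissimilar_pairs(dist, groups, "sideways", 0.5)


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------

class TestNeighborJoining:
    def _dist(self, ids, d):
        n = len(ids)
        arr = np.zeros((n, n))
        for (i, j), v in d.items():
            arr[i, j] = arr[j, i] = v
        return popgen.DistanceMatrix(ids, arr, arr**2, np.full((n, n), 1))

    def test_three_taxa_closed_form_branch_lengths(self):
        import io
        import skbio

        ids = ["a", "b", "c"]
        dist = self._dist(ids, {(0, 1): 0.6, (0, 2): 0.8, (1, 2): 0.9})
        tree = skbio.TreeNode.read(io.StringIO(popgen.nj_tree(dist)))
        tips = {t.name: t.length for t in tree.tips()}
        # b_a = (d_ab + d_ac - d_bc)/2 etc.
        dm = tree.tip_tip_distances()
        assert dm["a", "b"] == pytest.approx(0.6, abs=1e-9)
        assert dm["a", "c"] == pytest.approx(0.8, abs=1e-9)
        assert dm["b", "c"] == pytest.approx(0.9, abs=1e-9)
        assert tips["a"] == pytest.approx((0.6 + 0.8 - 0.9) / 2, abs=1e-9)

    def test_recovers_additive_four_taxon_topologies(self):
        rng = np.random.default_rng(31)
        ids = ["a", "b", "c", "d"]
        for _ in range(25):
            # tree ((a,b),(c,d)) with random positive branch lengths
            ba, bb, bc, bd, mid = rng.uniform(0.05, 1.0, 5)
            d = {
                (0, 1): ba + bb,
                (2, 3): bc + bd,
                (0, 2): ba + mid + bc,
                (0, 3): ba + mid + bd,
                (1, 2): bb + mid + bc,
                (1, 3): bb + mid + bd,
            }
            dist = self._dist(ids, d)
            dmap = {ids[i]: {ids[j]: dist.d[i, j] for j in range(4)} for i in range(4)}
            expected = four_point_topology(dmap, ids)
            got = newick_cherries(popgen.nj_tree(dist), ids)
            assert got == expected

    def test_additive_path_lengths_reproduced(self):
        import io
        import skbio

        ids = ["a", "b", "c", "d"]
        d = {(0, 1): 0.3, (2, 3): 0.5, (0, 2): 0.9, (0, 3): 1.0,
             (1, 2): 1.0, (1, 3): 1.1}
        dist = self._dist(ids, d)
        tree = skbio.TreeNode.read(io.StringIO(popgen.nj_tree(dist)))
        dm = tree.tip_tip_distances()
        for (i, j), v in d.items():
            assert dm[ids[i], ids[j]] == pytest.approx(v, abs=1e-9)

    def test_missing_distance_names_pair(self):
        ids = ["a", "b", "c"]
        arr = np.zeros((3, 3))
        arr[0, 2] = arr[2, 0] = np.nan
        dist = popgen.DistanceMatrix(ids, arr, arr, np.full((3, 3), 1))
        with pytest.raises(ValueError, match="a and c"):
            popgen.nj_tree(dist)

    def test_fewer_than_three_samples_rejected(self):
        dist = self._dist(["a", "b"], {(0, 1): 0.5})
        with pytest.raises(ValueError, match="at least 3"):
            popgen.nj_tree(dist)


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

class TestGenotypePCA:
    def test_duplicated_sample_has_identical_scores(self):
        rng = np.random.default_rng(13)
        cols = [rng.choice([0, 1, 2], 6).tolist() for _ in range(40)]
        for c in cols:  # make every column polymorphic
            c[0], c[1] = 0, 2
        m = make_matrix(cols)
        m.dosage[5, :] = m.dosage[4, :]  # duplicate the last sample
        res = popgen.pca(m, n_components=3)
        assert np.allclose(res.scores[4], res.scores[5], atol=1e-9)

    def test_pc1_separates_strong_pools(self):
        from snppanel import sim

        cfg = sim.SimConfig(n_per_group=(20, 20), n_markers=300, fst=0.4,
                            inbreeding=0.95, missing_rate=0.0, seed=21)
        ds = sim.simulate_genotypes(cfg)
        res = popgen.pca(ds.matrix, n_components=2)
        labels = np.array([ds.matrix.groups[s] for s in ds.matrix.samples])
        pc1 = res.scores[:, 0]
        b, r = pc1[labels == "B"], pc1[labels == "R"]
        assert max(b.min(), r.min()) > min(b.max(), r.max()) or \
            max(r.min(), b.min()) > min(r.max(), b.max())
        assert (b.max() < r.min()) or (r.max() < b.min())  # zero overlap

    def test_variance_fractions_conserved(self):
        rng = np.random.default_rng(14)
        cols = [rng.choice([0, 1, 2], 8).tolist() for _ in range(30)]
        for c in cols:
            c[0], c[1] = 0, 2
        m = make_matrix(cols)
        res = popgen.pca(m, n_components=7)  # n-1 components = full spectrum
        assert res.variance_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-12).all()  # sorted descending

    def test_component_cap_warns(self):
        m = make_matrix([[0, 1, 2, 1]] * 5)
        with pytest.warns(UserWarning, match="capping"):
            res = popgen.pca(m, n_components=10)
        assert res.scores.shape[1] == 3

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(15)
        cols = [rng.choice([0, 1, 2], 10).tolist() for _ in range(50)]
        for c in cols:
            c[0], c[1] = 0, 2
        m = make_matrix(cols)
        res = popgen.pca(m, n_components=4)
        gram = res.scores.T @ res.scores
        assert np.allclose(gram, np.diag(np.diag(gram)), atol=1e-9)


# --------------------------------------------------------------------------
# AMOVA / PhiPT
# --------------------------------------------------------------------------

class TestAmova:
    def test_hand_example_two_vs_two(self):
        m = make_matrix([[0, 0, 2, 2]], samples=["a", "b", "c", "d"])
        dist = popgen.simple_matching_dissimilarity(m)
        res = popgen.amova_from_distances(dist, ["G1", "G1", "G2", "G2"], n_perm=0)
        assert res.ss_total == pytest.approx(4.0)
        assert res.ss_within == pytest.approx(0.0)
        assert res.n0 == pytest.approx(2.0)
        assert res.va == pytest.approx(2.0)
        assert res.vw == pytest.approx(0.0)
        assert res.phi_pt == pytest.approx(1.0)

    def test_agrees_with_double_loop_brute_force(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            L = int(rng.integers(3, 12))
            dosage = rng.choice([0, 1, 2], size=(n, L))
            labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
            m = make_matrix([dosage[:, j] for j in range(L)],
                            samples=[f"s{i}" for i in range(n)])
            dist = popgen.simple_matching_dissimilarity(m)
            st_o, sw_o = brute_force_amova_ss(dosage, labels)
            res = popgen.amova_from_distances(dist, labels, n_perm=0)
            assert res.ss_total == pytest.approx(st_o)
            assert res.ss_within == pytest.approx(sw_o)

    def test_from_ss_reproduces_printed_decomposition(self):
        res = popgen.amova_from_ss(13226.23, 168008.8, [195, 182])
        assert res.ms_within == pytest.approx(448.02, abs=0.005)
        assert round(res.va, 2) == 67.87
        assert round(res.phi_pt, 3) == 0.132
        assert round(res.pct_among) == 13
        assert round(res.pct_within) == 87
        assert round(res.va + res.vw, 2) == 515.89

    def test_from_ss_and_from_distances_agree(self):
        rng = np.random.default_rng(43)
        m = make_matrix([rng.choice([0, 1, 2], 12) for _ in range(20)],
                        samples=[f"s{i}" for i in range(12)])
        labels = ["A"] * 5 + ["B"] * 7
        dist = popgen.simple_matching_dissimilarity(m)
        res_d = popgen.amova_from_distances(dist, labels, n_perm=0)
        res_s = popgen.amova_from_ss(res_d.ss_among, res_d.ss_within, [5, 7])
        for attr in ("ms_among", "ms_within", "n0", "va", "vw", "phi_pt",
                     "pct_among", "pct_within"):
            assert getattr(res_s, attr) == pytest.approx(getattr(res_d, attr))

    def test_equal_group_sizes_give_n0_equal_n(self):
        res = popgen.amova_from_ss(10.0, 50.0, [30, 30])
        assert res.n0 == pytest.approx(30.0)

    def test_zero_among_ss_reports_negative_phi_unclamped(self):
        res = popgen.amova_from_ss(0.0, 100.0, [5, 5])
        assert res.va < 0 and res.phi_pt < 0

    def test_null_groups_give_small_phi_and_nonsignificant_p(self):
        from snppanel import sim

        cfg = sim.SimConfig(n_per_group=(30, 30), n_markers=200, fst=0.0,
                            inbreeding=0.95, missing_rate=0.0, seed=51)
        ds = sim.simulate_genotypes(cfg)
        dist = popgen.simple_matching_dissimilarity(ds.matrix)
        labels = [ds.matrix.groups[s] for s in ds.matrix.samples]
        res = popgen.amova_from_distances(dist, labels, n_perm=199, seed=52)
        assert abs(res.phi_pt) < 0.05
        assert res.p_perm > 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            popgen.amova_from_ss(1.0, 2.0, [5, 0])

    def test_table_shape_and_internal_consistency(self):
        res = popgen.amova_from_ss(13226.23, 168008.8, [195, 182])
        t = res.to_frame()
        assert list(t.Source) == ["Among groups", "Within groups", "Total"]
        assert t.SS.iloc[2] == pytest.approx(t.SS.iloc[0] + t.SS.iloc[1])
        assert t.df.iloc[2] == t.df.iloc[0] + t.df.iloc[1]
        assert res.pct_among + res.pct_within == pytest.approx(100.0)


# --------------------------------------------------------------------------
# LD
# --------------------------------------------------------------------------

class TestLdFilter:
    def test_het_and_missing_thresholds(self):
        ho_high = [1, 1, 0, 0, 0, 0, 0, 0, 0, 0]        # Ho = 0.2 > 0.15
        miss_high = [MISSING, MISSING, MISSING, 1, 0, 0, 0, 0, 0, 2]  # 30% missing
        clean = [0, 2, 0, 2, 0, 2, 0, 2, 1, 0]
        mono = [0] * 10
        m = make_matrix([ho_high, miss_high, clean, mono])
        out = popgen.ld_filter_markers(m)
        assert out.marker_ids() == ["m3", "m4"]  # monomorphic passes here


class TestLdR2:
    def test_marker_with_itself_r2_one(self):
        x = [0, 2, 0, 2, 1, 0]
        m = make_matrix([x, x])
        pairs = popgen.ld_r2(m)
        assert pairs.r2.iloc[0] == pytest.approx(1.0)

    def test_orthogonal_dosages_r2_zero(self):
        m = make_matrix([[0, 2, 0, 2], [0, 0, 2, 2]])
        pairs = popgen.ld_r2(m)
        assert pairs.r2.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative_correlation_r2_one(self):
        m = make_matrix([[0, 0, 2, 2], [2, 2, 0, 0]])
        pairs = popgen.ld_r2(m)
        assert pairs.r2.iloc[0] == pytest.approx(1.0)

    def test_zero_variance_pair_skipped_and_counted(self):
        m = make_matrix([[1, 1, 1, 1], [0, 1, 2, 0]])
        pairs = popgen.ld_r2(m)
        assert pairs.empty
        assert pairs.attrs["skipped"] == 1

    def test_same_chromosome_scope(self):
        m1 = make_matrix([[0, 2, 0, 2], [0, 0, 2, 2]], chrom="chr1")
        from snppanel.containers import GenotypeMatrix, MarkerRecord

        markers = list(m1.markers) + [
            MarkerRecord(id="other", chrom="chr2", pos=500, ref="A", alt="G")
        ]
        m = GenotypeMatrix(
            m1.samples, markers,
            np.column_stack([m1.dosage, np.array([0, 1, 2, 1])]),
        )
        assert len(popgen.ld_r2(m, scope="chrom")) == 1
        assert len(popgen.ld_r2(m, scope="genome")) == 3

    def test_matches_haplotype_formula_in_inbred_limit(self):
        # fully homozygous dosages = 2x haplotypes; composite r2 must equal
        # the haplotype D^2/(p1 q1 p2 q2)
        rng = np.random.default_rng(61)
        for _ in range(20):
            h1 = rng.choice([0, 1], 30)
            h2 = rng.choice([0, 1], 30)
            if h1.std() == 0 or h2.std() == 0:
                continue
            m = make_matrix([2 * h1, 2 * h2])
            pairs = popgen.ld_r2(m)
            pab = np.mean(h1 * h2)
            p1, p2 = h1.mean(), h2.mean()
            D = pab - p1 * p2
            r2_hap = D * D / (p1 * (1 - p1) * p2 * (1 - p2))
            assert pairs.r2.iloc[0] == pytest.approx(r2_hap, abs=1e-12)


class TestClassifyLd:
    @pytest.mark.parametrize(
        "r2,expected",
        [(0.95, "high"), (0.90, "high"), (0.89, "moderate"), (0.50, "moderate"),
         (0.49, "low"), (0.10, "low"), (0.05, "very_low"), (0.0, "very_low")],
    )
    def test_bin_boundaries(self, r2, expected):
        pairs = pd.DataFrame(
            {"marker_1": ["a"], "marker_2": ["b"], "chrom": ["chr1"],
             "bp_distance": [100], "r2": [r2], "p_value": [0.5]}
        )
        out, _ = popgen.classify_ld(pairs)
        assert out.bin.iloc[0] == expected

    def test_summary_counts_per_chromosome_and_genome(self):
        pairs = pd.DataFrame(
            {"marker_1": list("abcd"), "marker_2": list("efgh"),
             "chrom": ["chr1", "chr1", "chr2", "chr2"],
             "bp_distance": [10, 20, 30, 40],
             "r2": [0.95, 0.05, 0.95, 0.3], "p_value": [0.01] * 4}
        )
        _, summary = popgen.classify_ld(pairs)
        genome_high = summary[(summary.chrom == "genome") & (summary.bin == "high")]
        assert genome_high.n_pairs.iloc[0] == 2
        chr1_high = summary[(summary.chrom == "chr1") & (summary.bin == "high")]
        assert chr1_high.n_pairs.iloc[0] == 1

    def test_non_monotone_edges_rejected(self):
        pairs = pd.DataFrame({"r2": [0.5], "bp_distance": [1], "chrom": ["c"]})
        with pytest.raises(ValueError, match="edges"):
            popgen.classify_ld(pairs, edges=(0.5, 0.4, 0.9))
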