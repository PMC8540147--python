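import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.stats.ordination import pcoa as skbio_pcoa
from skbio.tree import nj as skbio_nj

from agripop.datatypes import GenotypeMatrix
from agripop.ordination import PCoA, ibs_distance, nj_tree, tree_distance_matrix

from conftest import random_additive_tree, random_gm


def _gm(dosages, mask=None):
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    return GenotypeMatrix(
        [f"S{i+1}" for i in range(n)], [f"M{j+1}" for j in range(m)], dosages, mask
    )


class TestIBS:
    def test_identical_rows_distance_zero(self):
        gm = _gm(np.tile([0, 1, 2, 1], (2, 1)))
        assert ibs_distance(gm)["S1", "S2"] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        gm = _gm(np.vstack([np.zeros(10, dtype=int), np.full(10, 2)]))
        assert ibs_distance(gm)["S1", "S2"] == 1.0

    def test_matches_per_locus_enumeration(self):
        rng = np.random.default_rng(13)
        gm = random_gm(rng, n=8, m=60, missing_rate=0.1)
        dm = ibs_distance(gm)
        for i in range(8):
            for j in range(i + 1, 8):
                sims, count = 0.0, 0
                for l in range(60):
                    if not gm.missing_mask[i, l] and not gm.missing_mask[j, l]:
                        sims += (2 - abs(int(gm.dosages[i, l]) - int(gm.dosages[j, l]))) / 2
                        count += 1
                assert dm[i, j] == pytest.approx(1 - sims / count)

    def test_entries_in_unit_interval(self):
        gm = random_gm(np.random.default_rng(1), n=10, m=40)
        d = ibs_distance(gm).data
        assert (d >= 0).all() and (d <= 1).all()

    def test_no_shared_calls_error_names_pair(self):
        mask = np.array([[False, True], [True, False]])
        gm = _gm(np.zeros((2, 2), dtype=int), mask)
        with pytest.raises(ValueError, match="S1.*S2"):
            ibs_distance(gm)


class TestPCoA:
    def test_collinear_points_recovered_on_one_axis(self):
        coords = np.array([0.0, 1.0, 3.0])
        d = np.abs(coords[:, None] - coords[None, :])
        fit = PCoA().fit(DistanceMatrix(d, list("abc")))
        assert fit.percent_variance_[0] == pytest.approx(100.0)
        ax1 = fit.coordinates_["PCo1"].to_numpy()
        got = np.abs(ax1[:, None] - ax1[None, :])
        assert np.allclose(got, d, atol=1e-9)

    def test_unit_square_splits_variance_evenly(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        fit = PCoA().fit(DistanceMatrix(d, list("abcd")))
        assert np.allclose(fit.eigenvalues_[:2], fit.eigenvalues_[0])
        assert np.allclose(fit.percent_variance_[:2], [50.0, 50.0])

    def test_label_permutation_permutes_coordinates(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        labels = list("abcdef")
        fit = PCoA().fit(DistanceMatrix(d, labels))
        perm = [3, 1, 4, 0, 5, 2]
        fit_p = PCoA().fit(DistanceMatrix(d[np.ix_(perm, perm)], [labels[i] for i in perm]))
        a = fit.coordinates_.loc[labels].to_numpy()
        b = fit_p.coordinates_.loc[labels].to_numpy()
        assert np.allclose(np.abs(a), np.abs(b), atol=1e-8)
        assert np.allclose(fit.percent_variance_, fit_p.percent_variance_)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(7, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        fit = PCoA().fit(DistanceMatrix(d, [str(i) for i in range(7)]))
        coords = fit.coordinates_.to_numpy()
        got = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.allclose(got, d, atol=1e-8)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(d, [str(i) for i in range(8)])
        ours = PCoA().fit(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        assert np.allclose(ours.eigenvalues_[:3], ref.eigvals.to_numpy()[:3], atol=1e-8)

    def test_degenerate_all_zero_distances(self):
        with pytest.raises(ValueError, match="degenerate|positive"):
            PCoA().fit(DistanceMatrix(np.zeros((4, 4)), list("abcd")))


class TestNJ:
    def test_four_taxon_exact_recovery(self):
        # tree ((A:1,B:2):5,C:3,D:4) -> additive distances
        d = DistanceMatrix(
            np.array(
                [
                    [0, 3, 9, 10],
                    [3, 0, 10, 11],
                    [9, 10, 0, 7],
                    [10, 11, 7, 0.0],
                ]
            ),
            list("ABCD"),
        )
        tree = nj_tree(d)
        got = tree_distance_matrix(tree)
        assert np.allclose(got.filter(list("ABCD")).data, d.data, atol=1e-12)
        a = tree.find("A")
        assert {t.name for t in a.parent.children} == {"A", "B"}
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxon_star_closed_form(self):
        d = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]), list("ABC"))
        tree = nj_tree(d)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_additive_matrices_inverted_exactly(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ref = random_additive_tree(rng, 10)
            d = ref.tip_tip_distances()
            tree = nj_tree(d)
            got = tree_distance_matrix(tree).filter(list(d.ids))
            assert np.allclose(got.data, d.data, atol=1e-9)

    def test_near_additive_path_lengths_correlate(self):
        rng = np.random.default_rng(12)
        ref = random_additive_tree(rng, 10)
        d = ref.tip_tip_distances().data
        noisy = d + rng.normal(0, 0.01, d.shape)
        noisy = np.triu(noisy, 1)
        noisy = noisy + noisy.T
        dm = DistanceMatrix(noisy, [f"t{i}" for i in range(10)])
        got = tree_distance_matrix(nj_tree(dm)).filter(list(dm.ids)).data
        iu = np.triu_indices(10, 1)
        r = np.corrcoef(got[iu], d[iu])[0, 1]
        assert r > 0.99

    def test_agrees_with_reference_nj_on_additive_input(self):
        rng = np.random.default_rng(30)
        ref_tree = random_additive_tree(rng, 8)
        d = ref_tree.tip_tip_distances()
        ours = tree_distance_matrix(nj_tree(d)).filter(list(d.ids))
        theirs = skbio_nj(d).tip_tip_distances().filter(list(d.ids))
        assert np.allclose(ours.data, theirs.data, atol=1e-8)

    def test_non_finite_distances_rejected(self):
        d = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            nj_tree(DistanceMatrix(d, list("abc")))
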