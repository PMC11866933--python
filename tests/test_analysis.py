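"""Chain geometry, clustering and saturation-concentration bookkeeping."""

import numpy as np
import pytest

import cocomo2 as c
from cocomo2.analysis import cluster_chains, detect_coexistence, unwrap_chain
from tests.conftest import make_state


def union_find_clusters(centers, rgs, box, factor):
    """Brute-force connected-components oracle on the thresholded pair graph.

    Edges are enumerated from the full minimum-image distance matrix and
    merged with explicit union-find; independent of the clustering path.
    """
    n = len(centers)
    delta = centers[:, None, :] - centers[None, :, :]
    if box is not None:
        delta = delta - box * np.round(delta / box)
    d = np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))
    cutoff = factor * (rgs[:, None] + rgs[None, :]) / 2
    ii, jj = np.nonzero(np.triu(d < cutoff, k=1))

    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in zip(ii.tolist(), jj.tolist()):
        parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    ids = {r: k for k, r in enumerate(dict.fromkeys(roots))}
    return np.array([ids[r] for r in roots])


def labels_equivalent(a, b):
    return len(set(zip(a.tolist(), b.tolist()))) == len(set(a.tolist())) == len(set(b.tolist()))


class TestChainGeometry:
    def test_single_bead_chain_rg_zero(self, params2):
        st = make_state(["G"], [np.array([[5.0, 5, 5]])], [20] * 3, params2)
        _, rgs = c.chain_centers_and_rg(st)
        assert rgs[0] == 0.0

    def test_two_bead_rg_half_distance(self, params2):
        st = make_state(["GG"], [np.array([[5.0, 5, 5], [6.0, 5, 5]])],
                        [20] * 3, params2)
        _, rgs = c.chain_centers_and_rg(st)
        assert rgs[0] == pytest.approx(0.5)

    def test_rg_rotation_invariant(self, params2):
        from scipy.spatial.transform import Rotation

        coil = c.make_random_coil("A" * 20, seed=3).coords
        st = make_state(["A" * 20], [coil + 10], [40] * 3, params2)
        rot = Rotation.from_euler("zyx", [11, 62, -40], degrees=True).as_matrix()
        st2 = make_state(["A" * 20], [(coil @ rot.T) + 10], [40] * 3, params2)
        _, a = c.chain_centers_and_rg(st)
        _, b = c.chain_centers_and_rg(st2)
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_chain_across_boundary_measured_whole(self, params2):
        # chain straddling the periodic boundary: same R_g as the whole chain
        coil = c.make_random_coil("A" * 16, seed=5).coords
        box = np.array([20.0] * 3)
        st_whole = make_state(["A" * 16], [coil + 10], box, params2)
        st_split = make_state(["A" * 16], [np.mod(coil + [19.5, 10, 10], box)],
                              box, params2)
        _, a = c.chain_centers_and_rg(st_whole)
        _, b = c.chain_centers_and_rg(st_split)
        assert a[0] == pytest.approx(b[0], rel=1e-9)

    def test_unwrap_restores_bond_continuity(self):
        box = np.array([10.0, 10, 10])
        coords = np.array([[9.8, 5, 5], [0.1, 5, 5], [0.4, 5, 5]])
        whole = unwrap_chain(coords, box)
        d = np.linalg.norm(np.diff(whole, axis=0), axis=1)
        assert np.all(d < 1.0)


class TestClusterChains:
    def test_two_distant_chains_both_dilute(self):
        centers = np.array([[2.0, 2, 2], [20.0, 20, 20]])
        rgs = np.array([1.0, 1.0])
        res = cluster_chains(centers, rgs, box=np.array([40.0] * 3))
        assert res.n_clusters == 2
        assert res.n_dilute == 2

    def test_single_linkage_transitivity(self):
        # A-B and B-C within cutoff, A-C beyond: one 3-chain cluster
        centers = np.array([[0.0, 0, 0], [2.0, 0, 0], [4.0, 0, 0]])
        rgs = np.array([1.0, 1.0, 1.0])  # cutoff 2.4
        res = cluster_chains(centers, rgs, box=np.array([40.0] * 3))
        assert res.n_clusters == 1
        assert res.sizes[0] == 3

    def test_droplet_plus_scattered_monomers(self):
        rng = np.random.default_rng(0)
        droplet = 50.0 + rng.normal(scale=1.5, size=(160, 3))
        corners = np.array([[5.0, 5, 5], [95, 5, 5], [5, 95, 5], [5, 5, 95],
                            [95, 95, 95]])
        centers = np.vstack([droplet, corners])
        rgs = np.full(165, 1.5)
        res = cluster_chains(centers, rgs, box=np.array([100.0] * 3),
                             monomer_threshold=5)
        assert res.n_dilute == 5
        assert res.largest_cluster == 160

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(7)
        box = np.array([30.0] * 3)
        for trial in range(20):
            n = 50
            centers = rng.random((n, 3)) * 30
            rgs = 0.5 + rng.random(n)
            res = cluster_chains(centers, rgs, box=box)
            oracle = union_find_clusters(centers, rgs, box, 2.4)
            assert labels_equivalent(res.labels, oracle)

    def test_relabeling_and_translation_invariance(self):
        rng = np.random.default_rng(3)
        box = np.array([30.0] * 3)
        centers = rng.random((40, 3)) * 30
        rgs = 0.5 + rng.random(40)
        base = cluster_chains(centers, rgs, box=box)
        perm = rng.permutation(40)
        permuted = cluster_chains(centers[perm], rgs[perm], box=box)
        assert labels_equivalent(base.labels[perm], permuted.labels)
        shifted = cluster_chains(np.mod(centers + [7.7, -4.2, 13.9], box), rgs,
                                 box=box)
        assert labels_equivalent(base.labels, shifted.labels)

    def test_global_rg_mode(self):
        centers = np.array([[0.0, 0, 0], [2.9, 0, 0]])
        rgs = np.array([0.1, 2.4])  # pairwise mean 1.25 -> cutoff 3.0
        joined = cluster_chains(centers, rgs, box=np.array([40.0] * 3))
        assert joined.n_clusters == 1
        # global mean 1.25 gives the same here; shrink rgs to split
        split = cluster_chains(centers, np.array([0.1, 0.2]),
                               box=np.array([40.0] * 3), rg_mode="global")
        assert split.n_clusters == 2


class TestEstimateCsat:
    def _frames(self, params2, n_dilute, box=100.0, n_frames=3):
        """Frames with a tight droplet plus n_dilute isolated single chains."""
        rng = np.random.default_rng(1)
        frames = []
        for _ in range(n_frames):
            seqs, coords = [], []
            for k in range(12):  # droplet chains, packed well inside the cutoff
                seqs.append("GG")
                base = 50 + rng.normal(scale=0.1, size=3)
                coords.append(np.array([base, base + [0.4, 0, 0]]))
            for k in range(n_dilute):
                seqs.append("GG")
                base = np.array([5.0 + 7 * k, 5.0, 5.0])
                coords.append(np.array([base, base + [0.4, 0, 0]]))
            frames.append(make_state(seqs, coords, [box] * 3, params2))
        return frames

    def test_no_dilute_chains_gives_zero(self, params2):
        frames = self._frames(params2, 0)
        est = c.estimate_csat(frames, monomer_threshold=5)
        assert est.value == 0.0

    def test_all_monomeric_gives_total_concentration(self, params2):
        rng = np.random.default_rng(2)
        seqs = ["GG"] * 10
        coords = []
        for k in range(10):
            base = np.array([10.0 * (k % 5) + 5, 40.0 * (k // 5) + 10, 50.0])
            coords.append(np.array([base, base + [0.4, 0, 0]]))
        st = make_state(seqs, coords, [100.0] * 3, params2)
        est = c.estimate_csat([st])
        assert est.value == pytest.approx(c.concentration(10, [100.0] * 3))

    def test_constant_twelve_dilute_in_100nm_box(self, params2):
        frames = self._frames(params2, 12)
        est = c.estimate_csat(frames, monomer_threshold=5)
        assert est.value == pytest.approx(19.93, abs=0.01)
        assert np.all(est.per_frame == est.per_frame[0])

    def test_linearity_in_dilute_count(self, params2):
        a = c.estimate_csat(self._frames(params2, 4)).value
        b = c.estimate_csat(self._frames(params2, 8)).value
        assert b == pytest.approx(2 * a, rel=1e-9)

    def test_window_selection_and_validation(self, params2):
        frames = self._frames(params2, 2, n_frames=5)
        est = c.estimate_csat(frames, window=(3, 5))
        assert est.window == (3, 5)
        assert len(est.per_frame) == 2
        with pytest.raises(ValueError):
            c.estimate_csat(frames, window=(4, 9))
        with pytest.raises(ValueError):
            c.estimate_csat([])


class TestDetectCoexistence:
    def _result(self, sizes, monomer_threshold=5):
        sizes = np.array(sizes)
        labels = np.repeat(np.arange(len(sizes)), sizes)
        n_dilute = int(np.sum(sizes[sizes < monomer_threshold]))
        from cocomo2.analysis import ClusterResult
        return ClusterResult(labels=labels, sizes=sizes,
                             monomer_threshold=monomer_threshold,
                             n_dilute=n_dilute, dilute_concentration=0.0)

    def test_all_monomers_is_dissolved(self):
        series = [self._result([1] * 30)] * 3
        assert detect_coexistence(series, condensate_size=20) == "dissolved"

    def test_no_dilute_is_fully_condensed(self):
        series = [self._result([30])] * 3
        assert detect_coexistence(series, condensate_size=20) == "fully_condensed"

    def test_droplet_with_stable_dilute_is_coexisting(self):
        series = [self._result([24] + [1] * 6)] * 3
        assert detect_coexistence(series, condensate_size=20) == "coexisting"

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            detect_coexistence([])
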