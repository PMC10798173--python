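"""Sign-flip cluster permutation test: t-maps, clustering, null calibration."""

import numpy as np
import pytest
from scipy import stats

from tempopred import cluster_perm as cp


class TestTmap:
    def test_closed_form_t(self, rng):
        vals = np.array([0.3, -0.1, 0.7, 0.2, 0.4])
        data = vals[:, None, None]
        t, p, zv = cp.one_sample_tmap(data)
        expected_t = vals.mean() / (vals.std(ddof=1) / np.sqrt(5))
        assert t[0, 0] == pytest.approx(expected_t, abs=1e-12)
        assert p[0, 0] == pytest.approx(2 * stats.t.sf(abs(expected_t), 4), abs=1e-12)
        assert not zv.any()

    def test_symmetric_sample_gives_t_zero(self):
        data = np.array([-1.0, 0.0, 1.0])[:, None, None]
        t, p, _ = cp.one_sample_tmap(data)
        assert t[0, 0] == 0.0
        assert p[0, 0] == 1.0

    def test_zero_variance_flagged_with_sign(self):
        data = np.ones((5, 1, 1))
        t, p, zv = cp.one_sample_tmap(data)
        assert zv[0, 0]
        assert t[0, 0] == np.inf
        assert p[0, 0] == 0.0

    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            cp.one_sample_tmap(np.zeros((1, 2, 2)))


def _flood_fill(supra, start):
    """Brute-force rook-connected component containing ``start``."""
    comp, frontier = {start}, [start]
    while frontier:
        i, j = frontier.pop()
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nb = (i + di, j + dj)
            if (
                0 <= nb[0] < supra.shape[0]
                and 0 <= nb[1] < supra.shape[1]
                and supra[nb]
                and nb not in comp
            ):
                comp.add(nb)
                frontier.append(nb)
    return comp


class TestFindClusters:
    def test_no_suprathreshold_bins(self):
        t = np.zeros((3, 3))
        p = np.ones((3, 3))
        assert cp.find_clusters(t, p, np.ones((3, 3), bool)) == []

    def test_single_isolated_bin(self):
        t = np.zeros((3, 3))
        p = np.ones((3, 3))
        t[1, 1], p[1, 1] = 3.5, 0.01
        clusters = cp.find_clusters(t, p, np.ones((3, 3), bool))
        assert len(clusters) == 1
        assert clusters[0].member_bins == [(1, 1)]
        assert clusters[0].stat == 3.5
        assert clusters[0].sign == 1

    def test_components_match_flood_fill(self, rng):
        # two L-shaped same-sign components plus scattered negatives on 5x5
        t = rng.normal(0, 0.1, (5, 5))
        p = np.ones((5, 5))
        pos = [(0, 0), (1, 0), (1, 1), (3, 3), (3, 4), (4, 4)]
        neg = [(0, 4), (4, 0)]
        for ij in pos:
            t[ij], p[ij] = 3.0, 0.01
        for ij in neg:
            t[ij], p[ij] = -3.0, 0.01
        clusters = cp.find_clusters(t, p, np.ones((5, 5), bool))
        supra_pos = np.zeros((5, 5), bool)
        for ij in pos:
            supra_pos[ij] = True
        expected = {frozenset(_flood_fill(supra_pos, (0, 0))),
                    frozenset(_flood_fill(supra_pos, (3, 3))),
                    frozenset({(0, 4)}), frozenset({(4, 0)})}
        got = {frozenset(c.member_bins) for c in clusters}
        assert got == expected
        for c in clusters:
            assert c.stat == pytest.approx(sum(t[ij] for ij in c.member_bins))


class TestPermutationTest:
    def _toy_data(self, rng, n_sub=12, shape=(6, 5), effect=0.0):
        data = rng.normal(0, 1, (n_sub, *shape))
        data[:, 1:4, 1:4] += effect
        return data

    def test_sign_symmetry(self, rng):
        data = self._toy_data(rng, effect=1.0)
        r1 = cp.permutation_test(data, n_perm=200, seed=7)
        r2 = cp.permutation_test(-data, n_perm=200, seed=7)
        s1 = sorted((c.stat, c.p) for c in r1.clusters)
        s2 = sorted((-c.stat, c.p) for c in r2.clusters)
        for (a, pa), (b, pb) in zip(s1, s2):
            assert a == pytest.approx(b, abs=1e-10)
            assert pa == pytest.approx(pb, abs=1e-12)

    def test_p_floor_and_determinism_and_order_invariance(self, rng):
        data = self._toy_data(rng, effect=1.5)
        r1 = cp.permutation_test(data, n_perm=100, seed=3)
        assert all(c.p >= 1 / 101 for c in r1.clusters)
        r2 = cp.permutation_test(data, n_perm=100, seed=3)
        np.testing.assert_array_equal(r1.perm_stats, r2.perm_stats)
        # participant order must not change the observed map or clusters
        perm = rng.permutation(data.shape[0])
        r3 = cp.permutation_test(data[perm], n_perm=100, seed=3)
        np.testing.assert_allclose(r1.tmap, r3.tmap, atol=1e-12)
        assert sorted(c.stat for c in r1.clusters) == pytest.approx(
            sorted(c.stat for c in r3.clusters)
        )

    def test_reduces_to_1d_direct_implementation(self, rng):
        # single STD row: compare against an independent 1-D permutation test
        n_sub, n_bins, n_perm = 10, 15, 400
        data = rng.normal(0, 1, (n_sub, n_bins, 1))
        data[:, 4:8, 0] += 0.9
        res = cp.permutation_test(data, n_perm=n_perm, seed=11)

        flat = data[:, :, 0]
        tcrit = stats.t.ppf(0.975, n_sub - 1)

        def tvals(x):
            return x.mean(0) / (x.std(0, ddof=1) / np.sqrt(n_sub))

        def extreme(x):
            t = tvals(x)
            supra = np.abs(t) >= tcrit
            best = 0.0
            run, sign = 0.0, 0
            for k in range(n_bins):
                s = np.sign(t[k]) if supra[k] else 0
                if s != 0 and s == sign:
                    run += t[k]
                else:
                    run, sign = (t[k], s) if s != 0 else (0.0, 0)
                if abs(run) > abs(best):
                    best = run
            return best

        rng2 = np.random.default_rng(11)
        signs = np.where(rng2.random((n_perm, n_sub)) < 0.5, 1.0, -1.0)
        signs[0] = 1.0
        ref = np.array([extreme(flat * s[:, None]) for s in signs])
        np.testing.assert_allclose(np.sort(ref), np.sort(res.perm_stats), atol=1e-9)

    def test_max_abs_reference_variant(self, rng):
        data = self._toy_data(rng, effect=1.5)
        res = cp.permutation_test(data, n_perm=150, seed=5, reference="max_abs")
        assert (res.perm_stats >= 0).all()
        sig = [c for c in res.clusters if c.significant]
        assert len(sig) >= 1

    def test_planted_effect_detected(self, rng):
        # power check: strong 3x3 offset in 19 participants is found nearly always
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            data = rng.normal(0, 1, (19, 8, 8))
            data[:, 2:5, 2:5] += 1.5
            res = cp.permutation_test(data, n_perm=300, seed=int(rng.integers(2**31)))
            planted = {(i, j) for i in range(2, 5) for j in range(2, 5)}
            for c in res.clusters:
                if c.significant and c.sign > 0:
                    if len(planted & set(c.member_bins)) >= len(planted) / 2:
                        hits += 1
                        break
        assert hits >= int(0.95 * n_rep) - 3  # 3-sigma slack on a 95% power target

    def test_matches_mne_observed_clusters(self, rng):
        mne_stats = pytest.importorskip("mne.stats")
        n_sub = 13
        data = rng.normal(0, 1, (n_sub, 7, 6))
        data[:, 1:4, 1:4] += 0.8
        res = cp.permutation_test(data, n_perm=100, seed=2)
        tcrit = stats.t.ppf(0.975, n_sub - 1)
        t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            data.reshape(n_sub, -1).reshape(n_sub, 7, 6),
            threshold=tcrit,
            n_permutations=50,
            tail=0,
            adjacency=None,
            seed=1,
            out_type="mask",
        )
        np.testing.assert_allclose(t_obs, res.tmap, atol=1e-8)
        mne_stats_sets = {
            frozenset(map(tuple, np.argwhere(m))) for m in clusters
        }
        ours = {frozenset(c.member_bins) for c in res.clusters}
        assert ours == mne_stats_sets
        for c in res.clusters:
            mask = np.zeros((7, 6), bool)
            for ij in c.member_bins:
                mask[ij] = True
            assert c.stat == pytest.approx(t_obs[mask].sum(), abs=1e-8)
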