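"""Tests for spatial ICA decomposition, partner matching and reliability."""

import itertools

import numpy as np
import pytest

from restconn import hpmica
from restconn.hpmica import (ComponentSet, cluster_onesample_map,
                             cronbach_alpha, decompose_subject,
                             hierarchical_match, match_components,
                             select_reproducible)
from restconn.preprocess import BoldRun


def _zscore_rows(X):
    X = np.asarray(X, float)
    return (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)


def _make_run(data):
    return BoldRun(subject_id="s0", group="control", data=data,
                   voxel_size_mm=(3, 3, 3), tr_seconds=2.0,
                   mask=np.ones(data.shape[:3], dtype=bool), age=40, sex=0)


def _blob_sources(grid=(10, 10, 4), n=3, seed=0):
    from restconn.synth import make_spatial_sources
    return make_spatial_sources(grid, n, smooth_fwhm_mm=4.0,
                                voxel_size_mm=(3, 3, 3), seed=seed)


class TestDecompose:
    def test_noiseless_mixture_recovered(self):
        grid, n = (10, 10, 4), 3
        src = _blob_sources(grid, n)
        rng = np.random.default_rng(0)
        # super-Gaussian time courses keep sources identifiable
        tcs = rng.laplace(size=(60, n))
        data = (src.T @ tcs.T).reshape(grid + (60,))
        cs = decompose_subject(_make_run(data), n, seed=1)
        C = np.abs(_zscore_rows(cs.maps) @ _zscore_rows(src).T / src.shape[1])
        # every source matched by some component
        assert (C.max(axis=0) > 0.99).all()

    def test_rank_one_identity(self):
        grid = (8, 8, 4)
        src = _blob_sources(grid, 1)
        tc = np.random.default_rng(1).laplace(size=60)
        data = (src.T @ tc[None, :]).reshape(grid + (60,))
        cs = decompose_subject(_make_run(data), 1, seed=0)
        r = np.corrcoef(cs.maps[0], src[0])[0, 1]
        assert abs(r) > 0.999

    def test_deterministic_given_seed(self):
        data = np.random.default_rng(2).standard_normal((8, 8, 4, 50))
        a = decompose_subject(_make_run(data), 3, seed=11)
        b = decompose_subject(_make_run(data), 3, seed=11)
        assert np.array_equal(a.maps, b.maps)
        assert np.array_equal(a.time_courses, b.time_courses)

    def test_maps_are_zscored_with_nonnegative_skew(self):
        data = np.random.default_rng(3).standard_normal((8, 8, 4, 50))
        cs = decompose_subject(_make_run(data), 3, seed=0)
        from scipy.stats import skew
        assert np.abs(cs.maps.mean(1)).max() < 1e-6
        assert np.abs(cs.maps.std(1) - 1).max() < 1e-6
        assert (skew(cs.maps, axis=1) >= 0).all()

    def test_excessive_order_rejected(self):
        data = np.random.default_rng(4).standard_normal((4, 4, 2, 10))
        with pytest.raises(ValueError):
            decompose_subject(_make_run(data), 20, seed=0)


def _component_set(sid, maps):
    maps = _zscore_rows(maps)
    return ComponentSet(subject_id=sid, order=maps.shape[0], maps=maps,
                        time_courses=np.zeros((10, maps.shape[0])))


class TestMatchComponents:
    def _noisy_family(self, n_subj, n_comp, n_vox=300, noise=0.2, seed=0):
        rng = np.random.default_rng(seed)
        base = _zscore_rows(rng.standard_normal((n_comp, n_vox)))
        sets = []
        for s in range(n_subj):
            maps = base + noise * rng.standard_normal(base.shape)
            sets.append(_component_set(f"s{s}", maps))
        return base, sets

    def test_identical_sets_identity_pairing(self):
        base, _ = self._noisy_family(1, 3, noise=0)
        sets = [_component_set("a", base), _component_set("b", base)]
        clusters = match_components(sets, threshold=0.4)
        assert len(clusters) == 3
        for c in clusters:
            assert len(c) == 2
            idx = {m[0]: m[1] for m in c.members}
            assert idx["a"] == idx["b"]
            assert c.mean_similarity == pytest.approx(1.0)

    def test_permutation_and_sign_invariance(self):
        base, _ = self._noisy_family(1, 4, noise=0)
        perm = [2, 0, 3, 1]
        flip = np.array([1, -1, 1, -1])
        sets = [_component_set("a", base),
                _component_set("b", flip[:, None] * base[perm])]
        clusters = match_components(sets, threshold=0.4)
        assert len(clusters) == 4
        for c in clusters:
            pair = {m[0]: m for m in c.members}
            ia, ib = pair["a"][1], pair["b"][1]
            assert perm[ib] == ia
            # sign-aligned member maps agree
            assert np.corrcoef(c.member_maps[0], c.member_maps[1])[0, 1] > 0.99

    def test_matches_bruteforce_best_assignment(self):
        """Greedy partner matching equals the exhaustive optimum on
        small families (<= 4 subjects x <= 4 components)."""
        for seed in range(3):
            base, sets = self._noisy_family(3, 4, noise=0.3, seed=seed)
            rng = np.random.default_rng(100 + seed)
            # shuffle component order per subject to hide the identity
            shuffled = []
            perms = []
            for s in sets:
                p = rng.permutation(s.maps.shape[0])
                perms.append(p)
                shuffled.append(_component_set(s.subject_id, s.maps[p]))
            clusters = match_components(shuffled, threshold=0.2)
            got = {frozenset((m[0], m[1]) for m in c.members)
                   for c in clusters}
            best = self._bruteforce(shuffled)
            assert got == best

    @staticmethod
    def _bruteforce(sets):
        """Exhaustive best full assignment maximizing total |r|."""
        k = sets[0].maps.shape[0]
        n_vox = sets[0].maps.shape[1]
        sims = {}
        for a, b in itertools.combinations(range(len(sets)), 2):
            sims[(a, b)] = np.abs(sets[a].maps @ sets[b].maps.T) / n_vox
        best_score, best_assign = -np.inf, None
        for perms in itertools.product(
                *[itertools.permutations(range(k))
                  for _ in range(len(sets) - 1)]):
            assign = [tuple(range(k))] + [tuple(p) for p in perms]
            score = 0.0
            for (a, b), S in sims.items():
                for cl in range(k):
                    score += S[assign[a][cl], assign[b][cl]]
            if score > best_score:
                best_score, best_assign = score, assign
        return {frozenset((sets[s].subject_id, best_assign[s][cl])
                          for s in range(len(sets)))
                for cl in range(k)}

    def test_noise_components_left_unclustered(self):
        rng = np.random.default_rng(5)
        base = _zscore_rows(rng.standard_normal((2, 400)))
        sets = []
        for s in range(4):
            noise_comp = rng.standard_normal((1, 400))
            maps = np.vstack([base + 0.1 * rng.standard_normal(base.shape),
                              noise_comp])
            sets.append(_component_set(f"s{s}", maps))
        clusters = match_components(sets, threshold=0.5)
        full = [c for c in clusters if len(c) == 4]
        assert len(full) == 2
        clustered = {(m[0], m[1]) for c in clusters for m in c.members}
        assert all((f"s{s}", 2) not in clustered for s in range(4))

    def test_mask_mismatch_rejected(self):
        a = _component_set("a", np.random.default_rng(0).standard_normal((2, 100)))
        b = _component_set("b", np.random.default_rng(1).standard_normal((2, 120)))
        with pytest.raises(ValueError, match="mask"):
            match_components([a, b])


class TestHierarchical:
    def _clusters_at(self, order, maps):
        sets = [_component_set(f"s{i}", maps) for i in range(3)]
        cl = match_components(sets, threshold=0.4, order=order)
        for c in cl:
            c.order = order
        return cl

    def test_duplicated_orders_span_all(self):
        maps = _zscore_rows(np.random.default_rng(0).standard_normal((3, 300)))
        first = {o: self._clusters_at(o, maps) for o in (4, 6, 8)}
        groups = hierarchical_match(first, threshold=0.4)
        assert len(groups) == 3
        for g in groups:
            assert sorted(g.orders) == [4, 6, 8]

    def test_single_order_rejected(self):
        maps = _zscore_rows(np.random.default_rng(0).standard_normal((2, 200)))
        with pytest.raises(ValueError, match="single order|>= 2 model"):
            hierarchical_match({6: self._clusters_at(6, maps)})

    def test_min_orders_span_rule(self):
        rng = np.random.default_rng(1)
        shared = _zscore_rows(rng.standard_normal((2, 300)))
        lone = _zscore_rows(rng.standard_normal((1, 300)))
        first = {6: self._clusters_at(6, shared),
                 8: self._clusters_at(8, np.vstack([shared, lone]))}
        groups = hierarchical_match(first, threshold=0.4, min_orders=2)
        assert len(groups) == 2          # the lone network spans only order 8
        groups1 = hierarchical_match(first, threshold=0.4, min_orders=1)
        assert len(groups1) == 3


class TestSelection:
    def _cluster(self, alpha, n_members, order):
        maps = np.random.default_rng(0).standard_normal((n_members, 50))
        c = hpmica.ComponentCluster(
            members=[(f"s{i}", 0, 1) for i in range(n_members)],
            member_maps=maps, representative_map=maps[0],
            mean_similarity=0.9, order=order)
        c.alpha = alpha
        return c

    def test_argmax_alpha(self):
        g = hpmica.ClusterGroup(clusters=[self._cluster(0.9, 5, 6),
                                          self._cluster(0.7, 5, 8)],
                                representative_map=np.zeros(50),
                                mean_similarity=0.9)
        sel = select_reproducible([g])
        assert sel[0].alpha == 0.9

    def test_tie_breaks_membership_then_lower_order(self):
        g = hpmica.ClusterGroup(clusters=[self._cluster(0.8, 6, 6),
                                          self._cluster(0.8, 8, 10)],
                                representative_map=np.zeros(50),
                                mean_similarity=0.9)
        assert len(select_reproducible([g])[0]) == 8
        g2 = hpmica.ClusterGroup(clusters=[self._cluster(0.8, 8, 10),
                                           self._cluster(0.8, 8, 6)],
                                 representative_map=np.zeros(50),
                                 mean_similarity=0.9)
        assert select_reproducible([g2])[0].order == 6


class TestCronbachAlpha:
    def test_identical_items_alpha_one(self):
        item = np.random.default_rng(0).standard_normal(100)
        assert cronbach_alpha(np.tile(item, (4, 1))) == pytest.approx(1.0)

    def test_two_item_spearman_brown_closed_form(self):
        # equal-variance items at correlation r: alpha = 2r / (1 + r)
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        z = rng.standard_normal(2000)
        for r in (0.2, 0.5, 0.8):
            # construct exact sample correlation r with equal variances
            x0 = (x - x.mean()) / x.std(ddof=1)
            z0 = z - z.mean()
            z0 -= x0 * (z0 @ x0) / (x0 @ x0)
            z0 /= z0.std(ddof=1)
            y = r * x0 + np.sqrt(1 - r * r) * z0
            alpha = cronbach_alpha(np.vstack([x0, y]))
            assert alpha == pytest.approx(2 * r / (1 + r), abs=1e-10)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((2, 10_000))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_alpha_never_exceeds_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            X = rng.standard_normal((3, 50))
            assert cronbach_alpha(X) <= 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((1, 10)))
        with pytest.raises(ValueError):
            cronbach_alpha(np.array([[1.0, 1.0], [-1.0, -1.0]]))  # zero total var


class TestOneSampleMap:
    def test_hand_computed_t(self):
        maps = np.array([[1.0], [2.0], [3.0]])
        t, df = cluster_onesample_map(maps)
        assert t[0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)), abs=1e-4)
        assert t[0] == pytest.approx(3.4641, abs=1e-4)
        assert df == 2

    def test_constant_members_give_inf_sentinel(self):
        maps = np.full((3, 2), 5.0)
        maps[:, 1] = -5.0
        t, _ = cluster_onesample_map(maps)
        assert t[0] == np.inf and t[1] == -np.inf

    def test_symmetric_values_give_zero(self):
        t, _ = cluster_onesample_map(np.array([[-1.0], [0.0], [1.0]]))
        assert t[0] == 0.0

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            cluster_onesample_map(np.ones((1, 5)))
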