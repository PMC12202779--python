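import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from nichepart import (
    OtuTable,
    SampleMetadata,
    bh_adjust,
    differential_taxa,
    isotonic_fit,
    nmds,
    pairwise_permanova,
    pcoa,
    permanova,
)
from nichepart.errors import GroupingError, MetricError
from nichepart.multivariate import _pseudo_F


def euclid_dm(points, ids=None):
    points = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DistanceMatrix(squareform(pdist(points)), ids=ids)


class TestPcoa:
    def test_collinear_points_single_axis(self):
        D = euclid_dm([[0.0], [1.0], [2.0]])
        res = pcoa(D)
        assert np.sum(res.eigenvalues > 1e-9) == 1
        x = np.sort(res.coords[:, 0])
        assert np.diff(x) == pytest.approx([1.0, 1.0])

    def test_identical_samples_coincide(self):
        D = euclid_dm([[0, 0], [0, 0], [3, 4]])
        res = pcoa(D)
        assert res.coords[0] == pytest.approx(res.coords[1], abs=1e-9)

    def test_planar_cloud_two_axes_and_reconstruction(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(15, 2))
        D = euclid_dm(pts)
        res = pcoa(D)
        assert np.sum(res.eigenvalues > 1e-9) == 2
        recon = squareform(pdist(res.coords))
        assert np.allclose(recon, D.data, atol=1e-8)

    def test_coordinates_centered_and_eigenvalues_sorted(self):
        rng = np.random.default_rng(3)
        D = euclid_dm(rng.normal(size=(10, 4)))
        res = pcoa(D)
        assert np.allclose(res.coords.mean(axis=0), 0, atol=1e-9)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()
        # positive eigenvalue mass equals total squared centred coordinates
        assert res.eigenvalues[res.eigenvalues > 0].sum() == pytest.approx(
            (res.coords ** 2).sum(), rel=1e-9)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(7)
        D = euclid_dm(rng.normal(size=(12, 3)))
        ours = pcoa(D)
        ref = skbio_pcoa(D)
        assert ours.eigenvalues[:5] == pytest.approx(
            np.asarray(ref.eigvals)[:5], abs=1e-8)
        ours_d = squareform(pdist(ours.coords))
        ref_d = squareform(pdist(ref.samples.to_numpy()))
        assert np.allclose(ours_d, ref_d, atol=1e-8)

    def test_too_few_samples_rejected(self):
        with pytest.raises(MetricError):
            pcoa(euclid_dm([[0.0], [1.0]]))


class TestIsotonicFit:
    def test_monotone_unchanged(self):
        x = [1.0, 2.0, 2.0, 5.0]
        assert isotonic_fit(x) == pytest.approx(x)

    def test_single_violation_pooled(self):
        assert isotonic_fit([3.0, 1.0]) == pytest.approx([2.0, 2.0])

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        once = isotonic_fit(x)
        assert isotonic_fit(once) == pytest.approx(once, abs=1e-12)

    def test_matches_exhaustive_block_partition_solver(self):
        """Exact oracle: enumerate every contiguous block partition (n<=6),
        fit block means, keep the monotone-feasible fit with least SSE."""
        rng = np.random.default_rng(23)
        for _ in range(40):
            n = int(rng.integers(2, 7))
            x = rng.normal(size=n)
            best, best_sse = None, np.inf
            for cuts in itertools.product([0, 1], repeat=n - 1):
                bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
                fit = np.empty(n)
                for a, b in zip(bounds, bounds[1:]):
                    fit[a:b] = x[a:b].mean()
                if (np.diff(fit) < -1e-12).any():
                    continue
                sse = float(((fit - x) ** 2).sum())
                if sse < best_sse - 1e-15:
                    best, best_sse = fit, sse
            assert isotonic_fit(x) == pytest.approx(best, abs=1e-9)


class TestNmds:
    def test_triangle_embeds_exactly(self):
        D = euclid_dm([[0, 0], [1, 0], [0.3, 1.2]])
        res = nmds(D, k=2, seed=0, restarts=4)
        assert res.stress < 1e-6

    def test_embeddable_cloud_reaches_low_stress(self):
        rng = np.random.default_rng(4)
        D = euclid_dm(rng.normal(size=(12, 2)))
        res = nmds(D, k=2, seed=0, restarts=8)
        assert res.stress < 1e-3

    def test_stress_history_non_increasing(self):
        rng = np.random.default_rng(6)
        D = euclid_dm(rng.normal(size=(10, 4)))  # not embeddable in 2-D
        _, history = nmds(D, k=2, seed=1, restarts=1, return_history=True)
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        D = euclid_dm(rng.normal(size=(10, 2)))
        res1 = nmds(D, k=2, seed=2, restarts=8)
        D2 = DistanceMatrix(np.sqrt(D.data) + np.square(D.data) * 0.2,
                            ids=D.ids)
        res2 = nmds(D2, k=2, seed=2, restarts=8)
        assert abs(res1.stress - res2.stress) < 1e-4

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(10)
        D = euclid_dm(rng.normal(size=(8, 3)))
        a = nmds(D, k=2, seed=5, restarts=3)
        b = nmds(D, k=2, seed=5, restarts=3)
        assert a.coords == pytest.approx(b.coords, abs=0)

    def test_bad_dimensions_rejected(self):
        with pytest.raises(MetricError):
            nmds(euclid_dm([[0.0], [1.0], [2.0]]), k=3)


def two_cluster_dm(n_per=5, sep=50.0, seed=0, jitter=0.01):
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(0, jitter, size=(n_per, 2)),
                     rng.normal(sep, jitter, size=(n_per, 2))])
    ids = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    meta = SampleMetadata({i: i[0] for i in ids})
    return euclid_dm(pts, ids), meta


class TestPermanova:
    def test_separated_clusters_minimal_p(self):
        # three tight, well-separated clusters; a random label permutation
        # essentially never reproduces the generating partition (which would
        # tie F), so every permuted F falls below the observed one
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(100 * g, 0.01, size=(7, 2))
                         for g in range(3)])
        ids = [f"{g}_{i}" for g in "abc" for i in range(7)]
        D = euclid_dm(pts, ids)
        meta = SampleMetadata({s: s[0] for s in ids})
        res = permanova(D, meta, n_perm=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)
        assert res.df_among == 2 and res.df_within == 18

    def test_pseudo_F_invariant_under_relabeling(self):
        D, meta = two_cluster_dm(seed=3)
        swapped = SampleMetadata(
            {s: {"a": "x", "b": "w"}[g] for s, g in meta.groups.items()})
        f1 = permanova(D, meta, n_perm=9, seed=0).pseudo_F
        f2 = permanova(D, swapped, n_perm=9, seed=0).pseudo_F
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(31)
        for seed in range(5):
            pts = rng.normal(size=(12, 3))
            ids = [f"s{i}" for i in range(12)]
            D = euclid_dm(pts, ids)
            meta = SampleMetadata({s: "abc"[i % 3] for i, s in enumerate(ids)})
            ours = permanova(D, meta, n_perm=99, seed=seed)
            ref = skbio_permanova(D, [meta.group_of(s) for s in ids],
                                  permutations=99)
            assert ours.pseudo_F == pytest.approx(ref["test statistic"],
                                                  rel=1e-9)

    def test_exhaustive_matches_brute_force_enumeration(self):
        """n=4 (2+2): auto-switched exhaustive p equals a from-scratch
        enumeration over all 4! label orderings."""
        rng = np.random.default_rng(41)
        pts = rng.normal(size=(4, 2))
        ids = list("wxyz")
        D = euclid_dm(pts, ids)
        meta = SampleMetadata(dict(zip(ids, "aabb")))
        res = permanova(D, meta, n_perm=10 ** 6, seed=0)
        assert res.method == "exhaustive"
        d2 = D.data ** 2
        labels = np.array([0, 0, 1, 1])
        sizes = np.bincount(labels)
        f_obs = float(_pseudo_F(d2, labels, 2, sizes))

        def brute_F(lab):  # independent sums-of-squares evaluation
            n = 4
            sst = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
            ssw = 0.0
            for g in (0, 1):
                idx = [i for i in range(n) if lab[i] == g]
                ssw += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
            return ((sst - ssw) / 1) / (ssw / 2)

        count = sum(brute_F(labels[list(perm)]) >= f_obs - 1e-12
                    for perm in itertools.permutations(range(4)))
        assert res.p == pytest.approx(count / math.factorial(4), abs=1e-12)
        assert res.pseudo_F == pytest.approx(brute_F(labels), rel=1e-12)

    def test_reproducible_permutation_stream(self):
        D, meta = two_cluster_dm(n_per=6, sep=2.0, jitter=1.0, seed=5)
        a = permanova(D, meta, n_perm=99, seed=11)
        b = permanova(D, meta, n_perm=99, seed=11)
        assert a.p == b.p

    def test_small_group_rejected(self):
        D = euclid_dm(np.random.default_rng(0).normal(size=(3, 2)))
        meta = SampleMetadata({"s0": "a", "s1": "a", "s2": "b"})
        with pytest.raises(GroupingError):
            permanova(D, meta, n_perm=9)


class TestPairwisePermanova:
    @staticmethod
    def _three_groups(seed=0, sep=0.0):
        rng = np.random.default_rng(seed)
        pts = np.vstack([rng.normal(sep * g, 1.0, size=(5, 2))
                         for g in range(3)])
        ids = [f"{g}_{i}" for g in "abc" for i in range(5)]
        return euclid_dm(pts, ids), SampleMetadata({s: s[0] for s in ids})

    def test_three_groups_three_pairs(self):
        D, meta = self._three_groups(sep=4.0)
        out = pairwise_permanova(D, meta, n_perm=99, seed=1)
        assert len(out) == 3
        assert {(r["group_j"], r["group_k"]) for r in out} == \
            {("a", "b"), ("a", "c"), ("b", "c")}

    def test_adjusted_p_at_least_raw(self):
        D, meta = self._three_groups(seed=2)
        out = pairwise_permanova(D, meta, n_perm=99, seed=3)
        for r in out:
            assert r["p_adjusted"] >= r["result"].p - 1e-12

    def test_null_pairs_not_systematically_small(self):
        ps = []
        for seed in range(20):
            D, meta = self._three_groups(seed=seed)
            out = pairwise_permanova(D, meta, n_perm=99, seed=seed)
            ps += [r["p_adjusted"] for r in out]
        assert np.mean(np.array(ps) <= 0.05) < 0.2


class TestBhAdjust:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert bh_adjust([0.1, 0.1, 0.1]) == pytest.approx([0.1, 0.1, 0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(MetricError):
            bh_adjust([0.5, 1.2])


def spiked_table(seed, n_taxa=30, n_per_group=18, spike_frac=0.10,
                 base_frac=0.001, depth=5000):
    """Counts with taxon 0 at spike_frac in group a, base_frac elsewhere."""
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n_taxa - 1, 5.0))
    cols, sids, groups = [], [], {}
    for g in "abc":
        f = spike_frac if g == "a" else base_frac
        p = np.concatenate([[f], (1 - f) * base])
        for i in range(n_per_group):
            comp = rng.dirichlet(200 * p)
            cols.append(rng.multinomial(depth, comp))
            sid = f"{g}_{i}"
            sids.append(sid)
            groups[sid] = g
    t = OtuTable(tuple(f"T{i}" for i in range(n_taxa)), tuple(sids),
                 np.column_stack(cols))
    return t, SampleMetadata(groups)


class TestDifferentialTaxa:
    def test_flat_taxon_absent(self):
        t, meta = spiked_table(seed=1, spike_frac=0.001)
        # no spike: nothing should clear the effect threshold
        out = differential_taxa(t, meta)
        assert all(r.taxon != "T0" or r.effect_size < 3 for r in out)

    def test_spiked_taxon_detected_with_correct_group(self):
        t, meta = spiked_table(seed=2)
        out = differential_taxa(t, meta)
        hit = [r for r in out if r.taxon == "T0"]
        assert hit and hit[0].enriched_group == "a"
        assert hit[0].kw_p <= 0.05 and hit[0].effect_size >= 2.0

    def test_sorted_by_effect_descending(self):
        t, meta = spiked_table(seed=3)
        out = differential_taxa(t, meta)
        effects = [r.effect_size for r in out]
        assert effects == sorted(effects, reverse=True)

    def test_null_discovery_rate_bounded(self):
        rates = []
        for seed in range(15):
            t, meta = spiked_table(seed=seed, spike_frac=0.001)
            rng = np.random.default_rng(seed + 100)
            labels = list(meta.groups.values())
            rng.shuffle(labels)
            shuffled = SampleMetadata(dict(zip(meta.groups, labels)))
            out = differential_taxa(t, shuffled, effect_threshold=0.0)
            rates.append(len(out) / t.n_otus)
        assert np.mean(rates) <= 0.05 * 1.6
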