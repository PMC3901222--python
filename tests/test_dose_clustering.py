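"""K-means on dose-response profiles and the tandem k-selection rule."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import burndex as bx
from burndex.cohort_data import VariableKey
from burndex.dose_clustering import KScan
from burndex.preprocess import DoseResponseProfile


def profiles_from(X):
    return [
        DoseResponseProfile(VariableKey(f"v{i}", "HA"), (0.0, 20.0, 40.0), np.asarray(x, float), np.asarray(x, float))
        for i, x in enumerate(X)
    ]


def brute_force_wss(X, k):
    """Exhaustive minimum of the k-means objective over all k-partitions."""
    best = np.inf
    for assign in itertools.product(range(k), repeat=len(X)):
        if len(set(assign)) < k:
            continue
        a = np.array(assign)
        w = sum(((X[a == j] - X[a == j].mean(0)) ** 2).sum() for j in range(k))
        best = min(best, w)
    return best


def brute_force_silhouette(X, labels):
    """Textbook silhouette from the full pairwise distance matrix."""
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    out = np.empty(len(X))
    for i in range(len(X)):
        same = (labels == labels[i]) & (np.arange(len(X)) != i)
        if not same.any():
            out[i] = 0.0
            continue
        a = d[i, same].mean()
        b = min(d[i, labels == c].mean() for c in set(labels) if c != labels[i])
        out[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return out


class TestKMeans:
    @pytest.mark.parametrize("k", [2, 3])
    @pytest.mark.parametrize("trial", range(4))
    def test_matches_exhaustive_partition_minimum(self, k, trial):
        """On <= 8 profiles the restarted solver attains the global optimum
        found by enumerating every partition."""
        rng = np.random.default_rng(100 + trial)
        X = rng.normal(size=(7, 3))
        res = bx.kmeans_profiles(profiles_from(X), k, bx.ClusterConfig(replicates=30, seed=trial))
        assert res.within_ss == pytest.approx(brute_force_wss(X, k), abs=1e-9)

    def test_k1_degenerates_to_global_mean(self):
        X = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], float)
        res = bx.kmeans_profiles(profiles_from(X), 1)
        assert res.centroids[0] == pytest.approx(X.mean(0))
        assert res.silhouettes is None and res.mean_silhouette is None

    def test_separated_archetypes_split_perfectly(self):
        arch = bx.ArchetypeSpec.balanced(5, noise_sd=0.0)
        table, labels = bx.gen_archetype_cohort(arch, 3, seed=0)
        profs = bx.group_profiles(table)
        two = [p for p in profs if labels[p.variable] in ("monotone_up", "monotone_down")]
        res = bx.kmeans_profiles(two, 2, bx.ClusterConfig(replicates=10, seed=0))
        assert res.within_ss == pytest.approx(0.0, abs=1e-12)
        split = {labels[p.variable] for p, l in zip(two, res.labels) if l == 0}
        assert len(split) == 1

    def test_k_exceeding_distinct_profiles_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="distinct"):
            bx.kmeans_profiles(profiles_from(X), 2)

    def test_deterministic_given_seed(self, fixture_profiles):
        cfg = bx.ClusterConfig(replicates=10, seed=42)
        a = bx.kmeans_profiles(fixture_profiles, 4, cfg)
        b = bx.kmeans_profiles(fixture_profiles, 4, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert a.within_ss == b.within_ss

    def test_label_invariance_under_profile_permutation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 3))
        perm = rng.permutation(12)
        cfg = bx.ClusterConfig(replicates=40, seed=0)
        a = bx.kmeans_profiles(profiles_from(X), 3, cfg)
        b = bx.kmeans_profiles(profiles_from(X[perm]), 3, cfg)

        def partition(res):
            return {frozenset(k.analyte for k, c in res.assignment.items() if c == j)
                    for j in range(3)}

        names = {f"v{i}": f"v{j}" for i, j in enumerate(perm)}
        b_parts = {frozenset(names[a_] for a_ in part) for part in partition(b)}
        assert partition(a) == b_parts

    def test_best_restart_centroids_stable_on_fixture(self, fixture_profiles):
        """With ample restarts the fixture's k=4 optimum is unique: runs from
        unrelated seeds land on identical centroids."""
        a = bx.kmeans_profiles(fixture_profiles, 4, bx.ClusterConfig(replicates=500, seed=0))
        b = bx.kmeans_profiles(fixture_profiles, 4, bx.ClusterConfig(replicates=500, seed=999))
        ca = np.array(sorted(a.centroids.tolist()))
        cb = np.array(sorted(b.centroids.tolist()))
        assert np.abs(ca - cb).max() < 1e-9


class TestSilhouettes:
    def test_tight_far_pairs_score_high(self):
        X = np.array([[0, 0, 0], [0, 0, 0.1], [10, 10, 10], [10, 10, 10.1]], float)
        res = bx.kmeans_profiles(profiles_from(X), 2, bx.ClusterConfig(replicates=5, seed=0))
        assert (res.silhouettes > 0.9).all()

    def test_equidistant_point_scores_zero(self):
        X = np.array([[-1, -1, -1], [-1, -1, -1], [1, 1, 1], [1, 1, 1], [0, 0, 0]], float)
        vals = bx.silhouette_values(
            profiles_from(X),
            {VariableKey(f"v{i}", "HA"): c for i, c in enumerate([0, 0, 1, 1, 0])},
        )
        assert vals[VariableKey("v4", "HA")] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_brute_force_pairwise_implementation(self, trial):
        rng = np.random.default_rng(trial)
        X = rng.normal(size=(10, 3))
        labels = rng.integers(0, 3, 10)
        while len(set(labels)) < 2:
            labels = rng.integers(0, 3, 10)
        assignment = {VariableKey(f"v{i}", "HA"): int(c) for i, c in enumerate(labels)}
        got = bx.silhouette_values(profiles_from(X), assignment)
        want = brute_force_silhouette(X, labels)
        for i in range(10):
            assert got[VariableKey(f"v{i}", "HA")] == pytest.approx(want[i], abs=1e-9)

    def test_no_signal_limit_collapses_separation(self):
        """With effect_scale = 0 the raw profiles coincide up to noise, and
        the four-pattern separation collapses: the k=4 silhouette drops far
        below the planted-signal case.  (It does not reach zero because the
        [-1, 1] normalization stretches residual noise to full scale.)"""
        arch = bx.ArchetypeSpec.balanced(8, noise_sd=0.3)
        cfg = bx.ClusterConfig(replicates=10, seed=1)
        null_t, _ = bx.gen_archetype_cohort(arch, 5, effect_scale=0.0, seed=1)
        null = bx.kmeans_profiles(bx.group_profiles(null_t), 4, cfg)
        signal_t, _ = bx.gen_archetype_cohort(arch, 5, effect_scale=1.0, seed=1)
        signal = bx.kmeans_profiles(bx.group_profiles(signal_t), 4, cfg)
        assert null.mean_silhouette < 0.7 < signal.mean_silhouette


class TestScanAndChooseK:
    def test_within_ss_decreases_over_scan(self, fixture_profiles):
        scan = bx.scan_k(fixture_profiles, bx.ClusterConfig(k_min=2, k_max=8, replicates=10, seed=0))
        assert scan.within_ss[8] <= scan.within_ss[2]

    def test_archetype_scan_peaks_at_four(self):
        arch = bx.ArchetypeSpec.balanced(10, noise_sd=0.1)
        table, _ = bx.gen_archetype_cohort(arch, 7, seed=0)
        scan = bx.scan_k(bx.group_profiles(table), bx.ClusterConfig(replicates=10, seed=0))
        best = max(scan.mean_silhouette, key=scan.mean_silhouette.get)
        assert best == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_archetype_k_selection_recovers_four(self, seed):
        """Four planted patterns at moderate noise are recovered as k* = 4."""
        arch = bx.ArchetypeSpec.balanced(10, noise_sd=0.1)
        table, _ = bx.gen_archetype_cohort(arch, 7, seed=seed)
        scan = bx.scan_k(bx.group_profiles(table), bx.ClusterConfig(replicates=10, seed=seed))
        assert bx.choose_k(scan) == 4

    @pytest.mark.parametrize("seed", range(6))
    def test_archetype_recovery_ari(self, seed):
        """Clustering 4-archetype data at k=4 recovers the planted labels
        (adjusted Rand index >= 0.9 at noise_sd <= 0.15)."""
        arch = bx.ArchetypeSpec.balanced(10, noise_sd=0.15)
        table, labels = bx.gen_archetype_cohort(arch, 7, seed=seed)
        profs = bx.group_profiles(table)
        res = bx.kmeans_profiles(profs, 4, bx.ClusterConfig(replicates=20, seed=seed))
        truth = [labels[p.variable] for p in profs]
        got = [res.assignment[p.variable] for p in profs]
        assert adjusted_rand_score(truth, got) >= 0.9

    def test_unimodal_scan_returns_peak(self):
        scan = KScan(
            within_ss={2: 10.0, 3: 6.0, 4: 5.0},
            mean_silhouette={2: 0.4, 3: 0.6, 4: 0.5},
        )
        assert bx.choose_k(scan) == 3

    def test_local_max_rejected_when_big_gain_remains(self):
        scan = KScan(
            within_ss={k: 10.0 - k for k in range(2, 7)},
            mean_silhouette={2: 0.3, 3: 0.5, 4: 0.45, 5: 0.7, 6: 0.6},
        )
        # 3 is a local max but k=5 offers a 40% gain; 5 qualifies instead
        assert bx.choose_k(scan) == 5

    def test_marginal_gain_below_threshold_keeps_small_k(self):
        scan = KScan(
            within_ss={k: 10.0 - k for k in range(2, 7)},
            mean_silhouette={2: 0.3, 3: 0.5, 4: 0.45, 5: 0.51, 6: 0.4},
        )
        # best later gain is 2% < 5%: the first local max wins
        assert bx.choose_k(scan) == 3

    def test_monotone_scan_returns_boundary_peak(self):
        # a strictly rising silhouette has its only (boundary) peak at k_max
        scan = KScan(
            within_ss={2: 3.0, 3: 2.0, 4: 1.0},
            mean_silhouette={2: 0.2, 3: 0.3, 4: 0.5},
        )
        assert bx.choose_k(scan) == 4

    def test_scan_needs_three_points(self):
        with pytest.raises(ValueError):
            bx.choose_k(KScan(within_ss={2: 1, 3: 1}, mean_silhouette={2: 0.1, 3: 0.2}))
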