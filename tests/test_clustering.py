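"""Kinetic clustering: patterns, block-PLS, silhouette, k selection, signatures."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from netomics import (
    block_pls_cluster,
    choose_k,
    gen_blocks,
    pattern_cluster,
    silhouette_score,
    sparse_signature,
)
from netomics.clustering import ClusteringError
from netomics.profiles import ModeledProfileSet
from conftest import map_clusters


def mset_from_rows(rows: dict) -> ModeledProfileSet:
    fitted = pd.DataFrame.from_dict(rows, orient="index")
    idx = fitted.index
    return ModeledProfileSet(
        grid=np.arange(fitted.shape[1], dtype=float),
        fitted=fitted,
        model_class=pd.Series("spline_mean", index=idx),
        fit_quality=pd.Series(1.0, index=idx),
        kept=pd.Series(True, index=idx),
    )


class TestPatternCluster:
    def test_sign_pattern_of_differences(self):
        cl = pattern_cluster(mset_from_rows({"f": [1, 0.5, 2]}))
        assert cl.patterns["f"] == "-+"

    def test_same_pattern_same_cluster(self):
        cl = pattern_cluster(mset_from_rows({"a": [1, 2, 3], "b": [10, 20, 30]}))
        assert cl.labels["a"] == cl.labels["b"] and cl.k == 1

    def test_zero_band_maps_small_changes_to_zero(self):
        eps = 0.01 * 2.0  # default band: 1% of range
        cl = pattern_cluster(mset_from_rows({"f": [3, 3 + eps / 2, 1]}))
        assert cl.patterns["f"] == "0-"

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_invariant_under_positive_affine_transform(self, seed):
        rng = np.random.default_rng(seed)
        rows = {f"f{i}": rng.normal(size=6).tolist() for i in range(10)}
        base = pattern_cluster(mset_from_rows(rows))
        a, b = float(rng.uniform(0.5, 5)), float(rng.normal())
        transformed = {k: (a * np.array(v) + b).tolist() for k, v in rows.items()}
        moved = pattern_cluster(mset_from_rows(transformed))
        assert (base.patterns == moved.patterns).all()


def scaled_blocks(n_clusters, seed, sigma=0.2):
    blocks, truth = gen_blocks(n_clusters=n_clusters, sigma=sigma, seed=seed)
    from netomics import fold_change_filter, model_profiles, noise_filter, scale_profiles

    out = []
    for b in blocks:
        f, _ = fold_change_filter(b, 1.5)
        out.append(scale_profiles(noise_filter(model_profiles(f))))
    return out, truth


class TestBlockPLS:
    def test_one_archetype_two_signs_perfectly_recovered(self):
        scaled, truth = scaled_blocks(2, seed=0, sigma=0.1)
        cl = block_pls_cluster(scaled, ncomp=1)
        lab_truth = truth.cluster_labels()
        common = [f for f in cl.labels.index if f in lab_truth]
        ari = adjusted_rand_score(
            [lab_truth[f] for f in common], [cl.labels[f] for f in common]
        )
        assert cl.k == 2 and ari == pytest.approx(1.0)

    def test_two_archetypes_four_clusters_recovered(self):
        scaled, truth = scaled_blocks(4, seed=1, sigma=0.2)
        cl = block_pls_cluster(scaled, ncomp=2)
        lab_truth = truth.cluster_labels()
        common = [f for f in cl.labels.index if f in lab_truth]
        ari = adjusted_rand_score(
            [lab_truth[f] for f in common], [cl.labels[f] for f in common]
        )
        assert cl.k == 4 and ari >= 0.95

    def test_duplicated_feature_gets_identical_labels(self):
        scaled, _ = scaled_blocks(2, seed=2)
        dup = scaled[0].copy()
        dup.index = [f"dup:{f.split(':',1)[1]}" for f in dup.index]
        cl = block_pls_cluster([scaled[0], dup], ncomp=1)
        for f in scaled[0].index:
            assert cl.labels[f] == cl.labels[f"dup:{f.split(':',1)[1]}"]


def brute_silhouette(profiles: pd.DataFrame, labels) -> float:
    """Independent loop-based silhouette under correlation distance."""
    X = profiles.to_numpy(dtype=float)
    lab = np.asarray(labels)
    n = len(lab)

    def dist(i, j):
        return 1.0 - np.corrcoef(X[i], X[j])[0, 1]

    svals = []
    for i in range(n):
        same = [j for j in range(n) if lab[j] == lab[i] and j != i]
        if not same:
            svals.append(0.0)
            continue
        a = sum(dist(i, j) for j in same) / len(same)
        b = min(
            sum(dist(i, j) for j in range(n) if lab[j] == c)
            / sum(1 for j in range(n) if lab[j] == c)
            for c in set(lab) - {lab[i]}
        )
        svals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(svals))


class TestSilhouette:
    def test_two_anticorrelated_groups_score_one(self):
        up = np.array([0.0, 1.0, 2.0, 3.0])
        rows = {f"u{i}": up * s for i, s in enumerate((1, 2, 3))}
        rows |= {f"d{i}": -up * s for i, s in enumerate((1, 2, 3))}
        profiles = pd.DataFrame.from_dict(rows, orient="index")
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=profiles.index)
        assert silhouette_score(profiles, labels) == pytest.approx(1.0)

    def test_random_labels_on_exchangeable_profiles_near_zero(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            profiles = pd.DataFrame(rng.normal(size=(100, 8)))
            labels = pd.Series(rng.integers(1, 4, size=100), index=profiles.index)
            if labels.nunique() < 2:
                continue
            vals.append(silhouette_score(profiles, labels))
        assert abs(float(np.mean(vals))) <= 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        profiles = pd.DataFrame(rng.normal(size=(n, 7)))
        labels = pd.Series(rng.integers(1, 4, size=n), index=profiles.index)
        if labels.nunique() < 2:
            labels.iloc[0] = labels.iloc[0] % 3 + 1
        assert silhouette_score(profiles, labels) == pytest.approx(
            brute_silhouette(profiles, labels), abs=1e-12
        )

    def test_single_cluster_errors(self):
        profiles = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ClusteringError):
            silhouette_score(profiles, pd.Series([1] * 5, index=profiles.index))


class TestChooseK:
    def test_grid_of_size_one_returns_that_clustering(self):
        scaled, _ = scaled_blocks(4, seed=3)
        cl = choose_k(scaled, [2])
        assert cl.loadings.shape[1] == 2

    def test_chosen_silhouette_dominates_candidates(self):
        scaled, _ = scaled_blocks(4, seed=5)
        best = choose_k(scaled, [1, 2, 3])
        concat = pd.concat(scaled)
        for ncomp in (1, 2, 3):
            cand = block_pls_cluster(scaled, ncomp)
            if cand.k >= 2:
                assert best.silhouette >= silhouette_score(concat, cand.labels) - 1e-12

    def test_planted_k_selected(self):
        hits = 0
        for seed in range(10):
            scaled, _ = scaled_blocks(4, seed=seed)
            hits += choose_k(scaled, [1, 2, 3]).k == 4
        assert hits >= 9


class TestSparseSignature:
    def test_keepx_all_keeps_full_clusters(self):
        scaled, _ = scaled_blocks(4, seed=6)
        cl = choose_k(scaled, [2])
        sig = sparse_signature(cl, keepX=max(len(b) for b in scaled))
        all_sig = set().union(*sig.signature.values())
        assert all_sig == set(cl.labels.index)
        for c, members in sig.signature.items():
            assert set(members) == set(cl.labels.index[cl.labels == c])

    def test_keepx_one_keeps_one_feature_per_block_per_component(self):
        scaled, _ = scaled_blocks(4, seed=6)
        cl = choose_k(scaled, [2])
        sig = sparse_signature(cl, keepX=1)
        n_blocks, ncomp = 3, cl.loadings.shape[1]
        total = sum(len(m) for m in sig.signature.values())
        assert total <= n_blocks * ncomp

    def test_high_loading_features_survive_thresholding(self):
        scaled, truth = scaled_blocks(4, seed=7)
        cl = choose_k(scaled, [2])
        sig = sparse_signature(cl, keepX=3)
        mapping = map_clusters(truth.cluster_labels(), dict(cl.labels))
        for c, members in sig.signature.items():
            if c not in mapping:
                continue
            truth_c = mapping[c]
            lab = truth.cluster_labels()
            in_cluster = sum(1 for m in members if lab.get(m) == truth_c)
            assert in_cluster >= len(members) * 0.5
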