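"""Clustering, genealogy, polarity bookkeeping and growth rates."""

import numpy as np
import pandas as pd
import pytest

from polasym import lineage as lin, synthetic_data as syn


def brute_force_dbscan(points, epsilon, minpts):
    """Reachability-by-definition oracle: O(n^2) distance matrix, core
    points by neighbor count, clusters as epsilon-components of cores
    (numbered by smallest core index), border points to the lowest
    qualifying cluster."""
    points = np.asarray(points, float)
    n = len(points)
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    adj = d <= epsilon
    core = adj.sum(axis=1) >= minpts
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        frontier = {i}
        labels[i] = cluster
        while frontier:
            j = frontier.pop()
            for k in np.flatnonzero(adj[j] & core):
                if labels[k] == -1:
                    labels[k] = cluster
                    frontier.add(k)
        cluster += 1
    for i in range(n):
        if core[i] or labels[i] != -1:
            continue
        cands = [labels[k] for k in np.flatnonzero(adj[i] & core)]
        if cands:
            labels[i] = min(cands)
    return labels


class TestClusterMicrocolonies:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.normal((100, 100), 10, (20, 2))
        b = rng.normal((300, 100), 10, (20, 2))
        labels = lin.cluster_microcolonies(np.vstack([a, b]), epsilon=45, minpts=4)
        assert set(labels) == {0, 1}
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_single_point_is_noise(self):
        labels = lin.cluster_microcolonies(np.array([[5.0, 5.0]]), 45, 4)
        assert labels.tolist() == [-1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lin.cluster_microcolonies(np.empty((0, 2)), 45, 4)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            n = int(rng.integers(5, 100))
            pts = rng.uniform(0, 200, (n, 2))
            eps = float(rng.uniform(10, 60))
            minpts = int(rng.integers(2, 8))
            got = lin.cluster_microcolonies(pts, eps, minpts)
            assert got.tolist() == brute_force_dbscan(pts, eps, minpts).tolist()

    def test_agrees_with_sklearn_on_core_and_noise(self):
        from sklearn.cluster import DBSCAN

        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 150, (80, 2))
        got = lin.cluster_microcolonies(pts, 25, 4)
        sk = DBSCAN(eps=25, min_samples=4).fit(pts)
        assert set(np.flatnonzero(got == -1)) == set(np.flatnonzero(sk.labels_ == -1))
        assert len(set(got) - {-1}) == len(set(sk.labels_) - {-1})

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 100, (40, 2))
        perm = rng.permutation(40)
        l1 = lin.cluster_microcolonies(pts, 20, 3)
        l2 = lin.cluster_microcolonies(pts[perm], 20, 3)
        # same partition up to label renaming
        for i in range(40):
            for j in range(40):
                same1 = l1[perm[i]] == l1[perm[j]] and l1[perm[i]] != -1
                same2 = l2[i] == l2[j] and l2[i] != -1
                assert same1 == same2


@pytest.fixture(scope="module")
def trench_series():
    return syn.make_lineage_series(syn.LineageModelParams(generations=4, seed=11))


class TestTracking:
    def test_mother_identity_recovered(self, trench_series):
        masks = [f["mask"] for f in trench_series.frames]
        track = lin.track_mother_cells(masks)
        assert not track.excluded
        truth = [f["mother_label"] for f in trench_series.frames]
        assert track.labels == truth

    def test_empty_frame_excludes_lineage(self, trench_series):
        masks = [f["mask"].copy() for f in trench_series.frames]
        masks[3][:] = 0
        track = lin.track_mother_cells(masks)
        assert track.excluded and "frame 3" in track.reason

    def test_genealogy_division_count(self, trench_series):
        masks = [f["mask"] for f in trench_series.frames]
        gen = lin.build_genealogy(masks)
        dividers = [c for c in gen.cells.values() if c.children]
        # the final generation's division falls after the last frame, so
        # generations - 1 divisions are observable
        assert len(dividers) == 3
        for c in dividers:
            assert len(c.children) == 2


class TestPolarity:
    def test_polarity_matches_generator_truth(self, trench_series):
        masks = [f["mask"] for f in trench_series.frames]
        gen = lin.build_genealogy(masks)
        lin.assign_polarity_generations(gen, founder_old_pole="top")
        # map each tracked cell to the generator uid via per-frame labels
        for cell in gen.cells.values():
            f = cell.frames[0]
            uid = trench_series.frames[f]["labels"][cell.labels[f]]
            truth = trench_series.genealogy[uid]["old_pole"]
            assert cell.old_pole == truth

    def test_generations_increment_by_one(self, trench_series):
        masks = [f["mask"] for f in trench_series.frames]
        gen = lin.build_genealogy(masks)
        lin.assign_polarity_generations(gen, founder_old_pole="top")
        for c in gen.cells.values():
            for k in c.children:
                assert gen.cells[k].generation == c.generation + 1

    def test_old_pole_age_increments_only_in_keeper(self, trench_series):
        masks = [f["mask"] for f in trench_series.frames]
        gen = lin.build_genealogy(masks)
        lin.assign_polarity_generations(gen, founder_old_pole="top")
        for c in gen.cells.values():
            if not c.children or c.old_pole_age is None:
                continue
            kids = [gen.cells[k] for k in c.children]
            ages = sorted(k.old_pole_age for k in kids)
            assert ages == [1, c.old_pole_age + 1]

    def test_unbalanced_division_rejected(self):
        gen = lin.Genealogy()
        parent = lin.CellTrack(0, children=[1, 2, 3])
        gen.cells = {0: parent}
        for k in (1, 2, 3):
            gen.cells[k] = lin.CellTrack(k, parent=0, frames=[1], top_row={1: k})
        with pytest.raises(lin.GenealogyError):
            lin.assign_polarity_generations(gen)


class TestGrowthRate:
    def test_exact_on_noise_free_exponential(self):
        t = np.arange(40.0)  # minutes
        L = 30.0 * np.exp(0.01 * t)
        rates = lin.instantaneous_growth_rate(L, t, window=5)
        valid = rates[np.isfinite(rates)]
        assert len(valid) == 36
        assert np.abs(valid - 0.01).max() < 1e-10

    def test_constant_length_zero_rate(self):
        t = np.arange(20.0)
        rates = lin.instantaneous_growth_rate(np.full(20, 40.0), t)
        assert np.allclose(rates[np.isfinite(rates)], 0.0)

    def test_windows_do_not_cross_divisions(self):
        t = np.arange(20.0)
        L = np.concatenate([30 * np.exp(0.02 * t[:10]), 30 * np.exp(0.02 * t[:10])])
        rates = lin.instantaneous_growth_rate(L, t, window=5, division_indices=[10])
        # centered samples near the division boundary stay undefined
        assert np.isnan(rates[8]) and np.isnan(rates[9]) and np.isnan(rates[10])
        assert np.isfinite(rates[7]) and np.isfinite(rates[12])

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(1)
        t = np.arange(60.0)
        means = []
        for _ in range(50):
            L = 30.0 * np.exp(0.01 * t) * (1 + rng.normal(0, 0.02, 60))
            r = lin.instantaneous_growth_rate(L, t, window=5)
            means.append(np.nanmean(r))
        assert abs(np.mean(means) - 0.01) / 0.01 < 0.05

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            lin.instantaneous_growth_rate(np.array([1.0, -2.0]), np.array([0.0, 1.0]))


class TestPerGenerationMetrics:
    def test_full_inheritance_linear_growth(self):
        p = syn.LineageModelParams(
            generations=6, inheritance_fraction=1.0, synthesis_per_gen_px=10.0,
            division_noise_sd=0.0, seed=2,
        )
        gt = pd.concat([s.per_generation for s in syn.make_lineage_set(3, p)])
        gt = gt.rename(
            columns={"true_pole_area_px": "old_pole_sensor_area_norm",
                     "true_offset": "nucleoid_offset"}
        )
        out = lin.per_generation_metrics(gt, n_boot=200, seed=0)
        means = out["mean_old_pole_sensor_area_norm"].to_numpy()
        assert np.allclose(np.diff(means), 10.0)

    def test_zero_coupling_flat_within_ci(self):
        p = syn.LineageModelParams(
            generations=6, offset_coupling=0.0, division_noise_sd=0.01, seed=3
        )
        gt = pd.concat([s.per_generation for s in syn.make_lineage_set(8, p)])
        gt = gt.rename(
            columns={"true_pole_area_norm": "old_pole_sensor_area_norm",
                     "true_offset": "nucleoid_offset"}
        )
        out = lin.per_generation_metrics(gt, n_boot=500, seed=0)
        assert (out["ci_lo_nucleoid_offset"] <= 0.0).all()
        assert (out["ci_hi_nucleoid_offset"] >= 0.0).all()

    def test_positive_coupling_monotone(self):
        from scipy.stats import spearmanr

        p = syn.LineageModelParams(generations=8, seed=11)
        gt = pd.concat([s.per_generation for s in syn.make_lineage_set(6, p)])
        gt = gt.rename(
            columns={"true_pole_area_norm": "old_pole_sensor_area_norm",
                     "true_offset": "nucleoid_offset"}
        )
        out = lin.per_generation_metrics(gt, n_boot=100, seed=0)
        means = out["mean_nucleoid_offset"].to_numpy()
        assert spearmanr(out["generation"], means).statistic == 1.0
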