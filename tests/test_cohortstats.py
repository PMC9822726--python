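"""Fold changes, Spearman PCA, outlier removal, clustering, group tests."""

import numpy as np
import pandas as pd
import pytest

from dropmet import cohortstats as cs
from dropmet import synthgen as sg
from dropmet.normimpute import MetaboliteMatrix, exclude_unreliable


def matrix_from(values, meta_cols):
    idx = list(values.index)
    meta = pd.DataFrame(meta_cols, index=idx)
    meta["sample_id"] = idx
    return MetaboliteMatrix(values, meta)


def simple_matrix(run_values):
    """run_values: run -> {time_label -> {met -> value}}"""
    rows, meta = {}, {}
    for run, times in run_values.items():
        for tl, mets in times.items():
            sid = f"{run}_{tl}"
            rows[sid] = mets
            meta[sid] = dict(run=run, time_label=tl, replicate=1, arm_fio2=0.209,
                             rpe_last=5.0, completed=True)
    return matrix_from(pd.DataFrame(rows).T, pd.DataFrame(meta).T)


class TestFoldChanges:
    def test_basic_fold(self):
        m = simple_matrix({"r1": {"baseline": {"a": 2.0}, "30min": {"a": 8.0}}})
        fc = cs.fold_changes(m)
        got = fc[(fc.time_label == "30min")]["fold"].iloc[0]
        assert got == pytest.approx(4.0)

    def test_flat_profile_gives_unit_folds(self):
        m = simple_matrix({"r1": {tl: {"a": 3.0} for tl in ("baseline", "10min", "20min", "30min")}})
        fc = cs.fold_changes(m)
        assert fc["fold"].eq(1.0).all()

    def test_early_stop_re_encoded_to_final_slot(self):
        m = simple_matrix({"r1": {"baseline": {"a": 1.0}, "10min": {"a": 2.0}, "20min": {"a": 6.0},
                                  "recovery1": {"a": 3.0}}})
        fc = cs.fold_changes(m)
        assert "20min" not in set(fc["time_label"])
        re_row = fc[fc.time_label == "30min"]
        assert re_row["fold"].iloc[0] == pytest.approx(6.0)
        assert re_row["re_encoded"].all()

    def test_replicates_averaged_geometrically(self):
        rows = {
            "r1_baseline_1": {"a": 1.0}, "r1_baseline_2": {"a": 4.0},  # geomean 2
            "r1_30min_1": {"a": 8.0}, "r1_30min_2": {"a": 8.0},
        }
        meta = {sid: dict(run="r1", time_label=sid.split("_")[1], replicate=int(sid[-1]),
                          arm_fio2=0.209, rpe_last=5.0, completed=True) for sid in rows}
        m = matrix_from(pd.DataFrame(rows).T, pd.DataFrame(meta).T)
        fc = cs.fold_changes(m)
        assert fc[fc.time_label == "30min"]["fold"].iloc[0] == pytest.approx(4.0)

    def test_run_without_baseline_dropped(self, caplog):
        m = simple_matrix({"r1": {"baseline": {"a": 1.0}, "30min": {"a": 2.0}},
                           "r2": {"30min": {"a": 5.0}}})
        fc = cs.fold_changes(m)
        assert set(fc["run"]) == {"r1"}

    def test_scale_invariance_per_run(self):
        m1 = simple_matrix({"r1": {"baseline": {"a": 2.0, "b": 1.0}, "30min": {"a": 6.0, "b": 4.0}}})
        m2 = simple_matrix({"r1": {"baseline": {"a": 20.0, "b": 10.0}, "30min": {"a": 60.0, "b": 40.0}}})
        f1 = cs.fold_changes(m1).set_index(["metabolite", "time_label"])["fold"]
        f2 = cs.fold_changes(m2).set_index(["metabolite", "time_label"])["fold"]
        pd.testing.assert_series_equal(f1, f2)


class TestSpearmanPCA:
    def test_perfect_monotone_pair_eigenvalues(self):
        x = np.arange(1.0, 11)
        data = pd.DataFrame({"a": x, "b": np.exp(x)})
        pca = cs.spearman_pca(data)
        assert pca.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
        p1 = cs.spearman_pca(data)
        warped = data.copy()
        warped["a"] = np.exp(warped["a"])
        warped["b"] = warped["b"] ** 3
        warped["c"] = np.arctan(warped["c"])
        p2 = cs.spearman_pca(warped)
        np.testing.assert_allclose(p1.eigenvalues, p2.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(np.abs(p1.loadings), np.abs(p2.loadings), atol=1e-10)

    def test_constant_metabolite_excluded(self, caplog):
        rng = np.random.default_rng(1)
        data = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10), "c": 1.0})
        pca = cs.spearman_pca(data)
        assert pca.excluded == ["c"]
        assert "c" not in pca.loadings.index

    def test_missing_values_rejected(self):
        data = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="complete"):
            cs.spearman_pca(data)

    def test_planted_two_group_separation(self, cohort_config):
        """Low- vs high-exertion runs separate in rank-PCA score space.

        The rank transform compresses between-group gaps, so the silhouette
        ceiling is ~0.33 even noiselessly; we assert clear separation via
        a positive silhouette plus near-perfect ordering of projections
        along the ellipse-center axis."""
        from sklearn.metrics import roc_auc_score, silhouette_score

        panel_c = sg.panel_for(cohort_config)
        sils, aucs = [], []
        for seed in range(30):
            _, meta, gt = sg.simulate_cohort(panel_c, cohort_config, seed=seed, render=False)
            vals = sg.simulated_matrix(gt, cohort_config, seed=seed + 1000)
            fc = cs.fold_changes(MetaboliteMatrix(vals, meta))
            groups = pd.Series(gt.rpe_groups)
            final = cs.folds_at(fc).dropna(axis=1)
            keep = [r for r in final.index if groups.get(r) in ("low", "high")]
            pca = cs.spearman_pca(np.log(final.loc[keep]))
            g = groups.reindex(pca.scores.index)
            sils.append(silhouette_score(pca.scores.iloc[:, :2], g))
            sep = cs.ellipse_separation(pca, g)
            # the separation axis points from the first group's center
            # (alphabetical: "high") toward the second ("low")
            aucs.append(roc_auc_score((g == "low").astype(int), sep.projections))
        assert np.mean(sils) > 0.2
        assert np.mean(aucs) > 0.95


class TestHotelling:
    def _pca_from_scores(self, X):
        Xc = X - X.mean(0)
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        return cs.PCAResult(scores=pd.DataFrame(U * s), loadings=pd.DataFrame(Vt.T),
                            eigenvalues=(s**2) / (len(X) - 1))

    def test_centroid_run_kept_with_zero_t2(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        X[0] = X[1:].mean(0)  # close to the centroid
        pca = self._pca_from_scores(X)
        rep = cs.hotelling_filter(pca)
        assert rep.t2.iloc[0] < np.median(rep.t2)
        assert rep.t2.index[0] in rep.kept

    def test_gross_outlier_always_removed(self):
        removed = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 4))
            X[7] += 10.0  # 10-sigma offset
            rep = cs.hotelling_filter(self._pca_from_scores(X))
            removed += 7 in rep.removed
        assert removed == 100

    def test_degenerate_covariance_rejected(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10)
        pca = self._pca_from_scores(X)
        with pytest.raises(ValueError, match="degenerate"):
            cs.hotelling_filter(pca)


class TestEllipseSeparation:
    def test_identical_groups_flagged_degenerate(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 2))
        X = np.vstack([base, base])
        pca = cs.PCAResult(scores=pd.DataFrame(X), loadings=pd.DataFrame(np.eye(2)),
                           eigenvalues=np.ones(2))
        groups = pd.Series(["a"] * 6 + ["b"] * 6)
        sep = cs.ellipse_separation(pca, groups)
        assert sep.degenerate

    def test_pc1_shift_contributions_match_pc1_loadings(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(40, 2)) * [1.0, 0.3]
        scores[20:, 0] += 5.0  # shift along PC1 only
        loadings = pd.DataFrame(rng.normal(size=(6, 2)),
                                index=[f"m{i}" for i in range(6)], columns=["PC1", "PC2"])
        pca = cs.PCAResult(scores=pd.DataFrame(scores), loadings=loadings,
                           eigenvalues=np.array([2.0, 0.5]))
        groups = pd.Series(["a"] * 20 + ["b"] * 20)
        sep = cs.ellipse_separation(pca, groups)
        expected = loadings["PC1"].abs().sort_values(ascending=False).index
        assert list(sep.contributions.abs().sort_values(ascending=False).index)[:3] == list(expected[:3])

    def test_small_group_rejected(self):
        pca = cs.PCAResult(scores=pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2))),
                           loadings=pd.DataFrame(np.eye(2)), eigenvalues=np.ones(2))
        with pytest.raises(ValueError, match="fewer than 3"):
            cs.ellipse_separation(pca, pd.Series(["a", "a", "a", "b", "b"]))

    def test_glucose_and_lactate_major_contributors(self, cohort_config):
        """Seed-averaged contribution ranking puts glucose and lactate in the
        top five separators of low vs high exertion."""
        panel_c = sg.panel_for(cohort_config)
        agg = None
        for seed in range(30):
            _, meta, gt = sg.simulate_cohort(panel_c, cohort_config, seed=seed, render=False)
            vals = sg.simulated_matrix(gt, cohort_config, seed=seed + 1000)
            fc = cs.fold_changes(MetaboliteMatrix(vals, meta))
            groups = pd.Series(gt.rpe_groups)
            final = cs.folds_at(fc).dropna(axis=1)
            keep = [r for r in final.index if groups.get(r) in ("low", "high")]
            pca = cs.spearman_pca(np.log(final.loc[keep]))
            sep = cs.ellipse_separation(pca, groups.reindex(pca.scores.index))
            c = sep.contributions.abs()
            agg = c if agg is None else agg.add(c, fill_value=0)
        top5 = set(agg.sort_values(ascending=False).index[:5])
        assert {"glucose", "lactate"} <= top5


class TestHCluster:
    def test_identical_pair_merges_first(self):
        data = pd.DataFrame([[0.0, 0], [5, 5], [0, 0]], index=["a", "b", "c"],
                            columns=["x", "y"])
        res = cs.hcluster_samples(data, k=2, zscore=False)
        assert res.partition["a"] == res.partition["c"] != res.partition["b"]
        # first merge joins the identical pair at height 0
        assert res.linkage_matrix[0, 2] == 0.0

    def test_ultrametric_distances_reproduced_exactly(self):
        # 4-point ultrametric: d(a,b)=2, d(c,d)=2, across=6
        pts = pd.DataFrame([[0.0], [2.0], [10.0], [12.0]], index=list("abcd"))
        res = cs.hcluster_samples(pts, k=2, zscore=False)
        heights = sorted(res.linkage_matrix[:, 2])
        assert heights[0] == heights[1] == 2.0
        assert res.partition["a"] == res.partition["b"]
        assert res.partition["c"] == res.partition["d"]

    def test_newick_well_formed(self):
        rng = np.random.default_rng(0)
        data = pd.DataFrame(rng.normal(size=(5, 3)), index=[f"s{i}" for i in range(5)])
        res = cs.hcluster_samples(data)
        assert res.newick.endswith(";")
        assert res.newick.count("(") == 4  # n-1 internal nodes
        for lab in res.labels:
            assert lab in res.newick

    def test_mpr_three_phase_partition(self, panel, mpr_config):
        """The run's samples cluster into the planted three metabolic phases:
        baseline+early anaerobic laps, the L3 oxygen crisis, and the late
        oxidative phase through recovery; technical replicates co-cluster."""
        canonical = 0
        for seed in range(12):
            _, meta, gt = sg.simulate_mpr_run(panel, mpr_config, seed=seed, render=False)
            vals = sg.simulated_matrix(gt, mpr_config, seed=seed + 1000)
            qc, _ = exclude_unreliable(MetaboliteMatrix(vals, meta))
            logv = np.log(qc.values)
            logv = logv.loc[:, logv.std(ddof=1) >= 0.15]
            res = cs.hcluster_samples(logv, k=3, method="ward")
            part = {s.replace("MPR_", ""): c for s, c in res.partition.items()}
            reps_ok = all(part[f"{tl}_r1"] == part[f"{tl}_r2"] for tl in mpr_config.time_labels())
            phases = [{"baseline", "L1", "L2"}, {"L3"}, {"L4", "L5", "L6", "recovery"}]
            by_cluster = {}
            for s, c in part.items():
                by_cluster.setdefault(c, set()).add(s.rsplit("_r", 1)[0])
            canonical += reps_ok and sorted(map(sorted, by_cluster.values())) == sorted(
                map(sorted, phases)
            )
        assert canonical >= 8


class TestGroupTests:
    def test_identical_groups_p_one(self):
        fc = pd.DataFrame(dict(metabolite="m", time_label="t",
                               fold=[1.0, 2.0, 3.0] * 2,
                               rpe_group=["low"] * 3 + ["high"] * 3,
                               run=list("abcdef")))
        res = cs.group_tests(fc)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_exact_enumeration_small_groups(self):
        fc = pd.DataFrame(dict(metabolite="m", time_label="t",
                               fold=[1, 2, 3, 4, 5, 6],
                               rpe_group=["low"] * 3 + ["high"] * 3,
                               run=list("abcdef")))
        res = cs.group_tests(fc)
        assert res["p"].iloc[0] == pytest.approx(0.1)  # 2/20 rank splits, two-sided

    def test_empty_cell_flagged(self):
        fc = pd.DataFrame(dict(metabolite="m", time_label="t",
                               fold=[1.0, 2.0, 3.0],
                               rpe_group=["low", "low", "high"],
                               run=list("abc")))
        res = cs.group_tests(fc)
        assert res["flag"].iloc[0] == "empty_cell"
        assert np.isnan(res["p"].iloc[0])

    def test_bh_never_rejects_more_than_raw(self):
        rng = np.random.default_rng(0)
        rows = []
        for met in range(20):
            effect = 1.0 if met < 5 else 0.0
            folds = np.concatenate([rng.lognormal(0, 0.3, 8), rng.lognormal(effect, 0.3, 8)])
            rows.append(pd.DataFrame(dict(metabolite=f"m{met}", time_label="t",
                                          fold=folds, rpe_group=["low"] * 8 + ["high"] * 8,
                                          run=[f"r{i}" for i in range(16)])))
        res = cs.group_tests(pd.concat(rows, ignore_index=True))
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert (res["q"] <= 0.05).sum() <= (res["p"] <= 0.05).sum()
        # q-values monotone in p-values
        s = res.sort_values("p")
        assert s["q"].is_monotonic_increasing


class TestRPEGrouping:
    def test_well_separated_modes_recovered(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(np.concatenate([
            rng.normal(2, 0.3, 30).clip(1, 10),
            rng.normal(5.5, 0.3, 30).clip(1, 10),
            rng.normal(9, 0.3, 30).clip(1, 10),
        ]))
        grp = cs.rpe_grouping(vals, seed=0)
        assert (grp.assignment.iloc[:30] == "low").all()
        assert (grp.assignment.iloc[30:60] == "median").all()
        assert (grp.assignment.iloc[60:] == "high").all()

    def test_constant_rpe_degenerate(self):
        grp = cs.rpe_grouping(pd.Series([5.0] * 10))
        assert grp.method == "degenerate"
        assert "degenerate_single_value" in grp.flags

    def test_tiny_sample_uses_fixed_cuts(self):
        grp = cs.rpe_grouping(pd.Series([2.0, 5.0, 9.0]))
        assert grp.method == "fixed"
        assert list(grp.assignment) == ["low", "median", "high"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cs.rpe_grouping(pd.Series([0.5, 5.0, 8.0]))

    def test_mixture_membership_recovery(self, cohort_config):
        """GMM grouping recovers the planted mixture components."""
        panel_c = sg.panel_for(cohort_config)
        agree = []
        for seed in range(50):
            _, meta, gt = sg.simulate_cohort(panel_c, cohort_config, seed=seed, render=False)
            tg = pd.Series(gt.rpe_groups)
            rl = meta.drop_duplicates("run").set_index("run")["rpe_last"]
            grp = cs.rpe_grouping(rl, seed=seed)
            agree.append((grp.assignment.reindex(tg.index) == tg).mean())
        assert np.mean(agree) >= 0.9
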