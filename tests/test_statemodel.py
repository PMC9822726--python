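"""Krebs ratios, factor-analytic state model, reduction check, timeline."""

import numpy as np
import pandas as pd
import pytest

from dropmet import synthgen as sg
from dropmet.normimpute import MetaboliteMatrix, exclude_unreliable
from dropmet.statemodel import (

    factor_reduce,
    krebs_ratios,
    read_timeline,
    state_timeline,
    verify_reduction,
    write_timeline,
)


def matrix(values, time_labels=None, minutes=None):
    idx = list(values.index)
    meta = pd.DataFrame(index=idx)
    meta["sample_id"] = idx
    if time_labels is not None:
        meta["time_label"] = time_labels
        meta["minutes"] = minutes if minutes is not None else range(len(idx))
    return MetaboliteMatrix(values, meta)


class TestKrebsRatios:
    def test_simple_ratio(self):
        vals = pd.DataFrame({"lactate": [4.0], "pyruvate": [2.0], "citrate": [1.0],
                             "beta-hydroxybutyrate": [3.0], "acetoacetate": [1.5]},
                            index=["s1"])
        rat = krebs_ratios(matrix(vals))
        assert rat.loc["s1", "lactate/pyruvate"] == pytest.approx(2.0)
        assert rat.loc["s1", "beta-hydroxybutyrate/acetoacetate"] == pytest.approx(2.0)
        assert rat.loc["s1", "lactate/citrate"] == pytest.approx(4.0)
        assert rat.loc["s1", "pyruvate/citrate"] == pytest.approx(2.0)

    def test_per_sample_scaling_cancels(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.lognormal(size=(5, 4)),
                            columns=["lactate", "pyruvate", "citrate", "acetoacetate"],
                            index=[f"s{i}" for i in range(5)])
        scaled = vals.mul(rng.lognormal(size=5), axis=0)
        r1 = krebs_ratios(matrix(vals))
        r2 = krebs_ratios(matrix(scaled))
        pd.testing.assert_frame_equal(r1, r2)

    def test_absent_constituent_column_omitted(self, caplog):
        vals = pd.DataFrame({"lactate": [1.0], "pyruvate": [2.0]}, index=["s1"])
        rat = krebs_ratios(matrix(vals))
        assert "lactate/pyruvate" in rat.columns
        assert "lactate/citrate" not in rat.columns

    def test_missing_propagates(self):
        vals = pd.DataFrame({"lactate": [1.0, np.nan], "pyruvate": [2.0, 3.0]},
                            index=["s1", "s2"])
        rat = krebs_ratios(matrix(vals))
        assert np.isnan(rat.loc["s2", "lactate/pyruvate"])

    def test_mpr_lactate_citrate_peaks_at_max_rpe_lap(self, panel, mpr_config):
        """The anaerobic/TCA switch ratio peaks at the exhaustion lap and
        declines as oxidative metabolism takes over."""
        cfg_d = mpr_config.to_dict()
        cfg_d.update(replicate_cv=0.02)
        from dropmet.scenario import ScenarioConfig

        cfg = ScenarioConfig.from_dict(cfg_d)
        hits = 0
        for seed in range(10):
            _, meta, gt = sg.simulate_mpr_run(panel, cfg, seed=seed, render=False)
            vals = sg.simulated_matrix(gt, cfg, seed=seed + 1)
            rat = krebs_ratios(MetaboliteMatrix(vals, meta))
            prof = rat["lactate/citrate"].groupby(meta["time_label"]).mean()
            traj = mpr_config.rpe_model["trajectory"]
            max_rpe_lap = mpr_config.time_labels()[int(np.argmax(traj))]
            hits += prof.idxmax() == max_rpe_lap and prof["recovery"] < prof[max_rpe_lap]
        assert hits >= 9


class TestFactorReduce:
    def test_single_factor_structure_recovered(self):
        rng = np.random.default_rng(0)
        f = rng.normal(size=50)
        vals = pd.DataFrame({
            "a": np.exp(1.0 * f + rng.normal(0, 0.05, 50)),
            "b": np.exp(0.9 * f + rng.normal(0, 0.05, 50)),
            "c": np.exp(0.8 * f + rng.normal(0, 0.05, 50)),
        }, index=[f"s{i}" for i in range(50)])
        res = factor_reduce(matrix(vals), n_factors="auto", k_select="auto")
        assert res.n_factors == 1
        assert set(res.key_metabolites) == {"a", "b", "c"}

    def test_orthogonal_four_factor_kaiser_recovery(self):
        """Kaiser count finds the planted four orthogonal factors."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            F = rng.normal(size=(60, 4))
            cols = {}
            for j in range(4):
                for i in range(3):
                    cols[f"m{j}{i}"] = np.exp(F[:, j] + rng.normal(0, 0.35, 60))
            vals = pd.DataFrame(cols, index=[f"s{i}" for i in range(60)])
            res = factor_reduce(matrix(vals), n_factors=4)
            hits += int(np.sum(res.eigenvalues > 1)) == 4
        assert hits >= 48  # >= 95% of seeds

    def test_too_many_factors_rejected(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(np.exp(rng.normal(1, 1, size=(20, 3))), columns=list("abc"),
                            index=[f"s{i}" for i in range(20)])
        with pytest.raises(ValueError, match="factors"):
            factor_reduce(matrix(vals), n_factors=3)

    def test_mpr_key_set_recovery(self, panel, mpr_config):
        """On the packaged single-runner scenario, the QC-gated factor model
        selects exactly the planted nine key metabolites in >= 90% of seeds."""
        truth = set(mpr_config.key_metabolites)
        hits = 0
        for seed in range(50):
            _, meta, gt = sg.simulate_mpr_run(panel, mpr_config, seed=seed, render=False)
            vals = sg.simulated_matrix(gt, mpr_config, seed=seed + 1000)
            qc, _ = exclude_unreliable(MetaboliteMatrix(vals, meta))
            res = factor_reduce(qc, n_factors=4, k_select=9)
            hits += set(res.key_metabolites) == truth
        assert hits >= 45

    def test_mpr_factor_labels_cover_all_states(self, panel, mpr_config):
        _, meta, gt = sg.simulate_mpr_run(panel, mpr_config, seed=1, render=False)
        vals = sg.simulated_matrix(gt, mpr_config, seed=2)
        qc, _ = exclude_unreliable(MetaboliteMatrix(vals, meta))
        res = factor_reduce(qc, n_factors=4, k_select=9)
        assert set(res.factor_labels.values()) == {
            "anaerobic activity", "oxygen release", "TCA activity", "energetic"
        }
        assert "key metabolites (9)" in res.summary()

    def test_json_export(self, panel, mpr_config, tmp_path):
        _, meta, gt = sg.simulate_mpr_run(panel, mpr_config, seed=1, render=False)
        vals = sg.simulated_matrix(gt, mpr_config, seed=2)
        res = factor_reduce(MetaboliteMatrix(vals, meta), n_factors=4, k_select=9)
        path = tmp_path / "state.json"
        res.to_json(path)
        import json

        d = json.loads(path.read_text())
        assert d["n_factors"] == 4 and len(d["key_metabolites"]) == 9


class TestVerifyReduction:
    def test_full_set_gives_ari_one(self, panel, mpr_config):
        _, meta, gt = sg.simulate_mpr_run(panel, mpr_config, seed=0, render=False)
        vals = sg.simulated_matrix(gt, mpr_config, seed=1)
        m = MetaboliteMatrix(vals, meta)
        log_v = np.log(vals)
        keep = log_v.columns[log_v.std(ddof=1) >= 0.15]
        assert verify_reduction(m, list(keep)) == pytest.approx(1.0)

    def test_pure_noise_subset_gives_low_ari(self, panel, mpr_config):
        aris = []
        for seed in range(8):
            _, meta, gt = sg.simulate_mpr_run(panel, mpr_config, seed=seed, render=False)
            vals = sg.simulated_matrix(gt, mpr_config, seed=seed + 1)
            # glucose is planted flat: clustering on it alone is noise
            aris.append(verify_reduction(MetaboliteMatrix(vals, meta), ["glucose"],
                                         min_profile_sd=0.0))
        assert np.mean(aris) < 0.2

    def test_empty_key_set_rejected(self, panel, mpr_config):
        _, meta, gt = sg.simulate_mpr_run(panel, mpr_config, seed=0, render=False)
        vals = sg.simulated_matrix(gt, mpr_config, seed=1)
        with pytest.raises(ValueError):
            verify_reduction(MetaboliteMatrix(vals, meta), [])


class TestStateTimeline:
    def _results(self, panel, mpr_config, seed=1):
        _, meta, gt = sg.simulate_mpr_run(panel, mpr_config, seed=seed, render=False)
        vals = sg.simulated_matrix(gt, mpr_config, seed=seed + 1)
        m = MetaboliteMatrix(vals, meta)
        qc, _ = exclude_unreliable(m)
        return m, factor_reduce(qc, n_factors=4, k_select=9)

    def test_round_trip(self, panel, mpr_config, tmp_path):
        m, res = self._results(panel, mpr_config)
        tl = state_timeline(res, krebs_ratios(m))
        path = tmp_path / "timeline.csv"
        write_timeline(tl, path)
        back = read_timeline(path)
        pd.testing.assert_frame_equal(tl, back)

    def test_key_metabolite_rows_scaled_to_unit_interval(self, panel, mpr_config):
        m, res = self._results(panel, mpr_config)
        tl = state_timeline(res, None)
        key_rows = tl[tl.kind == "key_metabolite"]
        assert key_rows["value"].between(0, 1).all()
        assert set(key_rows["name"]) == set(res.key_metabolites)

    def test_oxygen_release_factor_peaks_at_max_rpe_lap(self, panel, mpr_config):
        hits = 0
        for seed in range(10):
            m, res = self._results(panel, mpr_config, seed=seed)
            tl = state_timeline(res, None)
            ox = tl[(tl.kind == "factor") & (tl.name == "oxygen release")]
            prof = ox.set_index("time_label")["value"]
            hits += prof.idxmax() == "L3"
        assert hits >= 9

    def test_flat_scores_give_flat_rows(self, panel, mpr_config):
        m, res = self._results(panel, mpr_config)
        res.time_scores.loc[:, :] = 0.0
        tl = state_timeline(res, None)
        assert (tl[tl.kind == "factor"]["value"] == 0).all()

    def test_needs_three_time_points(self, panel, mpr_config):
        m, res = self._results(panel, mpr_config)
        res.time_scores = res.time_scores.iloc[:2]
        with pytest.raises(ValueError):
            state_timeline(res, None)


class TestLoadingRecovery:
    def test_planted_loadings_recovered_up_to_permutation_and_sign(self):
        """Procrustes-style check: with orthogonal planted factors at low
        noise, rotated loadings match the planted pattern after matching
        columns by absolute correlation, with small aligned error."""
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            F = rng.normal(size=(80, 4))
            planted = np.zeros((12, 4))
            cols = {}
            for j in range(4):
                for i in range(3):
                    planted[3 * j + i, j] = 0.95
                    cols[f"m{j}{i}"] = np.exp(0.95 * F[:, j] + rng.normal(0, 0.25, 80))
            vals = pd.DataFrame(cols, index=[f"s{i}" for i in range(80)])
            res = factor_reduce(matrix(vals), n_factors=4)
            L = res.loadings.to_numpy()
            # match estimated columns to planted ones by |correlation|
            used = set()
            aligned = np.zeros_like(planted)
            for j in range(4):
                scores = [abs(np.dot(planted[:, j], L[:, k])) if k not in used else -1
                          for k in range(4)]
                k = int(np.argmax(scores))
                used.add(k)
                sign = np.sign(np.dot(planted[:, j], L[:, k])) or 1.0
                aligned[:, j] = sign * L[:, k]
            errs.append(np.abs(aligned - planted).mean())
        assert np.mean(errs) < 0.1
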