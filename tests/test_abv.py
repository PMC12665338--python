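"""Atlas-based volumetry: integration, standardization, statistics."""

import numpy as np
import pandas as pd
import pytest

from dtiabv.abv import (icv_ml, longitudinal_change, partial_corr,
                        percent_change, soi_group_stats, soi_partial_corr,
                        soi_volumes, standardize_icv, structure_volume)
from dtiabv.datasets import LONGITUDINAL_VOLUMES


class TestVolumes:
    def test_binary_map_closed_form(self):
        gm = np.zeros((20, 20, 20))
        mask = np.zeros((20, 20, 20), bool)
        mask[:10, :10, :10] = True  # 1000 voxels
        gm[mask] = 1.0
        assert structure_volume(gm, mask, 1.0) == pytest.approx(1.0)  # mL

    def test_linearity_in_probability(self):
        rng = np.random.default_rng(0)
        gm = rng.random((10, 10, 10))
        mask = rng.random((10, 10, 10)) > 0.5
        v1 = structure_volume(gm, mask, 8.0)
        v2 = structure_volume(gm / 2, mask, 8.0)
        assert v2 == pytest.approx(v1 / 2, rel=1e-12)

    def test_icv_totals_compartments(self):
        comps = {k: np.full((10, 10, 10), v)
                 for k, v in [("gm", 0.4), ("wm", 0.3), ("csf", 0.1)]}
        assert icv_ml(comps, 8.0) == pytest.approx(0.8 * 1000 * 8.0 / 1000.0)

    def test_empty_structure_warns_and_zeroes(self, caplog):
        comps = [{k: np.ones((5, 5, 5)) for k in ("gm", "wm", "csf")}]
        masks = {"present": np.ones((5, 5, 5), bool),
                 "absent": np.zeros((5, 5, 5), bool)}
        with caplog.at_level("WARNING"):
            vols, _ = soi_volumes(comps, masks, 1.0, ["s0"])
        assert vols.loc["s0", "absent"] == 0.0
        assert "absent" in caplog.text

    def test_volume_conservation_under_tiling(self):
        # disjoint masks tiling the compartment: volumes sum to the total
        rng = np.random.default_rng(1)
        gm = rng.random((8, 8, 8))
        half = np.zeros((8, 8, 8), bool)
        half[:4] = True
        v1 = structure_volume(gm, half, 1.0)
        v2 = structure_volume(gm, ~half, 1.0)
        assert v1 + v2 == pytest.approx(gm.sum() / 1000.0, rel=1e-12)


class TestStandardization:
    def test_formula_and_idempotence(self):
        vols = pd.DataFrame({"a": [10.0, 20.0]}, index=["c1", "p1"])
        icv = pd.Series([1400.0, 1600.0], index=["c1", "p1"])
        std = standardize_icv(vols, icv, ["c1"])
        assert std.loc["p1", "a"] == pytest.approx(20.0 * 1400.0 / 1600.0)
        # after standardization every subject sits at the reference ICV
        std_icv = pd.Series([1400.0, 1400.0], index=["c1", "p1"])
        again = standardize_icv(std, std_icv, ["c1"])
        assert (again - std).abs().to_numpy().max() < 1e-12


class TestGroupStats:
    def _cohort(self, groups, ages):
        return pd.DataFrame({
            "subject": [f"s{i}" for i in range(len(groups))],
            "group": groups, "age": ages,
            "timepoint": ["baseline"] * len(groups),
        })

    def test_identical_groups_null(self):
        vols = pd.DataFrame({"soi": [5.0] * 12},
                            index=[f"s{i}" for i in range(12)])
        cohort = self._cohort(["bvFTD"] * 6 + ["control"] * 6,
                              [60.0 + i for i in range(12)])
        out = soi_group_stats(vols, cohort, group_pairs=(("bvFTD", "control"),))
        assert out.z[0] == 0.0
        assert out.q[0] == pytest.approx(1.0)

    def test_age_confounded_null_controlled(self):
        # volume depends on age only; groups differ in age: the covariate
        # model must not call the group effect significant
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            age_p = rng.normal(70, 4, 30)
            age_c = rng.normal(55, 4, 30)
            ages = np.concatenate([age_p, age_c])
            vols = pd.DataFrame(
                {"soi": 10.0 - 0.05 * ages + 0.1 * rng.standard_normal(60)},
                index=[f"s{i}" for i in range(60)])
            cohort = self._cohort(["bvFTD"] * 30 + ["control"] * 30, ages)
            out = soi_group_stats(vols, cohort,
                                  group_pairs=(("bvFTD", "control"),))
            hits += int(out.p[0] < 0.05)
        assert hits <= 2

    def test_injected_atrophy_detected_in_right_sois(self):
        rng = np.random.default_rng(7)
        n = 40
        names = [f"soi{i}" for i in range(8)]
        affected = {"soi1", "soi4", "soi6"}
        data = {}
        for name in names:
            base = rng.normal(10, 0.5, 2 * n)
            if name in affected:
                base[:n] *= 0.85
            data[name] = base
        vols = pd.DataFrame(data, index=[f"s{i}" for i in range(2 * n)])
        ages = rng.normal(60, 8, 2 * n)
        cohort = self._cohort(["bvFTD"] * n + ["control"] * n, ages)
        out = soi_group_stats(vols, cohort, group_pairs=(("bvFTD", "control"),))
        sig = set(out[out.q < 0.05].structure)
        assert sig == affected

    def test_rank_deficient_design_named(self):
        vols = pd.DataFrame({"soi": np.arange(8.0)},
                            index=[f"s{i}" for i in range(8)])
        cohort = self._cohort(["bvFTD"] * 4 + ["control"] * 4, [60.0] * 8)
        cohort["age"] = [1.0] * 4 + [0.0] * 4  # age == group indicator
        with pytest.raises(ValueError, match="collinear"):
            soi_group_stats(vols, cohort, group_pairs=(("bvFTD", "control"),))


class TestLongitudinal:
    def test_percent_change_closed_forms(self):
        assert percent_change(426.5, 406.3) == pytest.approx(-4.74)
        assert percent_change(1.7, 1.5) == pytest.approx(-11.76)
        assert percent_change(389.0, 392.0) == pytest.approx(0.77)
        assert percent_change(5.0, 5.0) == 0.0

    def test_worked_example_all_structures(self):
        # the bundled group-mean table reproduces its printed percent column
        expected = {
            "Cerebrum GM": -4.74, "Cerebrum WM": 0.77, "Frontal lobe R": -1.6,
            "Frontal lobe L": -2.3, "Temporal lobe R": -2.19,
            "Temporal lobe L": -3.06, "Parietal lobe R": -2.27,
            "Parietal lobe L": -1.99, "Occipital lobe R": -2.17,
            "Occipital lobe L": -1.88, "Insula R": -4.41, "Insula L": -5.71,
            "Cerebellum": -3.71, "Brainstem": -3.33, "Hippocampus R": -3.45,
            "Hippocampus L": -3.7, "Amygdala R": -6.25, "Amygdala L": 0.0,
            "Caudate R": -11.76, "Caudate L": -5.88, "Putamen R": -8.0,
            "Putamen L": -16.0, "Thalamus R": -1.96, "Thalamus L": -1.96,
        }
        got = percent_change(LONGITUDINAL_VOLUMES.baseline_mean,
                             LONGITUDINAL_VOLUMES.followup_mean)
        for structure, value in expected.items():
            idx = LONGITUDINAL_VOLUMES.index.get_loc(structure)
            assert got[idx] == pytest.approx(value, abs=0.005), structure

    def _paired_setup(self):
        cohort = pd.DataFrame({
            "subject": ["p1", "p2", "p1", "p2", "c1", "c2", "c3"],
            "group": ["bvFTD"] * 4 + ["control"] * 3,
            "timepoint": ["baseline", "baseline", "followup", "followup",
                          "baseline", "baseline", "baseline"],
        })
        idx = pd.MultiIndex.from_frame(cohort[["subject", "timepoint"]])
        vols = pd.DataFrame({"soi": [10.0, 12.0, 9.0, 11.0, 11.0, 11.5, 12.0]},
                            index=idx)
        return vols, cohort

    def test_group_mean_percent_change(self):
        vols, cohort = self._paired_setup()
        out = longitudinal_change(vols, cohort)
        assert out["pct_change"][0] == pytest.approx(
            100 * (10.0 - 11.0) / 11.0, abs=0.005)

    def test_unpaired_followup_named(self):
        vols, cohort = self._paired_setup()
        cohort.loc[len(cohort)] = ["p9", "bvFTD", "followup"]
        with pytest.raises(ValueError, match="p9"):
            longitudinal_change(vols, cohort)


class TestPartialCorrelation:
    def test_exact_negative_relation(self):
        score = np.arange(10.0)
        vol = -2.0 * score
        age = np.random.default_rng(0).random(10)
        r, p = partial_corr(vol, score, age)
        assert r == pytest.approx(-1.0, abs=1e-9)

    def test_residualization_equals_recursive_formula(self):
        rng = np.random.default_rng(3)
        x, y, z = rng.random((3, 50))
        r, _ = partial_corr(x, y, z)
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        recursive = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
        assert r == pytest.approx(recursive, abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.random((40, 3)), columns=["x", "y", "z"])
        r, p = partial_corr(df.x.to_numpy(), df.y.to_numpy(), df.z.to_numpy())
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_age_confound_removed(self):
        rng = np.random.default_rng(5)
        age = rng.normal(60, 10, 200)
        vol = 10 - 0.05 * age + 0.05 * rng.standard_normal(200)
        score = 0.3 * age + rng.standard_normal(200)  # score tracks age only
        r, _ = partial_corr(vol, score, age)
        assert abs(r) < 0.1

    def test_constant_covariate_falls_back(self, caplog):
        rng = np.random.default_rng(6)
        x, y = rng.random((2, 20))
        with caplog.at_level("WARNING"):
            r, p = partial_corr(x, y, np.full(20, 60.0))
        from scipy import stats
        ref_r, ref_p = stats.pearsonr(x, y)
        assert r == pytest.approx(ref_r, abs=1e-12)
        assert "constant covariate" in caplog.text

    def test_soi_table_with_bh(self):
        rng = np.random.default_rng(8)
        n = 30
        score = rng.random(n) * 10
        age = rng.normal(60, 5, n)
        vols = pd.DataFrame({
            "linked": 5 - 0.3 * score + 0.05 * rng.standard_normal(n),
            "free": rng.standard_normal(n),
        }, index=[f"s{i}" for i in range(n)])
        scores = pd.Series(score, index=vols.index)
        ages = pd.Series(age, index=vols.index)
        out = soi_partial_corr(vols, scores, ages)
        linked = out[out.structure == "linked"].iloc[0]
        free = out[out.structure == "free"].iloc[0]
        assert linked.r < -0.9 and linked.q < 0.01
        assert free.q > 0.05
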