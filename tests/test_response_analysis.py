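"""Z-scoring, trial averaging, modulation statistics, and group inference."""

import numpy as np
import pandas as pd
import pytest

from tectolearn import response_analysis as resp
from tectolearn import synthetic_data as syn
from tectolearn.response_analysis import (AllTrialsExcludedError,
                                          compare_epochs, epoch_modulation,
                                          responsive_mask, trial_average,
                                          tukey_kramer, zscore_epoch)


class TestZScore:
    def test_mean_zero_sd_one(self, rng):
        x = rng.gamma(2.0, size=(5, 400))
        z, valid = zscore_epoch(x)
        assert valid.all()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1.0, rtol=1e-12)

    def test_zero_variance_cell_flagged(self, rng):
        x = np.vstack([np.full(100, 3.0), rng.normal(size=100)])
        z, valid = zscore_epoch(x)
        assert not valid[0] and valid[1]
        assert np.isnan(z[0]).all()

    def test_identical_segments_identical_z(self, rng):
        x = rng.normal(size=(3, 200))
        z1, _ = zscore_epoch(x)
        z2, _ = zscore_epoch(x.copy())
        np.testing.assert_array_equal(z1, z2)


class TestTrialAverage:
    def test_excursion_filter_counts(self, rng):
        z = rng.normal(size=(2, 4000))
        onsets = np.arange(36) * 100
        exc = np.zeros(36)
        exc[[3, 10, 20, 30]] = 0.3
        mean, n_excluded = trial_average(z, onsets, 50, exc)
        assert n_excluded == 4
        manual = np.stack([z[:, o:o + 50]
                           for o in onsets[exc <= 0.25]]).mean(axis=0)
        np.testing.assert_allclose(mean, manual)

    def test_no_excursions_plain_mean_and_single_trial(self, rng):
        z = rng.normal(size=(1, 500))
        mean, n = trial_average(z, np.array([17]), 40, np.array([0.0]))
        assert n == 0
        np.testing.assert_array_equal(mean, z[:, 17:57])

    def test_all_excluded_raises(self, rng):
        z = rng.normal(size=(1, 200))
        with pytest.raises(AllTrialsExcludedError):
            trial_average(z, np.array([0, 50]), 20, np.array([0.5, 0.9]))


class TestResponsiveMask:
    @pytest.mark.parametrize("peak,threshold,expected", [
        (1.2, 1.0, True),    # soma above the somatic threshold
        (0.8, 0.75, True),   # bouton above the axonal threshold
        (0.8, 1.0, False),   # same bouton fails the somatic threshold
    ])
    def test_thresholding(self, peak, threshold, expected):
        z = {"ES": np.zeros((1, 10)), "LS": np.zeros((1, 10))}
        z["LS"][0, 4] = peak
        assert responsive_mask(z, threshold)[0] == expected

    def test_monotone_in_threshold(self, rng):
        z = {ep: rng.normal(size=(50, 30)) for ep in ("ES", "LS", "VL")}
        lo = responsive_mask(z, 0.5)
        hi = responsive_mask(z, 1.5)
        assert (hi <= lo).all()


class TestEpochModulation:
    def test_hand_arithmetic(self):
        z = {"ES": np.full((1, 4), 1.0), "LS": np.full((1, 4), 0.4),
             "VL": np.full((1, 4), 1.0)}
        table = epoch_modulation(z).set_index("epoch")
        np.testing.assert_allclose(table["dz"],
                                   pd.Series({"ES": 0.2, "LS": -0.4,
                                              "VL": 0.2}))

    def test_zero_sum_and_identical_epochs(self, rng):
        base = rng.normal(size=(30, 20))
        z = {"ES": base + rng.normal(size=(30, 20)),
             "LS": base + rng.normal(size=(30, 20)),
             "VL": base + rng.normal(size=(30, 20))}
        table = epoch_modulation(z)
        sums = table.groupby("cell")[["dz", "dz_early", "dz_late"]].sum()
        np.testing.assert_allclose(sums.to_numpy(), 0.0, atol=1e-12)
        same = epoch_modulation({"ES": base, "LS": base, "VL": base})
        np.testing.assert_allclose(same["dz"], 0.0, atol=1e-12)


class TestGroupStats:
    @staticmethod
    def _cohort(effect_ls: float, n_mice=3, n_cells=40, seed=0, group="g"):
        rng = np.random.default_rng(seed)
        rows = []
        for m in range(n_mice):
            zbar = rng.normal(1.0, 0.3, size=(n_cells, 3))
            zbar[:, 1] += effect_ls
            dz = zbar - zbar.mean(axis=1, keepdims=True)
            for e, ep in enumerate(("ES", "LS", "VL")):
                rows.append(pd.DataFrame({
                    "cell": np.arange(n_cells), "mouse": f"m{m}",
                    "group": group, "epoch": ep, "zbar": zbar[:, e],
                    "dz": dz[:, e]}))
        return pd.concat(rows, ignore_index=True)

    def test_injected_ls_deficit_flags_expected_pairs(self):
        t = self._cohort(effect_ls=-0.4, seed=5)
        tk = tukey_kramer(t["dz"], t["epoch"],
                          blocks=t["mouse"].astype(str) + ":"
                          + t["cell"].astype(str))
        tk = tk.set_index(["group1", "group2"])
        assert tk.loc[("ES", "LS"), "reject"]
        assert tk.loc[("LS", "VL"), "reject"]
        assert not tk.loc[("ES", "VL"), "reject"]

    def test_interaction_detected_between_modulated_and_flat(self):
        a = self._cohort(effect_ls=-0.4, seed=1, group="mod")
        b = self._cohort(effect_ls=0.0, seed=2, group="flat")
        rep = compare_epochs(pd.concat([a, b], ignore_index=True))
        assert rep["p_interaction"] < 0.01
        terms = rep["anova"]["term"].tolist()
        assert terms == ["group", "mouse(group)", "cell(mouse)", "epoch",
                         "group x epoch", "mouse(group) x epoch"]

    def test_single_mouse_group_rejected(self):
        t = self._cohort(effect_ls=0.0, n_mice=1)
        with pytest.raises(ValueError, match="2 mice"):
            compare_epochs(t)

    def test_singular_design_rejected(self):
        t = self._cohort(effect_ls=0.0, n_mice=2, n_cells=1)
        # one observation per (mouse, epoch) cell leaves no residual df
        with pytest.raises(np.linalg.LinAlgError):
            compare_epochs(t)


class TestOrientationBias:
    @staticmethod
    def _cohorts(preset_names, n_animals=2, n_cells=40, seed0=0):
        from tectolearn.task_design import generate_session
        session = generate_session()
        recs, groups = {}, {}
        for g, preset in preset_names.items():
            for m in range(n_animals):
                rec, _ = syn.simulate_recording(session, preset,
                                                n_cells=n_cells,
                                                seed=seed0 + m)
                recs[f"{g}{m}"] = rec
                groups[f"{g}{m}"] = g
        return recs, groups

    def test_vertical_biased_preset_detected(self, default_session):
        preset = syn.CohortPreset(name="allv", selective_fraction=0.9,
                                  vertical_pref_fraction=1.0)
        rec, _ = syn.simulate_recording(default_session, preset, n_cells=60,
                                        seed=3)
        out = resp.orientation_bias({"a": rec, "b": rec},
                                    {"a": "g1", "b": "g2"})
        row = out["per_animal"].iloc[0]
        assert row["median_diff"] > 0
        assert row["n_pref_vertical"] > row["n_pref_horizontal"]
        assert row["p_chi2_bonferroni"] < 0.05

    def test_identical_groups_ks_zero(self, default_session):
        rec, _ = syn.simulate_recording(default_session, "WT_SC", n_cells=40,
                                        seed=7)
        out = resp.orientation_bias(
            {"a1": rec, "a2": rec, "b1": rec, "b2": rec},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert out["ks"]["statistic"] == 0.0
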