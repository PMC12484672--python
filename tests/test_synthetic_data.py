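"""Ground-truth structure and recovery properties of the synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from tectolearn import response_analysis as resp
from tectolearn import synthetic_data as syn
from tectolearn.synthetic_data import (DecayConfig, NoiseConfig, PRESETS,
                                       Recording, simulate_pupil,
                                       simulate_recording)

QUIET = NoiseConfig(amp_cv=0.0, frame_sigma=0.0, excursion_rate=0.0,
                    excursion_scale_mm=0.0)
NO_DECAY = DecayConfig(enabled=False)


class TestRecordingStructure:
    def test_shapes_events_and_nonnegativity(self, default_session):
        rec, truth = simulate_recording(default_session, "WT_SC", n_cells=20,
                                        seed=0)
        assert rec.activity.shape[0] == 20
        assert np.isfinite(rec.activity).all() and (rec.activity >= 0).all()
        assert len(rec.events) == 288
        assert rec.events["outcome_onset_frame"].max() < rec.n_frames
        assert (rec.excursion >= 0).all()
        assert len(truth) == 20

    def test_unknown_preset_and_bad_cell_count(self, default_session):
        with pytest.raises(KeyError):
            simulate_recording(default_session, "NOPE", n_cells=5, seed=0)
        with pytest.raises(ValueError):
            simulate_recording(default_session, "WT_SC", n_cells=0, seed=0)

    def test_determinism(self, toy_session):
        a, _ = simulate_recording(toy_session, "WT_SC", n_cells=5, seed=9)
        b, _ = simulate_recording(toy_session, "WT_SC", n_cells=5, seed=9)
        np.testing.assert_array_equal(a.activity, b.activity)

    def test_noiseless_flat_responses_repeat_across_epochs(self, toy_session):
        """With zero noise, no decay and a flat preset, the same aversive
        subtype evokes an identical response in every epoch."""
        rec, truth = simulate_recording(
            toy_session, "FLAT", n_cells=4, seed=2, noise=QUIET,
            decay=NO_DECAY)
        ev = rec.events
        wlen = int(round(2.0 * rec.frame_rate))
        snippets = {}
        for _, tr in ev[ev["outcome"] == "aversive"].iterrows():
            if tr["epoch"] not in ("ES", "LS", "VL"):
                continue
            o = tr["outcome_onset_frame"]
            snippets.setdefault(tr["aversive_type"], []).append(
                rec.activity[:, o:o + wlen])
        for typ, wins in snippets.items():
            for w in wins[1:]:
                np.testing.assert_allclose(w, wins[0], atol=1e-6,
                                           err_msg=typ)

    def test_hdf5_roundtrip(self, toy_session, tmp_path):
        rec, _ = simulate_recording(toy_session, "WT_SC", n_cells=3, seed=1)
        path = tmp_path / "rec.h5"
        rec.to_hdf5(path)
        back = Recording.from_hdf5(path)
        np.testing.assert_array_equal(back.activity, rec.activity)
        assert back.frame_rate == rec.frame_rate
        pd.testing.assert_frame_equal(
            back.events.astype(str), rec.events.astype(str))


class TestGroundTruthRecovery:
    def test_responsive_mask_balanced_accuracy(self, default_session):
        rec, truth = simulate_recording(default_session, "WT_SC",
                                        n_cells=300, seed=11)
        res = resp.epoch_outcome_traces(rec)
        mask = resp.responsive_mask(res["traces"], 1.0)
        true = truth["responsive"].to_numpy()
        tpr = (mask & true).sum() / true.sum()
        tnr = (~mask & ~true).sum() / (~true).sum()
        assert (tpr + tnr) / 2 >= 0.95

    def test_epoch_ordering_of_wt_preset(self, default_session):
        rec, _ = simulate_recording(default_session, "WT_SC", n_cells=150,
                                    seed=3)
        table = resp.analyze_recording(rec)
        means = table.groupby("epoch")["dz"].mean()
        assert means["LS"] < means["ES"]
        assert means["LS"] < means["VL"]

    def test_decay_visible_in_population_average(self, default_session):
        """With the default photobleach curve, early analyzed trials carry
        larger aversive responses than late ones within each epoch."""
        rec, _ = simulate_recording(default_session, "FLAT", n_cells=80,
                                    seed=4, noise=QUIET)
        from tectolearn.trajectory import aversive_trial_responses
        zbar, meta = aversive_trial_responses(rec)
        pop = np.nanmean(zbar, axis=0)
        per = 36
        folded = pop.reshape(3, per).mean(axis=0)
        assert folded[:6].mean() > folded[-6:].mean()


class TestPupil:
    def test_flat_quiet_pupil_is_constant_ratio(self, toy_session):
        preset = syn.CohortPreset(name="quiet", dilation_amp=(0, 0, 0),
                                  constriction_amp=0.0)
        pup = simulate_pupil(toy_session, preset, seed=0, noise_sd=0.0)
        from tectolearn.pupillometry import pupil_epoch_summary
        summ = pupil_epoch_summary(pup)
        np.testing.assert_allclose(summ["abar"], 1.0, atol=1e-9)
        np.testing.assert_allclose(summ["da"], 0.0, atol=1e-9)

    def test_median_area_matches_preset(self, toy_session):
        for name in ("WT_SC", "SCN2A_SC"):
            pup = simulate_pupil(toy_session, name, seed=1)
            from tectolearn.pupillometry import area_from_long_axis
            area = area_from_long_axis(pup.diameter_px)
            assert np.nanmedian(area) == pytest.approx(
                PRESETS[name].pupil_median_mm2, rel=0.05)

    def test_wt_dilation_smaller_in_volatile_epoch(self, default_session):
        from tectolearn.pupillometry import pupil_epoch_summary
        pup = simulate_pupil(default_session, "WT_SC", seed=5)
        summ = pupil_epoch_summary(pup).set_index("epoch")
        assert summ.loc["VL", "da"] < summ.loc["ES", "da"]
        assert summ.loc["VL", "da"] < summ.loc["LS", "da"]


class TestRFUnit:
    def test_center_outside_grid_rejected(self):
        from tectolearn.rf_mapping import checkerboard
        stim = checkerboard(nx=8, ny=6, duration_s=10, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_rf_unit((20.0, 3.0), 1.0, stim)

    def test_zero_gain_unit_has_no_sta_structure(self):
        from tectolearn.rf_mapping import checkerboard, reverse_correlation
        stim = checkerboard(nx=8, ny=6, duration_s=60, seed=3)
        act, _ = syn.simulate_rf_unit((4.0, 3.0), 1.0, stim, gain=0.0,
                                      noise_sd=0.1, seed=1)
        act = act + 1.0  # keep the trace positive-mean
        kernel = reverse_correlation(act, stim)
        assert np.abs(kernel).max() < 0.05
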