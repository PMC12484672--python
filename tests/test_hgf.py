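"""Hierarchical Gaussian filter: one-step oracle, invariants, and equations.

The key test re-evaluates every printed update formula in a straight-line,
no-abstraction oracle and compares the pipeline against it on random binary
sequences.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tectolearn.hgf import (HGFConfig, HGFFilter, HGFState, PARAM_LEVELS,
                            PARAM_NAMES, hgf_step, run_hgf, sigmoid,
                            subset_aversive)


def _oracle_run(u, omega2, omega3, mu2_0, sigma2_0, mu3_0, sigma3_0,
                epsilon3_form="printed"):
    """Straight-line re-evaluation of the observer equations (independent
    of the pipeline's abstractions)."""
    import math

    s = lambda x: 1.0 / (1.0 + math.exp(-x))
    mu2, mu3, sig2, sig3 = mu2_0, mu3_0, sigma2_0, sigma3_0
    out = []
    for uk in u:
        muhat1 = s(mu2)
        muhat2 = mu2
        muhat3 = mu3
        sigma1hat = muhat1 * (1 - muhat1)
        sigma2hat = sig2 + math.exp(mu3 + omega2)
        sigma3hat = sig3 + math.exp(omega3)
        delta1 = uk - s(mu2)
        sigma2_new = 1.0 / (sigma1hat + 1.0 / sigma2hat)
        mu2_new = mu2 + sigma2_new * delta1
        w2 = math.exp(mu3 + omega2) / (sig2 + math.exp(mu3 + omega2))
        r2 = (math.exp(mu3 + omega2) - sig2) / (sig2 + math.exp(mu3 + omega2))
        delta2 = (sigma2_new + (mu2_new - mu2) ** 2) / \
            (sig2 + math.exp(mu3 + omega2)) - 1.0
        sigma3_new = sigma3hat / (1 + sigma3hat * w2 * (w2 + r2 * delta2) / 2)
        mu3_new = mu3 + sigma3_new * w2 * delta2 / 2
        delta3 = (sigma3_new + (mu3_new - muhat3) ** 2) / sigma3hat - 1.0
        epsilon2 = sigma2_new * delta1
        if epsilon3_form == "printed":
            epsilon3 = sigma2hat * delta3 / sigma3_new
        else:
            epsilon3 = sigma3_new * w2 * delta2 / 2
        unc1 = sigma1hat
        unc2 = s(mu2_new) * (1 - s(mu2_new)) * sigma2_new
        unc3 = math.exp(mu3 + omega2)
        alpha1 = (s(mu2_new) - s(mu2)) / (uk - s(mu2))
        alpha2 = sigma2_new
        alpha3 = sigma3_new * math.exp(mu3 + omega2) / (2 * sigma2hat)
        out.append(dict(alpha1=alpha1, alpha2=alpha2, alpha3=alpha3,
                        muhat1=muhat1, muhat2=muhat2, muhat3=muhat3,
                        sigma2hat=sigma2hat, sigma3hat=sigma3hat,
                        unc1=unc1, unc2=unc2, unc3=unc3,
                        epsilon2=epsilon2, epsilon3=epsilon3))
        mu2, mu3, sig2, sig3 = mu2_new, mu3_new, sigma2_new, sigma3_new
    return pd.DataFrame(out)


class TestSigmoid:
    def test_symmetry_and_saturation(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(800.0) == pytest.approx(1.0)
        assert sigmoid(-800.0) == pytest.approx(0.0)

    @given(st.floats(-50, 50))
    @settings(max_examples=50, deadline=None)
    def test_antisymmetry(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0, abs=1e-12)


class TestOneStep:
    def test_hand_computed_first_step(self):
        cfg = HGFConfig(omega2=-2.0, mu2_0=0.0, sigma2_0=1.0,
                        mu3_0=1.0, sigma3_0=1.0)
        _, rec = hgf_step(HGFState.initial(cfg), 1, cfg)
        assert rec["muhat1"] == pytest.approx(0.5, rel=1e-10)
        assert rec["unc1"] == pytest.approx(0.25, rel=1e-10)
        assert rec["sigma2hat"] == pytest.approx(1.0 + np.exp(-1.0), rel=1e-10)
        assert rec["sigma2"] == pytest.approx(1.019307125774738, rel=1e-10)
        assert rec["mu2"] == pytest.approx(0.509653562887369, rel=1e-10)

    def test_muhat1_half_whenever_mu2_zero(self):
        cfg = HGFConfig()
        for mu3 in (-2.0, 0.0, 3.0):
            state = HGFState(mu2=0.0, mu3=mu3, sigma2=2.0, sigma3=0.5)
            _, rec = hgf_step(state, 0, cfg)
            assert rec["muhat1"] == 0.5
            assert rec["unc1"] == 0.25

    def test_alpha1_guard_near_singularity(self):
        # saturate mu2 so that u - s(mu2^(k-1)) underflows the guard
        cfg = HGFConfig(alpha1_guard=1e-8)
        state = HGFState(mu2=40.0, mu3=1.0, sigma2=1.0, sigma3=1.0)
        _, rec = hgf_step(state, 1, cfg)
        assert np.isnan(rec["alpha1"])


class TestTrajectories:
    def test_full_run_emits_13_parameters(self, default_session, default_hgf):
        traj = default_hgf["all"]
        assert len(traj) == 216
        assert set(PARAM_NAMES) <= set(traj.columns)
        assert len(PARAM_NAMES) == 13
        assert sorted(PARAM_LEVELS.values()) == [1] * 3 + [2] * 5 + [3] * 5
        finite = traj[list(PARAM_NAMES)].drop(columns="alpha1").notna()
        assert finite.all().all()

    def test_oracle_equivalence_on_random_sequences(self):
        rng = np.random.default_rng(7)
        cfg = HGFConfig()
        for _ in range(10):
            u = rng.integers(0, 2, 20)
            got = run_hgf(u, cfg)
            want = _oracle_run(u, cfg.omega2, cfg.omega3, cfg.mu2_0,
                               cfg.sigma2_0, cfg.mu3_0, cfg.sigma3_0)
            for name in PARAM_NAMES:
                np.testing.assert_allclose(
                    got[name].to_numpy(), want[name].to_numpy(),
                    rtol=1e-10, err_msg=name)

    def test_invariants_along_default_run(self, default_hgf):
        traj = default_hgf["all"]
        assert ((traj["muhat1"] > 0) & (traj["muhat1"] < 1)).all()
        np.testing.assert_allclose(traj["unc1"],
                                   traj["muhat1"] * (1 - traj["muhat1"]))
        assert (traj["sigma2"] > 0).all()
        assert (traj["sigma2"] <= traj["sigma2hat"] + 1e-15).all()
        # predicted level-3 variance is the previous posterior plus exp(omega3)
        cfg = HGFConfig()
        prev_sigma3 = np.r_[cfg.sigma3_0, traj["sigma3"].to_numpy()[:-1]]
        np.testing.assert_allclose(traj["sigma3hat"],
                                   prev_sigma3 + np.exp(cfg.omega3))

    def test_all_expected_outcomes_strengthen_belief(self):
        traj = run_hgf(np.zeros(100, dtype=int))
        assert (np.diff(traj["mu2"]) < 0).all()

    def test_determinism(self, default_session):
        u = default_session.contingency_vector()
        assert run_hgf(u).equals(run_hgf(u))

    def test_epsilon3_form_switch(self, default_session):
        u = default_session.contingency_vector()
        printed = run_hgf(u, HGFConfig(epsilon3_form="printed"))
        canonical = run_hgf(u, HGFConfig(epsilon3_form="canonical"))
        assert not np.allclose(printed["epsilon3"], canonical["epsilon3"])
        # the two forms agree on everything else
        np.testing.assert_allclose(printed["mu3"], canonical["mu3"])


class TestAversiveSubset:
    def test_default_session_keeps_108(self, default_session, default_hgf):
        sub = subset_aversive(default_hgf["all"], default_session)
        assert len(sub) == 108
        aversive_k = default_session.analyzed.query(
            "outcome == 'aversive'")["k"].to_numpy()
        assert np.array_equal(sub["k"].to_numpy(), aversive_k)

    def test_length_mismatch_rejected(self, default_session, default_hgf):
        with pytest.raises(ValueError, match="mismatch"):
            subset_aversive(default_hgf["all"].iloc[:100], default_session)


class TestEstimatorInterface:
    def test_get_set_params_roundtrip(self):
        f = HGFFilter(omega2=-3.0)
        params = f.get_params()
        assert params["omega2"] == -3.0
        f2 = HGFFilter().set_params(**params)
        assert f2.omega2 == -3.0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            HGFConfig(sigma2_0=0.0)
        with pytest.raises(ValueError):
            HGFConfig(epsilon3_form="bogus")
        with pytest.raises(ValueError):
            HGFFilter().transform([])
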