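"""Synthetic recordings, pupil traces, and receptive-field units.

This module generates trial-aligned deconvolved-activity matrices, platform
excursions and pupil-diameter series with the statistical structure the
analysis pipeline assumes, together with ground-truth labels for recovery
tests.  Activity is generated directly in deconvolved-spike-estimate space
(the pipeline's input domain); no calcium-kernel forward model or imaging
frames are simulated.

Cohort presets encode the qualitative population patterns of the study
conditions they emulate:

* ``WT_SC`` / ``WT_V1AXON`` — adaptation of aversive responses in the late
  stable epoch and recovery under volatility (LS < ES, LS < VL), stronger in
  the late response components.
* ``SCN2A_SC`` — no stable-epoch adaptation but volatility over-enhancement
  (VL > ES, LS), stronger in the early components.
* ``*_V1BLOCK``, ``*_RGC``, ``SCN2A_V1AXON`` — flat across epochs.

All cells additionally carry a slow power-law amplitude decay over presented
trials (photobleaching), trial-amplitude noise (truncated Gaussian) and
frame-level shot noise (half-normal).  A labeled subset of cells has its
aversive-response gain linked to a named observer parameter of the
hierarchical Gaussian filter, for coupling-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from . import hgf as hgf_mod
from .task_design import SessionDesign, ANALYSIS_EPOCHS

__all__ = [
    "CohortPreset",
    "PRESETS",
    "NoiseConfig",
    "DecayConfig",
    "Recording",
    "PupilRaw",
    "simulate_recording",
    "simulate_pupil",
    "simulate_rf_unit",
]


@dataclass(frozen=True)
class CohortPreset:
    """Per-condition response statistics for the synthetic generator."""

    name: str
    #: mean aversive-response multiplier per analysis epoch (ES, LS, VL)
    aversive_mult: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: cue-response multiplier per epoch
    cue_mult: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: omitted-outcome response multiplier per epoch (responses near zero)
    omitted_mult: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: weighting of the epoch modulation on the early vs late half of the
    #: outcome window (1, 1) = uniform
    early_late_weight: tuple[float, float] = (1.0, 1.0)
    #: fraction of cells responsive to the aversive stimuli
    responsive_fraction: float = 0.5
    #: fraction of cells responsive to the cue stimuli
    cue_responsive_fraction: float = 0.6
    #: fraction of cue-responsive cells with orientation-selective responses
    selective_fraction: float = 0.25
    #: of the selective cells, fraction preferring the vertical cue
    vertical_pref_fraction: float = 0.6
    #: fraction of responsive cells with observer-parameter-linked gain
    hgf_linked_fraction: float = 0.0
    #: (parameter name, signed gain) choices for linked cells
    hgf_links: tuple[tuple[str, float], ...] = ()
    #: responsiveness-threshold class ("somata" -> 1.0, "axon" -> 0.75)
    signal_class: str = "somata"
    # pupillometry
    pupil_median_mm2: float = 0.79
    #: aversive-outcome dilation amplitude (fractional area) per epoch
    dilation_amp: tuple[float, float, float] = (0.25, 0.25, 0.25)
    #: cue-evoked constriction amplitude (fractional area)
    constriction_amp: float = 0.08

    def __post_init__(self) -> None:
        for m in (*self.aversive_mult, *self.cue_mult, *self.omitted_mult):
            if m < 0:
                raise ValueError("multipliers must be non-negative")
        for f in (self.responsive_fraction, self.cue_responsive_fraction,
                  self.selective_fraction, self.hgf_linked_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


PRESETS: Mapping[str, CohortPreset] = {
    p.name: p for p in (
        CohortPreset(
            name="WT_SC",
            aversive_mult=(1.0, 0.65, 1.0),
            cue_mult=(1.0, 1.0, 1.0),
            early_late_weight=(0.5, 1.5),
            hgf_linked_fraction=0.2,
            hgf_links=(("unc3", 0.5), ("muhat3", 0.5)),
            signal_class="somata",
            pupil_median_mm2=0.79,
            dilation_amp=(0.25, 0.25, 0.15),
        ),
        CohortPreset(
            name="SCN2A_SC",
            aversive_mult=(1.0, 1.0, 1.35),
            cue_mult=(1.0, 1.0, 0.8),
            early_late_weight=(1.5, 0.5),
            hgf_linked_fraction=0.2,
            hgf_links=(("muhat1", 0.5), ("unc1", 0.5)),
            signal_class="somata",
            pupil_median_mm2=0.62,
            dilation_amp=(0.20, 0.20, 0.20),
        ),
        CohortPreset(name="WT_V1BLOCK", signal_class="somata",
                     pupil_median_mm2=0.79, dilation_amp=(0.2, 0.2, 0.2)),
        CohortPreset(name="SCN2A_V1BLOCK", signal_class="somata",
                     pupil_median_mm2=0.62, dilation_amp=(0.2, 0.2, 0.2)),
        CohortPreset(
            name="WT_V1AXON",
            aversive_mult=(1.0, 0.65, 1.0),
            early_late_weight=(0.5, 1.5),
            signal_class="axon",
            pupil_median_mm2=0.79,
            dilation_amp=(0.25, 0.25, 0.15),
        ),
        CohortPreset(name="SCN2A_V1AXON", signal_class="axon",
                     pupil_median_mm2=0.62),
        CohortPreset(name="WT_RGC", signal_class="axon", pupil_median_mm2=0.79),
        CohortPreset(name="SCN2A_RGC", signal_class="axon", pupil_median_mm2=0.62),
    )
}

#: flat reference preset for null/type-I calibration runs
FLAT_PRESET = CohortPreset(name="FLAT")


@dataclass(frozen=True)
class NoiseConfig:
    """Trial- and frame-level noise of the synthetic recordings."""

    amp_cv: float = 0.3          # truncated-Gaussian CV of trial amplitudes
    frame_sigma: float = 0.05    # half-normal frame noise (deconvolved units)
    excursion_rate: float = 0.05  # fraction of trials with large excursion
    excursion_scale_mm: float = 0.05  # typical quiescent excursion


@dataclass(frozen=True)
class DecayConfig:
    """Power-law photobleaching of response amplitudes, g(k) = a*k^b + c
    over the presented trial index."""

    a: float = 0.5
    b: float = -0.3
    c: float = 0.7
    enabled: bool = True

    def curve(self, k: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return np.ones_like(np.asarray(k, dtype=float))
        return self.a * np.asarray(k, dtype=float) ** self.b + self.c


@dataclass
class Recording:
    """A cells x frames deconvolved-activity matrix with event alignment."""

    activity: np.ndarray          # (n_cells, n_frames), non-negative
    frame_rate: float             # Hz
    events: pd.DataFrame          # per presented trial: onset/outcome frames
    excursion: np.ndarray         # per presented trial, mean |excursion| in mm
    metadata: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.activity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.activity.shape[1]

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("activity", data=self.activity, compression="gzip")
            f.create_dataset("excursion", data=self.excursion)
            f.attrs["frame_rate"] = self.frame_rate
            ev = f.create_group("events")
            ev.attrs["columns"] = list(self.events.columns)
            for col in self.events.columns:
                data = self.events[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                ev.create_dataset(col, data=data)
            meta = f.create_group("metadata")
            for k, v in self.metadata.items():
                meta.attrs[k] = v

    @classmethod
    def from_hdf5(cls, path) -> "Recording":
        with h5py.File(path, "r") as f:
            events = {}
            order = [c for c in f["events"].attrs.get("columns",
                                                      list(f["events"]))]
            for col in order:
                data = f["events"][col][()]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                events[col] = data
            return cls(
                activity=f["activity"][()],
                frame_rate=float(f.attrs["frame_rate"]),
                events=pd.DataFrame(events),
                excursion=f["excursion"][()],
                metadata=dict(f["metadata"].attrs),
            )


@dataclass
class PupilRaw:
    """Pupil long-axis diameter per video frame, with trial alignment."""

    diameter_px: np.ndarray
    frame_rate: float = 30.0
    calibration_px2_per_mm2: float = 6e3
    events: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def _resolve_preset(preset: CohortPreset | str) -> CohortPreset:
    if isinstance(preset, CohortPreset):
        return preset
    try:
        return PRESETS[preset] if preset != "FLAT" else FLAT_PRESET
    except KeyError:
        raise KeyError(
            f"unknown preset {preset!r}; available: {sorted(PRESETS)} or 'FLAT'"
        ) from None


def _response_kernel(rng: np.random.Generator, window_frames: int,
                     frame_rate: float) -> np.ndarray:
    """A unit-peak temporal response kernel with randomized peak latency.

    Randomized latency emulates retinotopy: each moving/looming stimulus
    reaches a given cell's receptive field at a different time.
    """
    t = np.arange(window_frames) / frame_rate
    peak = rng.uniform(0.2, 0.85) * t[-1]
    width = rng.uniform(0.12, 0.35)
    k = np.exp(-0.5 * ((t - peak) / width) ** 2)
    return k / k.max()


def _epoch_multiplier(preset: CohortPreset, kind: str) -> dict[str, tuple]:
    table = {"aversive": preset.aversive_mult, "cue": preset.cue_mult,
             "omitted": preset.omitted_mult}[kind]
    mult = dict(zip(ANALYSIS_EPOCHS, table))
    return mult


def simulate_recording(
    session: SessionDesign,
    preset: CohortPreset | str,
    n_cells: int,
    seed: int,
    frame_rate: float = 30.9,
    noise: NoiseConfig = NoiseConfig(),
    decay: DecayConfig = DecayConfig(),
    hgf_trajectories: pd.DataFrame | None = None,
    animal_id: str = "synthetic",
) -> tuple[Recording, pd.DataFrame]:
    """Simulate one animal's recording for a session.

    Returns the :class:`Recording` and a per-cell ground-truth table
    (responsiveness, cue preference, linked observer parameter and gain).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    preset = _resolve_preset(preset)
    rng = np.random.default_rng(seed)

    trials = session.trials
    n_trials = len(trials)
    timing = session.timing
    cue_len = int(round(timing["cue_duration_s"] * frame_rate))
    out_len = int(round(timing["outcome_duration_s"] * frame_rate))
    n_frames = int(round((trials["onset_s"].iloc[-1]
                          + timing["trial_duration_s"] + 2.0) * frame_rate))

    cue_on = np.round(trials["onset_s"].to_numpy() * frame_rate).astype(int)
    out_on = np.round(trials["outcome_onset_s"].to_numpy() * frame_rate).astype(int)

    # ---- per-cell ground truth ------------------------------------------
    responsive = rng.random(n_cells) < preset.responsive_fraction
    cue_resp = rng.random(n_cells) < preset.cue_responsive_fraction
    selective = cue_resp & (rng.random(n_cells) < preset.selective_fraction)
    pref_v = rng.random(n_cells) < preset.vertical_pref_fraction
    pref = np.where(selective, np.where(pref_v, "vertical", "horizontal"), "none")

    base_amp = np.where(responsive, rng.uniform(0.6, 1.4, n_cells), 0.0)
    cue_amp = np.where(cue_resp, rng.uniform(0.4, 1.0, n_cells), 0.0)

    linked = responsive & (rng.random(n_cells) <
                           (preset.hgf_linked_fraction /
                            max(preset.responsive_fraction, 1e-12)))
    link_param = np.full(n_cells, "none", dtype=object)
    link_gain = np.zeros(n_cells)
    if preset.hgf_links and linked.any():
        choices = rng.integers(0, len(preset.hgf_links), n_cells)
        for i in np.flatnonzero(linked):
            name, gain = preset.hgf_links[choices[i]]
            link_param[i] = name
            link_gain[i] = gain

    # ---- observer-parameter gain series over analyzed trials -------------
    link_series = {}
    if (link_gain != 0).any():
        if hgf_trajectories is None:
            hgf_trajectories = hgf_mod.run_hgf(session.contingency_vector())
        for name in set(link_param) - {"none"}:
            x = hgf_trajectories[name].to_numpy(dtype=float)
            x = x - np.nanmean(x)
            sd = np.nanstd(x)
            x = x / sd if sd > 0 else x
            link_series[name] = np.nan_to_num(x)

    # map presented trial -> analyzed index (or -1)
    k_analyzed = trials["k"].to_numpy() - 1  # -1 for non-analyzed

    # ---- stimulus-type kernels -------------------------------------------
    types = sorted(t for t in trials["aversive_type"].unique() if t != "none")
    av_kernels = {
        t: np.stack([_response_kernel(rng, out_len, frame_rate)
                     for _ in range(n_cells)])
        for t in types
    }
    cue_kernel = np.stack([_response_kernel(rng, cue_len, frame_rate)
                           for _ in range(n_cells)])
    # per-cell per-type amplitude heterogeneity
    type_amp = {t: base_amp * rng.uniform(0.6, 1.4, n_cells) for t in types}

    # early/late component weighting of the epoch modulation
    w_early, w_late = preset.early_late_weight
    half = out_len // 2
    comp_w = np.ones(out_len)
    comp_w[:half] = w_early
    comp_w[half:] = w_late

    av_mult = _epoch_multiplier(preset, "aversive")
    cue_mult = _epoch_multiplier(preset, "cue")

    g = decay.curve(trials["k_presented"].to_numpy())

    activity = np.zeros((n_cells, n_frames), dtype=np.float32)

    sel_gain = 1.8  # vertical/horizontal response ratio of selective cells
    for i in range(n_trials):
        epoch = trials["epoch"].iloc[i]
        m_av = av_mult.get(epoch, av_mult["ES"])
        m_cue = cue_mult.get(epoch, cue_mult["ES"])

        # cue response
        amp_c = cue_amp * m_cue * g[i]
        cue = trials["cue"].iloc[i]
        sel_mult = np.where(
            pref == "none", 1.0,
            np.where(pref == cue, sel_gain, 1.0) / np.sqrt(sel_gain),
        )
        amp_c = amp_c * sel_mult
        eps = 1.0 + noise.amp_cv * rng.standard_normal(n_cells)
        amp_c = np.clip(amp_c * np.clip(eps, 0.0, None), 0.0, None)
        s0, s1 = cue_on[i], cue_on[i] + cue_len
        activity[:, s0:s1] += (amp_c[:, None] * cue_kernel).astype(np.float32)

        # outcome response
        if trials["outcome"].iloc[i] == "aversive":
            t = trials["aversive_type"].iloc[i]
            amp = type_amp[t] * g[i]
            if link_series and k_analyzed[i] >= 0:
                lk = np.ones(n_cells)
                for name, series in link_series.items():
                    sel = link_param == name
                    lk[sel] += link_gain[sel] * series[k_analyzed[i]]
                amp = amp * np.clip(lk, 0.0, None)
            eps = 1.0 + noise.amp_cv * rng.standard_normal(n_cells)
            amp = np.clip(amp * np.clip(eps, 0.0, None), 0.0, None)
            # epoch modulation with early/late weighting
            mod = 1.0 + (m_av - 1.0) * comp_w
            shaped = av_kernels[t] * mod[None, :]
            s0, s1 = out_on[i], out_on[i] + out_len
            activity[:, s0:s1] += (amp[:, None] * shaped).astype(np.float32)
        # omitted outcome: no response (gray screen)

    activity += np.abs(
        rng.standard_normal(activity.shape).astype(np.float32)
    ) * np.float32(noise.frame_sigma)

    # platform excursion: mostly quiescent, occasional large excursions
    excursion = np.abs(rng.normal(0.0, noise.excursion_scale_mm, n_trials))
    big = rng.random(n_trials) < noise.excursion_rate
    excursion[big] = rng.uniform(0.3, 1.0, big.sum())

    events = pd.DataFrame({
        "k_presented": trials["k_presented"].to_numpy(),
        "k": trials["k"].to_numpy(),
        "epoch": trials["epoch"].to_numpy(),
        "cue": trials["cue"].to_numpy(),
        "outcome": trials["outcome"].to_numpy(),
        "aversive_type": trials["aversive_type"].to_numpy(),
        "cue_onset_frame": cue_on,
        "outcome_onset_frame": out_on,
    })
    ground_truth = pd.DataFrame({
        "cell": np.arange(n_cells),
        "responsive": responsive,
        "base_amp": base_amp,
        "cue_responsive": cue_resp,
        "orientation_pref": pref,
        "hgf_param": link_param,
        "hgf_gain": link_gain,
    })
    rec = Recording(
        activity=activity,
        frame_rate=frame_rate,
        events=events,
        excursion=excursion,
        metadata={"animal_id": animal_id, "preset": preset.name, "seed": seed},
    )
    return rec, ground_truth


def simulate_pupil(
    session: SessionDesign,
    preset: CohortPreset | str,
    seed: int,
    frame_rate: float = 30.0,
    noise_sd: float = 0.02,
    calibration_px2_per_mm2: float = 6e3,
) -> PupilRaw:
    """Simulate a pupil long-axis-diameter series for one session.

    Cue onsets evoke a transient constriction; aversive outcomes evoke a
    dilation whose magnitude follows the preset's per-epoch amplitudes.
    Baseline area is set so the session median matches the preset.  Noise is
    smooth (Gaussian-filtered white noise) as in slow pupil fluctuations.
    """
    preset = _resolve_preset(preset)
    rng = np.random.default_rng(seed)
    trials = session.trials
    n_frames = int(round((trials["onset_s"].iloc[-1]
                          + session.timing["trial_duration_s"] + 5.0)
                         * frame_rate))
    t = np.arange(n_frames) / frame_rate

    rel = np.ones(n_frames)  # relative pupil area

    # evoked kernels
    def _alpha_kernel(dur_s: float, tau_s: float) -> np.ndarray:
        tt = np.arange(int(round(dur_s * frame_rate))) / frame_rate
        k = (tt / tau_s) * np.exp(1.0 - tt / tau_s)
        return k

    constr = _alpha_kernel(2.0, 0.5)
    dilate = _alpha_kernel(4.0, 1.2)
    dil_amp = dict(zip(ANALYSIS_EPOCHS, preset.dilation_amp))

    cue_on = np.round(trials["onset_s"].to_numpy() * frame_rate).astype(int)
    out_on = np.round(trials["outcome_onset_s"].to_numpy() * frame_rate).astype(int)
    for i in range(len(trials)):
        s0 = cue_on[i]
        rel[s0:s0 + len(constr)] -= preset.constriction_amp * constr[
            :max(0, min(len(constr), n_frames - s0))]
        if trials["outcome"].iloc[i] == "aversive":
            epoch = trials["epoch"].iloc[i]
            amp = dil_amp.get(epoch, preset.dilation_amp[0])
            amp *= 1.0 + 0.15 * rng.standard_normal()
            s0 = out_on[i]
            rel[s0:s0 + len(dilate)] += amp * dilate[
                :max(0, min(len(dilate), n_frames - s0))]

    if noise_sd > 0:
        rel += gaussian_filter1d(rng.standard_normal(n_frames), sigma=frame_rate
                                 ) * noise_sd * np.sqrt(2 * np.sqrt(np.pi) * frame_rate)
    rel = np.clip(rel, 0.2, None)

    # diameter in pixels from target median area
    area_px2 = preset.pupil_median_mm2 * calibration_px2_per_mm2
    d0 = 2.0 * np.sqrt(area_px2 / np.pi / np.median(rel))
    diameter = d0 * np.sqrt(rel)

    events = pd.DataFrame({
        "k_presented": trials["k_presented"].to_numpy(),
        "k": trials["k"].to_numpy(),
        "epoch": trials["epoch"].to_numpy(),
        "outcome": trials["outcome"].to_numpy(),
        "cue_onset_frame": cue_on,
        "outcome_onset_frame": out_on,
    })
    return PupilRaw(diameter_px=diameter, frame_rate=frame_rate,
                    calibration_px2_per_mm2=calibration_px2_per_mm2,
                    events=events,
                    metadata={"preset": preset.name, "seed": seed})


def simulate_rf_unit(
    rf_center: tuple[float, float],
    rf_sd: float | tuple[float, float],
    stimulus,
    gain: float = 1.0,
    latency_s: float = 0.05,
    noise_sd: float = 0.0,
    seed: int | None = None,
    sample_rate: float = 60.0,
) -> tuple[np.ndarray, dict]:
    """Simulate a linear-Gaussian unit responding to a checkerboard movie.

    ``rf_center`` is (x, y) in field units; ``rf_sd`` the Gaussian SD in
    fields (scalar isotropic or (sd_x, sd_y)).  Returns the activity trace
    sampled on the reverse-correlation bin clock and the ground truth.
    A zero-gain unit yields a structureless trace (noise only).
    """
    frames = stimulus.frames  # (n_frames, ny, nx) in {0,1}
    ny, nx = frames.shape[1:]
    x0, y0 = rf_center
    if not (0 <= x0 < nx and 0 <= y0 < ny):
        raise ValueError(f"rf_center {rf_center} outside the {nx}x{ny} grid")
    sdx, sdy = (rf_sd, rf_sd) if np.isscalar(rf_sd) else rf_sd
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    w = np.exp(-0.5 * (((xs - x0) / sdx) ** 2 + ((ys - y0) / sdy) ** 2))

    reps = int(round(sample_rate / stimulus.update_hz))
    s = np.repeat(frames.reshape(len(frames), -1).astype(np.float32) - 0.5,
                  reps, axis=0)
    drive = gain * (s @ w.ravel().astype(np.float32))

    lag = int(round(latency_s * sample_rate))
    activity = np.zeros(len(drive), dtype=np.float64)
    activity[lag:] = drive[:len(drive) - lag]
    offset = 4.0 * max(drive.std(), 1e-12)
    activity = activity + offset
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        activity = activity + noise_sd * rng.standard_normal(len(activity))
    activity = np.clip(activity, 0.0, None)
    truth = {"center": (x0, y0), "sd": (sdx, sdy), "latency_s": latency_s,
             "size": sdx + sdy, "gain": gain}
    return activity, truth
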