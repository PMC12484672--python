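"""Pupil-area dynamics during the task.

The pupil is parameterized by its long-axis diameter (invariant to eye
position for a circular pupil on a spherical eyeball); area follows from the
circular-area formula under a fixed pixel-to-mm calibration
(6e3 pixel^2 = 1 mm^2).  Evoked dynamics are expressed as the proportional
change a(t) = <A(t)/A0>_trials relative to the 10-frame pre-onset baseline
A0, summarized over the 2-s outcome window (abar) and normalized across
epochs (da = abar - <abar>_epochs, zero-sum per animal).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .response_analysis import _sequential_anova, _dummies, tukey_kramer
from .synthetic_data import PupilRaw
from .task_design import ANALYSIS_EPOCHS

__all__ = [
    "area_from_long_axis",
    "evoked_trace",
    "pupil_epoch_summary",
    "pupil_group_stats",
]

N_BASELINE_FRAMES = 10


def area_from_long_axis(diameter_px, calibration_px2_per_mm2: float = 6e3
                        ) -> np.ndarray:
    """Circular pupil area in mm^2 from the long-axis diameter in pixels.

    Non-positive or non-finite diameters are marked missing (NaN).
    """
    d = np.asarray(diameter_px, dtype=float)
    area = np.pi * (d / 2.0) ** 2 / calibration_px2_per_mm2
    bad = ~np.isfinite(d) | (d <= 0)
    area = np.where(bad, np.nan, area)
    return area


def evoked_trace(area: np.ndarray, onsets: np.ndarray, window_len: int,
                 n_baseline: int = N_BASELINE_FRAMES,
                 max_missing_fraction: float = 0.2) -> tuple[np.ndarray, int]:
    """Trial-averaged proportional pupil change around stimulus onsets.

    For each trial, A(t)/A0 with A0 the mean area over ``n_baseline``
    pre-onset frames; trials with insufficient baseline frames or more than
    ``max_missing_fraction`` missing frames in baseline or window are
    dropped.  Returns (a(t) of length window_len, number of dropped trials).
    """
    area = np.asarray(area, dtype=float)
    rows = []
    dropped = 0
    for onset in np.asarray(onsets, dtype=int):
        if onset - n_baseline < 0 or onset + window_len > len(area):
            dropped += 1
            continue
        base = area[onset - n_baseline:onset]
        win = area[onset:onset + window_len]
        if (np.mean(~np.isfinite(base)) > max_missing_fraction
                or np.mean(~np.isfinite(win)) > max_missing_fraction):
            dropped += 1
            continue
        a0 = np.nanmean(base)
        if not np.isfinite(a0) or a0 <= 0:
            dropped += 1
            continue
        rows.append(win / a0)
    if not rows:
        raise RuntimeError("all trials dropped while computing the evoked trace")
    return np.nanmean(np.stack(rows), axis=0), dropped


def pupil_epoch_summary(pupil: PupilRaw, window_s: float = 2.0,
                        stimulus: str = "aversive",
                        epochs: tuple[str, ...] = ANALYSIS_EPOCHS) -> pd.DataFrame:
    """Per-epoch evoked summaries abar and da for one animal's session.

    Alignment is to the outcome onsets of aversive trials.  Also reports
    the session median pupil area (over all frames).
    """
    if pupil.events is None:
        raise ValueError("pupil trace lacks an event table")
    area = area_from_long_axis(pupil.diameter_px, pupil.calibration_px2_per_mm2)
    wlen = int(round(window_s * pupil.frame_rate))
    rows = []
    for epoch in epochs:
        ev = pupil.events
        sel = (ev["epoch"] == epoch) & (ev["outcome"] == stimulus)
        onsets = ev.loc[sel, "outcome_onset_frame"].to_numpy()
        a_t, dropped = evoked_trace(area, onsets, wlen)
        rows.append({"epoch": epoch, "abar": float(np.nanmean(a_t)),
                     "n_dropped": dropped})
    df = pd.DataFrame(rows)
    df["da"] = df["abar"] - df["abar"].mean()
    df["median_area_mm2"] = float(np.nanmedian(area))
    return df


def pupil_group_stats(per_animal: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Group statistics of the pupil summaries.

    ``per_animal`` is long-format with columns animal, group, epoch, da,
    median_area_mm2.  Computes the Mann-Whitney U test on median areas
    between the two groups (if exactly two), a two-way ANOVA (group x epoch)
    on da, and Tukey-Kramer pairwise epoch comparisons within each group.
    """
    required = {"animal", "group", "epoch", "da", "median_area_mm2"}
    if missing := required - set(per_animal.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    out: dict = {}
    groups = sorted(per_animal["group"].unique())
    counts = per_animal.groupby("group")["animal"].nunique()
    if (counts < 2).any():
        import warnings
        warnings.warn(f"singleton group(s) {counts[counts < 2].index.tolist()}; "
                      "tests skipped", stacklevel=2)
        return {"skipped": True, "n_animals": counts.to_dict()}

    if len(groups) == 2:
        med = per_animal.drop_duplicates(["animal", "group"])
        a = med.loc[med["group"] == groups[0], "median_area_mm2"]
        b = med.loc[med["group"] == groups[1], "median_area_mm2"]
        u = stats.mannwhitneyu(a, b, alternative="two-sided")
        out["median_area"] = {
            "groups": groups,
            "medians": [float(a.median()), float(b.median())],
            "U": float(u.statistic), "p": float(u.pvalue),
        }

    y = per_animal["da"].to_numpy(dtype=float)
    ge = (per_animal["group"].astype(str) + "@"
          + per_animal["epoch"].astype(str)).to_numpy()
    # animal block makes the error term the animal x epoch residual
    blocks = [
        ("group", _dummies(per_animal["group"])),
        ("animal(group)", _dummies(per_animal["animal"])),
        ("epoch", _dummies(per_animal["epoch"])),
        ("group x epoch", _dummies(ge)),
    ]
    anova = _sequential_anova(blocks, y)
    out["anova"] = anova
    out["p_interaction"] = float(
        anova.loc[anova["term"] == "group x epoch", "p"].iloc[0])

    tukey = {}
    for g, sub in per_animal.groupby("group"):
        if sub["epoch"].nunique() < 2 or sub["animal"].nunique() < 2:
            continue
        tukey[g] = tukey_kramer(sub["da"].to_numpy(), sub["epoch"].to_numpy(),
                                blocks=sub["animal"].to_numpy(), alpha=alpha)
    out["tukey"] = tukey
    return out
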