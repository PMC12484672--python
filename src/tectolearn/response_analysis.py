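"""Trial-aligned population response analysis.

Converts deconvolved activity to within-epoch z-scores Z(t), forms
trial-averaged evoked traces z(t) (excluding trials with excessive platform
excursion), selects responsive cells by a peak-z threshold (1 for somata,
0.75 for axonal boutons), and computes the contextual-modulation statistic

    dz = zbar - <zbar>_epochs,

the per-epoch mean outcome response minus its across-epoch mean.  Group
inference uses a nested ANOVA (mouse within experimental group) on zbar and
Tukey-Kramer pairwise epoch comparisons on dz, plus the orientation-bias
statistics of the cue responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import Recording
from .task_design import ANALYSIS_EPOCHS

__all__ = [
    "RESPONSIVE_THRESHOLDS",
    "zscore_epoch",
    "epoch_zscores",
    "trial_average",
    "epoch_outcome_traces",
    "responsive_mask",
    "epoch_modulation",
    "compare_epochs",
    "orientation_bias",
]

#: predetermined peak-z responsiveness thresholds by signal class
RESPONSIVE_THRESHOLDS = {"somata": 1.0, "axon": 0.75}

EXCURSION_THRESHOLD_MM = 0.25


class AllTrialsExcludedError(RuntimeError):
    pass


def zscore_epoch(segment: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score a cells x frames activity segment per cell.

    Returns (Z, valid): zero-variance cells are flagged invalid and their
    rows set to NaN for downstream exclusion.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 2 or segment.shape[1] < 2:
        raise ValueError("need a cells x frames segment with >= 2 frames")
    mu = segment.mean(axis=1, keepdims=True)
    sd = segment.std(axis=1, ddof=1, keepdims=True)
    valid = sd[:, 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (segment - mu) / sd
    z[~valid] = np.nan
    return z, valid


def _epoch_frame_bounds(recording: Recording, epoch: str) -> tuple[int, int]:
    ev = recording.events
    sel = ev["epoch"] == epoch
    if not sel.any():
        raise ValueError(f"no trials with epoch {epoch!r} in recording")
    onsets = ev.loc[sel, "cue_onset_frame"].to_numpy()
    all_onsets = ev["cue_onset_frame"].to_numpy()
    step = int(np.median(np.diff(all_onsets))) if len(all_onsets) > 1 else \
        recording.n_frames - int(onsets[-1])
    start = int(onsets[0])
    stop = min(int(onsets[-1]) + step, recording.n_frames)
    return start, stop


def epoch_zscores(recording: Recording, epoch: str,
                  scope: str = "epoch") -> tuple[np.ndarray, int, np.ndarray]:
    """Within-epoch z-scored activity for one analysis epoch.

    Returns (Z, frame_offset, valid).  ``scope="session"`` z-scores over the
    whole recording instead and slices out the epoch.
    """
    start, stop = _epoch_frame_bounds(recording, epoch)
    if scope == "epoch":
        z, valid = zscore_epoch(recording.activity[:, start:stop])
    elif scope == "session":
        z_full, valid = zscore_epoch(recording.activity)
        z = z_full[:, start:stop]
    else:
        raise ValueError("scope must be 'epoch' or 'session'")
    return z, start, valid


def trial_average(Z: np.ndarray, onsets: np.ndarray, window_len: int,
                  excursion: np.ndarray | None = None,
                  threshold_mm: float = EXCURSION_THRESHOLD_MM,
                  ) -> tuple[np.ndarray, int]:
    """Average aligned windows over trials, excluding high-excursion trials.

    ``onsets`` are frame indices into ``Z``; returns (cells x window mean,
    number of excluded trials).
    """
    onsets = np.asarray(onsets, dtype=int)
    if excursion is not None:
        keep = np.asarray(excursion) <= threshold_mm
    else:
        keep = np.ones(len(onsets), dtype=bool)
    n_excluded = int((~keep).sum())
    kept = onsets[keep]
    if kept.size == 0:
        raise AllTrialsExcludedError(
            f"all {len(onsets)} trials excluded by the excursion filter")
    windows = np.stack([Z[:, o:o + window_len] for o in kept])
    return windows.mean(axis=0), n_excluded


def epoch_outcome_traces(
    recording: Recording,
    stimulus: str = "aversive",
    epochs: tuple[str, ...] = ANALYSIS_EPOCHS,
    window_s: float = 2.0,
    threshold_mm: float = EXCURSION_THRESHOLD_MM,
    scope: str = "epoch",
) -> dict:
    """Trial-averaged evoked traces z(t) per epoch for one outcome class.

    Returns a dict with per-epoch cells x window arrays (``traces``), the
    per-epoch excluded-trial counts, and the zero-variance validity mask.
    """
    ev = recording.events
    wlen = int(round(window_s * recording.frame_rate))
    traces: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}
    valid_all = np.ones(recording.n_cells, dtype=bool)
    for epoch in epochs:
        z, offset, valid = epoch_zscores(recording, epoch, scope=scope)
        valid_all &= valid
        sel = (ev["epoch"] == epoch) & (ev["outcome"] == stimulus)
        idx = np.flatnonzero(sel.to_numpy())
        onsets = ev.loc[sel, "outcome_onset_frame"].to_numpy() - offset
        exc = recording.excursion[idx] if recording.excursion is not None else None
        traces[epoch], excluded[epoch] = trial_average(
            z, onsets, wlen, exc, threshold_mm)
    return {"traces": traces, "excluded": excluded, "valid": valid_all,
            "window_len": wlen}


def responsive_mask(z_by_epoch: dict[str, np.ndarray],
                    threshold: float) -> np.ndarray:
    """Cells whose trial-averaged trace peaks above threshold in any epoch."""
    peaks = np.stack([np.nanmax(z, axis=1) for z in z_by_epoch.values()])
    with np.errstate(invalid="ignore"):
        return np.nanmax(peaks, axis=0) > threshold


def epoch_modulation(z_by_epoch: dict[str, np.ndarray],
                     cells: np.ndarray | None = None) -> pd.DataFrame:
    """Per-cell epoch-mean responses and their across-epoch normalization.

    Returns a long table (cell, epoch, zbar, dz) including the early/late
    split of the outcome window at its midpoint; dz sums to zero across
    epochs per cell by construction.
    """
    epochs = list(z_by_epoch)
    n_cells = next(iter(z_by_epoch.values())).shape[0]
    if cells is None:
        cells = np.arange(n_cells)
    wlen = next(iter(z_by_epoch.values())).shape[1]
    half = wlen // 2
    zbar = np.stack([z.mean(axis=1) for z in z_by_epoch.values()])      # E x N
    zbar_e = np.stack([z[:, :half].mean(axis=1) for z in z_by_epoch.values()])
    zbar_l = np.stack([z[:, half:].mean(axis=1) for z in z_by_epoch.values()])
    dz = zbar - zbar.mean(axis=0, keepdims=True)
    dz_e = zbar_e - zbar_e.mean(axis=0, keepdims=True)
    dz_l = zbar_l - zbar_l.mean(axis=0, keepdims=True)
    out = []
    for i, epoch in enumerate(epochs):
        out.append(pd.DataFrame({
            "cell": cells, "epoch": epoch,
            "zbar": zbar[i], "dz": dz[i],
            "zbar_early": zbar_e[i], "dz_early": dz_e[i],
            "zbar_late": zbar_l[i], "dz_late": dz_l[i],
        }))
    df = pd.concat(out, ignore_index=True)
    return df.dropna(subset=["zbar"]).reset_index(drop=True)


def analyze_recording(recording: Recording, signal_class: str = "somata",
                      stimulus: str = "aversive", window_s: float = 2.0,
                      scope: str = "epoch") -> pd.DataFrame:
    """Responsive-cell modulation table for one recording."""
    res = epoch_outcome_traces(recording, stimulus=stimulus, window_s=window_s,
                               scope=scope)
    mask = responsive_mask(res["traces"], RESPONSIVE_THRESHOLDS[signal_class])
    mask &= res["valid"]
    traces = {ep: z[mask] for ep, z in res["traces"].items()}
    table = epoch_modulation(traces, cells=np.flatnonzero(mask))
    return table


# ---------------------------------------------------------------------------
# group statistics


def _dummies(labels: pd.Series | np.ndarray) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels).astype(str)).to_numpy(dtype=float)


def _sequential_anova(blocks: list[tuple[str, np.ndarray]],
                      y: np.ndarray) -> pd.DataFrame:
    """Sequential (type-I) ANOVA over nested column blocks.

    Ranks are computed incrementally so nested/collinear factor codings
    (mouse within group) receive the correct degrees of freedom.
    """
    n = len(y)
    X = np.ones((n, 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    rank_prev = 1
    rows = []
    for name, block in blocks:
        X = np.column_stack([X, block])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        rows.append({"term": name, "ss": rss_prev - rss,
                     "df": rank - rank_prev})
        rss_prev, rank_prev = rss, rank
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise np.linalg.LinAlgError("singular design: no residual degrees of freedom")
    ms_resid = rss_prev / df_resid
    out = pd.DataFrame(rows)
    out["F"] = (out["ss"] / out["df"].clip(lower=1)) / ms_resid
    out["p"] = stats.f.sf(out["F"], out["df"].clip(lower=1), df_resid)
    out.loc[out["df"] <= 0, ["F", "p"]] = np.nan
    out.attrs["df_resid"] = df_resid
    out.attrs["ms_resid"] = ms_resid
    return out


def tukey_kramer(values, labels, blocks=None, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons via the studentized range.

    With ``blocks`` given (e.g. the cell or animal each observation belongs
    to), the error term is the block x label interaction residual — the
    appropriate one for within-block-normalized quantities such as dz,
    whose per-block zero-sum otherwise deflates the pooled variance and
    inflates the false-positive rate.  Without blocks, the pooled
    within-label variance is used.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]
    names = np.unique(labels)
    k = len(names)
    if k < 2:
        raise ValueError("need >= 2 labels to compare")
    means = {g: values[labels == g].mean() for g in names}
    counts = {g: int((labels == g).sum()) for g in names}

    if blocks is not None:
        blocks = np.asarray(blocks)[keep]
        df_frame = pd.DataFrame({"v": values, "g": labels, "b": blocks})
        wide = df_frame.pivot_table(index="b", columns="g", values="v")
        wide = wide.dropna()
        n_b = len(wide)
        if n_b < 2:
            raise ValueError("need >= 2 complete blocks for the nested error term")
        arr = wide.to_numpy()
        resid = arr - arr.mean(axis=1, keepdims=True) \
            - arr.mean(axis=0, keepdims=True) + arr.mean()
        df_err = (n_b - 1) * (k - 1)
        mse = float((resid ** 2).sum() / df_err)
        counts = {g: n_b for g in names}
        means = {g: float(wide[g].mean()) for g in names}
    else:
        df_err = sum(counts.values()) - k
        mse = sum(((values[labels == g] - means[g]) ** 2).sum() for g in names) \
            / df_err

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = np.sqrt(mse / 2.0 * (1.0 / counts[a] + 1.0 / counts[b]))
            diff = means[b] - means[a]
            if se == 0:
                p = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / se
                p = float(stats.studentized_range.sf(q, k, df_err))
            rows.append({"group1": a, "group2": b, "meandiff": diff,
                         "p-adj": min(1.0, p), "reject": p < alpha})
    return pd.DataFrame(rows)


def compare_epochs(table: pd.DataFrame, value: str = "zbar",
                   dz_value: str = "dz", alpha: float = 0.05) -> dict:
    """Omnibus nested ANOVA and within-group Tukey-Kramer epoch comparisons.

    ``table`` must carry columns group, mouse, epoch and the response
    columns.  The ANOVA treats mouse as a fixed factor nested within group
    (sequential sums of squares) and includes cell-within-mouse effects, so
    the error term for the epoch x group interaction is the cell x epoch
    residual: between-cell response heterogeneity does not dilute the
    epoch contrasts.  Pairwise epoch contrasts within each group are
    Tukey-Kramer on the across-epoch-normalized responses with the same
    within-cell error term.
    """
    required = {"group", "mouse", "epoch", value, dz_value}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks columns: {sorted(missing)}")
    t = table.dropna(subset=[value]).copy()
    t["mouse_uid"] = t["group"].astype(str) + "/" + t["mouse"].astype(str)
    per_group_mice = t.groupby("group")["mouse_uid"].nunique()
    if (per_group_mice < 2).any():
        raise ValueError(
            "need >= 2 mice per group for the nested term; got "
            f"{per_group_mice.to_dict()}")

    y = t[value].to_numpy(dtype=float)
    ge = (t["group"].astype(str) + "@" + t["epoch"].astype(str)).to_numpy()
    me = (t["mouse_uid"] + "@" + t["epoch"].astype(str)).to_numpy()
    blocks = [
        ("group", _dummies(t["group"])),
        ("mouse(group)", _dummies(t["mouse_uid"])),
    ]
    if "cell" in t.columns:
        cell_uid = t["mouse_uid"] + ":" + t["cell"].astype(str)
        blocks.append(("cell(mouse)", _dummies(cell_uid)))
    blocks += [
        ("epoch", _dummies(t["epoch"])),
        ("group x epoch", _dummies(ge)),
        ("mouse(group) x epoch", _dummies(me)),
    ]
    anova = _sequential_anova(blocks, y)

    tukey = {}
    for g, sub in t.groupby("group"):
        tukey[g] = tukey_kramer(sub[dz_value].to_numpy(),
                                sub["epoch"].to_numpy(),
                                blocks=sub["mouse_uid"].astype(str) + ":"
                                + sub["cell"].astype(str)
                                if "cell" in sub.columns else None,
                                alpha=alpha)
    p_int = float(anova.loc[anova["term"] == "group x epoch", "p"].iloc[0])
    return {"anova": anova, "p_interaction": p_int, "tukey": tukey}


def orientation_bias(
    recordings: dict[str, Recording],
    groups: dict[str, str],
    cue_window_s: float = 1.0,
    threshold: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Population cue-orientation bias per animal and its group comparison.

    For cue-responsive cells (peak early-stable cue response > threshold for
    either orientation), computes the time-averaged vertical-horizontal
    response difference, its per-animal median, a per-cell rank test for
    orientation selectivity, a per-animal chi-square test of the
    vertical/horizontal preference counts (Bonferroni-corrected), and a
    two-sample Kolmogorov-Smirnov test of the per-animal medians between
    groups.
    """
    per_animal = []
    medians_by_group: dict[str, list[float]] = {}
    n_animals = len(recordings)
    for animal, rec in recordings.items():
        ev = rec.events
        z, offset, valid = epoch_zscores(rec, "ES")
        wlen = int(round(cue_window_s * rec.frame_rate))
        traces = {}
        trial_means = {}
        for cue in ("vertical", "horizontal"):
            sel = (ev["epoch"] == "ES") & (ev["cue"] == cue)
            onsets = ev.loc[sel, "cue_onset_frame"].to_numpy() - offset
            idx = np.flatnonzero(sel.to_numpy())
            exc = rec.excursion[idx] if rec.excursion is not None else None
            traces[cue], _ = trial_average(z, onsets, wlen, exc)
            keep = (exc <= EXCURSION_THRESHOLD_MM) if exc is not None else \
                np.ones(len(onsets), dtype=bool)
            trial_means[cue] = np.stack(
                [z[:, o:o + wlen].mean(axis=1) for o in onsets[keep]], axis=1)
        resp = valid & (
            (np.nanmax(traces["vertical"], axis=1) > threshold)
            | (np.nanmax(traces["horizontal"], axis=1) > threshold))
        if resp.sum() < 2:
            per_animal.append({"animal": animal, "group": groups[animal],
                               "n_responsive": int(resp.sum()),
                               "excluded": True})
            continue
        diff = (traces["vertical"].mean(axis=1)
                - traces["horizontal"].mean(axis=1))[resp]
        median = float(np.median(diff))

        # per-cell selectivity: two-sided rank test on per-trial responses
        n_v = n_h = 0
        for i in np.flatnonzero(resp):
            v, h = trial_means["vertical"][i], trial_means["horizontal"][i]
            p = stats.mannwhitneyu(v, h, alternative="two-sided").pvalue
            if p < alpha:
                if v.mean() > h.mean():
                    n_v += 1
                else:
                    n_h += 1
        if n_v + n_h > 0:
            chi2, p_chi = stats.chisquare([n_v, n_h])
        else:
            chi2, p_chi = 0.0, 1.0
        p_chi_bonf = min(1.0, p_chi * n_animals)
        frac_sel = (n_v + n_h) / resp.sum()
        per_animal.append({
            "animal": animal, "group": groups[animal], "excluded": False,
            "n_responsive": int(resp.sum()), "median_diff": median,
            "n_pref_vertical": n_v, "n_pref_horizontal": n_h,
            "selective_fraction": frac_sel,
            "chi2": float(chi2), "p_chi2_bonferroni": float(p_chi_bonf),
        })
        medians_by_group.setdefault(groups[animal], []).append(median)

    result = {"per_animal": pd.DataFrame(per_animal)}
    group_names = sorted(medians_by_group)
    if len(group_names) == 2:
        a, b = (medians_by_group[g] for g in group_names)
        if a and b:
            if a == b:
                result["ks"] = {"statistic": 0.0, "p": 1.0}
            else:
                ks = stats.ks_2samp(a, b)
                result["ks"] = {"statistic": float(ks.statistic),
                                "p": float(ks.pvalue)}
    return result
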