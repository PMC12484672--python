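# tectolearn

Analysis pipeline for **contextual visual learning in the early visual
system**: how population responses in the mouse superior colliculus (SC) —
and its retinal and cortical inputs — adapt when a probabilistic cue-outcome
association is stable, and recover or over-shoot when it becomes volatile.

The package is aimed at systems neuroscientists analyzing trial-aligned
two-photon calcium recordings (deconvolved activity) from an implicit
cue-outcome learning task, together with pupillometry and receptive-field
mapping. It ships a synthetic-data generator that emulates the statistical
structure of such recordings, so every stage of the analysis is testable
end to end without animal data.

## What it computes

**Task design.** An orientation cue (vertical/horizontal grating, 1 s)
predicts an outcome (one of six aversive sweep/loom stimuli, or an omitted
gray screen, 2 s). Three 72-trial stable blocks realize the expected
pairing (vertical→aversive, horizontal→omitted) in exactly 60/72 trials
(p = 5/6); the first block is excluded (habituation) and the remaining two
form the early-stable (ES) and late-stable (LS) analysis epochs. A
volatile epoch (VL) follows: three 24-trial sub-blocks at expected-pairing
probabilities 1/6, 1/2, 5/6. Each trial carries a contingency bit
u ∈ {0, 1} (0 = expected pairing).

**Bayesian observer.** A three-level binary hierarchical Gaussian filter
(HGF) is forward-filtered over the 216-trial contingency vector u.
Level 1 tracks the outcome, level 2 the contingency tendency μ₂ (with
μ̂₁ = s(μ₂), s the logistic sigmoid), level 3 the log-volatility μ₃.
Per trial it emits 13 quantities in five classes — learning rates α₁…₃,
prior predictions μ̂₁…₃, belief variances σ̂₂, σ̂₃, uncertainties unc₁…₃,
and precision-weighted prediction errors ε₂, ε₃.

**Population response analysis.** Activity is z-scored within epoch
(Z(t)), trial-averaged over aversive outcomes excluding trials with
platform excursion > 0.25 mm (z(t)), thresholded for responsiveness
(peak z > 1 for somata, > 0.75 for axonal boutons), summarized over the
2-s outcome window (z̄), and normalized across epochs:

    Δz = z̄ − ⟨z̄⟩_epochs .

Group inference: nested ANOVA on z̄ (mouse within experimental group, with
cell-within-mouse effects so the epoch × group interaction is tested
against the cell × epoch residual) and Tukey-Kramer pairwise epoch
comparisons on Δz with the same within-cell error term.

**Neuronal trajectories and observer correlation.** Per-cell aversive-trial
responses z̄ₖ are stimulus-type normalized (Δzₖ, per-type mean over 18
trials subtracted), and a power-law photobleaching curve
f(k) = a·k^b + c, fit to the epoch-averaged population mean, is removed
with one scalar per cell (Δzₖ^res = Δzₖ − d·f(k), |ρ(Δzₖ^res, f)| ≤ 0.05 by
construction). Residual trajectories are Pearson-correlated with each of
the 13 observer parameters; p-values become Storey q-values (q < 0.05
significant); per-level cumulative percentages, a 10,000-repetition
polarity-bias permutation test, and χ² group comparisons summarize the
representation.

**Pupillometry.** Pupil area from the long-axis diameter
(6 × 10³ px² = 1 mm²), evoked proportional change a(t) = ⟨A(t)/A₀⟩ against
a 10-frame pre-onset baseline, outcome-window summary ā, normalization
Δa = ā − ⟨ā⟩_epochs, Mann-Whitney U on median areas, two-way
(group × epoch) ANOVA and Tukey-Kramer on Δa.

**Receptive fields.** White-noise checkerboard (3.7° × 2.9° fields, 4 Hz,
10 min), response-weighted average over a 0.5-s window at 16.7-ms bins,
2-D Gaussian fit at peak latency, RF size = 2 · mean(SD_long, SD_short).

## Worked example

```python
import numpy as np, pandas as pd
from tectolearn import generate_session, run_hgf, subset_aversive
from tectolearn import synthetic_data as syn, response_analysis as resp
from tectolearn import trajectory as traj_mod, hgf_correlation as corr_mod

session = generate_session()                      # published design
u = session.contingency_vector()
print(session.n_analyzed, [int(u[i*72:(i+1)*72].sum()) for i in range(3)])
# 216 [12, 12, 36]   <- 216 analyzed trials; 12 unexpected per stable epoch

hgf = run_hgf(u)                                  # 216 x 13 observer series
hgf_av = subset_aversive(hgf, session)            # 108 aversive trials

tables, residuals = [], []
for m in range(4):                                # 4 synthetic animals
    rec, _ = syn.simulate_recording(session, "WT_SC", n_cells=100, seed=m)
    t = resp.analyze_recording(rec)
    t["mouse"], t["group"] = f"m{m}", "WT_SC"
    tables.append(t)
    residuals.append(traj_mod.neuronal_trajectories(rec).dz_res)
table = pd.concat(tables, ignore_index=True)

print(table.groupby("epoch")["dz"].mean().round(3).to_dict())
# {'ES': 0.065, 'LS': -0.122, 'VL': 0.058}
tk = resp.tukey_kramer(table["dz"], table["epoch"],
                       blocks=table["mouse"] + ":" + table["cell"].astype(str))
print(tk[["group1", "group2", "meandiff", "reject"]].to_string(index=False))
# group1 group2  meandiff  reject
#     ES     LS -0.187269    True
#     ES     VL -0.007287   False
#     LS     VL  0.179982    True
```

The Tukey-Kramer table shows the wild-type signature: aversive responses
adapt in the late-stable epoch (LS < ES) and recover under volatility
(LS < VL), with no ES-VL difference. Correlating the 400 residual
trajectories with the observer parameters,

```python
screen = corr_mod.CorrelationScreen().fit(np.vstack(residuals), hgf_av)
print(screen.level_summary_.to_string(index=False))
#  level  cum_pct_significant
#      1                63.25
#      2                90.00
#      3                79.50
```

gives the cumulative percentage of cells significantly correlated
(q < 0.05) with at least the parameters at each hierarchical level — the
per-level "representation" summary.

A command-line surface mirrors the library
(`tectolearn design | hgf | simulate | analyze | trajectory | correlate |
pupil | rf | run-all`); see `tectolearn --help`.

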