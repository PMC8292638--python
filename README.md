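# vte-kit

Machine-learning detection of **vicarious trial and error (VTE)** — the
pause-and-look vacillation rats show at maze choice points — from head
tracking and hippocampal field potentials.

## Who this is for

Labs running binary spatial decision tasks (plus/T/Y-mazes) who want
reproducible, algorithmic VTE labels instead of manual frame-by-frame
scoring, and who may want to ask whether hippocampal oscillations carry
information about these deliberative events. The package consumes
timestamped head coordinates (~35 Hz) and 1 kHz field-potential traces and
needs no video.

## The method

The classical single-metric detector is **zIdPhi**: the per-session z-score
of the integrated change in heading angle,

```
phi_i  = arctan2(dy_i, dx_i)
IdPhi  = sum_i |phi_i - phi_{i-1}|
```

thresholded at a percentile chosen to maximize the ROC area. zIdPhi
separates VTE from non-VTE distributions but not cleanly. vte-kit instead
trains standard classifiers on a small feature set per choice-epoch
trajectory — x/y position SDs, zIdPhi (and raw IdPhi), choice-point dwell
time, the r² of a degree-6 polynomial fit of y on x (head sweeps are
multivalued in x and fit poorly), and the number of Fourier coefficients
holding 95% of the fit's spectral energy — and evaluates them with a
**balanced, seeded split matrix**: 100 columns, each containing every VTE
trial plus an equal random draw of non-VTE trials, split 67/33 into
train/test. The same matrix is reused for every model and feature set, so
comparisons are paired per split. Models are k-nearest neighbors (k = 5)
and an RBF-kernel SVM with (γ, C) chosen from a 19 × 19 grid by internal
cross-validated AUC on training data only.

A parallel feature path works on the hippocampal LFP: theta cycles
segmented peak-to-peak on an 80 Hz low-passed trace (peaks ≥ 0.0833 s
apart), the per-cycle **asymmetry index** `AI = ln(asc) − ln(desc)`, low
(35–55 Hz) and high (61–100 Hz) gamma power from zero-lag Butterworth
filters and Hilbert envelopes, the per-cycle gamma ratio `GR = LG/HG`, and
1 Hz periodogram bins over 1–100 Hz with KS + Benjamini–Hochberg feature
selection. Oscillation results are reported as **Δ scores** — per-split
differences from the identical pipeline trained on randomly labeled data —
so zero means chance.

Label curation follows the four-rater protocol: majority consensus, 2–2
ties excluded, pairwise percent agreement and Cohen's κ reported, trials
with any |sample| > 4 session SDs in the analyzed epoch excluded, and whole
sessions dropped when more than 20% of trials are excluded or the AI
distribution skews the wrong way.

Because the original recordings are not in a public archive, the package
ships a **simulator** (`vte_kit.synthetic`) generating plus-maze sessions —
smooth arcs vs. head-sweep trajectories at 35 Hz, and LFP with phase-warped
asymmetric theta, theta-modulated gamma bursts, and 1/f background — with
configurable class-conditional effect sizes, so the entire pipeline is
testable end to end.

## Worked example

```bash
python examples/04_classification.py
```

```
pooled trials: 238 (43 VTE)
     zidphi_baseline: AUC=0.608  acc=0.607  prec=0.657  rec=0.517
       traj_only/knn: AUC=0.938  acc=0.858  prec=0.908  rec=0.811
       traj_only/svm: AUC=0.940  acc=0.887  prec=0.928  rec=0.850
```

Four simulated 60-trial sessions are pooled (238 trials survive curation,
43 VTEs), the shared split matrix is built at seed 1, and each row reports
means over the same 100 splits. The zIdPhi threshold, scored by the
two-point area of a hard classifier, sits far below both multi-feature
models — the package's central claim. `examples/05_delta_scores.py` shows
the oscillation side: choice-epoch LFP features give Δ-AUC ≈ +0.40 while
delay-epoch features (generated with no class differences) give ≈ 0.

The other examples (`01`–`03`) demonstrate session simulation and
curation, trajectory features, and oscillation features individually. The
same stages are scriptable via the `vte-kit` CLI
(`simulate`, `curate`, `extract-traj`, `extract-osc`, `extract-psd`,
`classify`, `evaluate`, `run-experiment`).

## Layout

- `src/vte_kit/core_io.py` — data model, CSV/binary formats, epoch slicing
- `src/vte_kit/trajectory_features.py` — IdPhi/zIdPhi, fit r², n_coef, baseline
- `src/vte_kit/oscillation_features.py` — theta cycles, AI, gamma, PSD
- `src/vte_kit/curation.py` — consensus, reliability, exclusion gates
- `src/vte_kit/classification.py` — split matrix, KNN, RBF-SVM, grids
- `src/vte_kit/evaluation_stats.py` — metrics, ROC/AUC, Δ scores, tests
- `src/vte_kit/synthetic.py` — maze + LFP simulator
- `src/vte_kit/pipeline.py`, `experiments.py`, `cli.py` — glue and entry points
- `docs/methods.md` — modeling and numerical choices in detail
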