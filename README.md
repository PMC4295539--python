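# pipecraft

A stream-based, incremental workflow engine for neuroimaging analyses,
with a bundled set of self-contained toy fMRI modules and a synthetic
4D-study generator so the whole system runs end-to-end without any
external neuroimaging package.

## The problem

Modern neuroimaging studies chain dozens of processing stages — motion
correction, quality control, smoothing, within-subject general linear
models, group statistics — over many subjects and sessions. Running these
by hand is error-prone and slow: re-running one late stage means either
re-running everything or manually tracking what is already done, and
comparing analysis variants (say, two smoothing kernels) usually means
duplicating whole directory trees.

`pipecraft` addresses this for people who build and run such pipelines:

- **Declarative modules.** Each stage is described by a small XML
  interface: its *domain* (`study` — run once; `subject` — once per
  subject; `session` — once per subject-session), its settings with
  defaults, and the named data *streams* it consumes and produces
  (`epi`, `structural`, `realignment_parameter`, ...).
- **Automatic wiring.** A tasklist only orders the modules. Each input
  stream is connected to the *last preceding producer* of that stream
  (a fully qualified `module.stream` reference can pick an earlier one).
  Dependencies are computed per *instance*: the smoothing instance for
  subject 4, session 2 depends on exactly the realignment instance for
  subject 4, session 2. Streams may cross domains down toward the leaves
  (a subject-level structural feeding each session) or fan in up toward
  the trunk (all sessions' contrast maps into one group test) — but never
  sideways.
- **Incremental execution.** Every completed instance leaves a
  `done_<stage>_<index>` flag holding a digest snapshot of its inputs.
  An instance is skipped iff its flag exists *and* its upstream digests
  are unchanged; adding a subject, editing a file, or changing remote
  data re-runs exactly the affected subgraph.
- **Branches.** A tasklist can fork into alternatives (e.g. 8 mm vs
  12 mm smoothing). The shared trunk executes once; repeated modules get
  incremented directory indices (`smooth_00001`, `smooth_00002`) and
  per-branch analysis directories via an `analysisid_suffix`.
- **Parallelism and remote trees.** A worker-pool backend dispatches each
  instance the moment its own dependencies complete, with output trees
  bitwise-identical to serial runs. A local analysis can also connect its
  input streams to a *remote* analysis tree (by default to the terminal
  producer of each stream) and re-runs dependents when remote bytes
  change.

## The statistics inside the toy modules

The toy modules are simple on purpose, so every claim is exactly
testable against generated ground truth:

- **Realignment** estimates per-volume integer translations by exhaustive
  search over ±3 voxels maximizing correlation with the first volume.
- **First level:** voxelwise OLS, `y = Xβ + ε` with boxcar (optionally
  canonical double-gamma HRF) task regressors plus motion and session-mean
  nuisance columns; `t = cᵀβ̂ / √(σ̂² cᵀ(XᵀX)⁻c)` with `df = n − rank(X)`.
  Contrasts are specified per session block as `sameforallsessions`,
  `singlesession:<name>`, or `uniquebysession` (T by default).
- **Second level:** voxelwise one-sample t across subjects,
  `df = n_subjects − 1`.
- **QC (tsdiffana-style):** per volume-pair mean squared successive
  difference scaled by the squared global mean (scale-invariant), with
  median-based outlier flagging.

## Worked example

```python
import tempfile
from pathlib import Path
import pipecraft as pc

root = Path(tempfile.mkdtemp())
cfg = pc.SyntheticStudyConfig(n_subjects=2, amplitude=4.0, noise_sd=0.5, seed=21)
study = pc.generate_synthetic_study(cfg, root)

interfaces = pc.builtin_interfaces()
tasklist = pc.builtin_tasklist("toy_fmri")     # import → trim → realign → QC
                                               # → smooth → 1st level → group t
model = (
    pc.FmriModel()
    .add_event("firstlevel_model", "*", "*", "task",
               cfg.activation_onsets, cfg.activation_duration)
    .add_contrast("firstlevel_model", "*", "sameforallsessions", [1])
)
params = pc.merge_parameters(
    pc.builtin_parameters(), tasklist, interfaces,
    {"tasksettings": {
        "discard_dummies": {"numdummies": 3},
        "smooth": {"FWHM": 8},                 # override the 10 mm default
        "firstlevel_model": {"model": model},
    }},
)
pipeline = pc.expand_tasklist(tasklist, interfaces)
record = pc.run_pipeline(pipeline, study, params)
record2 = pc.run_pipeline(pipeline, study, params)   # nothing left to do
```

Output of the run above (plus a look at the group t-map against the
generator's ground-truth sidecar):

```
first run : executed 13 instances, failed 0
second run: executed 0 instances (everything was done)
group t inside injected region : min 28.2
group t outside region (median |t|): 1.32
```

13 instances = 5 session-level stages × 2 subject-sessions, plus one
first-level GLM per subject (2), plus one study-level group test (1).
The second run executes nothing because every done-flag's input digests
are unchanged. The group t-map separates the injected activation region
(t ≥ 28) cleanly from the rest of the brain (median |t| ≈ 1.3).

The same analysis is available from the shell via a YAML config:

```bash
pipecraft run config.yaml        # execute (or resume) the analysis
pipecraft status <analysis-root> # per-instance done/pending table
pipecraft graph config.yaml      # dependency map in DOT format
pipecraft invalidate <analysis-root> realign S01 movie
pipecraft gc <analysis-root> --keep-above 2 [--dry-run]
pipecraft report <analysis-root> # multi-level HTML diagnostics report
```

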