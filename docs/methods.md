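# Methods

This note documents the engine's model of a pipeline, the numerical and
design choices behind the bundled toy modules and the synthetic-study
generator, and what the test suite does and does not establish.

## Pipeline model

**Domains and instances.** Domains form a tree rooted at `study`, with
`subject` below it and `session` (and optional registered siblings such
as `diffusion_session`) below that. A module instantiates once per
coordinate of its domain: one study instance, one per subject, one per
(subject, session). A coordinate is the path of identifiers below the
root; instance enumeration is deterministic (declared subject order, then
declared session order).

**Stage expansion and indexing.** A tasklist is flattened into a linear
stage list; each stage's index is 1 + the number of earlier occurrences
of the same module name, rendered as a five-digit zero-padded directory
suffix (`smooth_00001`). Branch alternatives are flattened in declaration
order and carry their alternative's `analysisid_suffix`, which is
appended to the analysis directory name so alternatives write to separate
trees while sharing the trunk. Stages declared after a branch belong to
the trunk and do not read from either alternative; a branch stage reads
from its own alternative and then the trunk, never from a sibling.
Initialisation stages share the same index counter and run
unconditionally on every invocation.

**Stream resolution.** Each input stream binds to the nearest preceding
visible stage that declares it as an output; stages that do not produce
the stream are skipped. A fully qualified reference `module.stream` on an
invocation binds to the most recent prior occurrence of the named module
instead. Resolution failures are raised when the dependency map is built,
before anything executes.

**Cross-domain edges.** For a resolved (source stage, target stage,
stream) triple, instance-level edges follow three rules: equal domains
pair identical coordinates; an ancestor-domain source contributes its
unique prefix instance to each target; a descendant-domain source fans in
every instance beneath the target's coordinate. Sideways (disjoint)
coordinates never share an edge — this is asserted on every build and
checked against a brute-force oracle over randomized pipelines in the
tests.

**Placement and registration.** The engine materializes exactly the
requested stream payloads under `inputs/<stream>/` in the consumer's
directory (hard links with copy fallback, to keep transfer cheap), with
fan-in sources in per-source subfolders keyed by coordinate; a JSON input
manifest records provenance digests. Placing inputs in a dedicated area
rather than the directory root keeps a module's own outputs from ever
colliding with (and, through hard links, corrupting) its inputs. On
completion, one record per declared output stream is registered with
SHA-256 content digests; undeclared files are ignored, a declared stream
without files is an error, and any file outside the instance's own
directory is an illegal write. Bundled modules write outputs via a
write-temp-then-rename helper so re-writing a file never mutates an
existing hard-linked copy downstream.

## Incremental execution

A completed instance holds a `done_<stage>_<index>` flag containing a
snapshot of its input digest multisets. `is_done` is true iff the flag
exists and the *current* upstream digests (live payloads are re-hashed,
so out-of-band edits are caught) equal the snapshot. Flags are written
atomically (temp + rename) so a crash cannot fake completion. At
map-build time, flags downstream of any stale or never-run instance are
deleted eagerly, and explicit invalidation likewise removes the selected
instances' flags plus the transitive downstream closure.

Garbage collection deletes the payload of streams whose producing
interface has a permanence rank below the threshold, marks their
manifests *stale* (digests retained), and keeps flags, logs, manifests
and provenance. A stale record does not invalidate consumers — the data
are regenerable, not changed — and when pending work actually needs a
collected payload, the engine pulls exactly its producer back into the
run set without touching the flags of that producer's other consumers.
This demand-driven regeneration assumes module determinism; the bundled
modules are deterministic and the provenance record stores the full
merged parameters to make reruns reproducible.

Two backends share the scheduling logic: `localsingle` executes the run
set serially in topological order; `localparallel` uses an in-process
thread pool and dispatches each instance the moment its own dependencies
complete. Interface resource estimates are carried through the parse for
cluster-submission extensions but are not consumed by the bundled
backends. On failure the dependent subgraph is blocked while independent
subtrees continue (a `fail_fast` switch stops dispatching instead).

**Remote connection.** A local pipeline's unconnected input streams bind
to a remote analysis tree via its provenance record: by default to the
terminal producer of each stream, or to an explicitly named earlier
stage. Remote payloads are re-hashed on every connection, so local
instances re-run exactly when the remote bytes they depend on change;
remote data are copied only when placed as inputs.

## Parameter merging

Settings for each stage merge from, lowest to highest precedence:
interface defaults, tasklist per-invocation settings, parameter-document
`tasksettings`, and user overrides. Placing document `tasksettings`
above invocation settings makes merging idempotent (re-merging an
already-merged set with empty overrides is the identity), which the suite
asserts; plain defaults documents carry only global namespaces and are
unaffected. Repeated modules are addressed as `name` for the first
occurrence and `name_0000k` for later ones. XML inclusion splices an
included document's children in place when its root tag matches the
including element (so `<local>` override sections can address the
included content); unresolvable targets and cycles are errors.

## Toy modules and numerical choices

- **Realignment** estimates integer translations only (rotation columns
  are written as zeros) by exhaustive search over ±3 voxels maximizing
  Pearson correlation with the first volume. Integer shifts avoid
  interpolation, so recovery of injected motion is exact at zero noise.
  Ties break toward the smallest L1 shift, then lexicographically, so an
  aligned series yields an all-zero motion table; constant volumes warn
  and assume zero shift.
- **Smoothing** uses a separable Gaussian with `sigma = FWHM/√(8 ln 2)`
  per axis in voxel units and zero-padded boundaries; total intensity is
  conserved for interior structure (the impulse-response test measures
  the half-maximum width at interior voxels). FWHM is in millimetres;
  the interface default is 10 mm.
- **QC metric**: mean over voxels of the squared difference of successive
  volumes, divided by the square of the series global mean. The scaling
  constant is one of several conventions in use; it was chosen to make
  the metric invariant to global intensity scaling. Outliers are flagged
  above `outlier_factor` (default 4) times the median metric.
- **Design matrices**: onsets and durations are in scans (conversion
  from seconds is the caller's job). Boxcars accumulate fractional
  overlap per scan, so a column integrates to the total event duration.
  The optional canonical HRF is a double-gamma (peak 6 s, undershoot
  16 s, ratio 1/6) sampled at the TR setting (default 2 s) and
  normalized to unit sum — a standard shape documented here as this
  package's own choice. Parametric modulators are mean-centered before
  scaling the boxcar, separating modulation from the main effect.
  "Moves and means" nuisance regressors are the six motion parameters
  plus one constant per session; motion columns are mean-centered and
  zero-variance columns (e.g. the never-estimated rotations) are dropped
  to keep designs full rank.
- **GLM**: voxelwise OLS with `df = n − rank(X)`; rank-deficient designs
  fall back to the pseudoinverse with a warning. Zero contrasts yield
  identically zero t-maps. F-shaped contrast matrices are assembled and
  stored but not inferred.
- **Second level**: voxelwise one-sample t with `df = n − 1`; voxels
  with zero between-subject variance and nonzero mean are flagged
  degenerate (±inf, capped at ±1e6 in the written map).

## Synthetic-study generator

The generator emulates DICOM-conversion output for a small block-design
study. Defaults: 2 subjects × 1 session, 24 usable scans after 3 brighter
dummy volumes (gain 1.2, mimicking pre-steady-state intensity), 16×16×12
voxels of 3 mm, TR 2 s, baseline 100 inside an ellipsoidal "brain",
activation blocks of 6 scans every 12 scans at amplitude 2 in a central
box region, Gaussian noise with unit standard deviation, and up to two
abrupt ±1-voxel head movements per session (never within the first
scans, so the reference volume is unmoved). Activation is added before
the motion shift (the activation moves with the head) and noise after.
Ground truth (shifts, timing, amplitude, region) is written as a JSON
sidecar per session; a fixed seed yields bitwise-identical NIfTI files.

These sizes keep a full pipeline run under a second while leaving every
contract observable; tests and the acceptance script scale subjects,
sessions, scans and noise per scenario (e.g. zero noise for exact
recovery, 2×2 coordinates for backend equivalence, 2000 simulations for
the type-I error of the group test).

What the generator does *not* emulate: real EPI autocorrelation and
drift, subvoxel or rotational motion, susceptibility distortion,
physiological noise, and anatomical variability. Passing tests therefore
establish the engine's bookkeeping contracts and the estimators'
correctness on their own assumptions — not performance on real scanner
data, where realignment needs subvoxel rigid-body estimation and GLMs
need drift and autocorrelation handling. The stream contracts are
designed so such modules can replace the toys without engine changes.

## Known limitations

- Stages after a branch cannot consume streams produced inside the
  branches; analyses that need per-branch continuation put those stages
  inside each alternative.
- Demand-driven regeneration after garbage collection relies on module
  determinism; a nondeterministic module would regenerate different
  bytes without invalidating downstream flags.
- The parallel backend is thread-based; modules that hold the
  interpreter for long pure-Python stretches gain little (the bundled
  modules spend their time in vectorized numeric code).
- `import`-type stages (no input streams) snapshot nothing, so edits to
  raw files outside the analysis tree require explicit invalidation.
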