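"""Self-contained toy neuroimaging modules and a synthetic-study generator.

These modules exercise the engine's stream contracts end-to-end on a
typical fMRI pipeline shape — EPI import, dummy-scan discard, rigid motion
correction, time-series QC, Gaussian smoothing, first-level GLM, group
t-test — without any external neuroimaging package. Their algorithms are
deliberately simple (integer-shift realignment, OLS, one-sample t) so that
every recovery property is exactly testable against the generator's
ground-truth sidecars.

The generator emulates the output of DICOM conversion: per session a 4D
EPI NIfTI series with injected per-scan integer-voxel head motion, a block
activation in a known region, leading "dummy" volumes with elevated
intensity (pre-steady-state), and Gaussian noise; per subject a 3D
structural volume. All coordinates are voxel-indexed and 0-based; volumes
are written with an RAS+ diagonal affine built from the configured voxel
size.
"""

from __future__ import annotations

import json
import os
import shutil
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .design import FmriModel, boxcar, build_design, expand_contrast
from .domains import StudyDescription, coord_ids
from .errors import SpecificationError

FWHM_TO_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# synthetic study generation


@dataclass
class SyntheticStudyConfig:
    """Study conditions for the synthetic generator.

    Defaults describe a small two-subject, one-session block-design study:
    24 usable scans preceded by 3 brighter dummy volumes, 16x16x12 voxels
    of 3 mm, activation blocks of 6 scans every 12 scans at amplitude 2
    on a baseline of 100, unit-variance noise, and up to ``motion_events``
    abrupt integer-voxel head movements per session.
    """

    n_subjects: int = 2
    session_names: tuple[str, ...] = ("movie",)
    n_scans: int = 24  # usable scans, after the dummies
    numdummies: int = 3
    shape: tuple[int, int, int] = (16, 16, 12)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr: float = 2.0
    motion_events: int = 2
    motion_max: int = 1  # per-axis magnitude of any injected shift, voxels
    activation_period: int = 12
    activation_duration: float = 6.0
    amplitude: float = 2.0
    noise_sd: float = 1.0
    baseline: float = 100.0
    dummy_gain: float = 1.2  # dummy volumes are brighter (pre-steady-state)
    seed: int = 0

    def __post_init__(self):
        if abs(self.motion_max) > 3:
            raise SpecificationError("injected shifts must stay within +/-3 voxels")
        if self.amplitude < 0:
            raise SpecificationError("activation amplitude must be >= 0")

    @property
    def activation_onsets(self) -> list[float]:
        onsets, t = [], 0.0
        while t + self.activation_duration <= self.n_scans:
            onsets.append(t)
            t += self.activation_period
        return onsets

    def subjects(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]


def _brain_mask(shape) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    center = (np.asarray(shape) - 1) / 2.0
    radii = np.asarray(shape) * 0.42
    r2 = sum(
        ((grid[a] - center[a]) / radii[a]) ** 2 for a in range(3)
    )
    return r2 <= 1.0


def _activation_mask(shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    cx, cy, cz = (s // 2 for s in shape)
    mask[cx - 2 : cx + 2, cy - 2 : cy + 2, cz - 1 : cz + 2] = True
    return mask


def _motion_schedule(rng: np.random.Generator, cfg: SyntheticStudyConfig) -> np.ndarray:
    """Per-volume integer shifts (total scans x 3). Zero over the dummies
    and the first usable scans, so the reference volume is unmoved."""
    total = cfg.numdummies + cfg.n_scans
    shifts = np.zeros((total, 3), dtype=int)
    if cfg.motion_events == 0 or cfg.motion_max == 0 or cfg.n_scans < 4:
        return shifts
    earliest = cfg.numdummies + 2
    times = rng.choice(
        np.arange(earliest, total), size=min(cfg.motion_events, total - earliest),
        replace=False,
    )
    current = np.zeros(3, dtype=int)
    for t in range(total):
        if t in times:
            axis = int(rng.integers(0, 3))
            step = int(rng.choice([-cfg.motion_max, cfg.motion_max]))
            proposed = current.copy()
            proposed[axis] = int(np.clip(proposed[axis] + step, -3, 3))
            current = proposed
        shifts[t] = current
    return shifts


def save_volume(data: np.ndarray, voxel_size_mm, path: Path) -> None:
    """Write a float32 NIfTI with an RAS+ diagonal affine.

    Writes to a temporary name and renames, so re-writing an output never
    mutates a previously hard-linked copy of it in a consumer's directory.
    """
    path = Path(path)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    tmp = path.with_name("tmp_" + path.name)
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(tmp))
    os.replace(tmp, path)


def write_text(path: Path, text: str) -> None:
    """Replace-not-truncate text writer (safe for hard-linked outputs)."""
    path = Path(path)
    tmp = path.with_name("tmp_" + path.name)
    tmp.write_text(text)
    os.replace(tmp, path)


def load_series(path: Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def generate_synthetic_study(
    config: SyntheticStudyConfig,
    root: Path,
    analysis_id: str = "analysis",
    seed: int | None = None,
) -> StudyDescription:
    """Write the raw study tree and return its description.

    Per session: ``epi_raw.nii`` (4D, dummies included) plus a
    ``truth.json`` sidecar recording the injected shifts, activation
    timing, amplitude and region for recovery tests. Per subject:
    ``structural.nii``. A fixed seed yields bitwise-identical output.
    """
    root = Path(root)
    seed = config.seed if seed is None else seed
    raw = root / "raw"
    brain = _brain_mask(config.shape)
    act_mask = _activation_mask(config.shape)
    base = config.baseline * brain.astype(float)
    regressor = boxcar(
        config.activation_onsets,
        [config.activation_duration] * len(config.activation_onsets),
        config.n_scans,
    )
    full_reg = np.concatenate([np.zeros(config.numdummies), regressor])

    locations: dict[tuple[str, ...], Path] = {}
    sessions_per_subject: dict[str, list[str]] = {}
    for si, subject in enumerate(config.subjects()):
        sessions_per_subject[subject] = list(config.session_names)
        subj_rng = np.random.default_rng([seed % (2**31), 101, si])
        struct_dir = raw / subject
        struct_dir.mkdir(parents=True, exist_ok=True)
        structural = base + subj_rng.normal(0.0, config.noise_sd, config.shape)
        struct_path = struct_dir / "structural.nii"
        save_volume(structural, config.voxel_size_mm, struct_path)
        locations[(subject,)] = struct_path
        for gi, session in enumerate(config.session_names):
            rng = np.random.default_rng([seed % (2**31), si, gi])
            shifts = _motion_schedule(rng, config)
            total = config.numdummies + config.n_scans
            series = np.empty(config.shape + (total,), dtype=float)
            for t in range(total):
                vol = base * (config.dummy_gain if t < config.numdummies else 1.0)
                vol = vol + config.amplitude * full_reg[t] * act_mask
                vol = np.roll(vol, tuple(shifts[t]), axis=(0, 1, 2))
                if config.noise_sd > 0:
                    vol = vol + rng.normal(0.0, config.noise_sd, config.shape)
                series[..., t] = vol
            sess_dir = raw / subject / session
            sess_dir.mkdir(parents=True, exist_ok=True)
            epi_path = sess_dir / "epi_raw.nii"
            save_volume(series, config.voxel_size_mm, epi_path)
            truth = {
                "shifts": shifts.tolist(),
                "numdummies": config.numdummies,
                "amplitude": config.amplitude,
                "onsets": config.activation_onsets,
                "duration": config.activation_duration,
                "baseline": config.baseline,
                "noise_sd": config.noise_sd,
                "activation_bbox": _bbox(act_mask),
            }
            (sess_dir / "truth.json").write_text(json.dumps(truth, indent=1))
            locations[(subject, session)] = epi_path

    return StudyDescription(
        analysis_root=root / "analysis",
        analysis_id=analysis_id,
        subjects=config.subjects(),
        sessions_per_subject=sessions_per_subject,
        input_locations=locations,
        numdummies=config.numdummies,
    )


def _bbox(mask: np.ndarray) -> list[list[int]]:
    idx = np.argwhere(mask)
    return [idx.min(axis=0).tolist(), (idx.max(axis=0) + 1).tolist()]


def bbox_to_mask(bbox: list[list[int]], shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    (x0, y0, z0), (x1, y1, z1) = bbox
    mask[x0:x1, y0:y1, z0:z1] = True
    return mask


# ---------------------------------------------------------------------------
# computational primitives


def discard_dummies(series: np.ndarray, numdummies: int) -> np.ndarray:
    """Drop the first ``numdummies`` volumes of a 4D series.

    Event onsets are *not* adjusted here; callers specify onsets on the
    post-discard scan grid.
    """
    n = series.shape[-1]
    if numdummies < 0:
        raise SpecificationError("numdummies must be >= 0")
    if numdummies >= n:
        raise SpecificationError(
            f"cannot discard {numdummies} dummy scans from a series of {n}"
        )
    return series[..., numdummies:]


def _correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def toy_realign(
    series: np.ndarray, max_shift: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integer-translation motion correction by exhaustive search.

    For each volume the shift in ``[-max_shift, max_shift]^3`` maximizing
    the correlation with the first volume is found and undone. Ties break
    toward the smallest shift (L1 norm, then lexicographic), so an
    already-aligned series yields an all-zero motion table. Returns
    ``(corrected series, per-volume shifts (n x 3), mean volume)``.
    """
    if series.shape[-1] < 2:
        raise SpecificationError("realignment needs at least 2 volumes")
    reference = series[..., 0]
    if np.ptp(reference) == 0:
        warnings.warn("reference volume is constant; assuming zero motion")
    candidates = sorted(
        product(range(-max_shift, max_shift + 1), repeat=3),
        key=lambda s: (sum(abs(v) for v in s), s),
    )
    n = series.shape[-1]
    shifts = np.zeros((n, 3), dtype=int)
    corrected = np.empty_like(series)
    corrected[..., 0] = reference
    for t in range(1, n):
        vol = series[..., t]
        if np.ptp(vol) == 0:
            warnings.warn(f"volume {t} is constant; assuming zero motion")
            corrected[..., t] = vol
            continue
        best, best_corr = (0, 0, 0), -np.inf
        for cand in candidates:
            undone = np.roll(vol, tuple(-c for c in cand), axis=(0, 1, 2))
            corr = _correlation(undone, reference)
            if corr > best_corr + 1e-12:
                best, best_corr = cand, corr
        shifts[t] = best
        corrected[..., t] = np.roll(vol, tuple(-c for c in best), axis=(0, 1, 2))
    return corrected, shifts, corrected.mean(axis=-1)


def gaussian_smooth(volume: np.ndarray, fwhm_mm, voxel_size_mm) -> np.ndarray:
    """Separable Gaussian smoothing with a kernel given as FWHM in mm.

    sigma per axis is ``fwhm / sqrt(8 ln 2)`` converted to voxel units.
    Boundary handling is zero-padding, so total intensity is conserved for
    interior structure. ``fwhm_mm`` may be a scalar or per-axis triple;
    zero is the identity.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise SpecificationError("smoothing FWHM must be >= 0")
    if np.all(fwhm == 0):
        return volume.copy()
    voxel = np.asarray(voxel_size_mm, dtype=float)
    sigma_vox = fwhm / FWHM_TO_SIGMA / voxel
    return gaussian_filter(volume, sigma=sigma_vox, mode="constant")


@dataclass
class QCReport:
    """Low-level time-series quality metrics.

    ``metrics[t]`` is the voxel-mean squared difference between volumes
    t+1 and t, scaled by the square of the series global mean (so the
    metric is invariant to global intensity scaling); length n_scans - 1.
    """

    metrics: np.ndarray
    mean_intensity: np.ndarray
    outliers: list[int]
    assets: list[str] = field(default_factory=list)


def tsdiffana_metrics(series: np.ndarray, outlier_factor: float = 4.0) -> QCReport:
    """Successive-volume difference diagnostics.

    Volume pairs whose metric exceeds ``outlier_factor`` times the median
    metric are flagged as outliers.
    """
    if series.shape[-1] < 2:
        raise SpecificationError("QC metrics need at least 2 volumes")
    global_mean = series.mean()
    scale = global_mean**2 if global_mean != 0 else 1.0
    diffs = np.diff(series, axis=-1)
    metrics = (diffs**2).mean(axis=(0, 1, 2)) / scale
    mean_intensity = series.mean(axis=(0, 1, 2))
    median = float(np.median(metrics))
    if median > 0:
        outliers = [int(i) for i in np.nonzero(metrics > outlier_factor * median)[0]]
    else:
        outliers = [int(i) for i in np.nonzero(metrics > 0)[0]]
    return QCReport(metrics=metrics, mean_intensity=mean_intensity, outliers=outliers)


def fit_first_level(
    data: np.ndarray, X: np.ndarray, contrasts=()
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray | None], int]:
    """Voxelwise ordinary least squares with t contrasts.

    ``data`` is (scans x voxels), ``X`` (scans x columns). Residual
    degrees of freedom are ``n - rank(X)``; a rank-deficient design falls
    back to the pseudoinverse with a warning. For each single-row contrast
    c, ``t = c beta / sqrt(sigma2 * c (X'X)^- c')``; multi-row (F) specs
    are assembled but not inferred (returned as None).
    """
    n = X.shape[0]
    if data.shape[0] != n:
        raise SpecificationError(
            f"design has {n} rows but the series has {data.shape[0]} scans"
        )
    rank = int(np.linalg.matrix_rank(X))
    if rank < X.shape[1]:
        warnings.warn(
            f"design is rank deficient (rank {rank} of {X.shape[1]}); "
            f"using pseudoinverse"
        )
    pinv = np.linalg.pinv(X)
    betas = pinv @ data
    residuals = data - X @ betas
    df = n - rank
    sigma2 = (residuals**2).sum(axis=0) / max(df, 1)
    xtx_pinv = np.linalg.pinv(X.T @ X)
    tmaps: list[np.ndarray | None] = []
    for c in contrasts:
        c = np.atleast_2d(np.asarray(c, dtype=float))
        if c.shape[0] > 1:
            tmaps.append(None)
            continue
        row = c[0]
        effect = row @ betas
        var_scale = float(row @ xtx_pinv @ row)
        denom = np.sqrt(sigma2 * var_scale)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, effect / np.where(denom > 0, denom, 1.0), 0.0)
        tmaps.append(t)
    return betas, sigma2, tmaps, df


def second_level_ttest(maps: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Voxelwise one-sample t across subjects (first axis).

    Returns ``(t map, df, degenerate mask)`` with ``df = n - 1``. Voxels
    with zero between-subject variance but a nonzero mean are degenerate
    (t is +/-inf there); zero-mean zero-variance voxels get t = 0.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n < 2:
        raise SpecificationError(
            "a second-level t-test needs at least 2 subjects"
        )
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    degenerate = (sd == 0) & (mean != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
        capped = np.sign(mean) * np.inf
    t = np.where(sd == 0, np.where(mean == 0, 0.0, capped), t)
    return t, n - 1, degenerate


# ---------------------------------------------------------------------------
# stream-compliant module implementations
#
# Each implementation receives a ModuleContext (instance, directory,
# settings, placed inputs, study) and returns {stream: [files]} relative to
# its directory. The engine registers the declared streams from that map.


def _single_input(ctx, stream: str) -> Path:
    files = [p for p in ctx.inputs.get(stream, []) if str(p).endswith(".nii")]
    if not files:
        files = list(ctx.inputs.get(stream, []))
    if len(files) != 1:
        raise SpecificationError(
            f"{ctx.instance}: expected exactly one {stream!r} input file, "
            f"got {len(files)}"
        )
    return Path(files[0])


def impl_checkparameters(ctx):
    """Initialisation module: sanity-check the study description."""
    study = ctx.study
    for subject in study.subjects:
        for session in study.sessions(subject):
            if (subject, session) not in study.input_locations:
                raise SpecificationError(
                    f"no input series for subject {subject!r} session {session!r}"
                )
    ctx.log(
        f"study ok: {len(study.subjects)} subjects, "
        f"{sum(len(study.sessions(s)) for s in study.subjects)} sessions"
    )
    return {}


def impl_epi_import(ctx):
    """Bring one session's raw 4D EPI series under engine control."""
    subject, session = coord_ids(ctx.instance.coordinate)
    src = ctx.study.input_locations[(subject, session)]
    dest = ctx.directory / "epi.nii"
    shutil.copyfile(src, dest)
    return {"epi": ["epi.nii"]}


def impl_structural_import(ctx):
    (subject,) = coord_ids(ctx.instance.coordinate)
    src = ctx.study.input_locations[(subject,)]
    dest = ctx.directory / "structural.nii"
    shutil.copyfile(src, dest)
    return {"structural": ["structural.nii"]}


def impl_trim_series(ctx):
    """Discard dummy scans (implementation behind the discard_dummies
    interface, resolved via its implementation alias)."""
    series, zooms = load_series(_single_input(ctx, "epi"))
    trimmed = discard_dummies(series, int(ctx.settings.get("numdummies", 0)))
    save_volume(trimmed, zooms, ctx.directory / "epi.nii")
    return {"epi": ["epi.nii"]}


def impl_realign(ctx):
    series, zooms = load_series(_single_input(ctx, "epi"))
    corrected, shifts, mean_vol = toy_realign(
        series, max_shift=int(ctx.settings.get("max_shift", 3))
    )
    save_volume(corrected, zooms, ctx.directory / "epi.nii")
    save_volume(mean_vol, zooms, ctx.directory / "meanepi.nii")
    # 6-column motion table: translations in mm, rotations zero
    table = np.zeros((series.shape[-1], 6))
    table[:, :3] = shifts * np.asarray(zooms)
    tmp_rp = ctx.directory / "tmp_rp.txt"
    np.savetxt(tmp_rp, table, fmt="%.6f")
    os.replace(tmp_rp, ctx.directory / "rp.txt")
    return {
        "epi": ["epi.nii"],
        "realignment_parameter": ["rp.txt"],
        "meanepi": ["meanepi.nii"],
    }


def impl_tsdiffana(ctx):
    series, _ = load_series(_single_input(ctx, "epi"))
    report = tsdiffana_metrics(
        series, outlier_factor=float(ctx.settings.get("outlier_factor", 4.0))
    )
    lines = ["pair\tmetric\tmean_intensity"]
    for i, metric in enumerate(report.metrics):
        lines.append(f"{i}\t{metric:.10g}\t{report.mean_intensity[i]:.10g}")
    write_text(ctx.directory / "metrics.tsv", "\n".join(lines) + "\n")
    write_text(
        ctx.directory / "qc.json",
        json.dumps(
            {
                "metrics": report.metrics.tolist(),
                "mean_intensity": report.mean_intensity.tolist(),
                "outliers": report.outliers,
            },
            indent=1,
        ),
    )
    return {"qc_timeseries": ["metrics.tsv", "qc.json"]}


def impl_smooth(ctx):
    series, zooms = load_series(_single_input(ctx, "epi"))
    fwhm = float(ctx.settings.get("FWHM", 0))
    out = np.stack(
        [
            gaussian_smooth(series[..., t], fwhm, zooms)
            for t in range(series.shape[-1])
        ],
        axis=-1,
    )
    save_volume(out, zooms, ctx.directory / "epi.nii")
    return {"epi": ["epi.nii"]}


def _session_of(ctx, path: Path) -> str:
    # placed layout: inputs/<stream>/<coordinate.../><file>
    rel = Path(path).relative_to(ctx.directory)
    return rel.parts[2]


def impl_firstlevel_model(ctx):
    """Within-subject GLM over all of the subject's sessions (fan-in)."""
    (subject,) = coord_ids(ctx.instance.coordinate)
    model = ctx.settings.get("model")
    if not isinstance(model, FmriModel):
        raise SpecificationError(
            f"{ctx.instance}: the firstlevel model setting must hold an "
            f"FmriModel with events (use add_event/add_contrast)"
        )
    hrf_mode = str(ctx.settings.get("hrf", "boxcar"))
    tr = float(ctx.settings.get("tr", 2.0))

    epi_by_session = {
        _session_of(ctx, p): Path(p)
        for p in ctx.inputs.get("epi", [])
        if str(p).endswith(".nii")
    }
    motion_by_session = {
        _session_of(ctx, p): Path(p)
        for p in ctx.inputs.get("realignment_parameter", [])
    }
    sessions_info = {}
    data_blocks = []
    shape = zooms = None
    for session in ctx.study.sessions(subject):
        series, zooms = load_series(epi_by_session[session])
        shape = series.shape[:3]
        motion = None
        if session in motion_by_session:
            motion = np.loadtxt(motion_by_session[session])
        sessions_info[session] = (series.shape[-1], motion)
        data_blocks.append(series.reshape(-1, series.shape[-1]).T)
    data = np.vstack(data_blocks)

    stage_name = ctx.instance.stage_name
    design = build_design(model, stage_name, subject, sessions_info, hrf_mode, tr)
    X = design.full_matrix()
    specs = model.contrasts_for(stage_name, subject)
    rows = [expand_contrast(s, design) for s in specs]
    betas, sigma2, tmaps, df = fit_first_level(data, X, rows)

    files_betas = ["betas.nii", "design.json"]
    save_volume(
        betas.T.reshape(shape + (betas.shape[0],)), zooms,
        ctx.directory / "betas.nii",
    )
    write_text(
        ctx.directory / "design.json",
        json.dumps(
            {
                "columns": design.column_names(),
                "n_rows": design.n_rows,
                "hrf": hrf_mode,
                "df": df,
            },
            indent=1,
        ),
    )
    files_cons, files_tmaps = [], ["dof.json"]
    contrast_meta = []
    for i, (spec, row, t) in enumerate(zip(specs, rows, tmaps), start=1):
        con = (row @ betas).sum(axis=0) if spec.contype == "F" else row[0] @ betas
        name = f"con_{i:03d}.nii"
        save_volume(con.reshape(shape), zooms, ctx.directory / name)
        files_cons.append(name)
        contrast_meta.append(
            {"index": i, "format": spec.format, "contype": spec.contype,
             "vector": np.asarray(spec.vector).tolist()}
        )
        if t is not None:
            tname = f"tmap_{i:03d}.nii"
            save_volume(t.reshape(shape), zooms, ctx.directory / tname)
            files_tmaps.append(tname)
    write_text(ctx.directory / "contrasts.json", json.dumps(contrast_meta, indent=1))
    files_cons.append("contrasts.json")
    write_text(ctx.directory / "dof.json", json.dumps({"df": df}))
    save_volume(sigma2.reshape(shape), zooms, ctx.directory / "resid_var.nii")
    files_betas.append("resid_var.nii")
    return {
        "firstlevel_betas": files_betas,
        "firstlevel_cons": files_cons,
        "firstlevel_tmaps": files_tmaps,
    }


def impl_secondlevel_ttest(ctx):
    """One-sample t across subjects for every first-level contrast."""
    by_contrast: dict[str, dict[str, Path]] = {}
    for p in ctx.inputs.get("firstlevel_cons", []):
        p = Path(p)
        if not p.name.endswith(".nii"):
            continue
        subject = _session_of(ctx, p)
        by_contrast.setdefault(p.name, {})[subject] = p
    if not by_contrast:
        raise SpecificationError(f"{ctx.instance}: no first-level contrast maps")
    outputs = []
    summary = {}
    for name in sorted(by_contrast):
        subject_maps = by_contrast[name]
        if len(subject_maps) < 2:
            raise SpecificationError(
                "a second-level t-test needs contrast maps from >= 2 subjects"
            )
        maps, zooms = [], None
        for subject in sorted(subject_maps):
            data, zooms = load_series(subject_maps[subject])
            maps.append(data)
        t, df, degenerate = second_level_ttest(np.stack(maps))
        out_name = name.replace("con_", "group_t_")
        save_volume(np.nan_to_num(t, posinf=1e6, neginf=-1e6), zooms,
                    ctx.directory / out_name)
        outputs.append(out_name)
        summary[out_name] = {
            "df": df,
            "n_subjects": len(subject_maps),
            "n_degenerate_voxels": int(degenerate.sum()),
        }
    write_text(ctx.directory / "secondlevel.json", json.dumps(summary, indent=1))
    outputs.append("secondlevel.json")
    return {"secondlevel_tmap": outputs}


DEFAULT_REGISTRY = {
    "checkparameters": impl_checkparameters,
    "epi_import": impl_epi_import,
    "structural_import": impl_structural_import,
    "trim_series": impl_trim_series,  # alias target of discard_dummies
    "realign": impl_realign,
    "tsdiffana": impl_tsdiffana,
    "smooth": impl_smooth,
    "firstlevel_model": impl_firstlevel_model,
    "secondlevel_ttest": impl_secondlevel_ttest,
}
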