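"""Diagnostics aggregation and garbage collection.

Diagnostics produced by individual instances (time-series QC tables,
motion parameter files) are collected into one multi-level HTML report so
results can be browsed vertically (within-subject, down the pipeline) and
horizontally (between-subject summary tables). Garbage collection deletes
the payload of streams whose producing interface carries a low
permanence-of-output rank, while keeping flags, manifests, logs and
provenance — deleted streams are regenerable on demand by the engine.
"""

from __future__ import annotations

import html
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import PROVENANCE_NAME, load_provenance
from .errors import PipelineError
from .streams import manifest_path, read_stream_record, write_stream_record


@dataclass
class GarbagePolicy:
    """Streams from interfaces ranked below ``keep_threshold`` are
    collectable; higher ranks mark more important data."""

    keep_threshold: int
    dry_run: bool = False

    def __post_init__(self):
        if self.keep_threshold < 0:
            raise PipelineError("gc keep threshold must be >= 0")


def _instance_dirs(analysis_root: Path, prov: dict, stage: dict):
    analysis_id = prov["study"]["analysis_id"]
    for inst in prov["instances"]:
        if inst["stage_key"] != stage["key"]:
            continue
        directory = analysis_root / (analysis_id + stage.get("branch_suffix", ""))
        directory = directory / stage["key"]
        for _, ident in inst["coordinate"]:
            directory = directory / ident
        yield inst, directory


def garbage_collect(analysis_root: Path, policy: GarbagePolicy) -> list[str]:
    """Delete collectable stream payloads; return the deletion manifest.

    Completion flags, stream manifests, input manifests, logs and the
    provenance record are never touched; manifests of deleted streams are
    marked stale so the engine knows the data are regenerable rather than
    changed. With ``dry_run`` the manifest is returned without deleting.
    """
    analysis_root = Path(analysis_root)
    prov = load_provenance(analysis_root)
    main_stages = [s for s in prov["stages"] if s["output_streams"]]
    if main_stages:
        min_rank = min(s["permanence_of_output"] for s in main_stages)
        if policy.keep_threshold <= min_rank:
            import warnings

            warnings.warn(
                f"gc threshold {policy.keep_threshold} is not above the lowest "
                f"permanence rank present ({min_rank}); nothing to delete"
            )
    deleted: list[str] = []
    for stage in main_stages:
        if stage["permanence_of_output"] >= policy.keep_threshold:
            continue
        for _inst, directory in _instance_dirs(analysis_root, prov, stage):
            for stream in stage["output_streams"]:
                record = read_stream_record(directory, stream)
                if record is None or record.stale:
                    continue
                for f in record.files:
                    target = directory / f.path
                    if target.exists():
                        deleted.append(str(target.relative_to(analysis_root)))
                        if not policy.dry_run:
                            target.unlink()
                if not policy.dry_run:
                    record.stale = True
                    write_stream_record(record, directory)
    return deleted


# ---------------------------------------------------------------------------
# multi-level diagnostics report


def _motion_summary(analysis_root: Path, prov: dict) -> pd.DataFrame | None:
    rows = []
    for stage in prov["stages"]:
        if "realignment_parameter" not in stage["output_streams"]:
            continue
        for inst, directory in _instance_dirs(analysis_root, prov, stage):
            record = read_stream_record(directory, "realignment_parameter")
            if record is None:
                continue
            for f in record.files:
                path = directory / f.path
                if not path.exists():
                    continue
                table = np.loadtxt(path)
                ids = [ident for _, ident in inst["coordinate"]]
                rows.append(
                    {
                        "stage": stage["key"],
                        "subject": ids[0] if ids else "",
                        "session": ids[1] if len(ids) > 1 else "",
                        "max_abs_translation_mm": float(
                            np.abs(table[:, :3]).max()
                        ),
                    }
                )
    if not rows:
        return None
    frame = pd.DataFrame(rows)
    return (
        frame.groupby("subject", as_index=False)["max_abs_translation_mm"]
        .max()
        .sort_values("subject")
    )


def collect_diagnostics(analysis_root: Path) -> dict:
    """Build the multi-level report; read-only over instance directories.

    Writes ``report/index.html`` (per-stage, per-subject, per-session
    asset links) and, when the study has at least two subjects, a
    between-subject motion summary table. Missing assets are noted, not
    fatal.
    """
    analysis_root = Path(analysis_root)
    report_dir = analysis_root / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    if not (analysis_root / PROVENANCE_NAME).exists():
        prov = {"stages": [], "instances": [], "study": {"subjects": []}}
    else:
        prov = load_provenance(analysis_root)

    sections = []
    n_assets = 0
    for stage in prov["stages"]:
        items = []
        for inst, directory in _instance_dirs(analysis_root, prov, stage):
            ids = "/".join(ident for _, ident in inst["coordinate"]) or "study"
            assets = []
            for candidate in ("metrics.tsv", "qc.json", "rp.txt",
                              "secondlevel.json", "design.json"):
                path = directory / candidate
                if path.exists():
                    rel = path.relative_to(analysis_root)
                    assets.append(f'<a href="../{rel}">{candidate}</a>')
                    n_assets += 1
            note = " ".join(assets) if assets else "<em>no assets</em>"
            items.append(
                f"<li>{html.escape(ids)} — {inst['status']} — {note}</li>"
            )
        sections.append(
            f"<h2>{html.escape(stage['key'])}</h2>\n<ul>\n"
            + "\n".join(items)
            + "\n</ul>"
        )

    subjects = prov["study"].get("subjects", [])
    motion = _motion_summary(analysis_root, prov) if len(subjects) >= 2 else None
    motion_html = ""
    if motion is not None:
        motion.to_csv(report_dir / "motion_summary.csv", index=False)
        motion_html = "<h2>Between-subject motion</h2>\n" + motion.to_html(
            index=False
        )

    index = report_dir / "index.html"
    index.write_text(
        "<html><head><title>Analysis report</title></head><body>\n"
        f"<h1>Analysis report ({len(prov['stages'])} stages)</h1>\n"
        + "\n".join(sections)
        + "\n"
        + motion_html
        + "\n</body></html>\n"
    )
    return {
        "index": index,
        "n_stages": len(prov["stages"]),
        "n_assets": n_assets,
        "motion_summary": motion,
    }
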