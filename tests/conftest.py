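"""Shared fixtures: toy-study builders and independent oracles."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

import pipecraft as pc
from pipecraft.interfaces import ModuleInvocation, Tasklist


# ---------------------------------------------------------------------------
# toy analysis builder


@dataclass
class ToyAnalysis:
    cfg: pc.SyntheticStudyConfig
    study: pc.StudyDescription
    pipeline: pc.ExpandedPipeline
    tasklist: Tasklist
    interfaces: dict
    params: object
    model: pc.FmriModel

    def run(self, **kwargs):
        return pc.run_pipeline(self.pipeline, self.study, self.params, **kwargs)

    def digests(self):
        return pc.output_tree_digests(self.pipeline, self.study)


def build_toy_analysis(
    root: Path,
    tasklist_name: str = "toy_fmri",
    cfg: pc.SyntheticStudyConfig | None = None,
    seed: int = 11,
) -> ToyAnalysis:
    cfg = cfg or pc.SyntheticStudyConfig(seed=seed)
    study = pc.generate_synthetic_study(cfg, root)
    interfaces = pc.builtin_interfaces()
    tasklist = pc.builtin_tasklist(tasklist_name)
    model = pc.FmriModel()
    model.add_event(
        "firstlevel_model", "*", "*", "task",
        cfg.activation_onsets, cfg.activation_duration,
    )
    model.add_contrast("firstlevel_model", "*", "sameforallsessions", [1])
    overrides = {"tasksettings": {"discard_dummies": {"numdummies": cfg.numdummies}}}
    pipeline = pc.expand_tasklist(tasklist, interfaces)
    for stage in pipeline.stages:
        if stage.name == "firstlevel_model":
            overrides["tasksettings"][stage.settings_key] = {"model": model}
    params = pc.merge_parameters(
        pc.builtin_parameters(), tasklist, interfaces, overrides
    )
    return ToyAnalysis(cfg, study, pipeline, tasklist, interfaces, params, model)


@pytest.fixture
def toy(tmp_path):
    return build_toy_analysis(tmp_path)


# ---------------------------------------------------------------------------
# random pipelines + the brute-force dependency oracle


def random_pipeline_and_study(rng: np.random.Generator, root: Path | str = "/tmp/x"):
    """A random chain-domain pipeline (<= 6 stages) over a small study,
    with every consumed stream guaranteed a producer."""
    domains = ["study", "subject", "session"]
    pool = ["a", "b", "c", "d"]
    n_stages = int(rng.integers(2, 7))
    interfaces, invocations = {}, []
    produced: list[str] = []
    for i in range(n_stages):
        name = f"mod{i}"
        outputs = list(
            rng.choice(pool, size=int(rng.integers(0, 3)), replace=False)
        )
        available = sorted(set(produced))
        inputs = []
        if available:
            inputs = list(
                rng.choice(
                    available,
                    size=int(rng.integers(0, min(2, len(available)) + 1)),
                    replace=False,
                )
            )
        interfaces[name] = pc.ModuleInterface(
            name=name,
            domain=str(rng.choice(domains)),
            input_streams=[str(s) for s in inputs],
            output_streams=[str(s) for s in outputs],
        )
        produced.extend(outputs)
        invocations.append(ModuleInvocation(name))
    tasklist = Tasklist(main=invocations)
    pipeline = pc.expand_tasklist(tasklist, interfaces)

    n_subjects = int(rng.integers(1, 4))
    subjects = [f"P{j}" for j in range(n_subjects)]
    sessions = {
        s: [f"run{k}" for k in range(int(rng.integers(1, 4)))] for s in subjects
    }
    study = pc.StudyDescription(
        analysis_root=Path(root),
        analysis_id="rnd",
        subjects=subjects,
        sessions_per_subject=sessions,
    )
    return pipeline, study


def oracle_dependency_map(pipeline, study):
    """Brute force: scan all stage pairs x all instance pairs, applying the
    last-producer rule and the domain read rules directly."""
    stages = pipeline.stages

    def coords(domain):
        if domain == "study":
            return [()]
        if domain == "subject":
            return [(("subject", s),) for s in study.subjects]
        return [
            (("subject", s), ("session", r))
            for s in study.subjects
            for r in study.sessions_per_subject[s]
        ]

    edges = set()
    for ti, target in enumerate(stages):
        for stream in target.interface.input_streams:
            qualified = target.qualified_inputs.get(stream)
            source = None
            for si in range(ti - 1, -1, -1):
                cand = stages[si]
                if cand.branch_path != target.branch_path[: len(cand.branch_path)]:
                    continue
                if qualified:
                    mod, src_stream = qualified.split(".", 1)
                    if cand.name == mod and src_stream in cand.interface.output_streams:
                        source = (cand, src_stream)
                        break
                elif stream in cand.interface.output_streams:
                    source = (cand, stream)
                    break
            assert source is not None, "oracle found no producer"
            src_stage, _ = source
            for tc in coords(target.interface.domain):
                for sc in coords(src_stage.interface.domain):
                    t_ids = tuple(i for _, i in tc)
                    s_ids = tuple(i for _, i in sc)
                    shorter = min(len(t_ids), len(s_ids))
                    if t_ids[:shorter] != s_ids[:shorter]:
                        continue  # sideways pair: no edge
                    if len(s_ids) <= len(t_ids):
                        if t_ids[: len(s_ids)] != s_ids:
                            continue
                    ok = (
                        s_ids == t_ids
                        or s_ids == t_ids[: len(s_ids)]
                        or s_ids[: len(t_ids)] == t_ids
                    )
                    if ok:
                        edges.add(
                            pc.DependencyEdge(
                                pc.InstanceKey(src_stage.name, src_stage.index, sc),
                                pc.InstanceKey(target.name, target.index, tc),
                                stream,
                            )
                        )
    return edges
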