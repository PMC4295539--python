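"""First-level fMRI model specification: events, contrasts, design matrices.

Events are declared against a named model stage with per-subject /
per-session scope (``"*"`` wildcards expand at design-build time, and a
more specific declaration overrides a wildcard one for the same event
name). Onsets and durations are in scans; conversion from seconds is the
caller's job. Each event yields a boxcar regressor on the scan grid
(fractional onsets and durations accumulate proportionally into the scans
they overlap), optionally convolved with a canonical double-gamma
haemodynamic response. Parametric modulators enter as mean-centered scaled
copies of the boxcar. Nuisance regressors are the six motion parameters
(3 translations + 3 rotations) plus one constant per session — the
"moves and means".

Contrast vectors are declared per session block in one of three formats:

``sameforallsessions``
    the vector is tiled across every session block;
``singlesession:<name>``
    the vector lands in the named session's block, zeros elsewhere;
``uniquebysession``
    one long vector consumed block-by-block across all sessions.

With ``auto_movesandmeans`` (the default) the nuisance columns receive
zeros automatically; otherwise the given vector must already cover them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .errors import ContrastWidthError, SpecificationError

WILDCARD = "*"
_FORMATS = ("sameforallsessions", "singlesession", "uniquebysession")


@dataclass
class EventSpec:
    module: str
    subject: str
    session: str
    event_name: str
    onsets: list[float]
    durations: list[float] | float
    parametric: list[float] | None = None

    def __post_init__(self):
        self.onsets = [float(o) for o in np.atleast_1d(self.onsets)]
        if any(not np.isfinite(o) or o < 0 for o in self.onsets):
            raise SpecificationError(
                f"event {self.event_name!r}: onsets must be finite and >= 0"
            )
        if np.ndim(self.durations) == 0:
            self.durations = float(self.durations)
        else:
            self.durations = [float(d) for d in self.durations]
            if len(self.durations) != len(self.onsets):
                raise SpecificationError(
                    f"event {self.event_name!r}: {len(self.durations)} durations "
                    f"for {len(self.onsets)} onsets"
                )
        if self.parametric is not None:
            self.parametric = [float(p) for p in self.parametric]
            if len(self.parametric) != len(self.onsets):
                raise SpecificationError(
                    f"event {self.event_name!r}: parametric modulator length "
                    f"{len(self.parametric)} does not match {len(self.onsets)} onsets"
                )

    def durations_list(self) -> list[float]:
        if np.ndim(self.durations) == 0:
            return [float(self.durations)] * len(self.onsets)
        return list(self.durations)

    def specificity(self) -> int:
        return int(self.subject != WILDCARD) + int(self.session != WILDCARD)

    def applies_to(self, subject: str, session: str) -> bool:
        return self.subject in (WILDCARD, subject) and self.session in (
            WILDCARD,
            session,
        )


@dataclass
class ContrastSpec:
    module: str
    subject: str
    format: str
    vector: np.ndarray
    contype: str = "T"
    auto_movesandmeans: bool = True

    def __post_init__(self):
        token = self.format.split(":", 1)[0]
        if token not in _FORMATS:
            raise SpecificationError(
                f"unknown contrast format {self.format!r}; expected one of "
                f"{_FORMATS} (singlesession takes ':<sessionname>')"
            )
        if token == "singlesession" and ":" not in self.format:
            raise SpecificationError(
                "singlesession format needs a session name: 'singlesession:<name>'"
            )
        self.vector = np.atleast_2d(np.asarray(self.vector, dtype=float))
        if self.vector.size == 0:
            raise SpecificationError("contrast vector must be nonempty")
        if self.contype not in ("T", "F"):
            raise SpecificationError(f"contype must be 'T' or 'F', got {self.contype!r}")

    def applies_to(self, subject: str) -> bool:
        return self.subject in (WILDCARD, subject)


class FmriModel:
    """Accumulating container for event and contrast specifications,
    mirroring the add-event / add-contrast user-script idiom."""

    def __init__(self):
        self.events: list[EventSpec] = []
        self.contrasts: list[ContrastSpec] = []

    def add_event(
        self,
        module: str,
        subject: str,
        session: str,
        event_name: str,
        onsets,
        durations,
        parametric=None,
    ) -> "FmriModel":
        self.events.append(
            EventSpec(module, subject, session, event_name, onsets, durations, parametric)
        )
        return self

    def add_contrast(
        self,
        module: str,
        subject: str,
        format: str,
        vector,
        contype: str = "T",
        auto_movesandmeans: bool = True,
    ) -> "FmriModel":
        self.contrasts.append(
            ContrastSpec(module, subject, format, vector, contype, auto_movesandmeans)
        )
        return self

    def events_for(self, module: str, subject: str, session: str) -> list[EventSpec]:
        """Applicable events, most specific declaration winning per name."""
        best: dict[str, EventSpec] = {}
        order: list[str] = []
        for spec in self.events:
            if spec.module != module or not spec.applies_to(subject, session):
                continue
            if spec.event_name not in best:
                order.append(spec.event_name)
                best[spec.event_name] = spec
            elif spec.specificity() >= best[spec.event_name].specificity():
                best[spec.event_name] = spec
        return [best[name] for name in order]

    def contrasts_for(self, module: str, subject: str) -> list[ContrastSpec]:
        return [
            c for c in self.contrasts if c.module == module and c.applies_to(subject)
        ]


def add_event(model: FmriModel, *args, **kwargs) -> FmriModel:
    return model.add_event(*args, **kwargs)


def add_contrast(model: FmriModel, *args, **kwargs) -> FmriModel:
    return model.add_contrast(*args, **kwargs)


# ---------------------------------------------------------------------------
# regressor construction


def boxcar(onsets: Sequence[float], durations: Sequence[float], n_scans: int,
           weights: Sequence[float] | None = None) -> np.ndarray:
    """Boxcar regressor on the scan grid.

    Each occurrence contributes its overlap (in scan units) with every
    scan, so fractional onsets and durations accumulate proportionally and
    the column integrates to the total event duration.
    """
    column = np.zeros(n_scans)
    if weights is None:
        weights = np.ones(len(list(onsets)))
    for onset, duration, weight in zip(onsets, durations, weights):
        if onset + duration > n_scans + 1e-9:
            raise SpecificationError(
                f"event occurrence at onset {onset} with duration {duration} "
                f"extends past the series end ({n_scans} scans)"
            )
        first = int(np.floor(onset))
        last = int(np.ceil(onset + duration))
        for t in range(first, min(last, n_scans)):
            overlap = min(t + 1.0, onset + duration) - max(float(t), onset)
            if overlap > 0:
                column[t] += weight * overlap
    return column


def canonical_hrf(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR.

    Peak at 6 s, undershoot at 16 s, undershoot ratio 1/6; normalized to
    unit sum so convolution preserves scale of sustained responses.
    """
    t = np.arange(0.0, duration_s, tr)
    h = gamma_dist.pdf(t, 6.0) - gamma_dist.pdf(t, 16.0) / 6.0
    total = h.sum()
    return h / total if total != 0 else h


@dataclass
class SessionDesign:
    """Design of one session: task regressors plus nuisance columns."""

    session: str
    task_names: list[str]
    task: np.ndarray  # n_scans x k
    nuisance_names: list[str]
    nuisance: np.ndarray  # n_scans x m (motion columns then the session mean)

    @property
    def n_scans(self) -> int:
        return self.task.shape[0]

    @property
    def n_task(self) -> int:
        return self.task.shape[1]

    @property
    def n_nuisance(self) -> int:
        return self.nuisance.shape[1]

    def matrix(self) -> np.ndarray:
        return np.hstack([self.task, self.nuisance])


@dataclass
class FirstLevelDesign:
    """Per-subject design: ordered session blocks laid out block-diagonally."""

    subject: str
    sessions: list[SessionDesign]

    @property
    def n_columns(self) -> int:
        return sum(s.n_task + s.n_nuisance for s in self.sessions)

    @property
    def n_rows(self) -> int:
        return sum(s.n_scans for s in self.sessions)

    def column_names(self) -> list[str]:
        names = []
        for s in self.sessions:
            names.extend(f"{s.session}:{n}" for n in s.task_names)
            names.extend(f"{s.session}:{n}" for n in s.nuisance_names)
        return names

    def full_matrix(self) -> np.ndarray:
        """Block-diagonal stack of the per-session matrices."""
        X = np.zeros((self.n_rows, self.n_columns))
        row = col = 0
        for s in self.sessions:
            block = s.matrix()
            X[row : row + s.n_scans, col : col + block.shape[1]] = block
            row += s.n_scans
            col += block.shape[1]
        return X

    def session_block_slices(self) -> list[tuple[slice, slice]]:
        """Per session: (task column slice, nuisance column slice)."""
        slices = []
        col = 0
        for s in self.sessions:
            task = slice(col, col + s.n_task)
            nuis = slice(col + s.n_task, col + s.n_task + s.n_nuisance)
            slices.append((task, nuis))
            col += s.n_task + s.n_nuisance
        return slices


def build_session_design(
    events: Sequence[EventSpec],
    session: str,
    n_scans: int,
    hrf_mode: str = "boxcar",
    tr: float = 2.0,
    motion: np.ndarray | None = None,
) -> SessionDesign:
    """Assemble one session's design from resolved event specifications.

    Events are order- and sort-invariant: permuting onsets (or the events'
    declaration order of occurrences) changes nothing. ``hrf_mode`` is
    either ``"boxcar"`` (no convolution) or ``"canonical"``.
    """
    if hrf_mode not in ("boxcar", "canonical"):
        raise SpecificationError(f"unknown hrf_mode {hrf_mode!r}")
    kernel = canonical_hrf(tr) if hrf_mode == "canonical" else None
    names: list[str] = []
    columns: list[np.ndarray] = []
    for spec in events:
        col = boxcar(spec.onsets, spec.durations_list(), n_scans)
        columns.append(col)
        names.append(spec.event_name)
        if spec.parametric is not None:
            centered = np.asarray(spec.parametric) - np.mean(spec.parametric)
            columns.append(
                boxcar(spec.onsets, spec.durations_list(), n_scans, weights=centered)
            )
            names.append(f"{spec.event_name}xparametric")
    if kernel is not None:
        columns = [np.convolve(c, kernel)[:n_scans] for c in columns]
    task = np.column_stack(columns) if columns else np.zeros((n_scans, 0))

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_scans:
            raise SpecificationError(
                f"motion parameters have {motion.shape[0]} rows for "
                f"{n_scans} scans"
            )
        # mean-center against the session mean and drop constant columns
        # (e.g. never-estimated rotations) to keep the design full rank
        motion = motion - motion.mean(axis=0)
        keep = np.ptp(motion, axis=0) > 0
        nuis_names = [
            f"motion{i + 1}" for i in range(motion.shape[1]) if keep[i]
        ]
        motion = motion[:, keep]
    else:
        motion = np.zeros((n_scans, 0))
        nuis_names = []
    nuisance = np.hstack([motion, np.ones((n_scans, 1))])
    nuis_names = nuis_names + ["mean"]
    return SessionDesign(session, names, task, nuis_names, nuisance)


def build_design(
    model: FmriModel,
    module: str,
    subject: str,
    sessions: Mapping[str, int] | Mapping[str, tuple[int, np.ndarray | None]],
    hrf_mode: str = "boxcar",
    tr: float = 2.0,
) -> FirstLevelDesign:
    """Build a subject's first-level design.

    ``sessions`` maps session name (in block order) to either the scan
    count, or a ``(scan count, motion parameter array)`` pair.
    """
    blocks = []
    for session, info in sessions.items():
        if isinstance(info, tuple):
            n_scans, motion = info
        else:
            n_scans, motion = info, None
        events = model.events_for(module, subject, session)
        blocks.append(
            build_session_design(events, session, n_scans, hrf_mode, tr, motion)
        )
    return FirstLevelDesign(subject=subject, sessions=blocks)


# ---------------------------------------------------------------------------
# contrast expansion


def expand_contrast(spec: ContrastSpec, design: FirstLevelDesign) -> np.ndarray:
    """Expand a contrast specification to full design width.

    Returns an array of shape (rows, n_columns); T contrasts have one row.
    """
    rows = spec.vector
    token = spec.format.split(":", 1)[0]
    slices = design.session_block_slices()
    out = np.zeros((rows.shape[0], design.n_columns))

    def block_width(i: int) -> int:
        s = design.sessions[i]
        return s.n_task if spec.auto_movesandmeans else s.n_task + s.n_nuisance

    def place(i: int, values: np.ndarray) -> None:
        task_slice, nuis_slice = slices[i]
        s = design.sessions[i]
        out[:, task_slice] = values[:, : s.n_task]
        if not spec.auto_movesandmeans:
            out[:, nuis_slice] = values[:, s.n_task :]

    if token == "sameforallsessions":
        for i in range(len(design.sessions)):
            if rows.shape[1] != block_width(i):
                raise ContrastWidthError(block_width(i), rows.shape[1],
                                         f"session block {design.sessions[i].session!r}")
            place(i, rows)
    elif token == "singlesession":
        name = spec.format.split(":", 1)[1]
        matches = [i for i, s in enumerate(design.sessions) if s.session == name]
        if not matches:
            raise SpecificationError(
                f"singlesession contrast names unknown session {name!r}"
            )
        for i in matches:
            if rows.shape[1] != block_width(i):
                raise ContrastWidthError(block_width(i), rows.shape[1],
                                         f"session block {name!r}")
            place(i, rows)
    else:  # uniquebysession
        expected = sum(block_width(i) for i in range(len(design.sessions)))
        if rows.shape[1] != expected:
            raise ContrastWidthError(expected, rows.shape[1], "uniquebysession")
        offset = 0
        for i in range(len(design.sessions)):
            w = block_width(i)
            place(i, rows[:, offset : offset + w])
            offset += w
    return out


# ---------------------------------------------------------------------------
# tabular sidecar loading


def load_events_tsv(text: str, module: str) -> FmriModel:
    """Load events from a TSV sidecar with columns
    subject, session, event, onsets, durations (onsets/durations are
    space-separated scan values; '*' wildcards allowed)."""
    from io import StringIO

    table = pd.read_csv(StringIO(text), sep="\t", dtype=str)
    model = FmriModel()
    for _, row in table.iterrows():
        onsets = [float(x) for x in str(row["onsets"]).split()]
        durations = [float(x) for x in str(row["durations"]).split()]
        model.add_event(
            module,
            row.get("subject", WILDCARD) or WILDCARD,
            row.get("session", WILDCARD) or WILDCARD,
            row["event"],
            onsets,
            durations if len(durations) > 1 else durations[0],
        )
    return model


def load_contrasts_tsv(text: str, module: str, model: FmriModel | None = None) -> FmriModel:
    """Load contrasts from a TSV sidecar with columns
    subject, format, vector, contype."""
    from io import StringIO

    table = pd.read_csv(StringIO(text), sep="\t", dtype=str)
    model = model or FmriModel()
    for _, row in table.iterrows():
        vector = [float(x) for x in str(row["vector"]).split()]
        model.add_contrast(
            module,
            row.get("subject", WILDCARD) or WILDCARD,
            row["format"],
            vector,
            (row.get("contype") or "T"),
        )
    return model
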