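"""Domain model for TCD exams and plain-text readers/writers.

A TCD exam consists of one or more 30-second cerebral blood-flow-velocity
(CBFV) envelope recordings per hemisphere, each taken at a fixed insonation
depth.  Envelope files are long-format CSV (one row per sample); subject
labels live in a separate two-column CSV so that envelope files stay
label-free.  Velocities are cm/s throughout, depths are mm; no unit
conversion is ever performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateBeatError, FormatError, ValidationError

HEMISPHERES = ("left", "right")
LVO = "LVO"
IHC = "IHC"
LABELS = (LVO, IHC)

#: plausible insonation depth range accepted by the data model (mm).  The
#: MCA acquisition protocol targets 45-60 mm; the wider bound admits
#: off-protocol but physically sensible recordings.
DEPTH_MIN_MM = 30.0
DEPTH_MAX_MM = 70.0

ENVELOPE_COLUMNS = (
    "subject_id",
    "hemisphere",
    "depth_mm",
    "fs_hz",
    "sample_index",
    "velocity",
)


@dataclass(eq=False)
class EnvelopeRecording:
    """One CBFV envelope trace at a fixed hemisphere and depth."""

    subject_id: str
    hemisphere: str
    depth_mm: float
    velocity: np.ndarray
    fs_hz: float = 125.0

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )
        if not self.fs_hz > 0:
            raise ValidationError(f"fs_hz must be positive, got {self.fs_hz}")
        if not (DEPTH_MIN_MM <= self.depth_mm <= DEPTH_MAX_MM):
            raise ValidationError(
                f"depth_mm={self.depth_mm} outside plausible range "
                f"[{DEPTH_MIN_MM}, {DEPTH_MAX_MM}] mm"
            )
        if self.velocity.ndim != 1:
            raise ValidationError("velocity must be one-dimensional")
        if not np.all(np.isfinite(self.velocity)):
            raise ValidationError("velocity contains non-finite values")

    @property
    def duration_s(self) -> float:
        return len(self.velocity) / self.fs_hz

    @property
    def n_samples(self) -> int:
        return len(self.velocity)


@dataclass(eq=False)
class Exam:
    """All envelope recordings for one subject plus an optional group label."""

    subject_id: str
    recordings: list = field(default_factory=list)
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise ValidationError(f"label must be in {LABELS} or None, got {self.label!r}")

    def recordings_for(self, hemisphere: str) -> list:
        return [r for r in self.recordings if r.hemisphere == hemisphere]


@dataclass(eq=False)
class AverageBeat:
    """The representative (averaged) beat waveform for one recording.

    ``t_d_index`` and ``t_s_index`` are the sample indices of the diastolic
    minimum and systolic maximum of the averaged beat.
    """

    subject_id: str
    hemisphere: str
    depth_mm: float
    fs_hz: float
    x: np.ndarray
    n_beats_used: int
    t_d_index: int = -1
    t_s_index: int = -1

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if len(self.x) < 3:
            raise ValidationError("average beat must have at least 3 samples")
        if self.t_d_index < 0:
            self.t_d_index = int(np.argmin(self.x))
        if self.t_s_index < 0:
            self.t_s_index = int(np.argmax(self.x))
        if not self.x[self.t_s_index] > self.x[self.t_d_index]:
            raise DegenerateBeatError(
                "flat average beat: systolic max does not exceed diastolic min"
            )

    @property
    def mean_velocity(self) -> float:
        return float(np.mean(self.x))


@dataclass(eq=False)
class BilateralPair:
    """The selected left/right average-beat pair for one subject."""

    subject_id: str
    left: AverageBeat
    right: AverageBeat

    def __post_init__(self) -> None:
        if self.left.hemisphere == self.right.hemisphere:
            raise ValidationError("bilateral pair requires distinct hemispheres")
        if self.left.subject_id != self.right.subject_id:
            raise ValidationError("bilateral pair mixes subjects")
        if self.left.hemisphere != "left":
            self.left, self.right = self.right, self.left


# ---------------------------------------------------------------------------
# envelope CSV
# ---------------------------------------------------------------------------

def read_envelope_csv(path) -> list:
    """Read long-format envelope CSV into a list of :class:`EnvelopeRecording`.

    One recording is one ``(subject_id, hemisphere, depth_mm)`` block whose
    ``sample_index`` runs contiguously from 0.  Blocks may appear in any
    order; sample order within a block must be monotone.
    """
    try:
        df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in ENVELOPE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"envelope CSV missing column(s): {', '.join(missing)}")
    if len(df) == 0:
        return []

    bad = ~np.isfinite(pd.to_numeric(df["velocity"], errors="coerce").to_numpy())
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
        raise FormatError(f"non-finite velocity value at line {line}")

    recordings = []
    for key, block in df.groupby(["subject_id", "hemisphere", "depth_mm"], sort=False):
        subject_id, hemisphere, depth_mm = key
        idx = block["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            first_bad = int(np.flatnonzero(idx != np.arange(len(idx)))[0])
            line = int(block.index[first_bad]) + 2
            raise FormatError(
                f"sample_index not contiguous from 0 in block {key} (line {line})"
            )
        fs = block["fs_hz"].unique()
        if len(fs) != 1:
            raise FormatError(f"inconsistent fs_hz within block {key}")
        recordings.append(
            EnvelopeRecording(
                subject_id=str(subject_id),
                hemisphere=str(hemisphere),
                depth_mm=float(depth_mm),
                fs_hz=float(fs[0]),
                velocity=block["velocity"].to_numpy(dtype=float),
            )
        )
    return recordings


def write_envelope_csv(recordings: Iterable[EnvelopeRecording], path) -> None:
    """Write recordings as long-format CSV; round-trips velocities exactly.

    Floats are serialized with :func:`repr` (shortest exact decimal), so a
    read-back reproduces the binary values bit-identically.
    """
    rows = []
    for rec in recordings:
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": rec.subject_id,
                    "hemisphere": rec.hemisphere,
                    "depth_mm": rec.depth_mm,
                    "fs_hz": rec.fs_hz,
                    "sample_index": np.arange(rec.n_samples),
                    "velocity": rec.velocity,
                }
            )
        )
    if rows:
        out = pd.concat(rows, ignore_index=True)
    else:
        out = pd.DataFrame(columns=list(ENVELOPE_COLUMNS))
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# subjects CSV
# ---------------------------------------------------------------------------

def read_subjects_csv(path) -> dict:
    """Read the two-column ``subject_id,label`` CSV into a dict."""
    try:
        df = pd.read_csv(path, dtype={"subject_id": str})
    except pd.errors.EmptyDataError:
        return {}
    for col in ("subject_id", "label"):
        if col not in df.columns:
            raise FormatError(f"subjects CSV missing column: {col}")
    labels = {}
    for i, row in df.iterrows():
        label = row["label"]
        if label not in LABELS:
            raise FormatError(f"unknown label {label!r} at line {i + 2}")
        labels[str(row["subject_id"])] = label
    return labels


def write_subjects_csv(labels: dict, path) -> None:
    pd.DataFrame(
        {"subject_id": list(labels.keys()), "label": list(labels.values())}
    ).to_csv(path, index=False)


def assemble_exams(
    recordings: Sequence[EnvelopeRecording], labels: Optional[dict] = None
) -> list:
    """Group recordings by subject into :class:`Exam` objects (file order)."""
    labels = labels or {}
    exams: dict = {}
    for rec in recordings:
        exam = exams.get(rec.subject_id)
        if exam is None:
            exam = Exam(
                subject_id=rec.subject_id, label=labels.get(rec.subject_id)
            )
            exams[rec.subject_id] = exam
        exam.recordings.append(rec)
    return list(exams.values())
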