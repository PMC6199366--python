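"""Velocity Curvature Index (VCI) and Velocity Asymmetry Index (VAI).

VCI quantifies how sharply structured the systolic complex of an average
beat waveform is.  The beat is smoothed with a short raised-cosine
(Hanning) kernel, discrete graph curvature is evaluated at every interior
sample,

    k(i) = |x[i+1] - 2 x[i] + x[i-1]| / (1 + (x[i] - x[i-1])^2)^(3/2),

and VCI is the sum of k over the *beat canopy* -- the set of samples whose
velocity exceeds the diastolic minimum by at least one quarter of the
diastolic-to-systolic range.  Differences are taken per sample index with
velocity in cm/s (no division by the sampling interval); 125 Hz is the
reference sampling rate under which VCI magnitudes are comparable.
Occlusion blunts and dampens the waveform, lowering its curvature, so for
a bilateral pair VCI is the minimum across the two hemispheres.

VAI is the ratio of the smaller to the larger mean velocity of the two
average beats, a dimensionless number in [0, 1]; 1 means symmetric flow.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import beats as beats_mod
from .errors import DegenerateBeatError, TcdError, ValidationError
from .exams import AverageBeat, BilateralPair, Exam

#: width of the pre-curvature smoothing window, in milliseconds
DEFAULT_WINDOW_MS = 9.0


@dataclass(eq=False)
class FeatureRow:
    """Per-subject feature triple consumed by the classifiers."""

    subject_id: str
    vci: float
    vai: float
    vci_left: float = float("nan")
    vci_right: float = float("nan")
    mu_left: float = float("nan")
    mu_right: float = float("nan")
    label: Optional[str] = None


def hanning_kernel(fs_hz: float, window_ms: float = DEFAULT_WINDOW_MS) -> np.ndarray:
    """Normalized raised-cosine smoothing kernel for a given sampling rate.

    The nonzero tap count is the nearest odd integer to
    ``window_ms * fs_hz / 1000``, floored at 3 so the kernel always
    smooths (a raised cosine's outer taps are zero and are dropped).  At
    the 125 Hz reference rate the 9 ms default yields the minimal 3-tap
    kernel [0.25, 0.5, 0.25]; at higher rates the kernel widens to keep
    its physical duration.
    """
    if window_ms <= 0:
        raise ValidationError("smoothing window must be positive")
    width = window_ms * fs_hz / 1000.0
    n_taps = max(3, 2 * int(round((width - 1.0) / 2.0)) + 1)
    kernel = np.hanning(n_taps + 2)[1:-1]
    return kernel / kernel.sum()


def smooth_beat(
    x: Sequence[float], fs_hz: float, window_ms: float = DEFAULT_WINDOW_MS
) -> np.ndarray:
    """Convolve a beat with the Hanning kernel ("same" length, reflected edges)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValidationError("beat must have at least 3 samples")
    kernel = hanning_kernel(fs_hz, window_ms)
    half = len(kernel) // 2
    if half >= len(x):
        raise ValidationError("beat too short for the smoothing kernel")
    padded = np.pad(x, half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


def curvature(x: Sequence[float]) -> np.ndarray:
    """Discrete graph curvature at every sample (0 at the two boundaries).

    Uses the first-order backward difference in the denominator and the
    second-order central difference in the numerator, both per sample
    index.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValidationError("curvature requires at least 3 samples")
    k = np.zeros(len(x))
    d1 = x[1:-1] - x[:-2]          # backward difference at interior points
    d2 = x[2:] - 2.0 * x[1:-1] + x[:-2]
    k[1:-1] = np.abs(d2) / (1.0 + d1 ** 2) ** 1.5
    return k


def beat_canopy(x: Sequence[float], t_d: int, t_s: int) -> np.ndarray:
    """Indices whose velocity exceeds a quarter of the diastolic-systolic range.

    The canopy is a set in the literal sense and may be non-contiguous.
    """
    x = np.asarray(x, dtype=float)
    if not x[t_s] > x[t_d]:
        raise DegenerateBeatError("degenerate beat: no diastolic-systolic range")
    threshold = x[t_d] + (x[t_s] - x[t_d]) / 4.0
    return np.flatnonzero(x >= threshold)


def vci_single(beat: AverageBeat, window_ms: float = DEFAULT_WINDOW_MS) -> float:
    """VCI of one average beat: smooth, then sum curvature over the canopy.

    Landmarks (diastolic minimum, systolic maximum) are recomputed on the
    smoothed beat, because curvature is evaluated on the smoothed beat.
    """
    s = smooth_beat(beat.x, beat.fs_hz, window_ms)
    t_d = int(np.argmin(s))
    t_s = int(np.argmax(s))
    canopy = beat_canopy(s, t_d, t_s)
    k = curvature(s)
    return float(k[canopy].sum())


def vci_pair(
    pair: BilateralPair, window_ms: float = DEFAULT_WINDOW_MS
) -> Tuple[float, float, float]:
    """Bilateral VCI: the minimum of the left and right values."""
    left = vci_single(pair.left, window_ms)
    right = vci_single(pair.right, window_ms)
    return min(left, right), left, right


def vai(pair: BilateralPair) -> Tuple[float, float, float]:
    """Velocity Asymmetry Index: min over max of the hemispheric mean velocities.

    Means are taken over the unsmoothed average beats.
    """
    mu_left = float(np.mean(pair.left.x))
    mu_right = float(np.mean(pair.right.x))
    if mu_left <= 0 or mu_right <= 0:
        raise ValidationError("implausible envelope: non-positive mean velocity")
    return min(mu_left, mu_right) / max(mu_left, mu_right), mu_left, mu_right


# ---------------------------------------------------------------------------
# cohort-level extraction
# ---------------------------------------------------------------------------

def extract_features(
    exams: Sequence[Exam],
    min_beats: int = beats_mod.DEFAULT_MIN_BEATS,
    min_hr_bpm: float = 35.0,
    max_hr_bpm: float = 180.0,
    corr_min: float = 0.9,
    amp_dev_max: float = 3.0,
    window_ms: float = DEFAULT_WINDOW_MS,
) -> Tuple[List[FeatureRow], List[Tuple[str, str]]]:
    """Run detect -> reject -> average -> pair -> VCI/VAI over a cohort.

    A recording contributes only if it retains at least ``min_beats``
    accepted beats; an exam is complete when both hemispheres have such a
    recording.  Incomplete or failing subjects are not errors: they are
    returned as ``(subject_id, reason)`` skip entries, mirroring exclusion
    from analysis.
    """
    rows: List[FeatureRow] = []
    skips: List[Tuple[str, str]] = []
    for exam in exams:
        usable = {}
        for rec in exam.recordings:
            try:
                seg = beats_mod.detect_beats(rec, min_hr_bpm, max_hr_bpm)
                seg = beats_mod.reject_outlier_beats(seg, corr_min, amp_dev_max)
                if seg.n_accepted < min_beats:
                    continue
                usable[rec] = beats_mod.average_beats(seg)
            except TcdError:
                continue
        try:
            pair = beats_mod.select_bilateral_pair(exam, usable)
            v, v_l, v_r = vci_pair(pair, window_ms)
            a, mu_l, mu_r = vai(pair)
        except TcdError as err:
            skips.append((exam.subject_id, str(err)))
            continue
        rows.append(
            FeatureRow(
                subject_id=exam.subject_id,
                vci=v,
                vai=a,
                vci_left=v_l,
                vci_right=v_r,
                mu_left=mu_l,
                mu_right=mu_r,
                label=exam.label,
            )
        )
    return rows, skips


def features_to_dataframe(rows: Sequence[FeatureRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in rows],
            "vci": [r.vci for r in rows],
            "vci_left": [r.vci_left for r in rows],
            "vci_right": [r.vci_right for r in rows],
            "vai": [r.vai for r in rows],
            "mu_left": [r.mu_left for r in rows],
            "mu_right": [r.mu_right for r in rows],
            "label": [r.label for r in rows],
        }
    )


def write_features_csv(rows: Sequence[FeatureRow], path) -> None:
    features_to_dataframe(rows).to_csv(path, index=False)


def read_features_csv(path) -> List[FeatureRow]:
    df = pd.read_csv(path, dtype={"subject_id": str})
    from .errors import FormatError

    for col in ("subject_id", "vci", "vai"):
        if col not in df.columns:
            raise FormatError(f"features CSV missing column: {col}")
    rows = []
    for _, r in df.iterrows():
        label = r.get("label")
        if pd.isna(label):
            label = None
        rows.append(
            FeatureRow(
                subject_id=str(r["subject_id"]),
                vci=float(r["vci"]),
                vai=float(r["vai"]),
                vci_left=float(r.get("vci_left", float("nan"))),
                vci_right=float(r.get("vci_right", float("nan"))),
                mu_left=float(r.get("mu_left", float("nan"))),
                mu_right=float(r.get("mu_right", float("nan"))),
                label=label,
            )
        )
    return rows
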