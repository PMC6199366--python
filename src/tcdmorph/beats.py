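"""Beat segmentation, quality control, and beat averaging.

The envelope of a pulsatile CBFV recording is segmented into individual
cardiac beats, anomalous beats are rejected automatically, and the
surviving beats are aligned at their onsets and averaged into one
representative beat per recording.  All three steps are deterministic
(no randomness), so detect -> reject -> average is reproducible for a
fixed input.

Detection strategy (the acquisition literature prescribes none): the
envelope is detrended with a ~2 s moving average (high-pass around 0.5
Hz), systolic peaks are found by prominence relative to the signal
inter-quartile range with a refractory distance set by the maximum
plausible heart rate, and each beat onset is placed at the diastolic
minimum between consecutive peaks.  The raw minimum is refined forward
toward the systolic foot by a noise-scaled tolerance so that broad,
noisy diastolic troughs do not drag the onset backwards.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Mapping, Optional

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    IncompleteExamError,
    NoBeatsError,
    NoUsableBeatsError,
    ValidationError,
)
from .exams import AverageBeat, BilateralPair, EnvelopeRecording, Exam, HEMISPHERES

#: beats with ≥ this many accepted beats make a recording "complete"
DEFAULT_MIN_BEATS = 15


def _hanning_smooth(x: np.ndarray, n_taps: int) -> np.ndarray:
    """Smooth with a normalized raised-cosine kernel, reflecting at edges."""
    if n_taps < 3:
        return x.astype(float)
    kernel = np.hanning(n_taps + 2)[1:-1]
    kernel /= kernel.sum()
    half = n_taps // 2
    if half >= len(x):
        return x.astype(float)
    padded = np.pad(x, half, mode="reflect")
    return np.convolve(padded, kernel, mode="valid")


@dataclass(eq=False)
class BeatSegmentation:
    """Onset-delimited beats of one recording plus per-beat accept flags.

    Beat ``i`` spans samples ``[onsets[i], onsets[i+1])``; the partial
    segments before the first and after the last onset are edge beats and
    are discarded outright.
    """

    subject_id: str
    hemisphere: str
    depth_mm: float
    fs_hz: float
    signal: np.ndarray
    onsets: np.ndarray
    accepted: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if np.any(np.diff(self.onsets) <= 0):
            raise ValidationError("onsets must be strictly increasing")
        if len(self.accepted) != max(len(self.onsets) - 1, 0):
            raise ValidationError("accepted flags must be one per beat")

    @property
    def n_beats(self) -> int:
        return max(len(self.onsets) - 1, 0)

    @property
    def n_accepted(self) -> int:
        return int(self.accepted.sum())

    def raw_beats(self) -> List[np.ndarray]:
        return [
            self.signal[self.onsets[i]: self.onsets[i + 1]]
            for i in range(self.n_beats)
        ]

    def beats(self, length: Optional[int] = None) -> np.ndarray:
        """All beats resampled to a common length (median beat length)."""
        raw = self.raw_beats()
        if not raw:
            return np.empty((0, 0))
        if length is None:
            length = int(round(float(np.median([len(b) for b in raw]))))
        return np.vstack([_resample_linear(b, length) for b in raw])


def _resample_linear(beat: np.ndarray, length: int) -> np.ndarray:
    if len(beat) == length:
        return np.asarray(beat, dtype=float)
    old = np.arange(len(beat), dtype=float)
    new = np.linspace(0.0, len(beat) - 1.0, length)
    return np.interp(new, old, beat)


def _refine_onsets(
    v_sm: np.ndarray,
    onsets: np.ndarray,
    back: int = 10,
    max_shift: int = 8,
) -> np.ndarray:
    """Second-pass onset refinement against a median beat template.

    Sample noise makes the argmin of a single beat wander across the flat
    pre-systolic foot.  A median template over all first-pass beats beats
    the noise down, so its internal minimum can be located precisely; each
    beat is then re-anchored to the template by cross-correlation over the
    steep systolic upstroke, which is far better conditioned than a
    pointwise minimum.
    """
    if len(onsets) < 3:
        return onsets
    period = int(np.median(np.diff(onsets)))
    window = max(int(round(0.9 * period)), 8)

    snippets = []
    for o in onsets:
        lo = o - back
        if lo < 0 or lo + window > len(v_sm):
            continue
        snippets.append(v_sm[lo: lo + window])
    if len(snippets) < 3:
        return onsets
    template = np.median(np.vstack(snippets), axis=0)
    t_norm = template - template.mean()
    # locate the foot on an extra-smoothed copy: the residual noise on the
    # median template still moves a pointwise argmin across the flat foot
    t_smooth = _hanning_smooth(template, 7)
    q = int(np.argmin(t_smooth[: min(2 * back + 5, window)]))

    refined = []
    for o in onsets:
        best_s, best_c = 0, -np.inf
        for s in range(-max_shift, max_shift + 1):
            lo = o - back + s
            if lo < 0 or lo + window > len(v_sm):
                continue
            seg = v_sm[lo: lo + window]
            c = float(np.dot(seg - seg.mean(), t_norm))
            if c > best_c:
                best_c, best_s = c, s
        refined.append(o + best_s + (q - back))
    refined = np.unique(np.asarray(refined, dtype=int))
    return refined[(refined >= 0) & (refined < len(v_sm))]


def detect_beats(
    rec: EnvelopeRecording,
    min_hr_bpm: float = 35.0,
    max_hr_bpm: float = 180.0,
    noise_floor_cms: float = 1.0,
) -> BeatSegmentation:
    """Segment a recording into beats at diastolic-minimum onsets.

    Raises :class:`NoBeatsError` when the envelope shows no pulsatility
    above ``noise_floor_cms``.  Beats whose duration falls outside the
    plausible heart-rate window are flagged as not accepted (they are
    typically spans bridging a signal dropout).
    """
    if rec.duration_s < 2.0:
        raise ValidationError("recording shorter than 2 s")
    v = rec.velocity.astype(float)
    fs = rec.fs_hz

    # detrend: remove slow drift (~0.5 Hz cutoff via 2 s moving average)
    win = max(int(round(2.0 * fs)), 3)
    kernel = np.ones(win) / win
    trend = np.convolve(np.pad(v, win // 2, mode="reflect"), kernel, mode="valid")[: len(v)]
    detrended = v - trend

    smooth = _hanning_smooth(detrended, 9)
    if np.ptp(smooth) < noise_floor_cms:
        raise NoBeatsError("no detectable pulsatility above the noise floor")

    iqr = float(np.subtract(*np.percentile(smooth, [75, 25])))
    min_dist = max(int(round(60.0 / max_hr_bpm * fs)), 1)
    max_dist = int(round(60.0 / min_hr_bpm * fs))

    # estimate the beat period by autocorrelation so that secondary humps
    # (reflected/dicrotic waves) inside one beat are not counted as beats
    ac = np.correlate(smooth, smooth, mode="full")[len(smooth) - 1:]
    lag_lo = min(min_dist, len(ac) - 1)
    lag_hi = min(max_dist + 1, len(ac))
    if lag_hi > lag_lo:
        best = lag_lo + int(np.argmax(ac[lag_lo:lag_hi]))
        period = best
        # the argmax may land on a multiple of the beat period; prefer the
        # smallest subdivision that still correlates strongly
        for k in (4, 3, 2):
            cand = int(round(best / k))
            if cand < lag_lo:
                continue
            lo, hi = max(cand - 3, lag_lo), min(cand + 4, lag_hi)
            if ac[lo:hi].max() > 0.5 * ac[best]:
                period = lo + int(np.argmax(ac[lo:hi]))
                break
    else:
        period = min_dist
    dist = max(min_dist, int(round(0.7 * period)))

    peaks, _ = find_peaks(smooth, prominence=0.25 * iqr, distance=dist)
    if len(peaks) < 2:
        raise NoBeatsError("fewer than two systolic peaks detected")

    # onset localization on a lightly smoothed copy of the raw envelope
    v_sm = _hanning_smooth(v, 9)
    resid = v - v_sm
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    delta = 0.5 * sigma

    onsets = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        seg = v_sm[p0:p1]
        m = p0 + int(np.argmin(seg))
        # walk forward to the systolic foot: last sample still within the
        # noise tolerance of the minimum (counteracts backward wander of
        # the argmin over shallow diastolic slopes)
        j = m
        floor = v_sm[m] + delta
        while j + 1 < p1 and v_sm[j + 1] <= floor:
            j += 1
        onsets.append(j)
    onsets = np.unique(np.asarray(onsets, dtype=int))
    onsets = _refine_onsets(v_sm, onsets)

    durations = np.diff(onsets) / fs
    lo, hi = 60.0 / max_hr_bpm, 60.0 / min_hr_bpm
    slack = 1.0 / fs
    accepted = (durations >= lo - slack) & (durations <= hi + slack)

    return BeatSegmentation(
        subject_id=rec.subject_id,
        hemisphere=rec.hemisphere,
        depth_mm=rec.depth_mm,
        fs_hz=fs,
        signal=v,
        onsets=onsets,
        accepted=accepted,
    )


def reject_outlier_beats(
    seg: BeatSegmentation,
    corr_min: float = 0.9,
    amp_dev_max: float = 3.0,
) -> BeatSegmentation:
    """Reject beats lacking pulsatile structure or deviating from the group.

    A beat is rejected iff its Pearson correlation with the mean of all
    *other* beats (resampled to a common length) falls below ``corr_min``,
    or its mean velocity deviates from the median beat mean by more than
    ``amp_dev_max`` robust standard deviations (1.4826 * MAD).
    """
    if seg.n_beats < 3:
        raise ValidationError("outlier rejection requires at least 3 detected beats")

    mat = seg.beats()
    means = mat.mean(axis=1)
    active = np.flatnonzero(seg.accepted)
    if len(active) == 0:
        raise NoUsableBeatsError("no beats left to screen")

    sub = mat[active]
    sub_means = means[active]
    total = sub.sum(axis=0)
    med = float(np.median(sub_means))
    mad = float(np.median(np.abs(sub_means - med)))
    robust_sd = 1.4826 * mad
    # guard against a zero spread (identical beats): never reject on amplitude
    floor = max(1e-12, 1e-9 * max(1.0, abs(med)))
    robust_sd = max(robust_sd, floor)

    accepted = seg.accepted.copy()
    for row, i in enumerate(active):
        others_mean = (total - sub[row]) / max(len(active) - 1, 1)
        b, o = sub[row], others_mean
        sb, so = b.std(), o.std()
        corr = 0.0 if sb == 0 or so == 0 else float(np.corrcoef(b, o)[0, 1])
        amp_dev = abs(sub_means[row] - med) / robust_sd
        if corr < corr_min or amp_dev > amp_dev_max:
            accepted[i] = False

    if not accepted.any():
        raise NoUsableBeatsError("all beats rejected by quality control")
    return replace(seg, accepted=accepted)


def average_beats(seg: BeatSegmentation) -> AverageBeat:
    """Average the accepted beats into one representative beat.

    Accepted beats are resampled (linear interpolation) to the median
    accepted beat length, aligned at onset, and averaged pointwise.
    """
    raw = [b for b, ok in zip(seg.raw_beats(), seg.accepted) if ok]
    if not raw:
        raise NoUsableBeatsError("cannot average zero accepted beats")
    length = int(round(float(np.median([len(b) for b in raw]))))
    stack = np.vstack([_resample_linear(b, length) for b in raw])
    x = stack.mean(axis=0)
    return AverageBeat(
        subject_id=seg.subject_id,
        hemisphere=seg.hemisphere,
        depth_mm=seg.depth_mm,
        fs_hz=seg.fs_hz,
        x=x,
        n_beats_used=len(raw),
    )


def select_bilateral_pair(
    exam: Exam, beats_by_recording: Mapping[EnvelopeRecording, AverageBeat]
) -> BilateralPair:
    """Pick, per hemisphere, the average beat with maximal mean velocity.

    Doppler velocity scales with the cosine of the beam-vessel angle, so
    the highest-velocity depth is taken as closest to truth.  Ties break
    toward the shallower depth, then toward earlier recording order.
    """
    chosen = {}
    for hemi in HEMISPHERES:
        best = None
        for rec in exam.recordings:
            if rec.hemisphere != hemi or rec not in beats_by_recording:
                continue
            beat = beats_by_recording[rec]
            if best is None:
                best = beat
                continue
            if beat.mean_velocity > best.mean_velocity or (
                beat.mean_velocity == best.mean_velocity
                and beat.depth_mm < best.depth_mm
            ):
                best = beat
        if best is None:
            raise IncompleteExamError(
                f"subject {exam.subject_id}: no usable {hemi} recording"
            )
        chosen[hemi] = best
    return BilateralPair(
        subject_id=exam.subject_id, left=chosen["left"], right=chosen["right"]
    )
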