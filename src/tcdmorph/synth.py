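"""Seeded synthetic TCD exam and feature-cohort generators.

No clinical waveform data are distributed with the package, so every
other module is exercised against this generator.  It emulates the
statistical structure of a bilateral MCA examination cohort:

* pulsatile CBFV beat trains (systolic peak, reflected wave, dicrotic
  wave on a diastolic floor), >= 15 beats per 30 s recording;
* multiple insonation depths per hemisphere with a cosine-of-angle
  amplitude factor peaking at a subject-specific optimal depth;
* beat-period and amplitude jitter, additive Gaussian noise, occasional
  corrupted (flat dropout) beats;
* occlusion morphology: LVO subjects get one ipsilateral hemisphere with
  a blunted, low-curvature systolic complex and a reduced velocity
  scale, calibrated so that group mean VAI lands near 0.65 (vs ~0.89
  for controls) and group VCI separates in the ~2.7 vs ~5 range;
* group heart rates: LVO 87.9 +/- 22.2 bpm, controls 71.2 +/- 11 bpm.

The waveform model is a three-pulse additive surrogate, a calibrated
stand-in for physiological beats, not a hemodynamic simulation.  All
generation is reproducible from (spec, seed); per-subject substreams are
derived by counter so subjects are independent of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ValidationError
from .exams import DEPTH_MAX_MM, DEPTH_MIN_MM, EnvelopeRecording, Exam, IHC, LVO
from .features import FeatureRow


# ---------------------------------------------------------------------------
# beat morphology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeatMorphology:
    """Three-pulse additive beat model, phases in fractions of the period.

    Each pulse is a two-sided Gaussian with separate rise and fall widths;
    the slow falling tail of the last (dicrotic) pulse doubles as the
    diastolic runoff.
    """

    v_dia: float
    amps: Tuple[float, float, float]
    centers: Tuple[float, float, float]
    rise_widths: Tuple[float, float, float]
    fall_widths: Tuple[float, float, float]


#: sharp, richly structured beat typical of unobstructed MCA flow
NORMAL_MORPHOLOGY = BeatMorphology(
    v_dia=30.0,
    amps=(55.0, 22.0, 14.0),
    centers=(0.14, 0.32, 0.52),
    rise_widths=(0.030, 0.06, 0.035),
    fall_widths=(0.05, 0.09, 0.16),
)

#: blunted/dampened beat distal to an occlusion: wider, flatter systole
BLUNTED_MORPHOLOGY = BeatMorphology(
    v_dia=32.0,
    amps=(23.0, 10.0, 5.0),
    centers=(0.24, 0.44, 0.62),
    rise_widths=(0.10, 0.14, 0.10),
    fall_widths=(0.18, 0.20, 0.26),
)


def make_beat_template(morph: BeatMorphology, n_samples: int) -> np.ndarray:
    """Evaluate one beat of ``n_samples`` samples on phase [0, 1)."""
    if n_samples < 3:
        raise ValidationError("beat template needs at least 3 samples")
    phase = np.arange(n_samples) / n_samples
    v = np.full(n_samples, float(morph.v_dia))
    for a, c, wr, wf in zip(
        morph.amps, morph.centers, morph.rise_widths, morph.fall_widths
    ):
        w = np.where(phase < c, wr, wf)
        v += a * np.exp(-0.5 * ((phase - c) / w) ** 2)
    if np.any(v <= 0):
        raise ValidationError("morphology parameters yield non-positive velocity")
    return v


def _jitter_morphology(
    morph: BeatMorphology, rng: np.random.Generator, spread: float
) -> BeatMorphology:
    """Per-subject log-normal jitter of amplitudes and widths."""
    def jit(values, scale):
        return tuple(float(v * rng.lognormal(0.0, scale)) for v in values)

    return replace(
        morph,
        v_dia=float(morph.v_dia * rng.lognormal(0.0, spread / 2)),
        amps=jit(morph.amps, spread),
        rise_widths=jit(morph.rise_widths, spread),
        fall_widths=jit(morph.fall_widths, spread),
    )


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a synthetic waveform cohort."""

    n_lvo: int = 33
    n_ihc: int = 33
    fs_hz: float = 125.0
    duration_s: float = 30.0
    depths_mm: Tuple[float, ...] = (45.0, 50.0, 55.0, 60.0)
    hr_mean_lvo: float = 87.9
    hr_sd_lvo: float = 22.2
    hr_mean_ihc: float = 71.2
    hr_sd_ihc: float = 11.0
    hr_clip_bpm: Tuple[float, float] = (45.0, 140.0)
    mean_velocity_cms: float = 55.0
    #: ipsilateral/contralateral velocity ratio for LVO (targets VAI ~ 0.65)
    lvo_scale_mean: float = 0.65
    lvo_scale_sd: float = 0.12
    #: SD of the log hemispheric asymmetry for controls (targets VAI ~ 0.89)
    ihc_asym_sd: float = 0.12
    noise_sd_cms: float = 0.6
    period_jitter: float = 0.03
    amp_jitter: float = 0.04
    p_corrupt: float = 0.03
    morph_jitter: float = 0.10
    angle_scale_rad_per_mm: float = 0.04

    def __post_init__(self) -> None:
        if self.n_lvo < 0 or self.n_ihc < 0:
            raise ValidationError("group sizes must be non-negative")
        if not all(DEPTH_MIN_MM <= d <= DEPTH_MAX_MM for d in self.depths_mm):
            raise ValidationError("depths must lie within 30-70 mm")
        if self.fs_hz <= 0 or self.duration_s <= 0:
            raise ValidationError("fs_hz and duration_s must be positive")


# ---------------------------------------------------------------------------
# waveform generation
# ---------------------------------------------------------------------------

def _beat_train(
    morph: BeatMorphology,
    level: float,
    hr_bpm: float,
    n_total: int,
    fs_hz: float,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, List[int], List[Tuple[int, int]]]:
    """Concatenate jittered beats; returns (clean signal, onsets, corrupt spans).

    Each beat is normalized to mean ``level`` so that hemisphere velocity
    scales translate exactly into mean-velocity ratios.
    """
    base_period = 60.0 / hr_bpm * fs_hz
    pieces: List[np.ndarray] = []
    onsets: List[int] = []
    corrupt: List[Tuple[int, int]] = []
    t = 0
    while t < n_total:
        n_j = int(round(base_period * (1.0 + rng.normal(0.0, spec.period_jitter))))
        n_j = max(n_j, 5)
        amp_factor = 1.0 + rng.normal(0.0, spec.amp_jitter)
        is_corrupt = rng.random() < spec.p_corrupt
        if is_corrupt:
            beat = np.full(n_j, 0.5 * level)
            corrupt.append((t, min(t + n_j, n_total)))
        else:
            beat = make_beat_template(morph, n_j)
            beat = beat / beat.mean() * level * amp_factor
        onsets.append(t)
        pieces.append(beat)
        t += n_j
    clean = np.concatenate(pieces)[:n_total]
    return clean, onsets, corrupt


def _true_onsets(
    clean: np.ndarray, starts: Sequence[int], corrupt: Sequence[Tuple[int, int]]
) -> List[int]:
    """Ground-truth diastolic-minimum onsets for fully recorded clean beats."""
    n = len(clean)
    spans = list(corrupt)

    def in_corrupt(i: int) -> bool:
        return any(s - 2 <= i < e + 2 for s, e in spans)

    out = []
    for j, start in enumerate(starts):
        if start == 0 or start >= n:
            continue  # the very first beat has no preceding diastole
        end = starts[j + 1] if j + 1 < len(starts) else n
        if end > n or in_corrupt(start):
            continue
        lo, hi = max(start - 12, 0), min(start + 6, n)
        out.append(lo + int(np.argmin(clean[lo:hi])))
    return out


def generate_exam(
    subject_id: str,
    group: str,
    spec: CohortSpec,
    rng: np.random.Generator,
) -> Tuple[Exam, dict]:
    """One subject's exam (all hemispheres and depths) plus ground truth."""
    if group not in (LVO, IHC):
        raise ValidationError(f"group must be LVO or IHC, got {group!r}")
    n_total = int(round(spec.fs_hz * spec.duration_s))

    if group == LVO:
        hr_mean, hr_sd = spec.hr_mean_lvo, spec.hr_sd_lvo
    else:
        hr_mean, hr_sd = spec.hr_mean_ihc, spec.hr_sd_ihc
    hr = float(np.clip(rng.normal(hr_mean, hr_sd), *spec.hr_clip_bpm))

    # hemispheric velocity scales: controls get a mild random asymmetry,
    # LVO subjects a reduced ipsilateral scale targeting the group VAI
    ipsilateral: Optional[str] = None
    if group == LVO:
        ipsilateral = "left" if rng.random() < 0.5 else "right"
        s = float(np.clip(rng.normal(spec.lvo_scale_mean, spec.lvo_scale_sd),
                          2 * spec.lvo_scale_mean - 0.98, 0.98))
        scales = {h: (s if h == ipsilateral else 1.0) for h in ("left", "right")}
    else:
        delta = rng.normal(0.0, spec.ihc_asym_sd)
        scales = {"left": float(np.exp(delta / 2)), "right": float(np.exp(-delta / 2))}

    global_factor = float(rng.lognormal(0.0, 0.08))
    d_opt = float(rng.uniform(45.0, 60.0))  # shared across hemispheres

    morphs = {}
    for hemi in ("left", "right"):
        base = BLUNTED_MORPHOLOGY if hemi == ipsilateral else NORMAL_MORPHOLOGY
        morphs[hemi] = _jitter_morphology(base, rng, spec.morph_jitter)

    exam = Exam(subject_id=subject_id, label=group)
    truth: dict = {
        "group": group,
        "ipsilateral": ipsilateral,
        "hr_bpm": hr,
        "scales": scales,
        "d_opt_mm": d_opt,
        "recordings": {},
    }
    for hemi in ("left", "right"):
        for depth in spec.depths_mm:
            factor = float(
                np.cos(spec.angle_scale_rad_per_mm * (depth - d_opt))
            )
            level = spec.mean_velocity_cms * scales[hemi] * factor * global_factor
            clean, starts, corrupt = _beat_train(
                morphs[hemi], level, hr, n_total, spec.fs_hz, spec, rng
            )
            noisy = clean + rng.normal(0.0, spec.noise_sd_cms, size=n_total) \
                if spec.noise_sd_cms > 0 else clean
            exam.recordings.append(
                EnvelopeRecording(
                    subject_id=subject_id,
                    hemisphere=hemi,
                    depth_mm=depth,
                    fs_hz=spec.fs_hz,
                    velocity=noisy,
                )
            )
            truth["recordings"][f"{hemi}:{depth:g}"] = {
                "onsets": _true_onsets(clean, starts, corrupt),
                "corrupt_spans": [list(span) for span in corrupt],
                "level_cms": level,
            }
    return exam, truth


def generate_cohort(spec: CohortSpec, seed: int) -> Tuple[List[Exam], dict]:
    """A full seeded cohort; subject substreams are counter-derived."""
    exams: List[Exam] = []
    truth: dict = {"seed": int(seed), "subjects": {}}
    groups = [(LVO, i) for i in range(spec.n_lvo)] + [
        (IHC, i) for i in range(spec.n_ihc)
    ]
    for counter, (group, i) in enumerate(groups):
        subject_id = f"{group.lower()}{i + 1:03d}"
        rng = np.random.default_rng([seed, counter])
        exam, sub_truth = generate_exam(subject_id, group, spec, rng)
        exams.append(exam)
        truth["subjects"][subject_id] = sub_truth
    return exams, truth


# ---------------------------------------------------------------------------
# direct feature-cohort generation (bypassing waveforms)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureCohortSpec:
    """Truncated-normal (VCI, VAI) group distributions with a Gaussian copula.

    Default means match the clinical group means (VCI 2.66 vs 4.95, VAI
    0.65 vs 0.89); default SDs are inferred from the published bootstrap
    CIs of those means.
    """

    n_lvo: int = 33
    n_ihc: int = 33
    vci_mean_lvo: float = 2.66
    vci_sd_lvo: float = 0.85
    vci_mean_ihc: float = 4.95
    vci_sd_ihc: float = 1.16
    vai_mean_lvo: float = 0.65
    vai_sd_lvo: float = 0.205
    vai_mean_ihc: float = 0.89
    vai_sd_ihc: float = 0.088
    correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lvo < 0 or self.n_ihc < 0:
            raise ValidationError("group sizes must be non-negative")
        for sd in (self.vci_sd_lvo, self.vci_sd_ihc, self.vai_sd_lvo, self.vai_sd_ihc):
            if sd <= 0:
                raise ValidationError("feature SDs must be positive")
        if not -1.0 < self.correlation < 1.0:
            raise ValidationError("correlation must lie in (-1, 1)")


def _truncnorm_from_normal(z, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = stats.norm.cdf(z)
    return stats.truncnorm.ppf(np.clip(u, 1e-12, 1 - 1e-12), a, b, loc=mean, scale=sd)


def generate_feature_cohort(spec: FeatureCohortSpec) -> List[FeatureRow]:
    """Draw (VCI, VAI, label) rows directly from the group distributions."""
    rng = np.random.default_rng(spec.seed)
    cov = np.array([[1.0, spec.correlation], [spec.correlation, 1.0]])
    rows: List[FeatureRow] = []
    for group, n in ((LVO, spec.n_lvo), (IHC, spec.n_ihc)):
        if n == 0:
            continue
        z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        if group == LVO:
            vci = _truncnorm_from_normal(z[:, 0], spec.vci_mean_lvo, spec.vci_sd_lvo, 0.0, np.inf)
            vai = _truncnorm_from_normal(z[:, 1], spec.vai_mean_lvo, spec.vai_sd_lvo, 0.0, 1.0)
        else:
            vci = _truncnorm_from_normal(z[:, 0], spec.vci_mean_ihc, spec.vci_sd_ihc, 0.0, np.inf)
            vai = _truncnorm_from_normal(z[:, 1], spec.vai_mean_ihc, spec.vai_sd_ihc, 0.0, 1.0)
        for i in range(n):
            rows.append(
                FeatureRow(
                    subject_id=f"{group.lower()}{i + 1:03d}",
                    vci=float(vci[i]),
                    vai=float(vai[i]),
                    label=group,
                )
            )
    return rows
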