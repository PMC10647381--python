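"""Synthetic RR-interval cohorts with known age/gender/condition structure.

Every subject gets SDNN and RMSSD targets from the linear age-dependency
functions of the corresponding condition —

* healthy:     SDNN = 60.62 - 0.49*age,  RMSSD = 42.19 - 0.32*age
* arrhythmia:  SDNN = 44.30 - 0.13*age,  RMSSD = 37.71 - 0.046*age

— plus an additive gender offset on SDNN (default -2 ms for women) and a
seeded between-subject Gaussian perturbation. The RR stream itself is a
stationary Gaussian AR(1) process moment-matched to the targets: with
marginal sd sigma = SDNN and lag-1 autocorrelation rho, the expected
squared successive difference is 2*sigma^2*(1-rho), so

    rho = 1 - RMSSD^2 / (2 * SDNN^2),

valid whenever RMSSD < 2*SDNN. Ectopic beats (V/S with a premature beat +
compensatory pause that preserves local time), artifact gaps (beats
removed, X boundary markers inserted) and AFIB-like segments (rho set to 0
with inflated variance) can be injected on top. Everything is a pure
function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .io_formats import BeatAnnotation, Subject, write_annotations, write_cohort

#: (intercept_ms, slope_ms_per_year) of the mean-SDNN / mean-RMSSD
#: age-dependency functions per condition.
DEPENDENCY_COEFFS = {
    ("healthy", "sdnn"): (60.62, -0.49),
    ("healthy", "rmssd"): (42.19, -0.32),
    ("arrhythmia", "sdnn"): (44.30, -0.13),
    ("arrhythmia", "rmssd"): (37.71, -0.046),
}

RR_CLIP_MS = (300.0, 2000.0)
TARGET_FLOOR_MS = 3.0


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation parameters (defaults emulate the study cohorts:
    mixed-age adult Holter populations with ~800 ms mean RR)."""

    n_subjects: int = 200
    age_range: tuple[float, float] = (20.0, 80.0)
    gender_balance: float = 0.5        # fraction female
    condition_mix: float = 0.0         # fraction arrhythmia
    gluco_mix: tuple[float, float, float] = (1.0, 0.0, 0.0)  # ND, GD, BD
    mean_rr_ms: float = 800.0
    gender_offset_ms: float = -2.0     # added to SDNN target for women
    noise_sd_ms: float = 5.0           # between-subject target spread
    ectopic_rate: float = 0.0
    artifact_rate: float = 0.0         # expected artifact spans per hour
    record_min: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not 0 <= self.ectopic_rate < 1:
            raise ValueError("ectopic_rate must be in [0, 1)")
        if abs(sum(self.gluco_mix) - 1.0) > 1e-9:
            raise ValueError("gluco_mix must sum to 1")


@dataclass(frozen=True)
class SubjectTargets:
    sdnn_target: float
    rmssd_target: float
    rho: float


def ar1_rho(sdnn: float, rmssd: float) -> float:
    """Lag-1 autocorrelation that moment-matches SDNN and RMSSD targets."""
    if sdnn <= 0 or rmssd <= 0:
        raise ValueError("targets must be positive")
    if rmssd**2 >= 4 * sdnn**2:
        raise ValueError("need rmssd < 2*sdnn for a valid AR(1) rho")
    return 1.0 - rmssd**2 / (2.0 * sdnn**2)


def target_hrv(
    subject: Subject, cfg: SynthConfig, rng: np.random.Generator | None = None
) -> SubjectTargets:
    """Draw a subject's SDNN/RMSSD targets from its dependency functions.

    BD-class subjects draw from the arrhythmia-style (shallow-slope)
    functions regardless of their nominal condition: in this synthetic
    world bad glucose regulation flattens the age trend, mirroring the
    degraded autonomic profile the analysis is meant to detect.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    condition = (
        "arrhythmia" if subject.gluco_class == "BD" else subject.condition
    )
    base_sdnn = _linear(condition, "sdnn", subject.age)
    base_rmssd = _linear(condition, "rmssd", subject.age)
    if subject.gender == "F":
        base_sdnn += cfg.gender_offset_ms
    for _ in range(100):
        s = base_sdnn + rng.normal(0.0, cfg.noise_sd_ms)
        r = base_rmssd + rng.normal(0.0, cfg.noise_sd_ms)
        s = max(s, TARGET_FLOOR_MS)
        r = max(r, TARGET_FLOOR_MS)
        if r**2 < 4 * s**2:
            return SubjectTargets(s, r, ar1_rho(s, r))
    raise ValueError("could not draw valid targets (rmssd < 2*sdnn)")


def _linear(condition: str, param: str, age: float) -> float:
    intercept, slope = DEPENDENCY_COEFFS[(condition, param)]
    return intercept + slope * age


def gen_rr(
    targets: SubjectTargets,
    duration_min: float,
    cfg: SynthConfig = SynthConfig(),
    seed: int | None = None,
) -> list[BeatAnnotation]:
    """Generate an N-labeled annotation stream from a stationary AR(1)
    RR process with the subject's target moments."""
    if duration_min < 1:
        raise ValueError("duration must be at least 1 minute")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    mu, sigma, rho = cfg.mean_rr_ms, targets.sdnn_target, targets.rho
    duration_ms = duration_min * 60_000.0
    # generous upper bound on beat count, then trim to duration
    n_est = int(duration_ms / max(mu - 4 * sigma, RR_CLIP_MS[0])) + 16
    innov_sd = sigma * np.sqrt(max(0.0, 1.0 - rho**2))
    x0 = rng.normal(0.0, sigma)
    e = rng.normal(0.0, innov_sd, size=n_est - 1)
    rest, _ = lfilter([1.0], [1.0, -rho], e, zi=np.array([rho * x0]))
    x = np.concatenate([[x0], rest])
    rr = np.clip(mu + x, *RR_CLIP_MS)
    t = np.concatenate([[0.0], np.cumsum(rr)])
    # keep the first beat at/after the duration so the stream spans it fully
    cut = int(np.searchsorted(t, duration_ms)) + 1
    return [BeatAnnotation(float(ti), "N") for ti in t[:cut]]


def inject_ectopics(
    stream: Sequence[BeatAnnotation], ectopic_rate: float, seed: int
) -> list[BeatAnnotation]:
    """Relabel interior beats V/S at the given rate, shifting each ectopic
    30% early with a compensatory pause (two-interval sum preserved)."""
    if not 0 <= ectopic_rate < 1:
        raise ValueError("ectopic_rate must be in [0, 1)")
    beats = list(stream)
    if ectopic_rate == 0 or len(beats) < 3:
        return beats
    rng = np.random.default_rng(seed)
    out = beats.copy()
    hit = rng.random(len(beats)) < ectopic_rate
    kinds = rng.random(len(beats)) < 0.5
    last_ectopic = -2
    for i in range(1, len(beats) - 1):
        # adjacent hits are skipped so each premature shift + compensatory
        # pause stays local (two-interval sum preserved around every ectopic)
        if not hit[i] or i - 1 == last_ectopic:
            continue
        prev_rr = beats[i].time_ms - beats[i - 1].time_ms
        out[i] = BeatAnnotation(
            beats[i].time_ms - 0.3 * prev_rr, "V" if kinds[i] else "S"
        )
        last_ectopic = i
    return out


def inject_artifacts(
    stream: Sequence[BeatAnnotation],
    artifact_rate: float,
    seed: int,
    span_s: tuple[float, float] = (5.0, 30.0),
) -> list[BeatAnnotation]:
    """Remove beats inside Poisson-placed artifact spans and mark the span
    edges with X pseudo-beats."""
    if artifact_rate < 0:
        raise ValueError("artifact_rate must be non-negative")
    beats = list(stream)
    if artifact_rate == 0 or len(beats) < 2:
        return beats
    rng = np.random.default_rng(seed)
    total_ms = beats[-1].time_ms - beats[0].time_ms
    n_spans = rng.poisson(artifact_rate * total_ms / 3_600_000.0)
    spans = []
    for _ in range(n_spans):
        length = rng.uniform(*span_s) * 1000.0
        start = beats[0].time_ms + rng.uniform(0.0, max(total_ms - length, 0.0))
        spans.append((start, start + length))
    return apply_artifact_spans(beats, spans)


def apply_artifact_spans(
    stream: Sequence[BeatAnnotation], spans: Sequence[tuple[float, float]]
) -> list[BeatAnnotation]:
    """Deterministic core of artifact injection: beats inside any [lo, hi]
    span are dropped and X markers inserted at the span edges."""
    events: list[BeatAnnotation] = []
    spans = sorted(spans)
    for b in stream:
        if any(lo <= b.time_ms <= hi for lo, hi in spans):
            continue
        events.append(b)
    for lo, hi in spans:
        events.append(BeatAnnotation(lo, "X"))
        events.append(BeatAnnotation(hi, "X"))
    events.sort(key=lambda b: b.time_ms)
    # drop exact-time duplicates that can arise from touching spans
    deduped = [events[0]] if events else []
    for b in events[1:]:
        if b.time_ms > deduped[-1].time_ms:
            deduped.append(b)
    return deduped


def sample_cohort(
    cfg: SynthConfig,
    out_dir: str | Path | None = None,
    balanced: bool = False,
) -> tuple[list[Subject], dict[str, list[BeatAnnotation]]]:
    """Draw a cohort and one annotation stream per subject.

    With ``balanced=True`` the cohort enumerates age-group x gender cells
    round-robin instead of sampling them (n_subjects=12 gives exactly one
    subject per cell). When ``out_dir`` is given, per-subject annotation
    CSVs and a ``subjects.csv`` manifest are written there.
    """
    rng = np.random.default_rng(cfg.seed)
    subjects: list[Subject] = []
    streams: dict[str, list[BeatAnnotation]] = {}
    hba1c_means = {"ND": 5.4, "GD": 6.8, "BD": 9.0}
    group_edges = [(20, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 80)]
    for i in range(cfg.n_subjects):
        if balanced:
            cell = i % 12
            lo, hi = group_edges[cell // 2]
            age = rng.uniform(max(lo, cfg.age_range[0]), min(hi, cfg.age_range[1]))
            gender = "M" if cell % 2 == 0 else "F"
        else:
            age = rng.uniform(*cfg.age_range)
            gender = "F" if rng.random() < cfg.gender_balance else "M"
        condition = "arrhythmia" if rng.random() < cfg.condition_mix else "healthy"
        gluco = str(rng.choice(["ND", "GD", "BD"], p=cfg.gluco_mix))
        hba1c = float(
            np.clip(rng.normal(hba1c_means[gluco], 0.4), 4.0, 15.0)
        )
        subject = Subject(
            subject_id=f"S{i:04d}", age=float(age), gender=gender,
            condition=condition, gluco_class=gluco, hba1c=hba1c,
        )
        targets = target_hrv(subject, cfg, rng)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        stream = gen_rr(targets, cfg.record_min, cfg, seed=sub_seed)
        if cfg.ectopic_rate > 0:
            stream = inject_ectopics(stream, cfg.ectopic_rate, sub_seed + 1)
        if cfg.artifact_rate > 0:
            stream = inject_artifacts(stream, cfg.artifact_rate, sub_seed + 2)
        subjects.append(subject)
        streams[subject.subject_id] = stream
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(subjects, out_dir / "subjects.csv")
        for sid, stream in streams.items():
            write_annotations(stream, out_dir / f"{sid}.csv")
    return subjects, streams
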