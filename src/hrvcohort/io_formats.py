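"""Beat-annotation, RR-series and cohort-table I/O.

The canonical internal time unit is milliseconds. Two annotation dialects
are supported:

* ``csv`` — the package's own plain-text fixture format, a two-column table
  ``time_ms,label``.
* ``wfdb`` — PhysioNet MIT-format annotation files (``.atr``/``.ecg``...),
  read by a small built-in parser; sample indices are converted to
  milliseconds using the sampling frequency from the companion ``.hea``
  header.

Beat labels follow the AAMI classes N (normal), A (atrial), V
(ventricular), S (supraventricular), F (fusion), Q (unclassifiable or
paced), plus the package's own X pseudo-label marking the boundary of a
detected-artifact span: any interval touching an X marker is never treated
as an NN interval.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_LABELS = frozenset("NAVSFQX")

#: MIT annotation type codes -> AAMI class used by this package.
#: Normal-conducted beats (incl. bundle-branch block and escape beats) map
#: to N; atrial premature/aberrated to A; supraventricular premature and
#: nodal to S; ventricular ectopy to V; fusion to F; paced/unknown to Q;
#: the noise marker '~' to the artifact pseudo-label X.
MIT_CODE_TO_LABEL = {
    1: "N",   # normal
    2: "N",   # LBBB
    3: "N",   # RBBB
    11: "N",  # nodal escape -> conducted, kept N
    34: "N",  # atrial escape
    4: "A",   # aberrated atrial premature
    8: "A",   # atrial premature
    7: "S",   # nodal (junctional) premature
    9: "S",   # supraventricular premature
    5: "V",   # premature ventricular contraction
    10: "V",  # ventricular escape
    41: "V",  # R-on-T PVC
    6: "F",   # fusion of ventricular and normal
    38: "Q",  # fusion of paced and normal
    12: "Q",  # paced
    13: "Q",  # unclassifiable
    14: "X",  # signal quality change / noise
}


class AnnotationError(ValueError):
    """Raised for malformed or non-conforming annotation inputs."""


@dataclass(frozen=True)
class BeatAnnotation:
    """A single annotated beat: time from record start (ms) and AAMI label."""

    time_ms: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise AnnotationError(f"unknown beat label {self.label!r}")
        if self.time_ms < 0:
            raise AnnotationError(f"negative beat time {self.time_ms}")


@dataclass(frozen=True)
class RRInterval:
    """One inter-beat interval with the labels of both endpoint beats."""

    rr_ms: float
    start_label: str
    end_label: str
    onset_ms: float  # time of the starting beat


@dataclass
class RRSeries:
    """An ordered sequence of inter-beat intervals derived from annotations."""

    intervals: list[RRInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def span_ms(self) -> float:
        if not self.intervals:
            return 0.0
        last = self.intervals[-1]
        return last.onset_ms + last.rr_ms - self.intervals[0].onset_ms


@dataclass(frozen=True)
class Subject:
    """Cohort member: demographics, cardiac condition and glucose class."""

    subject_id: str
    age: float
    gender: str  # "M" or "F"
    condition: str  # "healthy" or "arrhythmia"
    gluco_class: str = "unknown"  # ND / GD / BD / unknown
    hba1c: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.age < 130:
            raise ValueError(f"age {self.age} outside (0, 130)")
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be M or F, got {self.gender!r}")
        if self.condition not in ("healthy", "arrhythmia"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.gluco_class not in ("ND", "GD", "BD", "unknown"):
            raise ValueError(f"unknown gluco class {self.gluco_class!r}")
        if self.gluco_class == "unknown" and self.hba1c is not None:
            raise ValueError("gluco_class 'unknown' requires absent HbA1c")


def _check_monotone(times: Sequence[float]) -> None:
    for i in range(1, len(times)):
        if times[i] <= times[i - 1]:
            raise AnnotationError(
                f"beat times not strictly increasing at index {i} "
                f"({times[i - 1]} -> {times[i]})"
            )


def read_annotations(path: str | Path, dialect: str = "csv") -> list[BeatAnnotation]:
    """Read a beat-annotation stream, sorted by time, in milliseconds.

    Parameters
    ----------
    path
        Annotation file. For the ``wfdb`` dialect this is the binary
        annotation file (e.g. ``rec.atr``); the sampling frequency is taken
        from ``rec.hea`` next to it.
    dialect
        ``"csv"`` (columns ``time_ms,label``) or ``"wfdb"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        beats = _read_csv_annotations(path)
    elif dialect == "wfdb":
        beats = _read_wfdb_annotations(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_monotone([b.time_ms for b in beats])
    return beats


def _read_csv_annotations(path: Path) -> list[BeatAnnotation]:
    df = pd.read_csv(path, dtype={"label": str})
    missing = {"time_ms", "label"} - set(df.columns)
    if missing:
        raise AnnotationError(f"annotation csv missing columns {sorted(missing)}")
    return [
        BeatAnnotation(float(t), str(lab))
        for t, lab in zip(df["time_ms"], df["label"])
    ]


def _read_header_fs(header_path: Path) -> float:
    """Sampling frequency (Hz) from a WFDB .hea record line; defaults to 250."""
    if not header_path.exists():
        raise FileNotFoundError(
            f"WFDB header {header_path} required to convert samples to ms"
        )
    for line in header_path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        # record_name nsig [fs[/counter] [counter_base] [nsamples]]
        if len(fields) >= 3:
            return float(fields[2].split("/")[0])
        return 250.0
    raise AnnotationError(f"empty WFDB header {header_path}")


def _read_wfdb_annotations(path: Path) -> list[BeatAnnotation]:
    """Parse a MIT-format annotation file into millisecond beat annotations.

    The format is a stream of little-endian 16-bit words: the top 6 bits are
    the annotation type code, the low 10 bits the time increment in samples.
    Pseudo-codes SKIP(59), NUM(60), SUB(61), CHN(62) and AUX(63) are handled
    per the PhysioNet specification; a (0, 0) word terminates the stream.
    """
    fs = _read_header_fs(path.with_suffix(".hea"))
    data = path.read_bytes()
    beats: list[BeatAnnotation] = []
    t_samples = 0
    i = 0
    n = len(data)
    while i + 1 < n:
        word = struct.unpack_from("<H", data, i)[0]
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if code == 0 and delta == 0:  # end of annotations
            break
        if code == 59:  # SKIP: next 4 bytes are a long time increment
            if i + 3 >= n:
                raise AnnotationError("truncated SKIP annotation")
            high, low = struct.unpack_from("<HH", data, i)
            i += 4
            t_samples += (high << 16) | low
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers: ignored
            continue
        if code == 63:  # AUX: delta = byte count, padded to even
            i += delta + (delta & 1)
            continue
        t_samples += delta
        label = MIT_CODE_TO_LABEL.get(code)
        if label is None:
            raise AnnotationError(f"unknown MIT annotation code {code}")
        beats.append(BeatAnnotation(t_samples / fs * 1000.0, label))
    return beats


def annotations_to_rr(beats: Sequence[BeatAnnotation]) -> RRSeries:
    """Derive the inter-beat interval series from an annotation stream.

    Each of the n-1 intervals carries the labels of both endpoint beats, so
    downstream cleaning can reject intervals adjacent to ectopic beats or
    artifact markers without revisiting the annotations.
    """
    if len(beats) < 2:
        raise AnnotationError("need at least 2 beats to form an RR series")
    _check_monotone([b.time_ms for b in beats])
    intervals = [
        RRInterval(
            rr_ms=b1.time_ms - b0.time_ms,
            start_label=b0.label,
            end_label=b1.label,
            onset_ms=b0.time_ms,
        )
        for b0, b1 in zip(beats[:-1], beats[1:])
    ]
    return RRSeries(intervals)


def write_annotations(beats: Iterable[BeatAnnotation], path: str | Path) -> None:
    """Write beats in the package csv dialect (``time_ms,label``)."""
    df = pd.DataFrame(
        {"time_ms": [b.time_ms for b in beats], "label": [b.label for b in beats]}
    )
    df.to_csv(path, index=False, float_format="%.12g")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as csv, reals at 12 significant digits."""
    records.to_csv(path, index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_cohort(path: str | Path) -> list[Subject]:
    """Read a cohort metadata table (subject_id,age,gender,condition,...)."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    subjects = []
    for row in df.itertuples(index=False):
        hba1c = getattr(row, "hba1c", None)
        if hba1c is not None and pd.isna(hba1c):
            hba1c = None
        subjects.append(
            Subject(
                subject_id=str(row.subject_id),
                age=float(row.age),
                gender=str(row.gender),
                condition=str(row.condition),
                gluco_class=str(getattr(row, "gluco_class", "unknown")),
                hba1c=None if hba1c is None else float(hba1c),
            )
        )
    return subjects


def write_cohort(subjects: Iterable[Subject], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "gender": s.gender,
                "condition": s.condition,
                "gluco_class": s.gluco_class,
                "hba1c": s.hba1c,
            }
            for s in subjects
        ]
    )
    df.to_csv(path, index=False, float_format="%.12g")
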