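"""End-to-end convenience pipeline: cohort streams -> per-subject HRV ->
dependency fits. Thin glue over the stage modules; every step is also
usable on its own."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cohort_stats import DependencyFit, fit_dependency, subject_mean_hrv
from .hrv_params import WindowSpec, windowed_hrv
from .io_formats import BeatAnnotation, Subject, annotations_to_rr
from .nn_cleaning import CleaningConfig, screen_recording


def cohort_hrv_table(
    subjects: Sequence[Subject],
    streams: dict[str, list[BeatAnnotation]],
    spec: WindowSpec = WindowSpec(30),
    cfg: CleaningConfig = CleaningConfig(),
    methods: Sequence[str] = ("A", "C"),
    parameters: Sequence[str] = ("sdnn", "rmssd"),
    afib: dict[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-subject mean windowed HRV joined with demographics.

    Recordings failing the AFIB/pause screen are dropped. Output columns:
    subject demographics plus ``A_SDNN``, ``A_rMSSD``, ... per requested
    method and parameter.
    """
    afib = afib or {}
    tables: dict[str, pd.DataFrame] = {}
    kept: list[Subject] = []
    for s in subjects:
        rr = annotations_to_rr(streams[s.subject_id])
        if not screen_recording(rr, afib.get(s.subject_id, False), cfg).accepted:
            continue
        tables[s.subject_id] = windowed_hrv(rr, spec, cfg, methods)
        kept.append(s)
    per_method = [
        subject_mean_hrv(tables, method=m, parameters=parameters)
        for m in methods
    ]
    hrv = per_method[0]
    for extra in per_method[1:]:
        hrv = hrv.merge(extra, on="subject_id")
    demo = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "age": s.age,
                "gender": s.gender,
                "condition": s.condition,
                "gluco_class": s.gluco_class,
                "hba1c": s.hba1c,
            }
            for s in kept
        ]
    )
    return demo.merge(hrv, on="subject_id")


def fit_cohort_dependency(
    cohort: pd.DataFrame, parameter: str = "A_SDNN"
) -> DependencyFit:
    """OLS age-dependency fit of one per-subject HRV column."""
    sub = cohort.dropna(subset=[parameter])
    return fit_dependency(sub["age"], sub[parameter])
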