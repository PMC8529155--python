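"""Published cohort fixtures and their summary statistics.

Ships machine-readable transcriptions of the study cohort tables — patient
characteristics (17 patients: lesion, fiducial and plan counts per side)
and per-lesion margin results (42 lung lesions: optimal fiducial set,
per-axis ITV_tracking margin, GTV-to-marker distances) — and reproduces
the printed summary statistics from them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "load_patient_characteristics",
    "load_lesion_margins",
    "patient_records",
    "lesion_records",
    "summarize_margins",
    "summarize_cohort",
    "MarginSummary",
    "CohortSummary",
]

AXES = ("rl", "ap", "is")


def _data_path(name: str):
    return resources.files("fidmargin.data") / name


def load_patient_characteristics() -> pd.DataFrame:
    """Per-patient GTV / fiducial / plan counts (17 rows)."""
    return pd.read_csv(_data_path("patient_characteristics.csv"))


def load_lesion_margins() -> pd.DataFrame:
    """Per-lesion optimal fiducial set, margins and distances (42 rows).

    ``optimal_fm_set`` and ``distances_mm`` hold ;-separated entries for
    two-marker sets.
    """
    df = pd.read_csv(_data_path("lesion_margins.csv"))
    df["optimal_fm_set"] = df["optimal_fm_set"].str.split(";")
    df["distances_mm"] = df["distances_mm"].apply(
        lambda s: [float(v) for v in str(s).split(";")])
    return df


@dataclass
class PatientRecord:
    patient_id: int
    gtv_counts: tuple   # (right, left, total)
    fm_counts: tuple    # (right, left, total)
    n_plans: int
    n_log_plans: int


@dataclass
class LesionRecord:
    patient_id: int
    side: str
    gtv_id: int
    optimal_fm_set: list
    margins_mm: np.ndarray   # (R-L, A-P, I-S)
    distances_mm: list


def patient_records() -> list[PatientRecord]:
    df = load_patient_characteristics()
    recs = []
    for _, r in df.iterrows():
        rec = PatientRecord(
            patient_id=int(r.patient_id),
            gtv_counts=(int(r.gtv_right), int(r.gtv_left), int(r.gtv_total)),
            fm_counts=(int(r.fm_right), int(r.fm_left), int(r.fm_total)),
            n_plans=int(r.n_plans),
            n_log_plans=int(r.n_log_plans),
        )
        if rec.gtv_counts[2] != rec.gtv_counts[0] + rec.gtv_counts[1]:
            raise ValueError(f"patient {rec.patient_id}: GTV totals mismatch")
        if rec.fm_counts[2] != rec.fm_counts[0] + rec.fm_counts[1]:
            raise ValueError(f"patient {rec.patient_id}: FM totals mismatch")
        recs.append(rec)
    return recs


def lesion_records() -> list[LesionRecord]:
    df = load_lesion_margins()
    return [
        LesionRecord(
            patient_id=int(r.patient_id),
            side=str(r.side),
            gtv_id=int(r.gtv_id),
            optimal_fm_set=list(r.optimal_fm_set),
            margins_mm=np.array([r.margin_rl_mm, r.margin_ap_mm,
                                 r.margin_is_mm]),
            distances_mm=list(r.distances_mm),
        )
        for _, r in df.iterrows()
    ]


@dataclass
class MarginSummary:
    n_lesions: int
    mean_mm: np.ndarray          # per axis, rounded to 1 decimal
    sd_mm: np.ndarray            # sample sd (n-1), rounded to 1 decimal
    n_within_threshold: int      # lesions with all margins < threshold
    threshold_mm: float
    distance_mean_mm: float      # mean over per-lesion mean distances
    distance_sd_mm: float
    sd_undefined: bool = False   # single-record input


@dataclass
class CohortSummary:
    n_patients: int
    total_gtvs: int
    total_fms: int
    fm_totals_by_side: tuple     # (right, left)
    gtv_totals_by_side: tuple
    median_fms_per_patient: float
    total_plans: int
    total_log_plans: int


def summarize_margins(records: list[LesionRecord],
                      threshold_mm: float = 5.0) -> MarginSummary:
    """Per-axis mean and sample SD of the margins, threshold count, and
    the GTV-to-marker distance summary.

    The distance summary first averages the listed distances within each
    lesion (a two-marker lesion contributes one value) and then takes the
    mean and sample SD across lesions, which is the aggregation that
    reproduces the published cohort summary.
    """
    if not records:
        raise ValueError("no lesion records")
    margins = np.stack([r.margins_mm for r in records])
    sd_undefined = len(records) < 2
    sd = (np.zeros(3) if sd_undefined
          else margins.std(axis=0, ddof=1))
    within = int(np.sum(np.all(margins < threshold_mm, axis=1)))
    dists = np.array([np.mean(r.distances_mm) for r in records])
    d_sd = 0.0 if dists.size < 2 else float(dists.std(ddof=1))
    return MarginSummary(
        n_lesions=len(records),
        mean_mm=np.round(margins.mean(axis=0), 1),
        sd_mm=np.round(sd, 1),
        n_within_threshold=within,
        threshold_mm=threshold_mm,
        distance_mean_mm=round(float(dists.mean()), 1),
        distance_sd_mm=round(d_sd, 1),
        sd_undefined=sd_undefined,
    )


def summarize_cohort(records: list[PatientRecord]) -> CohortSummary:
    """Column totals and the median fiducial count per patient."""
    if not records:
        raise ValueError("no patient records")
    fm_totals = [r.fm_counts[2] for r in records]
    return CohortSummary(
        n_patients=len(records),
        total_gtvs=sum(r.gtv_counts[2] for r in records),
        total_fms=sum(fm_totals),
        fm_totals_by_side=(sum(r.fm_counts[0] for r in records),
                           sum(r.fm_counts[1] for r in records)),
        gtv_totals_by_side=(sum(r.gtv_counts[0] for r in records),
                            sum(r.gtv_counts[1] for r in records)),
        median_fms_per_patient=float(np.median(fm_totals)),
        total_plans=sum(r.n_plans for r in records),
        total_log_plans=sum(r.n_log_plans for r in records),
    )
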