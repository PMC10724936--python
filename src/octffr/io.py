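"""Reading and writing the pipeline's delimited-text artifacts."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from octffr.profile import RadiiProfile
from octffr.synthetic import ClinicalRecord, LesionRecord


@dataclass
class LoadedCohort:
    """Cohort re-read from disk; duck-compatible with SyntheticCohort for
    feature assembly and labeling."""

    patients: list
    lesions: list
    profiles: dict

    def to_frame(self) -> pd.DataFrame:
        raise NotImplementedError("use the original cohort.csv")


def read_profile(csv_path, markers_path, lesion_id: str) -> RadiiProfile:
    table = pd.read_csv(csv_path)
    markers = json.loads(Path(markers_path).read_text())
    return RadiiProfile(
        lesion_id=lesion_id,
        radii=table["radius_mm"].to_numpy(dtype=float),
        frame_spacing=float(markers.get("frame_spacing", 0.2)),
        segment_start=int(markers["segment_start"]),
        segment_end=int(markers["segment_end"]),
        lesion_start=int(markers["lesion_start"]),
        lesion_end=int(markers["lesion_end"]),
    )


def read_cohort_dir(cohort_dir) -> tuple[LoadedCohort, pd.DataFrame]:
    """Load `cohort.csv` plus per-lesion profiles and marker sidecars."""
    cohort_dir = Path(cohort_dir)
    table = pd.read_csv(cohort_dir / "cohort.csv")
    patients = []
    for pid, rows in table.groupby("patient_id", sort=False):
        r = rows.iloc[0]
        patients.append(ClinicalRecord(
            patient_id=pid, sex=r["sex"], age=float(r["age"]),
            height=float(r["height"]), weight=float(r["weight"]),
            smoking=int(r["smoking"]), aht=int(r["aht"]),
            dyslipidemia=int(r["dyslipidemia"]), diabetes=int(r["diabetes"]),
            echo_ef=float(r["echo_ef"]),
            diastolic_pattern=int(r["diastolic_pattern"]),
            ivs=float(r["ivs"]), hb=float(r["hb"]), ht=float(r["ht"])))
    lesions, profiles = [], {}
    for r in table.itertuples(index=False):
        lid = r.lesion_id
        lesions.append(LesionRecord(
            lesion_id=lid, patient_id=r.patient_id, vessel=r.vessel,
            proximal_lad=int(r.proximal_lad), Pd=float(r.Pd), Pa=float(r.Pa),
            D=int(r.D), mld=float(r.mld)))
        profiles[lid] = read_profile(
            cohort_dir / "profiles" / f"{lid}.csv",
            cohort_dir / "profiles" / f"{lid}.markers.json", lid)
    return LoadedCohort(patients=patients, lesions=lesions,
                        profiles=profiles), table
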