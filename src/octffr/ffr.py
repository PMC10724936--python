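"""Drift-corrected FFR ground truth.

Fractional flow reserve is the ratio of the pressure distal to a stenosis
(Pd) over the aortic pressure (Pa) at maximal hyperemia.  After the
measurement the pressure wire is pulled back to the catheter tip and the
residual difference between the two transducers — the pressure drift D — is
recorded.  A drift of 2–3 mmHg is treated as relevant and added back to the
recorded distal pressure before computing FFR; drifts of 0–1 mmHg are left
uncorrected, and a drift beyond ±3 mmHg indicates the pressures should have
been re-equalized and the measurement repeated.

A lesion is labeled functionally significant (y = 1) when the corrected
FFR is at most 0.80; the clinically uncertain "gray zone" is the interval
[0.75, 0.85] (narrowed to [0.75, 0.83] for one subgroup analysis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

#: Drift magnitudes (mmHg) considered relevant enough to correct.
DEFAULT_DRIFT_RELEVANCE = frozenset({2, 3})

#: FFR cutoff below-or-equal which a lesion is functionally significant.
SIGNIFICANCE_CUTOFF = 0.80

#: Default gray-zone bounds (inclusive).
GRAY_ZONE = (0.75, 0.85)


@dataclass(frozen=True)
class PressureRecord:
    """Measured pressures for one lesion.

    Pd and Pa are the distal and aortic pressures (mmHg) at the start of
    the FFR investigation; D is the pressure drift (mmHg), the arithmetic
    difference between the drift-check aortic and distal pressures.
    """

    Pd: float
    Pa: float
    D: int = 0

    def __post_init__(self):
        if self.Pa <= 0 or self.Pd <= 0:
            raise ValueError("pressures must be positive")
        if abs(self.D) > 10:
            raise ValueError(f"drift {self.D} mmHg outside sanity bound ±10")
        if self.D != int(self.D):
            raise ValueError("drift must be an integer number of mmHg")


def correct_distal_pressure(Pd: float, D: int) -> float:
    """Drift-corrected distal pressure: Pd + D."""
    return Pd + D


def corrected_ffr(record: PressureRecord,
                  drift_relevance=DEFAULT_DRIFT_RELEVANCE) -> float:
    """Corrected FFR = corrected_Pd / Pa, applying drift correction only
    when |D| is in the relevance set (default {2, 3} mmHg).

    A drift beyond the largest relevant magnitude is flagged with a warning
    (clinical protocol would re-equalize and repeat) and left uncorrected,
    as is a negative drift.  A result above 1.0 is physiologically
    implausible and triggers a warning, but is returned unclamped.
    """
    if abs(record.D) > max(drift_relevance, default=3):
        warnings.warn(
            f"drift {record.D} mmHg exceeds the re-equalization bound; "
            "measurement should be repeated — no correction applied",
            stacklevel=2,
        )
        value = record.Pd / record.Pa
    elif abs(record.D) in drift_relevance:
        if record.D < 0:
            warnings.warn(
                f"negative drift {record.D} mmHg corrected with signed addition",
                stacklevel=2,
            )
        value = correct_distal_pressure(record.Pd, record.D) / record.Pa
    else:
        value = record.Pd / record.Pa
    if value > 1.0:
        warnings.warn(f"corrected FFR {value:.3f} exceeds 1.0", stacklevel=2)
    return value


def label_lesion(ffr: float) -> int:
    """Binary significance label: 1 if corrected FFR <= 0.80 else 0."""
    if not (0 < ffr < 1.2):
        raise ValueError(f"corrected FFR {ffr} outside plausible range (0, 1.2)")
    return 1 if ffr <= SIGNIFICANCE_CUTOFF else 0


def zone_of(ffr: float, lo: float = GRAY_ZONE[0], hi: float = GRAY_ZONE[1]) -> str:
    """Zone assignment: 'below' (< lo), 'gray' ([lo, hi], inclusive), 'above'."""
    if not lo < hi:
        raise ValueError("zone bounds must satisfy lo < hi")
    if ffr < lo:
        return "below"
    if ffr <= hi:
        return "gray"
    return "above"


def label_cohort(cohort: pd.DataFrame,
                 drift_relevance=DEFAULT_DRIFT_RELEVANCE,
                 gray_zone=GRAY_ZONE) -> pd.DataFrame:
    """Apply drift correction, labeling and zoning to a cohort table.

    Expects columns ``lesion_id, Pd, Pa, D``; returns a frame with columns
    ``lesion_id, corrected_ffr, label, zone, adjusted`` where ``adjusted``
    marks lesions whose corrected FFR differs from the raw Pd/Pa ratio.
    """
    rows = []
    for rec in cohort.itertuples(index=False):
        pr = PressureRecord(Pd=rec.Pd, Pa=rec.Pa, D=int(rec.D))
        ffr = corrected_ffr(pr, drift_relevance=drift_relevance)
        rows.append({
            "lesion_id": rec.lesion_id,
            "corrected_ffr": ffr,
            "label": label_lesion(ffr),
            "zone": zone_of(ffr, *gray_zone),
            "adjusted": ffr != pr.Pd / pr.Pa,
        })
    return pd.DataFrame(rows)
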