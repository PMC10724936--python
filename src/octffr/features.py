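"""Geometric feature extraction and feature-matrix assembly.

Twelve geometric quantities are computed from the lumen-radii profile of
each lesion; together with the physician-estimated minimal lumen diameter
(MLD) and thirteen clinical covariates they form a 26-column feature
matrix.  Columns are L1-normalized (each column divided by the sum of its
absolute values) before modeling, and perfectly correlated features are
pruned so that each univariate vote carries distinct information.

The MLD is deliberately distinct from twice the profile's minimum radius:
the former is the expert's estimate on the imaging console, the latter is
computed from the extracted radii signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from octffr.profile import RadiiProfile

#: The 12 geometric feature names, in the order they are computed.
GEOMETRIC_FEATURES = [
    "mean_lumen_radius",
    "minimum_lumen_radius",
    "maximum_lumen_radius",
    "mean_lumen_radius_stenosis",
    "mean_radius_per_length",
    "maximum_radius_rapport",
    "stenosis_lesion_length",
    "percentage_diameter_reduction",
    "proximal_radius_rapport",
    "radius_rapport",
    "proximal_area",
    "distal_area",
]

#: The 13 clinical covariates.
CLINICAL_FEATURES = [
    "sex", "age", "height", "weight", "smoking", "aht", "dyslipidemia",
    "diabetes", "echo_ef", "diastolic_pattern", "ivs", "hb", "ht",
]

#: Full 26-column schema: 12 geometric + physician MLD + 13 clinical.
FEATURE_COLUMNS = GEOMETRIC_FEATURES + ["minimal_lumen_diameter"] + CLINICAL_FEATURES

#: Univariate-accuracy rank order of the 26 features on the study data
#: (descending accuracy of the best base learner per feature).  Used as the
#: canonical rank for collinearity pruning and top-k sweeps on real data;
#: synthetic runs rank by measured accuracy instead.
TABLE_RANK_ORDER = [
    "minimal_lumen_diameter",
    "proximal_radius_rapport",
    "radius_rapport",
    "percentage_diameter_reduction",
    "mean_lumen_radius",
    "minimum_lumen_radius",
    "weight",
    "mean_lumen_radius_stenosis",
    "mean_radius_per_length",
    "maximum_radius_rapport",
    "stenosis_lesion_length",
    "ht",
    "ivs",
    "maximum_lumen_radius",
    "smoking",
    "dyslipidemia",
    "aht",
    "diastolic_pattern",
    "age",
    "diabetes",
    "distal_area",
    "echo_ef",
    "hb",
    "height",
    "proximal_area",
    "sex",
]


@dataclass(frozen=True)
class GeometricFeatures:
    """The 12 geometric quantities derived from one radii profile."""

    mean_lumen_radius: float            # r_mean over the segment (mm)
    minimum_lumen_radius: float         # r_min over the segment (mm)
    maximum_lumen_radius: float         # r_max over the segment (mm)
    mean_lumen_radius_stenosis: float   # mean radius over the lesion (mm)
    mean_radius_per_length: float       # r_mean / segment length (mm/mm)
    maximum_radius_rapport: float       # (r_max - r_min) / r_max
    stenosis_lesion_length: float       # lengthS (mm)
    percentage_diameter_reduction: float  # 100*(1 - 2 r_mean/(r_prox + r_dist))
    proximal_radius_rapport: float      # (r_prox - r_dist) / r_prox
    radius_rapport: float               # ((r_prox+r_dist)/2 - r_min) / ((r_prox+r_dist)/2)
    proximal_area: float                # pi * r_prox^2 (mm^2)
    distal_area: float                  # pi * r_dist^2 (mm^2)

    def as_dict(self) -> dict:
        return asdict(self)


def compute_geometric_features(profile: RadiiProfile) -> GeometricFeatures:
    """Compute the 12 geometric features from a radii profile.

    Means are taken over inclusive frame ranges; lengths use
    (end - start) * frame_spacing.  The proximal/distal reference radii are
    the radii at the annotated lesion-boundary frames.
    """
    if profile.segment_end == profile.segment_start:
        raise ValueError("zero-length vessel segment")
    seg = profile.segment_radii
    r_mean = float(seg.mean())
    r_min = float(seg.min())
    r_max = float(seg.max())
    r_prox = profile.r_proximal
    r_dist = profile.r_distal
    mid = (r_prox + r_dist) / 2.0
    return GeometricFeatures(
        mean_lumen_radius=r_mean,
        minimum_lumen_radius=r_min,
        maximum_lumen_radius=r_max,
        mean_lumen_radius_stenosis=float(profile.lesion_radii.mean()),
        mean_radius_per_length=r_mean / profile.segment_length,
        maximum_radius_rapport=(r_max - r_min) / r_max,
        stenosis_lesion_length=profile.lesion_length,
        percentage_diameter_reduction=100.0 * (1.0 - 2.0 * r_mean / (r_prox + r_dist)),
        proximal_radius_rapport=(r_prox - r_dist) / r_prox,
        radius_rapport=(mid - r_min) / mid,
        proximal_area=np.pi * r_prox ** 2,
        distal_area=np.pi * r_dist ** 2,
    )


def assemble_feature_matrix(cohort) -> pd.DataFrame:
    """Build the lesions x 26 feature matrix from a cohort.

    ``cohort`` is any object exposing ``lesions`` (records with
    ``lesion_id``, ``mld``, ``patient_id``), ``profiles`` (lesion_id ->
    RadiiProfile) and ``patients`` (records with the clinical covariates).
    Missing covariates raise with the lesion and column named; nothing is
    imputed silently.
    """
    patients = {p.patient_id: p for p in cohort.patients}
    rows = []
    for lesion in cohort.lesions:
        lid = lesion.lesion_id
        if lid not in cohort.profiles:
            raise ValueError(f"lesion {lid}: no radii profile")
        row = compute_geometric_features(cohort.profiles[lid]).as_dict()
        if lesion.mld is None or (isinstance(lesion.mld, float) and np.isnan(lesion.mld)):
            raise ValueError(f"lesion {lid}: missing column minimal_lumen_diameter")
        row["minimal_lumen_diameter"] = lesion.mld
        clin = patients[lesion.patient_id]
        for col in CLINICAL_FEATURES:
            val = getattr(clin, col, None)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                raise ValueError(f"lesion {lid}: missing column {col}")
            if col == "sex":           # encode F/M as 0/1 so columns are numeric
                val = 1.0 if val == "M" else 0.0
            row[col] = float(val)
        row["lesion_id"] = lid
        rows.append(row)
    matrix = pd.DataFrame(rows).set_index("lesion_id")[FEATURE_COLUMNS]
    if matrix.isna().any().any():
        bad = matrix.columns[matrix.isna().any()].tolist()
        raise ValueError(f"missing values after assembly in columns {bad}")
    matrix.attrs["normalized"] = False
    return matrix


def l1_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each feature column by the sum of its absolute values.

    Normalization is per column so that features with incommensurable units
    (mm, years, percent) each end up on a comparable scale while the shape
    of every univariate signal is preserved (correlations are unchanged).
    """
    if matrix.attrs.get("normalized", False):
        raise ValueError("feature matrix is already L1-normalized")
    norms = matrix.abs().sum(axis=0)
    zero = norms[norms == 0].index.tolist()
    if zero:
        raise ValueError(f"all-zero columns cannot be L1-normalized: {zero}")
    out = matrix / norms
    out.attrs["normalized"] = True
    return out


def pearson_correlation_matrix(matrix: pd.DataFrame,
                               feature_subset=None) -> pd.DataFrame:
    """Pairwise Pearson correlations for the given feature subset.

    A constant column has undefined correlation; it is reported as 0 with a
    warning (its diagonal entry stays 1).
    """
    if feature_subset is None:
        feature_subset = list(matrix.columns)
    if len(feature_subset) == 0:
        raise ValueError("feature subset must be non-empty")
    if len(matrix) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    sub = matrix[list(feature_subset)]
    constant = sub.columns[sub.std(ddof=0) == 0].tolist()
    if constant:
        warnings.warn(
            f"constant columns have undefined correlation, reported as 0: {constant}",
            stacklevel=2,
        )
    corr = sub.corr(method="pearson").fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def prune_perfectly_correlated(matrix: pd.DataFrame,
                               threshold: float = 0.999,
                               rank_order=None):
    """Drop the later-ranked member of every feature pair with |r| >= threshold.

    ``rank_order`` defaults to the matrix's column order; for study-style
    runs pass :data:`TABLE_RANK_ORDER`.  Returns ``(pruned_matrix,
    removed_names)``; deterministic and idempotent.
    """
    if rank_order is None:
        rank_order = list(matrix.columns)
    rank = {name: i for i, name in enumerate(rank_order)}
    corr = pearson_correlation_matrix(matrix).abs()
    cols = sorted(matrix.columns, key=lambda c: rank.get(c, len(rank)))
    removed: list[str] = []
    for i, a in enumerate(cols):
        if a in removed:
            continue
        for b in cols[i + 1:]:
            if b not in removed and corr.loc[a, b] >= threshold:
                removed.append(b)
    pruned = matrix.drop(columns=removed)
    pruned.attrs["normalized"] = matrix.attrs.get("normalized", False)
    return pruned, removed
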