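"""Synthetic cohort generator.

The study population this package targets — 80 patients with 102
intermediate coronary lesions, FFR 0.80 +/- 0.08 concentrated in the
[0.75, 0.85] gray zone, vessel mix 57/20/25 (LAD/LCX/RCA), and 15 lesions
with a relevant pressure drift (12 at 2 mmHg, 3 at 3 mmHg) — comes from a
private single-center registry.  This module generates cohorts with that
statistical structure so the full analysis pipeline is testable end to end.

The generator works backwards from physiology: a target FFR is drawn from
a three-zone mixture calibrated to the cohort marginals, and the stenosis
severity that reproduces it through a monotone pressure-drop surrogate is
solved for.  The surrogate (viscous + turbulent loss terms over the
narrowed lumen) is deliberately simple: it supplies a monotone, geometry-
determined link between the radii profile and FFR, not hemodynamic realism.
Measured pressures are then sampled so that drift correction recovers the
true FFR up to instrument rounding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from octffr.profile import RadiiProfile

MAX_PULLBACK_MM = 75.0       # longest vessel length one pullback can cover
FRAMES_PER_MM = 5            # axial sampling rate of the pullback
RADIUS_FLOOR_MM = 0.1        # noise never closes the lumen below this

# pressure-drop surrogate defaults: hyperemic flow (mL/s) and loss
# coefficients, weighted toward the scale-free turbulent term so that the
# dimensionless narrowing ratios carry most of the FFR signal
DEFAULT_FLOW = 2.0
DEFAULT_VISCOUS_COEFF = 0.3
DEFAULT_TURBULENT_COEFF = 0.7

VESSELS = ("LAD", "LCX", "RCA")


@dataclass(frozen=True)
class FfrMixture:
    """Three-zone FFR mixture: below 0.75, gray [0.75, 0.85], above 0.85.

    Default masses follow the study cohort (25/47/30 of 102 lesions); the
    within-zone laws are truncated normals below/above and uniform inside
    the gray zone, chosen once so the induced distribution reproduces the
    cohort marginals (mean 0.80, sd 0.08, 48/102 at FFR <= 0.80).
    """

    masses: tuple = (25 / 102, 47 / 102, 30 / 102)
    lo: float = 0.75
    hi: float = 0.85
    below_mean: float = 0.71
    below_sd: float = 0.05
    below_floor: float = 0.50
    above_mean: float = 0.875
    above_sd: float = 0.035
    above_ceil: float = 1.00

    def __post_init__(self):
        if abs(sum(self.masses) - 1.0) > 1e-9 or any(m < 0 for m in self.masses):
            raise ValueError("zone masses must be a probability vector")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        zone = rng.choice(3, size=n, p=np.asarray(self.masses))
        out = np.empty(n)
        out[zone == 1] = rng.uniform(self.lo, self.hi, (zone == 1).sum())
        out[zone == 0] = _truncated_normal(
            rng, self.below_mean, self.below_sd,
            self.below_floor, self.lo, (zone == 0).sum())
        out[zone == 2] = _truncated_normal(
            rng, self.above_mean, self.above_sd,
            self.hi, self.above_ceil, (zone == 2).sum())
        return out


def _truncated_normal(rng, mean, sd, lo, hi, n):
    """Truncated normal via inverse-CDF sampling (vectorized, rng-driven)."""
    from scipy.stats import truncnorm
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(size=n)
    return truncnorm.ppf(u, a, b, loc=mean, scale=sd)


#: Patient-level marginal distributions of the clinical covariates,
#: calibrated to the study's baseline table (n = 80): 82% male, age
#: 60.5 +/- 11.2 y, BMI 27.7 +/- 2.5 kg/m^2, hypertension 75%,
#: dyslipidemia 77.5%, diabetes 33.75%, smoking history 52.5%,
#: EF 48.28 +/- 6.31%.  Values without a printed marginal (height, IVS,
#: Hb, Ht, diastolic pattern) use population-typical laws.
DEFAULT_CLINICAL_MARGINALS = {
    "p_male": 0.82,
    "age_mean": 60.5, "age_sd": 11.2,
    "bmi_mean": 27.7, "bmi_sd": 2.5,
    "height_male": (175.0, 7.0), "height_female": (162.0, 7.0),
    "p_smoking": (0.475, 0.30, 0.225),   # never / past / present
    "p_aht": 0.75,
    "p_dyslipidemia": 0.775,
    "p_diabetes": 0.3375,
    "ef_mean": 48.28, "ef_sd": 6.31,
    "diastolic_pattern_p": (0.35, 0.40, 0.20, 0.05),  # ordinal grades 0-3
    "ivs_mean": 11.0, "ivs_sd": 1.5,
    "hb_mean": 14.0, "hb_sd": 1.5,
    "ht_mean": 42.0, "ht_sd": 4.0,
    # weak coupling of select covariates to lesion severity (per standardized
    # unit of (0.8 - FFR)/0.08); zero decouples clinical data from FFR
    "weight_coupling": 2.0,   # kg
    "ht_coupling": 1.0,       # percent
}


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    sex: str                 # 'F' or 'M'
    age: float               # years
    height: float            # cm
    weight: float            # kg
    smoking: int             # 0 no, 1 past, 2 present
    aht: int
    dyslipidemia: int
    diabetes: int
    echo_ef: float           # percent
    diastolic_pattern: int   # ordinal grade
    ivs: float               # interventricular septum, mm
    hb: float                # g/dL
    ht: float                # percent

    def __post_init__(self):
        if self.age <= 0 or self.height <= 0 or self.weight <= 0:
            raise ValueError("age, height and weight must be positive")
        if not (0 < self.echo_ef < 100) or not (0 < self.ht < 100):
            raise ValueError("echo_ef and ht must lie in (0, 100)")


@dataclass(frozen=True)
class LesionRecord:
    lesion_id: str
    patient_id: str
    vessel: str              # LAD / LCX / RCA
    proximal_lad: int        # 1 if a proximal LAD lesion
    Pd: float                # recorded distal pressure, mmHg
    Pa: float                # aortic pressure, mmHg
    D: int                   # pressure drift, mmHg
    mld: float               # physician-estimated minimal lumen diameter, mm


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults are the study-cohort conditions."""

    n_patients: int = 80
    n_lesions: int = 102
    lesions_per_patient: tuple = (0.75, 0.20, 0.05)   # P(1), P(2), P(3)
    vessel_mix: tuple = (57 / 102, 20 / 102, 25 / 102)  # LAD, LCX, RCA
    ffr_target: FfrMixture = field(default_factory=FfrMixture)
    drift_counts: tuple = ((2, 12), (3, 3))   # (drift mmHg, lesion count)
    radius_noise_sd: float = 0.05     # mm, per-frame measurement noise
    pressure_noise_sd: float = 5.0    # mmHg, aortic pressure variability
    mld_noise_sd: float = 0.10        # mm, physician annotation noise
    pressure_resolution: float = 1.0  # mmHg, instrument granularity
    Pa_mean: float = 100.0            # mmHg
    clinical_marginals: dict = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_MARGINALS))
    seed: int = 0

    def __post_init__(self):
        for vec in (self.lesions_per_patient, self.vessel_mix):
            if abs(sum(vec) - 1.0) > 1e-9 or any(p < 0 for p in vec):
                raise ValueError("probability vectors must be non-negative and sum to 1")
        for sd in (self.radius_noise_sd, self.pressure_noise_sd, self.mld_noise_sd):
            if sd < 0:
                raise ValueError("noise sds must be non-negative")
        n_drift = sum(c for _, c in self.drift_counts)
        if n_drift > self.n_lesions:
            raise ValueError(
                f"{n_drift} drifted lesions exceed the {self.n_lesions}-lesion budget")
        if not (self.n_patients <= self.n_lesions <= 3 * self.n_patients):
            raise ValueError("n_lesions must lie in [n_patients, 3*n_patients]")


@dataclass
class SyntheticCohort:
    """Generated patients, lesions, radii profiles and latent true FFR."""

    config: CohortConfig
    patients: list
    lesions: list
    profiles: dict           # lesion_id -> RadiiProfile
    true_ffr: dict           # lesion_id -> fraction in (0, 1]

    def __post_init__(self):
        ids = [l.lesion_id for l in self.lesions]
        if len(set(ids)) != len(ids):
            raise ValueError("lesion ids must be unique")
        pids = {p.patient_id for p in self.patients}
        for l in self.lesions:
            if l.patient_id not in pids:
                raise ValueError(f"lesion {l.lesion_id} references unknown patient")
            if l.lesion_id not in self.profiles:
                raise ValueError(f"lesion {l.lesion_id} has no profile")

    def to_frame(self) -> pd.DataFrame:
        """One row per lesion: identifiers, pressures, MLD and clinical covariates."""
        patients = {p.patient_id: p for p in self.patients}
        rows = []
        for l in self.lesions:
            p = patients[l.patient_id]
            rows.append({
                "lesion_id": l.lesion_id, "patient_id": l.patient_id,
                "vessel": l.vessel, "proximal_lad": l.proximal_lad,
                "Pd": l.Pd, "Pa": l.Pa, "D": l.D, "mld": l.mld,
                "sex": p.sex, "age": p.age, "height": p.height,
                "weight": p.weight, "smoking": p.smoking, "aht": p.aht,
                "dyslipidemia": p.dyslipidemia, "diabetes": p.diabetes,
                "echo_ef": p.echo_ef, "diastolic_pattern": p.diastolic_pattern,
                "ivs": p.ivs, "hb": p.hb, "ht": p.ht,
            })
        return pd.DataFrame(rows)

    def patient_of(self) -> pd.Series:
        """lesion_id -> patient_id mapping (the CV grouping)."""
        return pd.Series({l.lesion_id: l.patient_id for l in self.lesions})

    def write_dir(self, out_dir) -> None:
        """Write cohort.csv plus per-lesion profile CSVs and marker sidecars."""
        out = Path(out_dir)
        (out / "profiles").mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "cohort.csv", index=False)
        for lid, prof in self.profiles.items():
            pd.DataFrame({
                "frame": np.arange(len(prof.radii)),
                "radius_mm": prof.radii,
            }).to_csv(out / "profiles" / f"{lid}.csv", index=False)
            markers = {
                "segment_start": prof.segment_start,
                "segment_end": prof.segment_end,
                "lesion_start": prof.lesion_start,
                "lesion_end": prof.lesion_end,
                "frame_spacing": prof.frame_spacing,
            }
            (out / "profiles" / f"{lid}.markers.json").write_text(
                json.dumps(markers))


def sample_radii_profile(severity: float,
                         lesion_length: float,
                         baseline_radius: float,
                         taper: float = 0.0,
                         noise_sd: float = 0.0,
                         rng: np.random.Generator | None = None,
                         segment_length: float = 20.0,
                         frame_spacing: float = 1.0 / FRAMES_PER_MM,
                         lesion_center: float | None = None,
                         lesion_id: str = "lesion") -> RadiiProfile:
    """Synthesize a lumen-radii pullback signal with one stenosis.

    The healthy lumen tapers linearly proximal-to-distal by the fraction
    ``taper``; a raised-cosine narrowing of fractional depth ``severity``
    (relative to the local healthy radius) spans ``lesion_length`` mm around
    ``lesion_center`` (segment midpoint by default).  I.i.d. Gaussian radius
    noise is added and floored at 0.1 mm.  Markers are set to the segment
    ends and the lesion ends.
    """
    if not 0 <= severity < 1:
        raise ValueError("severity must lie in [0, 1): a lumen cannot close")
    if baseline_radius <= 0:
        raise ValueError("baseline_radius must be positive")
    if segment_length > MAX_PULLBACK_MM:
        raise ValueError(
            f"segment length {segment_length} mm exceeds the "
            f"{MAX_PULLBACK_MM:.0f} mm pullback limit")
    if not 0 < lesion_length < segment_length:
        raise ValueError("lesion_length must be positive and shorter than the segment")
    if noise_sd > 0 and rng is None:
        raise ValueError("rng required when noise_sd > 0")

    n_frames = int(round(segment_length / frame_spacing)) + 1
    x = np.arange(n_frames) * frame_spacing
    healthy = baseline_radius * (1.0 - taper * x / segment_length)

    half = lesion_length / 2.0
    if lesion_center is None:
        lesion_center = segment_length / 2.0
    lesion_center = float(np.clip(lesion_center, half, segment_length - half))

    # raised-cosine narrowing: full depth at the center, zero at the ends
    rel = (x - lesion_center) / half
    shape = np.where(np.abs(rel) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * rel)), 0.0)
    radii = healthy * (1.0 - severity * shape)
    if noise_sd > 0:
        radii = radii + rng.normal(0.0, noise_sd, n_frames)
    radii = np.maximum(radii, RADIUS_FLOOR_MM)

    lesion_start = int(round((lesion_center - half) / frame_spacing))
    lesion_end = lesion_start + int(round(lesion_length / frame_spacing))
    return RadiiProfile(
        lesion_id=lesion_id,
        radii=radii,
        frame_spacing=frame_spacing,
        segment_start=0,
        segment_end=n_frames - 1,
        lesion_start=lesion_start,
        lesion_end=min(lesion_end, n_frames - 1),
    )


def ffr_from_geometry(profile: RadiiProfile,
                      Pa: float = 100.0,
                      flow: float = DEFAULT_FLOW,
                      viscous_coeff: float = DEFAULT_VISCOUS_COEFF,
                      turbulent_coeff: float = DEFAULT_TURBULENT_COEFF) -> float:
    """Monotone stenosis pressure-drop surrogate mapping geometry to FFR.

    The drop combines a viscous (Poiseuille-like) term proportional to the
    lesion length and to the excess resistance of the narrowed lumen over
    the healthy reference (the proximal-boundary radius), and a turbulent
    expansion term quadratic in flow and in the area ratio:

        dP = Kv * lengthS * (1/r_min^4 - 1/r_ref^4) * Q
           + Kt * (A_prox/A_min - 1)^2 * Q^2

    FFR = clamp((Pa - dP)/Pa, 0.01, 1.0).  With no narrowing the excess
    resistance and the area ratio both vanish, so FFR = 1.  This is a
    plumbing surrogate, not a hemodynamic model: it only guarantees
    monotonicity in severity and lesion length.
    """
    if Pa <= 0 or flow <= 0:
        raise ValueError("Pa and flow must be positive")
    r_min = float(profile.segment_radii.min())
    if r_min <= 0:
        raise ValueError("minimum lumen radius must be positive")
    r_ref = profile.r_proximal
    dp = _pressure_drop(r_min, r_ref, profile.lesion_length,
                        flow, viscous_coeff, turbulent_coeff)
    return float(np.clip((Pa - dp) / Pa, 0.01, 1.0))


def _pressure_drop(r_min, r_ref, length_s, flow, kv, kt):
    viscous = kv * length_s * max(1.0 / r_min ** 4 - 1.0 / r_ref ** 4, 0.0) * flow
    area_ratio = (r_ref / r_min) ** 2
    turbulent = kt * max(area_ratio - 1.0, 0.0) ** 2 * flow ** 2
    return viscous + turbulent


def sample_pressures(true_ffr: float,
                     drift: int,
                     Pa_mean: float = 100.0,
                     noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None,
                     resolution: float = 1.0):
    """Sample (Pd, Pa, D) so that drift correction recovers ``true_ffr``.

    Pa is drawn around ``Pa_mean``; the drift-corrected distal pressure is
    ``true_ffr * Pa`` rounded to the instrument resolution, and the recorded
    Pd is that value minus the drift — applying the correction Pd + D and
    dividing by Pa returns the true FFR up to rounding.
    """
    if not 0 < true_ffr <= 1:
        raise ValueError("true_ffr must lie in (0, 1]")
    if drift < 0 or drift != int(drift):
        raise ValueError("drift must be a non-negative integer (mmHg)")
    if noise_sd > 0 and rng is None:
        raise ValueError("rng required when noise_sd > 0")

    pa = Pa_mean if noise_sd == 0 else rng.normal(Pa_mean, noise_sd)
    if resolution > 0:
        pa = round(pa / resolution) * resolution
        corrected_pd = round(true_ffr * pa / resolution) * resolution
    else:
        corrected_pd = true_ffr * pa
    pd_recorded = corrected_pd - drift
    return float(pd_recorded), float(pa), int(drift)


def sample_clinical(rng: np.random.Generator,
                    marginals: dict | None = None,
                    severity_z: float = 0.0,
                    patient_id: str = "P000") -> ClinicalRecord:
    """Draw one patient's clinical covariates from the cohort marginals.

    ``severity_z`` is the patient's standardized lesion burden,
    (0.8 - mean true FFR) / 0.08; the coupling coefficients in ``marginals``
    let weight and hematocrit carry a weak severity signal (all-zero
    couplings make the clinical covariates independent of FFR).
    """
    m = dict(DEFAULT_CLINICAL_MARGINALS)
    if marginals:
        m.update(marginals)
    male = rng.uniform() < m["p_male"]
    h_mean, h_sd = m["height_male"] if male else m["height_female"]
    height = float(np.clip(rng.normal(h_mean, h_sd), 140.0, 210.0))
    bmi = float(np.clip(rng.normal(m["bmi_mean"], m["bmi_sd"]), 16.0, 45.0))
    weight = bmi * (height / 100.0) ** 2 + m["weight_coupling"] * severity_z
    return ClinicalRecord(
        patient_id=patient_id,
        sex="M" if male else "F",
        age=float(np.clip(rng.normal(m["age_mean"], m["age_sd"]), 25.0, 95.0)),
        height=height,
        weight=float(max(weight, 40.0)),
        smoking=int(rng.choice(3, p=np.asarray(m["p_smoking"]))),
        aht=int(rng.uniform() < m["p_aht"]),
        dyslipidemia=int(rng.uniform() < m["p_dyslipidemia"]),
        diabetes=int(rng.uniform() < m["p_diabetes"]),
        echo_ef=float(np.clip(rng.normal(m["ef_mean"], m["ef_sd"]), 15.0, 75.0)),
        diastolic_pattern=int(rng.choice(4, p=np.asarray(m["diastolic_pattern_p"]))),
        ivs=float(np.clip(rng.normal(m["ivs_mean"], m["ivs_sd"]), 6.0, 18.0)),
        hb=float(np.clip(rng.normal(m["hb_mean"], m["hb_sd"]), 8.0, 19.0)),
        ht=float(np.clip(rng.normal(m["ht_mean"], m["ht_sd"])
                         + m["ht_coupling"] * severity_z, 20.0, 60.0)),
    )


def _severity_for_ffr(target_ffr, baseline, taper, center, lesion_length,
                      segment_length, Pa, flow, kv, kt):
    """Solve for the raised-cosine severity whose noiseless profile yields
    ``target_ffr`` through the pressure-drop surrogate (continuous limit)."""
    r_prox_factor = 1.0 - taper * (center - lesion_length / 2.0) / segment_length
    distal_end = 1.0 - taper

    def achieved(severity):
        r_center = baseline * (1.0 - taper * center / segment_length) * (1.0 - severity)
        r_min = min(r_center, baseline * distal_end)
        r_ref = baseline * r_prox_factor
        dp = _pressure_drop(r_min, r_ref, lesion_length, flow, kv, kt)
        return float(np.clip((Pa - dp) / Pa, 0.01, 1.0))

    if achieved(0.0) <= target_ffr:
        return 0.0, achieved(0.0)
    s = brentq(lambda s: achieved(s) - target_ffr, 0.0, 0.95, xtol=1e-10)
    return float(s), target_ffr


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort from a :class:`CohortConfig`.

    Deterministic in the config (including its seed): the same config
    regenerates the identical cohort.  Lesions are distributed 1-3 per
    patient to hit the lesion budget exactly; drift is assigned to exactly
    the configured lesion counts; each patient's lesions share one clinical
    record.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n_pat, n_les = config.n_patients, config.n_lesions

    counts = 1 + rng.choice(3, size=n_pat, p=np.asarray(config.lesions_per_patient))
    while counts.sum() != n_les:
        i = int(rng.integers(n_pat))
        if counts.sum() > n_les and counts[i] > 1:
            counts[i] -= 1
        elif counts.sum() < n_les and counts[i] < 3:
            counts[i] += 1

    target_ffr = config.ffr_target.sample(n_les, rng)

    # drift assignment: exactly the configured counts, disjoint lesion sets
    drift = np.zeros(n_les, dtype=int)
    n_drifted = sum(c for _, c in config.drift_counts)
    chosen = rng.choice(n_les, size=n_drifted, replace=False)
    pos = 0
    for d_value, d_count in config.drift_counts:
        drift[chosen[pos:pos + d_count]] = d_value
        pos += d_count

    patients, lesions, profiles, true_ffr = [], [], {}, {}
    lesion_idx = 0
    for p_idx in range(n_pat):
        pid = f"P{p_idx:04d}"
        lesion_params = []
        for _ in range(counts[p_idx]):
            i = lesion_idx
            lesion_idx += 1
            lid = f"L{i:05d}"
            vessel = VESSELS[int(rng.choice(3, p=np.asarray(config.vessel_mix)))]
            proximal_lad = int(vessel == "LAD" and rng.uniform() < 0.5)
            # analyzed segment around one focal-to-diffuse lesion: the
            # annotated segment is 15-30 mm of the pullback and the lesion
            # occupies 55-65% of it, with mild physiological taper
            baseline = float(np.clip(rng.normal(1.6, 0.08), 1.3, 1.9))
            segment_length = float(rng.uniform(15.0, 30.0))
            lesion_length = segment_length * float(rng.uniform(0.55, 0.65))
            taper = float(rng.uniform(0.0, 0.02))
            half = lesion_length / 2.0
            center = float(rng.uniform(half + 0.5, segment_length - half - 0.5))
            severity, f_true = _severity_for_ffr(
                target_ffr[i], baseline, taper, center, lesion_length,
                segment_length, config.Pa_mean, DEFAULT_FLOW,
                DEFAULT_VISCOUS_COEFF, DEFAULT_TURBULENT_COEFF)
            prof = sample_radii_profile(
                severity, lesion_length, baseline, taper=taper,
                noise_sd=config.radius_noise_sd, rng=rng,
                segment_length=segment_length, lesion_center=center,
                lesion_id=lid)
            pd_rec, pa_rec, d_rec = sample_pressures(
                f_true, int(drift[i]), Pa_mean=config.Pa_mean,
                noise_sd=config.pressure_noise_sd, rng=rng,
                resolution=config.pressure_resolution)
            mld = max(2.0 * float(prof.segment_radii.min())
                      + rng.normal(0.0, config.mld_noise_sd), 2 * RADIUS_FLOOR_MM)
            profiles[lid] = prof
            true_ffr[lid] = f_true
            lesion_params.append((lid, vessel, proximal_lad, pd_rec, pa_rec,
                                  d_rec, mld, f_true))
        burden = float(np.mean([lp[7] for lp in lesion_params]))
        patient = sample_clinical(
            rng, config.clinical_marginals,
            severity_z=(0.8 - burden) / 0.08, patient_id=pid)
        patients.append(patient)
        for lid, vessel, prox, pd_rec, pa_rec, d_rec, mld, _ in lesion_params:
            lesions.append(LesionRecord(
                lesion_id=lid, patient_id=pid, vessel=vessel,
                proximal_lad=prox, Pd=pd_rec, Pa=pa_rec, D=d_rec, mld=mld))

    return SyntheticCohort(config=config, patients=patients, lesions=lesions,
                           profiles=profiles, true_ffr=true_ffr)
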