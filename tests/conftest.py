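import numpy as np
import pytest

from octffr.features import assemble_feature_matrix, l1_normalize
from octffr.ffr import label_cohort
from octffr.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized default cohort: 80 patients, 102 lesions."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def default_labels(default_cohort):
    return label_cohort(default_cohort.to_frame())


@pytest.fixture(scope="session")
def default_features(default_cohort):
    return l1_normalize(assemble_feature_matrix(default_cohort))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """A noise-free 300-lesion cohort: geometry fully determines FFR."""
    cfg = CohortConfig(n_patients=240, n_lesions=300, radius_noise_sd=0.0,
                       pressure_noise_sd=0.0, mld_noise_sd=0.0, seed=5)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noiseless_frame(noiseless_cohort):
    df = noiseless_cohort.to_frame()
    labels = label_cohort(df)
    features = l1_normalize(assemble_feature_matrix(noiseless_cohort))
    return df, features, labels


def random_profile(rng):
    """A random but valid radii profile for property tests."""
    from octffr.profile import RadiiProfile
    n = int(rng.integers(8, 120))
    radii = rng.uniform(0.3, 3.0, n)
    seg_start = int(rng.integers(0, max(n // 8, 1)))
    seg_end = int(rng.integers(min(seg_start + 4, n - 1), n))
    les_start = int(rng.integers(seg_start, seg_end))
    les_end = int(rng.integers(les_start, seg_end + 1))
    return RadiiProfile(lesion_id="rand", radii=radii,
                        frame_spacing=float(rng.uniform(0.1, 0.5)),
                        segment_start=seg_start, segment_end=seg_end,
                        lesion_start=les_start, lesion_end=les_end)


def brute_force_geometric_features(profile):
    """Literal per-frame reference implementation of the 12 geometric features."""
    import math
    seg = [profile.radii[i] for i in range(profile.segment_start,
                                           profile.segment_end + 1)]
    les = [profile.radii[i] for i in range(profile.lesion_start,
                                           profile.lesion_end + 1)]
    r_mean = sum(seg) / len(seg)
    r_min, r_max = min(seg), max(seg)
    r_prox = profile.radii[profile.lesion_start]
    r_dist = profile.radii[profile.lesion_end]
    seg_len = (profile.segment_end - profile.segment_start) * profile.frame_spacing
    mid = (r_prox + r_dist) / 2
    return {
        "mean_lumen_radius": r_mean,
        "minimum_lumen_radius": r_min,
        "maximum_lumen_radius": r_max,
        "mean_lumen_radius_stenosis": sum(les) / len(les),
        "mean_radius_per_length": r_mean / seg_len,
        "maximum_radius_rapport": (r_max - r_min) / r_max,
        "stenosis_lesion_length": (profile.lesion_end - profile.lesion_start)
                                  * profile.frame_spacing,
        "percentage_diameter_reduction": 100 * (1 - 2 * r_mean / (r_prox + r_dist)),
        "proximal_radius_rapport": (r_prox - r_dist) / r_prox,
        "radius_rapport": (mid - r_min) / mid,
        "proximal_area": math.pi * r_prox ** 2,
        "distal_area": math.pi * r_dist ** 2,
    }


def brute_force_auc(scores, labels):
    """O(n^2) pair-counting AUC."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
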