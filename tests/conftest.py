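import numpy as np
import pandas as pd
import pytest
from scipy.spatial import Delaunay

from fvuln.synthetic import SynthConfig, generate_dataset


def mc_hull_volume(points: np.ndarray, n_samples: int = 200_000, seed: int = 0):
    """Monte-Carlo rejection estimate of a convex-hull volume.

    Independent oracle for the exact Qhull volume: sample the bounding
    box uniformly and test membership via Delaunay simplex location.
    Returns (estimate, standard_error).
    """
    points = np.asarray(points, float)
    tri = Delaunay(points)
    lo, hi = points.min(axis=0), points.max(axis=0)
    box_vol = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, points.shape[1]))
    inside = tri.find_simplex(samples) >= 0
    p = inside.mean()
    est = box_vol * p
    se = box_vol * np.sqrt(p * (1 - p) / n_samples)
    return est, se


@pytest.fixture(scope="session")
def small_traits() -> pd.DataFrame:
    """Six species, hand-built: sp1/sp2 share all categories (one FE)."""
    rows = [
        # species, size, diet, home, position, activity, schooling
        ("sp1", "0-7", "planktivore", "sedentary", "benthic", "diurnal", "solitary"),
        ("sp2", "0-7", "planktivore", "sedentary", "benthic", "diurnal", "solitary"),
        ("sp3", ">80", "piscivore", "mobile-between-reefs", "pelagic", "nocturnal", "large-gt50"),
        ("sp4", "15.1-30", "omnivore", "mobile-within-reef", "bentho-pelagic", "both", "pairing"),
        ("sp5", "30.1-50", "mobile-invertivore", "sedentary", "benthic", "diurnal", "small-3-20"),
        ("sp6", "7.1-15", "herbivorous-detritivorous", "sedentary", "benthic", "diurnal", "medium-20-50"),
    ]
    cols = ["species_id", "size_class", "diet", "home_range", "position", "activity", "schooling"]
    return pd.DataFrame(rows, columns=cols).set_index("species_id")


@pytest.fixture(scope="session")
def dataset():
    """Mid-sized synthetic survey shared across tests (deterministic)."""
    return generate_dataset(SynthConfig(n_species=150, seed=3))


@pytest.fixture(scope="session")
def default_cfg():
    return SynthConfig()
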