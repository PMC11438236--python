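import warnings

import numpy as np
import pytest

from hullmass.pipeline import SpecimenRecord
from hullmass.synthetic import SyntheticBodySpec, make_body


RECORD_COLUMNS = (
    "species", "clade", "known_mass_kg", "mch_volume_m3",
    "humerus_circ_mm", "femur_circ_mm", "humerus_len_mm", "femur_len_mm",
    "mass_provenance",
)


def frame_to_records(frame):
    """Convert a synthetic specimen DataFrame to SpecimenRecord objects."""
    records = []
    for _, row in frame.iterrows():
        kwargs = {k: row[k] for k in RECORD_COLUMNS}
        for key, value in list(kwargs.items()):
            if isinstance(value, float) and np.isnan(value):
                kwargs[key] = None
        records.append(SpecimenRecord(**kwargs))
    return records


def monte_carlo_volume_centroid(hull, n_samples, rng):
    """Rejection-sampling oracle: volume and centroid of a hull from uniform
    samples in its bounding box (independent of the analytic path)."""
    lo = hull.vertices.min(axis=0)
    hi = hull.vertices.max(axis=0)
    box_volume = float(np.prod(hi - lo))
    samples = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = np.all(
        samples @ hull.equations[:, :3].T + hull.equations[:, 3] <= 1e-12, axis=1
    )
    p = inside.mean()
    volume = box_volume * p
    volume_se = box_volume * np.sqrt(p * (1 - p) / n_samples)
    interior = samples[inside]
    centroid = interior.mean(axis=0)
    centroid_se = interior.std(axis=0, ddof=1) / np.sqrt(len(interior))
    return volume, volume_se, centroid, centroid_se


@pytest.fixture(scope="session")
def croc_body():
    """A crocodylian-like synthetic body (tail-heavy) with its ground truth."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_body(SyntheticBodySpec(template="crocodylian_like", seed=11))


@pytest.fixture(scope="session")
def mammal_body():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return make_body(SyntheticBodySpec(template="mammal_like", seed=12))
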