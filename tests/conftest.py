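import numpy as np
import pandas as pd
import pytest


def make_detections(rows):
    """Build a detections frame from (site, species, minutes, behavior?, n_ind?) tuples.

    Times are minutes after 2017-02-01 00:00; behavior defaults to
    'feeding', n_individuals to 1.
    """
    base = pd.Timestamp("2017-02-01 00:00:00")
    recs = []
    for i, row in enumerate(rows):
        site, species, minutes = row[0], row[1], row[2]
        behavior = row[3] if len(row) > 3 else "feeding"
        n_ind = row[4] if len(row) > 4 else 1
        recs.append(
            {
                "image_id": f"img{i:04d}",
                "site_id": site,
                "species": species,
                "timestamp": base + pd.Timedelta(minutes=float(minutes)),
                "behavior": behavior,
                "n_individuals": n_ind,
                "year_label": "2017",
            }
        )
    df = pd.DataFrame(recs)
    return df.sort_values(["site_id", "timestamp"], kind="mergesort").reset_index(drop=True)


@pytest.fixture
def detections_factory():
    return make_detections


@pytest.fixture(scope="session")
def small_sim():
    """One small synthetic study shared by read-only tests."""
    from scavcam.simulate import SimConfig, simulate_study

    return simulate_study(SimConfig(n_sites=10, n_winters=2, rng_seed=42))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170101)
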