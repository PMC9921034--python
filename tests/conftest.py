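import numpy as np
import pandas as pd
import pytest

import progarray as pa


@pytest.fixture(scope="session")
def small_landscape():
    """Three moderately diverged populations of 12 adults, 800 loci."""
    cfg = pa.LandscapeConfig(
        n_populations=3, n_loci=800, fst_target=0.3, inbreeding_f=0.1,
        n_adults_per_pop=12, seed=42,
    )
    return pa.generate_landscape(cfg)


@pytest.fixture(scope="session")
def family_site(small_landscape):
    """A progeny array at site P01 with mixed selfing and mild noise."""
    adults, freqs, _ = small_landscape
    matrix, fam, truth = pa.generate_families(
        adults, pa.FamilyDesign(), 0.5, freqs,
        pa.NoiseModel(error_rate_epsilon=0.005, locus_missing_rate=0.03),
        seed=7, site="P01",
    )
    return matrix, fam, truth, freqs


@pytest.fixture()
def toy_matrix():
    """3 samples x 4 loci with one missing call and full metadata."""
    dos = np.array(
        [[0, 1, 2, 0], [2, np.nan, 1, 0], [1, 0, 0, 2]], dtype=float
    )
    li = pd.DataFrame(
        {
            "clone_id": ["c1", "c2", "c3", "c4"],
            "ref": ["A", "C", "G", "T"],
            "alt": ["T", "G", "A", "C"],
            "reproducibility": [1.0, 1.0, 0.99, 1.0],
            "call_rate": [1.0, 2 / 3, 1.0, 1.0],
        },
        index=["L1", "L2", "L3", "L4"],
    )
    return pa.GenotypeMatrix(
        pd.DataFrame(dos, index=["s1", "s2", "s3"], columns=li.index), li
    )


@pytest.fixture(scope="session")
def sim_mating():
    """One panmictic population of 20 adults, 1200 loci, for estimator tests."""
    cfg = pa.LandscapeConfig(
        n_populations=1, n_loci=1200, fst_target=0.0, inbreeding_f=0.0,
        n_adults_per_pop=20, seed=99,
    )
    return pa.generate_landscape(cfg)
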