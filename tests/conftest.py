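import numpy as np
import pytest

from periradiomics import regions, synthetic

#: small grid used by pipeline-level tests to keep them fast
SMALL_PHANTOM = synthetic.PhantomConfig(
    grid_shape=(4, 32, 32), tumor_radius_mm=4.0, pixel_spacing_mm=(0.75, 0.75)
)


@pytest.fixture()
def rng():
    # fresh deterministic stream per test: outcomes independent of test order
    return np.random.default_rng(20230517)


@pytest.fixture(scope="session")
def small_phantom():
    cfg = synthetic.PhantomConfig(seed=7, class_label="non_pCR")
    series, tumor = synthetic.generate_phantom(cfg)
    region = regions.peritumoral_ring(tumor, cfg.pixel_spacing_mm)
    return cfg, series, region


@pytest.fixture(scope="session")
def small_cohort_tables():
    """Feature tables for a tiny imaging cohort (shared across tests)."""
    from periradiomics.pipeline import extract_cohort_features

    train = synthetic.generate_cohort(
        synthetic.CohortSpec(n_pcr=6, n_non_pcr=10, group="train", seed=11), SMALL_PHANTOM
    )
    test = synthetic.generate_cohort(
        synthetic.CohortSpec(n_pcr=3, n_non_pcr=5, group="test", seed=911), SMALL_PHANTOM
    )
    return extract_cohort_features(train), extract_cohort_features(test)
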