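import numpy as np
import pandas as pd
import pytest

from codmix.synthio import GeneratorConfig, generate_all


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down survey: same structure, ~1/4 of the stations."""
    return GeneratorConfig(seed=7, n_stations=30, n_regions=6, haul_rate=0.35,
                           n_ref_per_pop=150)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_all(small_config)


@pytest.fixture(scope="session")
def default_bundle():
    """Full-scale survey at the default study conditions (generated once)."""
    return generate_all(GeneratorConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_survey(n_per_cell=5, years=(2000, 2001), regions=(1, 2), seed=0):
    """Tiny fully crossed survey table for design/fit unit tests."""
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for year in years:
        for region in regions:
            for eco in ("fjord", "northsea"):
                for vt in ("eelgrass", "macroalgae"):
                    for _ in range(n_per_cell):
                        i += 1
                        rows.append({
                            "fish_id": f"f{i}", "station": f"st{region}",
                            "year": year, "region": region,
                            "wave_exposure": float(rng.uniform(0.2, 0.8)),
                            "veg_type": vt,
                            "veg_cover": int(rng.integers(1, 6)),
                            "ecotype": eco,
                            "length_cm": float(rng.uniform(7, 13)),
                        })
    return pd.DataFrame(rows)
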