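import io

import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """Default synthetic study (session-wide, deterministic)."""
    from scatcomp import generate_study

    return generate_study()


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """Default synthetic study written to CSVs."""
    from scatcomp import generate_study, SyntheticConfig

    out = tmp_path_factory.mktemp("fixture")
    generate_study(SyntheticConfig(), out_dir=out)
    return out


def scats_csv(rows) -> io.StringIO:
    """Build an in-memory scats.csv from (scat_id, predator, date, x, y, area,
    pack_id, prey_species) tuples."""
    df = pd.DataFrame(
        rows,
        columns=["scat_id", "predator", "date", "x_m", "y_m", "area", "pack_id",
                 "prey_species"],
    )
    return io.StringIO(df.to_csv(index=False))


@pytest.fixture
def toy_traits():
    return pd.DataFrame(
        {
            "species": ["kudu", "impala", "duiker", "steenbok", "buffalo"],
            "mean_female_mass_kg": [170.0, 40.0, 18.0, 11.0, 520.0],
            "water_dependency": ["medium", "high", "low", "low", "high"],
            "feeding_guild": ["browser", "mixed_feeder", "browser", "browser",
                              "grassland_grazer"],
            "size_class": ["L", "M", "S", "S", "XL"],
        }
    )
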