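import pandas as pd
import pytest

from meadow import datasets
from meadow.vegdata import SurveyDesign


@pytest.fixture(scope="session")
def zone_vegetation() -> pd.DataFrame:
    return datasets.load_zone_vegetation()


@pytest.fixture(scope="session")
def forage_species() -> pd.DataFrame:
    return datasets.load_forage_species()


@pytest.fixture(scope="session")
def animal_units() -> pd.DataFrame:
    return datasets.load_animal_units()


@pytest.fixture(scope="session")
def livestock_census() -> pd.DataFrame:
    return datasets.load_livestock_census()


@pytest.fixture(scope="session")
def soil_chemistry() -> pd.DataFrame:
    return datasets.load_soil_chemistry()


@pytest.fixture(scope="session")
def criteria():
    return datasets.load_scoring_criteria()


@pytest.fixture(scope="session")
def design() -> SurveyDesign:
    return SurveyDesign(n_quadrats=30, quadrat_area=1.0)


def observations_from_counts(counts_per_quadrat: dict[str, list[int]]) -> pd.DataFrame:
    """Build a quadrat observation frame from {species: per-quadrat counts}."""
    rows = []
    for species, counts in counts_per_quadrat.items():
        for i, c in enumerate(counts):
            if c > 0:
                rows.append(
                    {
                        "zone": "Z",
                        "plot": "P1",
                        "quadrat": f"Q{i + 1:02d}",
                        "species": species,
                        "count": c,
                    }
                )
    return pd.DataFrame(rows, columns=["zone", "plot", "quadrat", "species", "count"])
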