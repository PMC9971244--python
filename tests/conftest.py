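import io

import pandas as pd
import pytest

import graphactivity as ga
from graphactivity.fixtures import data_text


@pytest.fixture(scope="session")
def smiles() -> dict:
    return ga.load_smiles()


@pytest.fixture(scope="session")
def taxifolin(smiles) -> ga.MolecularGraph:
    return ga.from_smiles(smiles["Taxfolin"], "Taxfolin")


@pytest.fixture(scope="session")
def training_df() -> pd.DataFrame:
    return pd.read_csv(io.StringIO(data_text("training_flavonoids.csv")))


@pytest.fixture(scope="session")
def refit(training_df) -> ga.Ic50PolynomialResults:
    """Exact interpolant of the bundled training table (solved once)."""
    return ga.Ic50PolynomialModel.from_dataframe(training_df).fit()


@pytest.fixture(scope="session")
def screening() -> list:
    return ga.load_screening_table()
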