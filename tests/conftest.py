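from pathlib import Path

import pandas as pd
import pytest

from cerna_texo import PipelineConfig, SimulationDesign, generate_dataset

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_design() -> SimulationDesign:
    return SimulationDesign(seed=1)


@pytest.fixture(scope="session")
def dataset(default_design):
    """One full synthetic dataset shared across tests (seed 1)."""
    matrices, truth, annotation, evidence, survival = generate_dataset(default_design)
    return {"matrices": matrices, "truth": truth, "annotation": annotation,
            "evidence": evidence, "survival": survival, "design": default_design}


def load_axis_fixture(name: str) -> pd.DataFrame:
    """The bundled worked-example survival-axis tables (lncrnas|mirna|mrnas)."""
    return pd.read_csv(DATA_DIR / name, sep="\t")


@pytest.fixture(scope="session")
def luminal_b_axes() -> pd.DataFrame:
    return load_axis_fixture("luminal_b_survival_axes.tsv")


@pytest.fixture(scope="session")
def tnbc_axes() -> pd.DataFrame:
    return load_axis_fixture("tnbc_survival_axes.tsv")
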