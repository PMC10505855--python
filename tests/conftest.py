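import numpy as np
import pandas as pd
import pytest

import patchchoice as pc
from patchchoice.domain import Patch, PatchCatalog, TripTable
from patchchoice.model import ModelLayout, ModelParams


@pytest.fixture(scope="session")
def catalog():
    return PatchCatalog.default()


@pytest.fixture(scope="session")
def fixture_data():
    """The margin-matched study fixture (trips + households), default seed."""
    return pc.default_fixture()


@pytest.fixture(scope="session")
def std_fixture(fixture_data):
    trips, households = fixture_data
    std, scaling = pc.standardize_covariates(trips)
    return std, scaling, households


@pytest.fixture(scope="session")
def reduced_layout():
    """Two patches, one season, one covariate, choice model only."""
    cat = PatchCatalog(patches=(Patch("a", "ice"), Patch("b", "ice")))
    layout = ModelLayout(
        patches=cat.names,
        seasons=("ice",),
        genders=(),
        age_classes=(),
        choice_covariates=("income_std",),
        success_covariates=(),
        include_success=False,
    )
    return cat, layout


def make_reduced_table(cat, layout, alpha, beta, n=40, seed=0, missing_frac=0.0):
    """Simulate a small 2-patch choice-only table from known truth."""
    rng = np.random.default_rng(seed)
    inc = rng.normal(size=n)
    eta = np.asarray(alpha)[None, :] + inc[:, None] * np.asarray(beta)[None, :]
    p = np.exp(eta) / np.exp(eta).sum(1, keepdims=True)
    patch = np.where(rng.random(n) < p[:, 0], cat.names[0], cat.names[1])
    df = pd.DataFrame(
        dict(
            trip_id=[f"t{i}" for i in range(n)],
            harvester_id="h1",
            household_id="hh1",
            gender="man",
            age_class="under30",
            season="ice",
            patch=patch,
            success=0,
            group_size=2,
            income=inc,
            in_degree=1,
            out_degree=1,
        )
    )
    df["income_std"] = inc
    df["in_degree_std"] = 0.0
    df["out_degree_std"] = 0.0
    df["group_size_std"] = 0.0
    if missing_frac > 0:
        k = int(round(missing_frac * n))
        df.loc[: k - 1, "income_std"] = np.nan
        df.loc[: k - 1, "income"] = np.nan
    return TripTable(df, cat, validate=False)


@pytest.fixture(scope="session")
def random_params(catalog):
    """One random full parameter set (fixed seed) for oracle comparisons."""
    layout = ModelLayout.default(catalog)
    rng = np.random.default_rng(7)
    params = pc.sample_params_from_prior(pc.PriorConfig.default(), layout, rng)
    return params
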