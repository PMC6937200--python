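"""Shared fixtures: small synthetic surveys and hand-built diet matrices."""

import numpy as np
import pandas as pd
import pytest

import dietstat as ds


def make_matrix(weights, counts=None, columns=None, labels=None) -> ds.DietMatrix:
    """Build a DietMatrix from plain arrays for hand-worked examples."""
    w = np.asarray(weights, dtype=float)
    c = np.asarray(counts if counts is not None else weights, dtype=float)
    if columns is None:
        columns = list(ds.PREY_GROUPS[: w.shape[1]])
    idx = [f"f{i}" for i in range(w.shape[0])]
    lab = labels if labels is not None else {}
    lab_df = pd.DataFrame(
        {
            "station_id": lab.get("station_id", ["st1"] * len(idx)),
            "year": lab.get("year", [2012] * len(idx)),
            "area": lab.get("area", ["SW"] * len(idx)),
            "length_group": lab.get("length_group", ["M"] * len(idx)),
        },
        index=idx,
    )
    return ds.DietMatrix(
        weight=pd.DataFrame(w, index=idx, columns=columns),
        count=pd.DataFrame(c, index=idx, columns=columns),
        labels=lab_df,
    )


def random_complete_matrix(rng, n_stomachs=12, n_groups=5) -> ds.DietMatrix:
    """Random matrix with no empty stomachs (every row has some content)."""
    w = rng.gamma(1.0, 1.0, (n_stomachs, n_groups)) * (
        rng.random((n_stomachs, n_groups)) < 0.7
    )
    # guarantee completeness: give each empty row one prey entry
    for i in range(n_stomachs):
        if w[i].sum() == 0:
            w[i, rng.integers(n_groups)] = rng.gamma(1.0, 1.0)
    c = np.where(w > 0, np.ceil(w * rng.uniform(1, 50, w.shape)), 0.0)
    return make_matrix(w, c)


@pytest.fixture(scope="session")
def small_survey() -> ds.SurveyDataset:
    """Two years x five areas x two stations x ten stomachs (200 fish)."""
    return ds.generate(ds.GeneratorConfig(seed=11, years=(2011, 2012), n_stations=2))


@pytest.fixture(scope="session")
def diet_matrix(small_survey) -> ds.DietMatrix:
    return ds.build_diet_matrix(small_survey.stomachs, small_survey.stations)
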