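"""Shared fixtures: fixture datasets and a reusable pooled fit at study scale."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import strawsense as ss
from strawsense.core_data import PanelDataset, SampleRecord


@pytest.fixture(scope="session")
def tiny():
    return ss.make_fixture("tiny")


@pytest.fixture(scope="session")
def pooled_demo():
    return ss.make_fixture("pooled_demo")


@pytest.fixture(scope="session")
def hier_demo():
    return ss.make_fixture("hier_demo")


@pytest.fixture(scope="session")
def default_ds():
    return ss.generate_dataset(ss.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def pooled_demo_fit(pooled_demo):
    """Pooled robust fit on the 207-sample demo, shared across tests."""
    ds, truth = pooled_demo
    rf = ds.regression_frame()
    data = ss.RegressionData(y=rf["y"].to_numpy(), x=rf["x"].to_numpy())
    spec = ss.ModelSpec(kind="pooled", n_chains=3, n_iterations=5000,
                        n_burnin=1500, seed=42)
    draws = ss.fit_pooled(data, spec)
    return ds, truth, data, draws


def dataset_from_matrix(M: np.ndarray, var_names: list[str] | None = None) -> PanelDataset:
    """Wrap an (n, p) matrix as sensory attributes of a minimal dataset so the
    clustering/PCA surface can be exercised on arbitrary numeric data.

    Values must lie in [0, 10] (they are panel-scale ratings here)."""
    M = np.asarray(M, float)
    n, p = M.shape
    names = var_names or [f"v{j + 1}" for j in range(p)]
    records = [
        SampleRecord(
            sample_id=f"S{i:03d}", genotype=f"G{i:03d}", year=2019, month=1,
            sensory={nm: float(M[i, j]) for j, nm in enumerate(names)},
            ssc=7.0, ta=0.8, ph=3.5, volatiles={},
        )
        for i in range(n)
    ]
    return PanelDataset(records=records, attribute_names=names, compound_names=[])
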