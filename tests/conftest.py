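import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import cytoplate as cp
from cytoplate.simulate import draw_ground_truth, ground_truth_to_table


@pytest.fixture(scope="session")
def small_params():
    """A small, fast, noiseless well used across segmentation tests."""
    return cp.WellSimParams(
        n_cells=80,
        image_shape=(768, 768),
        noise_sd=0.0,
        marker_models={"gH2AX": cp.MarkerModel(positive_fraction=0.5)},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_well(small_params):
    images, gt = cp.simulate_well(small_params)
    return images, gt


def match_to_truth(table: pd.DataFrame, gt: pd.DataFrame):
    """Match detected cells to ground-truth cells by nearest centroid.

    Returns (distances, gt_rows) aligned with the table rows.
    """
    tree = cKDTree(np.c_[gt["row"], gt["col"]])
    d, idx = tree.query(np.c_[table["centroid_row"], table["centroid_col"]])
    return d, gt.iloc[idx].reset_index(drop=True)


def marker_ledger_table(seed: int, n: int, positive_fraction: float,
                        channel: str = "m", **params_kw) -> pd.DataFrame:
    """Ground-truth cell table with one marker channel (no rendering)."""
    params = cp.WellSimParams(
        n_cells=n,
        image_shape=(4096, 4096),
        marker_models={channel: cp.MarkerModel(positive_fraction=positive_fraction)},
        seed=seed,
        **params_kw,
    )
    gt = draw_ground_truth(params, np.random.default_rng(seed))
    return ground_truth_to_table(gt, well_id=f"W{seed}")


def random_cell_table(rng: np.random.Generator, n: int = 200,
                      channels=("a", "b", "c")) -> pd.DataFrame:
    """Arbitrary (non-generative) cell table for brute-force oracle tests."""
    df = pd.DataFrame({
        "well_id": "R",
        "cell_label": np.arange(1, n + 1),
        "centroid_row": rng.uniform(0, 100, n),
        "centroid_col": rng.uniform(0, 100, n),
        "area": rng.uniform(50, 300, n),
    })
    for ch in channels:
        df[f"{ch}_integrated"] = rng.lognormal(8, 1.5, n)
        df[f"{ch}_mean"] = df[f"{ch}_integrated"] / df["area"]
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def replace(params, **kw):
    return dataclasses.replace(params, **kw)
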