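"""Shared fixtures, including the two heavy simulation studies.

The type-I calibration and power studies are session-scoped because both the
module-level property tests and the acceptance tests read different aspects
of the same replicate sets; each study runs once per session.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pytest

from firenet.data_io import GroupObservation, slice_window
from firenet.network_core import GBIMatrix, build_gbi
from firenet.permutation_inference import BaciConfig, run_baci, run_scenario_test
from firenet.synthetic_data import (
    DEFAULT_WINDOWS,
    SyntheticConfig,
    generate_dataset,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def data_dir() -> Path:
    return DATA_DIR


def obs(gid: str, members, day: int = 1, loc=(0.0, 0.0)) -> GroupObservation:
    return GroupObservation(
        group_id=gid,
        obs_date=dt.date(2013, 6, day),
        location=loc,
        members=frozenset(members),
    )


@pytest.fixture
def make_obs():
    return obs


def random_gbi(rng: np.random.Generator, max_rows: int = 8, max_cols: int = 8,
               min_sightings: int = 0) -> GBIMatrix:
    """A random small GBI (no filtering by default) for oracle comparisons."""
    n_rows = int(rng.integers(2, max_rows + 1))
    n_cols = int(rng.integers(2, max_cols + 1))
    m = (rng.random((n_rows, n_cols)) < 0.45).astype(np.uint8)
    m[m.sum(axis=1) == 0, rng.integers(0, n_cols)] = 1
    keep = m.sum(axis=0) >= max(min_sightings, 1)
    if keep.sum() < 2:
        return random_gbi(rng, max_rows, max_cols, min_sightings)
    m = m[:, keep]
    m = m[m.sum(axis=1) >= 1]
    return GBIMatrix(
        entries=m,
        row_labels=tuple(f"g{i}" for i in range(m.shape[0])),
        col_labels=tuple(f"i{j}" for j in range(m.shape[1])),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130715)


# ---------------------------------------------------------------------------
# heavy simulation studies (shared across test modules)

N_CALIBRATION_REPLICATES = 200
N_POWER_REPLICATES = 100


@pytest.fixture(scope="session")
def null_calibration_pvalues() -> np.ndarray:
    """Degree-test p-values on 200 effect-free datasets.

    Neutral generator (exchangeable groups, no period effect), one arm of 40
    individuals, 30 observation days per period, 500 permutations; dataset
    and test seeds fixed to the replicate index.
    """
    ps = np.empty(N_CALIBRATION_REPLICATES)
    for r in range(N_CALIBRATION_REPLICATES):
        cfg = SyntheticConfig.neutral(
            seed=r, n_individuals=40, frac_affected=1.0,
            n_obs_days_pre=30, n_obs_days_post=30,
        )
        _, observations, _, _ = generate_dataset(cfg)
        pre = build_gbi(slice_window(observations, DEFAULT_WINDOWS["pre"]))
        post = build_gbi(slice_window(observations, DEFAULT_WINDOWS["post"]))
        res = run_scenario_test(
            pre, post, metric="weighted_degree", n_permutations=500,
            tail="greater", seed=r,
        )
        ps[r] = res.p_one_tailed
    return ps


@pytest.fixture(scope="session")
def effect_recovery_study() -> dict:
    """100 replicate BACI runs at the default (effect-injected) config.

    Returns the affected-arm degree shifts and observed coefficients, and
    the one-tailed p-values of both arms (500 permutations each).
    """
    d_affected, d_unaffected = [], []
    coef_affected, p_affected, p_unaffected = [], [], []
    for r in range(N_POWER_REPLICATES):
        cfg = SyntheticConfig(seed=r)
        population, observations, _, _ = generate_dataset(cfg)
        result = run_baci(
            observations, population.scar, DEFAULT_WINDOWS,
            BaciConfig(n_permutations=500, seed=100_000 + r,
                       metrics=("weighted_degree",)),
        )
        cells = {
            (c["scenario"], c["period"]): c["mean_weighted_degree"]
            for c in result.summary
        }
        d_affected.append(cells[("affected", "post")] - cells[("affected", "pre")])
        d_unaffected.append(cells[("unaffected", "post")] - cells[("unaffected", "pre")])
        for t in result.tests:
            if t.label == "affected":
                coef_affected.append(t.observed_coef)
                p_affected.append(t.p_one_tailed)
            else:
                p_unaffected.append(t.p_one_tailed)
    return {
        "d_affected": np.array(d_affected),
        "d_unaffected": np.array(d_unaffected),
        "coef_affected": np.array(coef_affected),
        "p_affected": np.array(p_affected),
        "p_unaffected": np.array(p_unaffected),
    }
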