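"""Shared fixtures: simulated ensembles reused across the suite.

The heavy fixtures are session-scoped so the desk-scale base-circuit run and
the mini-scale PSF/uncoupled runs are simulated exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import emstem as es

#: Seed for all simulated fixtures; fixed once for the whole suite.
SUITE_SEED = 11


@pytest.fixture(scope="session")
def desk_bundle() -> es.CircuitAnalysis:
    """Base circuit at desk scale: 5 replicates x 1000 models x 50 inits."""
    cfg = es.RunConfig.preset("desk", circuit="base", seed=SUITE_SEED, quality_sweep=True)
    return es.run_full_analysis(cfg)


@pytest.fixture(scope="session")
def mini_base() -> es.CircuitAnalysis:
    """Base circuit at mini scale (2 x 600 x 30) for geometry comparisons."""
    cfg = es.RunConfig.preset("mini", circuit="base", seed=SUITE_SEED)
    return es.run_full_analysis(cfg)


@pytest.fixture(scope="session")
def mini_uncoupled() -> es.CircuitAnalysis:
    cfg = es.RunConfig.preset("mini", circuit="uncoupled", seed=SUITE_SEED)
    return es.run_full_analysis(cfg)


@pytest.fixture(scope="session")
def mini_sweeps() -> dict:
    """Perturbation sweeps (de10/ref/oe10) for every PSF circuit, mini scale."""
    out = {}
    for circuit, node in [
        ("grhl2", "GRHL2"), ("grhl2_kd", "GRHL2"), ("ovol", "OVOL"), ("nrf2", "NRF2")
    ]:
        cfg = es.RunConfig.preset("mini", circuit=circuit, seed=SUITE_SEED,
                                  perturbation_node=node)
        out[circuit] = es.perturbation_sweep(cfg)
    return out


@pytest.fixture()
def toy_labeled() -> pd.DataFrame:
    """Hand-built labeled solution table with known window occupancies.

    Single replicate; LIN28 values chosen so that a [-1, 1] window contains
    3 of 4 he solutions, 1 of 2 hm, 1 of 3 e, and 0 of 1 m.
    """
    rows = [
        # phenotype, LIN28
        ("he", 0.0), ("he", 0.5), ("he", -1.0), ("he", 5.0),
        ("hm", 0.2), ("hm", 2.0),
        ("e", -0.5), ("e", -3.0), ("e", 4.0),
        ("m", 9.0),
    ]
    return pd.DataFrame({
        "replicate": 0,
        "param_set": range(len(rows)),
        "n_states": 1,
        "LIN28": [v for _, v in rows],
        "phenotype": [c for c, _ in rows],
    })
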