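"""Shared fixtures.

The expensive session fixtures grow tumours once and let every test
branch copies of them, so paired-seed comparisons (treated vs control,
ablation variants) share the identical pre-treatment state.
"""

import numpy as np
import pytest

import tumourca as tca

GROW_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture()
def config():
    return tca.default_config()


@pytest.fixture(scope="session")
def default_config_session():
    return tca.default_config()


@pytest.fixture(scope="session")
def grown(default_config_session):
    """Untreated growth from one cell to 400 h, one run per seed."""
    cfg = default_config_session
    return {
        seed: tca.run_experiment(cfg, None, seed=seed, horizon_h=400.0)
        for seed in GROW_SEEDS
    }


@pytest.fixture()
def small_config():
    """A 30x30 lattice for cheap automaton-level tests."""
    cfg = tca.default_config()
    cfg.grid.rows = cfg.grid.cols = 30
    cfg.grid.vessel_density = 0.01
    return cfg


def dominance_runs(df, after=401.0):
    """Contiguous windows (start, end) of S-G2-M dominance in a census."""
    post = df[df.time_h > after]
    dom = post[post.n_sg2m > post.n_g1].time_h.values
    runs = []
    if dom.size:
        s = e = dom[0]
        for x in dom[1:]:
            if x <= e + 1:
                e = x
            else:
                runs.append((s, e))
                s = e = x
        runs.append((s, e))
    return runs
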