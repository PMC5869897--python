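import numpy as np
import pandas as pd
import pytest

from cortimap import synthetic
from cortimap.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def truth():
    return synthetic.GroundTruth(seed=0)


@pytest.fixture(scope="session")
def arch32():
    return synthetic.make_architecture(32, seed=0)


@pytest.fixture(scope="session")
def dist32():
    return synthetic.make_distances(32, seed=0)


@pytest.fixture(scope="session")
def tracing32(arch32, dist32, truth):
    return synthetic.make_tracing(arch32, dist32, truth, n_injections=11)


@pytest.fixture(scope="session")
def celltypes():
    return synthetic.make_celltypes()


@pytest.fixture(scope="session")
def small_config():
    """Reduced study conditions for fast end-to-end tests."""
    return PipelineConfig(
        n_areas=12,
        seed=3,
        n_injections=8,
        cluster_restarts=10,
        n_surrogates=0,
    )


@pytest.fixture(scope="session")
def small_result(small_config):
    return run_pipeline(small_config)


@pytest.fixture(scope="session")
def full_result():
    """One full default-scale pipeline run shared across tests."""
    return run_pipeline(PipelineConfig())


def make_tiny_arch():
    """Hand-built, fully measured four-area architecture table."""
    areas = ["V1x", "V2x", "V3x", "THx"]
    df = pd.DataFrame(
        {
            "arch_type": [8, 6, 5, 2],
            "rho_total": [1.6e5, 1.1e5, 9.0e4, 6.0e4],
            "rho_23": [1.2e5, 8.5e4, 7.0e4, 4.8e4],
            "rho_4": [2.6e5, 1.8e5, 1.5e5, 0.0],
            "rho_5": [1.4e5, 9.0e4, 7.5e4, 5.2e4],
            "rho_6": [1.6e5, 1.1e5, 9.0e4, 6.6e4],
            "thickness_total": [1.35, 1.6, 1.8, 2.1],
            "frac_1": [0.09, 0.09, 0.09, 0.10],
            "frac_23": [0.31, 0.32, 0.33, 0.40],
            "frac_4": [0.22, 0.18, 0.15, 0.0],
            "frac_5": [0.15, 0.16, 0.17, 0.22],
            "frac_6": [0.23, 0.25, 0.26, 0.28],
            "surface": [1500.0, 1000.0, 400.0, 200.0],
            "src_density": "measured",
            "src_thickness": "measured",
        },
        index=pd.Index(areas, name="area"),
    )
    fr = [c for c in df.columns if c.startswith("frac_")]
    df[fr] = df[fr].div(df[fr].sum(axis=1), axis=0)
    df.loc["THx", "frac_4"] = 0.0
    return df


@pytest.fixture()
def tiny_arch():
    return make_tiny_arch()
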