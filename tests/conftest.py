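import numpy as np
import pandas as pd
import pytest

from maturix.simulate import SimulationConfig, simulate_design, simulate_expression


@pytest.fixture(scope="session")
def default_design():
    """The default synthetic reciprocal-cross design (18 sows, ~63 fetuses)."""
    return simulate_design(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study exercising every gene class."""
    cfg = SimulationConfig(
        seed=5,
        n_genes={
            "null": 60,
            "submodel1": 15,
            "submodel2": 15,
            "submodel3": 15,
            "submodel4": 15,
            "maternal_interaction": 10,
            "paternal_interaction": 10,
            "network_block_1": 8,
            "network_block_2": 8,
            "network_block_3": 8,
            "network_block_4": 8,
        },
    )
    design = simulate_design(cfg)
    expr, truth = simulate_expression(cfg, design)
    return cfg, design, expr, truth


def one_fetus_per_sow_design(n_per_cell: int = 3) -> pd.DataFrame:
    """A design where every sow contributes a single fetus (OLS limit)."""
    rows = []
    i = 0
    for age in ("d90", "d110"):
        for g in ("LW", "MS", "LWMS", "MSLW"):
            for _ in range(n_per_cell):
                rows.append(
                    {"sample_id": f"s{i:03d}", "sow_id": f"sow{i:03d}", "age": age,
                     "fetal_genotype": g}
                )
                i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def singleton_design():
    return one_fetus_per_sow_design()
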