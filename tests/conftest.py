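import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from betacross.config import SimulationConfig
from betacross import synthetic
from betacross.io import GROUP_CASE, GROUP_CONTROL


def make_sheet(n_control: int, n_case: int) -> pd.DataFrame:
    ids = [f"C{i}" for i in range(n_control)] + [f"P{i}" for i in range(n_case)]
    groups = [GROUP_CONTROL] * n_control + [GROUP_CASE] * n_case
    return pd.DataFrame({"sample_id": ids, "group": groups, "dataset_id": "DS1"})


def make_matrix(rows: dict, n_control: int, n_case: int) -> pd.DataFrame:
    """Probe-by-sample matrix from {probe_id: list of values} (NaN allowed)."""
    sheet = make_sheet(n_control, n_case)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(sheet["sample_id"])), sheet


@pytest.fixture(scope="session")
def small_sim():
    """A 2,000-probe synthetic study at the default design (34 + 31, 3 datasets)."""
    cfg = SimulationConfig(n_probes=2000, seed=11)
    manifest = synthetic.generate_manifest(cfg)
    beta, sheet, truth = synthetic.generate_beta(manifest, cfg)
    return cfg, manifest, beta, sheet, truth
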