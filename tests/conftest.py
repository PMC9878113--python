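import numpy as np
import pandas as pd
import pytest

from tgamir.io import ExpressionMatrix
from tgamir.simulate import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study bundle (16/group, coupling 0.7)."""
    return generate_bundle(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def null_bundle():
    """A bundle with no planted effects and no couplings."""
    cfg = SimulationConfig(
        seed=11,
        frac_de_mirna=0.0,
        frac_de_mrna=0.0,
        n_regulatory_pairs=0,
        coupling_strength=0.0,
        n_mrna=100,
        n_hf_informative_mirna=0,
    )
    return generate_bundle(cfg)


def make_matrix(values, feature_ids=None, sample_ids=None, detected=None, scale="raw", platform="miRNA"):
    values = np.asarray(values, dtype=float)
    n_f, n_s = values.shape
    feature_ids = feature_ids or [f"f{i}" for i in range(n_f)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_s)]
    vdf = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    if detected is None:
        ddf = pd.DataFrame(True, index=feature_ids, columns=sample_ids)
    else:
        ddf = pd.DataFrame(np.asarray(detected, dtype=bool), index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(vdf, ddf, scale=scale, platform=platform)


@pytest.fixture
def two_group_meta():
    """Minimal metadata: 4 TGA_RV + 4 control samples."""
    rows = []
    for i in range(4):
        rows.append((f"s{i}", "TGA_RV", False, False, 150.0, 4.0, 100.0))
    for i in range(4, 8):
        rows.append((f"s{i}", "control", None, None, None, None, None))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "group", "overt_hf", "death", "ntprobnp", "hstnt", "egfr"],
    )
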