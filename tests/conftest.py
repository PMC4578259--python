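import numpy as np
import pandas as pd
import pytest

from omicpersona.core_io import FeatureMatrix, SampleDesign
from omicpersona import synthetic as sy


def make_design(n_individuals: int, n_visits: int, chip_per_individual: bool = True):
    rows = []
    for i in range(n_individuals):
        ind = f"I{i:02d}"
        for v in range(1, n_visits + 1):
            rows.append(
                {
                    "sample_id": f"{ind}_v{v}",
                    "individual_id": ind,
                    "visit": v,
                    "group": "g1" if i % 2 == 0 else "g2",
                    "chip": f"chip{i}" if chip_per_individual else f"chip{v}",
                }
            )
    return SampleDesign(pd.DataFrame(rows))


def matrix_from_array(values: np.ndarray, design: SampleDesign, scale="trait",
                      prefix="f"):
    ids = [f"{prefix}{i}" for i in range(values.shape[0])]
    return FeatureMatrix(
        pd.DataFrame(values, index=ids, columns=design.sample_ids), scale
    )


@pytest.fixture(scope="session")
def design12():
    cfg = sy.SyntheticConfig(seed=0)
    return sy.generate_design(cfg)


@pytest.fixture(scope="session")
def small_bundle():
    """Compact full bundle exercising every planted effect."""
    cfg = sy.SyntheticConfig(
        n_genes=1500,
        cpg_per_gene=(1, 6),
        n_mirna=120,
        n_traits=30,
        seed=20,
    )
    cfg.axis_spec.n_correlated_genes = 40
    cfg.extreme_spec.n_per_individual = 12
    cfg.extreme_spec.n_meth_per_individual = 10
    cfg.ase_spec.n_sites = 600
    return cfg, sy.generate_multiomic(cfg)
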