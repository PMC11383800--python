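import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from stomascore import synth
from stomascore.variants import VariantDataset


@pytest.fixture(scope="session")
def study():
    """One small synthetic study shared across read-only tests."""
    cfg = synth.SynthConfig(seed=11, n_hist=25, n_mod=50, pool_size=150,
                            gene_length_range=(600, 2000))
    return synth.generate_study(cfg, with_climate=True)


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    synth.write_study(study, str(out))
    return out


def make_dataset(dosages, positions=None, chrom="Chr1", ann=None, **info):
    """Hand-build a VariantDataset from a dosage matrix (sites x samples)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    positions = positions if positions is not None else list(range(1, n_sites + 1))
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": positions,
            "ref": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
            "DP": info.get("DP", [30.0] * n_sites),
            "FS": info.get("FS", [0.1] * n_sites),
            "ReadPosRankSum": info.get("ReadPosRankSum", [0.0] * n_sites),
            "ann": ann if ann is not None else [[] for _ in range(n_sites)],
        }
    )
    samples = [f"S{i}" for i in range(n_samples)]
    return VariantDataset(sites, dosages, samples)
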