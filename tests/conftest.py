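import numpy as np
import pytest
from hypothesis import settings

import stdgcc
from stdgcc.training import TrainConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

# conditions of the synthetic recovery study: strips, K=5, 30x30 lattice,
# 150 genes, fold change 4, 20% dropout; scaled-down training profile
STUDY_DELTA = 150.0  # 1.5 lattice spacings: connects the 4-neighborhood


def make_study_dataset(seed: int) -> stdgcc.SyntheticDataset:
    return stdgcc.generate_dataset(seed=seed)


def study_config(seed: int, ablation: str = "full") -> TrainConfig:
    return TrainConfig.fast_profile(delta=STUDY_DELTA, seed=seed,
                                    ablation=ablation)


@pytest.fixture(scope="session")
def study_runs():
    """Full-pipeline results on the synthetic strips study, shared across
    tests: 'full' and 'no_contrastive' over 5 seeds, the other two ablation
    modes on one seed."""
    runs = {}
    for mode, seeds in (("full", range(1, 6)), ("no_contrastive", range(1, 6)),
                        ("no_decoder", [1]), ("no_vgcn", [1])):
        for seed in seeds:
            ds = make_study_dataset(seed)
            res = stdgcc.run_pipeline(ds.dataset, k=ds.spec.K,
                                      cfg=study_config(seed, mode))
            runs[(mode, seed)] = (ds, res)
    return runs


@pytest.fixture
def tiny_dataset():
    """A small, quick synthetic section for unit-level pipeline tests."""
    return stdgcc.generate_dataset(K=3, grid=(12, 12), genes=40,
                                   markers_per_domain=5, seed=7)


@pytest.fixture
def tiny_config():
    return TrainConfig.fast_profile(delta=STUDY_DELTA, seed=7, epochs=25,
                                    hvg_t=40)
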