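"""Shared fixtures.

The expensive fixtures train the boundary classifier on the default
synthetic benchmark (three 1000-bin chromosomes: one train, one validation,
one held-out test) at a given noise level, and are session-scoped so each
training happens at most once per test run.
"""

from types import SimpleNamespace

import numpy as np
import pytest

from hictad.model import BoundaryClassifier, ModelConfig
from hictad.pipeline import call_tads
from hictad.synth import SimConfig, make_benchmark


def _run_benchmark(cfg: SimConfig, n_train: int = 1) -> SimpleNamespace:
    split, sims = make_benchmark(cfg, n_train_chroms=n_train)
    fit = BoundaryClassifier(ModelConfig()).fit(split)
    test_chrom = f"chrS{n_train + 1}"
    matrix, truth = sims[test_chrom]
    result = call_tads(fit.net, matrix)
    return SimpleNamespace(cfg=cfg, split=split, sims=sims, fit=fit,
                           matrix=matrix, truth=truth, result=result)


@pytest.fixture(scope="session")
def benchmark_run():
    """Factory: full pipeline on the default benchmark at a noise level."""
    cache: dict[float, SimpleNamespace] = {}

    def run(noise: float) -> SimpleNamespace:
        if noise not in cache:
            cache[noise] = _run_benchmark(SimConfig(noise_sigma=noise))
        return cache[noise]

    return run


@pytest.fixture(scope="session")
def recovery_run() -> SimpleNamespace:
    """Noise-free benchmark with three training chromosomes (several hundred
    planted boundaries) for the parameter-recovery properties."""
    return _run_benchmark(SimConfig(noise_sigma=0.0), n_train=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
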