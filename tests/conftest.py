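"""Shared fixtures: the default error-free study scenario is expensive
enough (~5 s) to build once per session and reuse across modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def errorfree_scenario():
    from npgreat.synthetic_data import scenario

    return scenario(seed=1, error_rate=0.0)


@pytest.fixture(scope="session")
def errorfree_result(errorfree_scenario):
    from npgreat.pipeline import PipelineConfig, run_pipeline

    sc = errorfree_scenario
    return run_pipeline(sc.reads, sc.contigs, sc.probes, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(20_250_921)


def random_dna(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
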