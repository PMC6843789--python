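from types import SimpleNamespace

import numpy as np
import pytest

from epsclust.pipeline import RunConfig, run_compare, run_detect
from epsclust.synthetic_data import SimulationConfig, generate_run

BENCH_SEED = 42
SEED_ROLES = {"EpsA", "EpsB", "EpsC", "EpsD", "EpsE"}


def _run(cfg: SimulationConfig, k_groups: int = 3) -> SimpleNamespace:
    records, habitats, library, truth = generate_run(cfg)
    detect = run_detect(records, library, habitats, RunConfig(seed=1))
    compare = run_compare(detect, RunConfig(seed=1, k_groups=k_groups))
    features = {f.feature_id: f for r in records for f in r.features}
    planted = [
        cl for g in truth["genomes"].values() for cl in g["clusters"]
    ]
    return SimpleNamespace(
        cfg=cfg,
        records=records,
        habitats=habitats,
        library=library,
        truth=truth,
        detect=detect,
        compare=compare,
        features=features,
        planted=planted,
    )


@pytest.fixture(scope="session")
def bench() -> SimpleNamespace:
    """Default synthetic benchmark: 20 genomes, fixed seed, full pipeline."""
    return _run(SimulationConfig(seed=BENCH_SEED))


@pytest.fixture(scope="session")
def disjoint_bench() -> SimpleNamespace:
    """Benchmark variant with fully disjoint per-habitat family pools."""
    return _run(
        SimulationConfig(seed=BENCH_SEED, n_genomes=12, disjoint_habitat_pools=True)
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def planted_member_ids(cluster_truth: dict) -> frozenset:
    return frozenset(m["feature_id"] for m in cluster_truth["members"])


def has_detectable_seed(cluster_truth: dict) -> bool:
    return any(
        m["role"] in SEED_ROLES and not m["pseudo"] for m in cluster_truth["members"]
    )
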