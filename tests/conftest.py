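"""Shared fixtures: seeded RNGs, random annotation factories, small bundles."""

from __future__ import annotations

import numpy as np
import pytest

from tescope.annotation import TEAnnotation
from tescope.simulate import SimulationConfig, simulate_expression, simulate_te_copies


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


_CLASS_STRINGS = (
    "LTR/ERV1",
    "LTR/Gypsy",
    "DNA/hAT-Charlie",
    "LINE/L2",
    "SINE/tRNA",
    "Unknown",
    "Simple_repeat",
    "Low_complexity",
)


def random_annotation(
    rng: np.random.Generator,
    contig: str,
    start: int | None = None,
    length: int | None = None,
    class_family: str | None = None,
) -> TEAnnotation:
    start = int(rng.integers(0, 2000)) if start is None else start
    length = int(rng.integers(30, 400)) if length is None else length
    return TEAnnotation(
        contig_id=contig,
        start=start,
        end=start + length,
        strand="+" if rng.random() < 0.5 else "-",
        sw_score=int(rng.integers(1, 2000)),
        pct_divergence=round(float(rng.uniform(0, 40)), 1),
        pct_deleted=round(float(rng.uniform(0, 5)), 1),
        pct_inserted=round(float(rng.uniform(0, 5)), 1),
        repeat_name=f"rep{int(rng.integers(1, 50))}",
        repeat_class_family=str(rng.choice(_CLASS_STRINGS)),
        repeat_start=1,
        repeat_end=length,
        repeat_left=0,
        rm_id=int(rng.integers(1, 10000)),
        overlap_flag=bool(rng.random() < 0.2),
    )


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    return SimulationConfig(seed=11, reads_per_sample=5000, dispersion=0.0)


@pytest.fixture(scope="session")
def noise_free_copies(noise_free_config):
    return simulate_te_copies(noise_free_config)


@pytest.fixture(scope="session")
def noise_free_bundle(noise_free_config, noise_free_copies):
    return simulate_expression(noise_free_config, noise_free_copies, condition="development")
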