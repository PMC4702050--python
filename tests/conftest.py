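from __future__ import annotations

import numpy as np
import pytest

from degradomir.io import CollapsedRead, Library
from degradomir.synthetic import PlantSpec, make_genome, write_fixture_set


def make_library(seq_rpm: dict[str, float], kind: str = "degradome",
                 name: str = "lib") -> Library:
    """Library with prescribed RPMs (bypasses pre-treatment)."""
    reads = [CollapsedRead(s, 1, r) for s, r in seq_rpm.items()]
    return Library(name=name, kind=kind, reads=reads, total_raw=len(reads))


@pytest.fixture(scope="session")
def small_spec() -> PlantSpec:
    return PlantSpec(n_hairpins=5, genome_len=60_000, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return make_genome(small_spec)


@pytest.fixture(scope="session")
def small_fixture_set(small_spec, tmp_path_factory):
    """A complete on-disk fixture set shared across pipeline tests."""
    outdir = tmp_path_factory.mktemp("fixture_set")
    return write_fixture_set(small_spec, outdir)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
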