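"""Shared fixtures: one planted synthetic epigenome and one pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from crcpipe import RunConfig, SyntheticConfig, plant_epigenome, run_all


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """A default-condition synthetic epigenome with planted circuit."""
    out = tmp_path_factory.mktemp("sim")
    config = SyntheticConfig(seed=11)
    truth, paths = plant_epigenome(config, out)
    return config, truth, paths


@pytest.fixture(scope="session")
def pipeline_run(sim, tmp_path_factory):
    """A full default-parameter pipeline run over the shared epigenome."""
    _, truth, paths = sim
    out = tmp_path_factory.mktemp("run")
    config = RunConfig(
        peaks=str(paths["peaks"]),
        genes=str(paths["genes"]),
        genome=str(paths["genome"]),
        motifs=str(paths["motifs"]),
        signal=str(paths["signal"]),
        tf_list=str(paths["tf_list"]),
        out_dir=str(out),
    )
    result = run_all(config)
    return result, truth, paths


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
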