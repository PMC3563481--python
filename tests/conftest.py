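"""Shared fixtures: canonical synthetic scenarios and their pipeline runs.

Everything here is generated at test time from documented seeds; building
the scenario bundles and running both analysis modes is cheap enough to do
once per session and share.
"""

from __future__ import annotations

import pytest

from trbackmap.pipeline import RunConfig, RunInputs, run_tr_backmap, run_wg
from trbackmap.synth import make_fixture


@pytest.fixture(scope="session")
def clean_ts():
    return make_fixture("CLEAN")


@pytest.fixture(scope="session")
def paralog_ts():
    return make_fixture("PARALOG95")


@pytest.fixture(scope="session")
def identical_dup_ts():
    return make_fixture("IDENTICAL_DUP")


@pytest.fixture(scope="session")
def lowdepth_ts():
    return make_fixture("LOWDEPTH")


def _inputs(ts):
    return RunInputs(genome=ts.genome, targets=ts.targets, pairs=ts.pairs)


@pytest.fixture(scope="session")
def paralog_run(paralog_ts):
    """TR+backmap mode on the paralog scenario (the core mechanism demo)."""
    return run_tr_backmap(RunConfig(seed=1), inputs=_inputs(paralog_ts), write_artifacts=False)


@pytest.fixture(scope="session")
def paralog_wg_run(paralog_ts):
    return run_wg(RunConfig(seed=1), inputs=_inputs(paralog_ts), write_artifacts=False)


@pytest.fixture(scope="session")
def clean_run(clean_ts):
    return run_tr_backmap(RunConfig(seed=1), inputs=_inputs(clean_ts), write_artifacts=False)


@pytest.fixture(scope="session")
def clean_wg_run(clean_ts):
    return run_wg(RunConfig(seed=1), inputs=_inputs(clean_ts), write_artifacts=False)


@pytest.fixture(scope="session")
def identical_dup_run(identical_dup_ts):
    return run_tr_backmap(
        RunConfig(seed=1), inputs=_inputs(identical_dup_ts), write_artifacts=False
    )
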