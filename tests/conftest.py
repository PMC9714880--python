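"""Shared fixtures.

The heavy simulated sessions (full simulation-campaign counts) are
session-scoped so the behavioral acceptance checks share one set of runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from actionreg import tasks
from actionreg.config import SimConfig


@pytest.fixture(scope="session")
def cfg() -> SimConfig:
    return SimConfig()


def _session(task: str, group: str, seed: int) -> "pandas.DataFrame":
    config = SimConfig()
    specs = tasks.make_session(task, group, config, seed=seed)
    return tasks.run_session(specs, group, config, seed=seed)


@pytest.fixture(scope="session")
def decision_nt():
    """200 decision trials (100 choice / 100 instructed), neurotypical."""
    return _session("decision", "neurotypical", seed=11)


@pytest.fixture(scope="session")
def decision_pd():
    return _session("decision", "pd", seed=13)


@pytest.fixture(scope="session")
def flanker_nt():
    """200 flanker trials (100 congruent / 100 incongruent), neurotypical."""
    return _session("flanker", "neurotypical", seed=17)


@pytest.fixture(scope="session")
def flanker_pd():
    return _session("flanker", "pd", seed=19)


@pytest.fixture(scope="session")
def stop_nt():
    """100 go + 250 stop trials with the SSD staircase, neurotypical."""
    return _session("stop_signal", "neurotypical", seed=23)


@pytest.fixture(scope="session")
def stop_pd():
    return _session("stop_signal", "pd", seed=29)


@pytest.fixture(scope="session")
def all_sessions(decision_nt, decision_pd, flanker_nt, flanker_pd, stop_nt, stop_pd):
    return {
        ("decision", "neurotypical"): decision_nt,
        ("decision", "pd"): decision_pd,
        ("flanker", "neurotypical"): flanker_nt,
        ("flanker", "pd"): flanker_pd,
        ("stop_signal", "neurotypical"): stop_nt,
        ("stop_signal", "pd"): stop_pd,
    }
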