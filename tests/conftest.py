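"""Shared fixtures: one reference full-protocol run reused across modules."""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from pcrtwin import fixtures as fx
from pcrtwin.engine import run_protocol, stage_targets

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_run():
    """(protocol, config, trace, targets) for the packaged 30-cycle run."""
    protocol, _ = fx.reference_protocol()
    cfg = fx.reference_simulation_config()
    trace = run_protocol(protocol, cfg)
    return protocol, cfg, trace, stage_targets(protocol)
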