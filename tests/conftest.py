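"""Shared fixtures: simulated recordings reused across the suite.

Session scope keeps the expensive simulate+idealize work to one pass.
"""

import pytest

from poregram import pipeline, synth


@pytest.fixture(scope="session")
def channel():
    return synth.ChannelModel()


@pytest.fixture(scope="session")
def unit_model():
    return synth.UnitModel()


@pytest.fixture(scope="session")
def octamer_plan():
    return synth.ConcatemerPlan(n_units=8)


@pytest.fixture(scope="session")
def octamer_recording(channel, unit_model, octamer_plan):
    """A 6 s octamer recording (C-first forced) plus ground truth."""
    return synth.simulate_trace(
        channel, unit_model, octamer_plan, duration=6.0, seed=42,
        force_direction="C_first",
    )


@pytest.fixture(scope="session")
def octamer_analysis(octamer_recording):
    """Full idealization + parse + stats of the shared octamer recording."""
    trace, _ = octamer_recording
    ideal, events, stats = pipeline.analyze_trace(trace)
    return ideal, events, stats


@pytest.fixture(scope="session")
def nonamer_gsh_recording():
    """Nonamer with a glutathionylated unit 5, dense capture for speed."""
    ch = synth.ChannelModel(analyte_conc=4.0)
    plan = synth.ConcatemerPlan(n_units=9, ptm_unit_index=5)
    return synth.simulate_trace(
        ch, synth.UnitModel(), plan, ptm=synth.PTM_PRESETS["GSH"],
        duration=6.0, seed=7, force_direction="C_first",
    )


@pytest.fixture(scope="session")
def nonamer_gsh_stats(nonamer_gsh_recording):
    trace, gt = nonamer_gsh_recording
    events, stats = pipeline.stats_from_ground_truth(trace, gt)
    return events, stats
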