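"""End-to-end convenience: trace -> idealization -> parsed events -> stats.

Idealization (event detection and change-point segmentation) runs on the
acquisition-bandwidth trace; the 2 kHz zero-phase post-filter is applied
only for rms-noise measurement, matching how the quadrature-corrected noise
is defined.
"""

from __future__ import annotations

import pandas as pd

from . import grammar, idealize, levelstats
from .trace_io import Trace

POSTFILTER_HZ = 2_000.0


def analyze_trace(
    trace: Trace,
    band_table: dict | None = None,
    baseline: float | None = None,
    threshold_frac: float = 0.9,
    min_return_frac: float = 0.95,
    penalty: float | None = None,
    postfilter_hz: float = POSTFILTER_HZ,
):
    """Run the full analysis on one trace.

    Returns ``(ideal, events, stats)``: the idealization, the parsed
    translocation events, and the per-level statistics table.
    """
    ideal = idealize.idealize_trace(
        trace, baseline=baseline, threshold_frac=threshold_frac,
        min_return_frac=min_return_frac, penalty=penalty,
    )
    events = grammar.parse_idealization(ideal, band_table)
    trace2k = idealize.postfilter(trace, postfilter_hz)
    open_rms2k = levelstats.open_pore_rms(trace2k, ideal.event_windows)
    stats = levelstats.annotate_events(
        events, trace, trace2k, ideal.baseline_pA, open_rms2k
    )
    return ideal, events, stats


def stats_from_ground_truth(trace: Trace, gt, postfilter_hz: float = POSTFILTER_HZ):
    """Parse and annotate events directly from simulator ground truth.

    Bypasses idealization: level boundaries come from the ground-truth
    record, so this isolates the statistics stage from segmentation error
    (and is the fast path for large synthetic cohorts).
    """
    from .idealize import EventWindow, LevelSegment

    baseline = float(trace.metadata.get("open_current_pA"))
    windows, events = [], []
    for eid, ev in enumerate(gt.events):
        if not ev.levels:
            continue
        windows.append(
            EventWindow(ev.levels[0].start_idx, ev.levels[-1].end_idx, ev.complete)
        )
        labelled = []
        for lv in ev.levels:
            seg = LevelSegment(
                lv.start_idx, lv.end_idx, lv.mean_pA, lv.rms_pA, lv.dwell_ms
            )
            labelled.append((lv.label, seg))
        events.append(grammar.parse_event(labelled, complete=ev.complete, event_id=eid))
    trace2k = idealize.postfilter(trace, postfilter_hz)
    open_rms2k = levelstats.open_pore_rms(trace2k, windows)
    stats = levelstats.annotate_events(events, trace, trace2k, baseline, open_rms2k)
    return events, stats


def events_to_table(events, stats: pd.DataFrame) -> pd.DataFrame:
    """Alias exposing the stats table in event-table column order."""
    return stats
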