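"""Parsing idealized levels into the translocation grammar.

A translocation event reads, left to right: an optional initial spike to
~0 pA (the first unit passing the pore rapidly), then repeats of a
three-level feature — A (C-terminus-first threading: A1 linker, A2 partly
unfolded Trx, A3 unfolding/passage) or B (N-terminus-first). An n-unit
concatemer yields at most n-1 repeats after the spike. Direction is assigned
from the feature kinds: all A -> C-first, all B -> N-first, a block of B
strictly after a block of A -> mixed (disulfide-linked double constructs);
anything else is unknown. Levels that do not fit the grammar are recorded as
parse residue, never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .idealize import LevelSegment

#: Default residual-current bands (% of open current), half-open with a
#: shared boundary belonging to the LOWER band. Matched to the synthetic
#: generator defaults; real recordings should calibrate or override.
DEFAULT_BANDS = {
    "spike": (0.0, 2.0),
    "A3": (2.0, 5.0),
    "B3": (5.0, 9.0),
    "A1": (12.0, 18.0),
    "B1": (18.0, 25.0),
    "A2": (25.0, 35.0),
    "B2": (35.0, 45.0),
}

#: A spike smeared by the analog filter can land above the spike band; a
#: leading terminal-level label this short is still read as the spike.
SPIKE_MAX_DWELL_MS = 2.0


@dataclass
class UnitFeature:
    """One three-level repeat (A1/A2/A3 or B1/B2/B3) of a translocation.

    ``levels`` holds (label, LevelSegment) pairs in time order. A complete
    feature has all three levels; ``missing_level`` marks a feature whose
    X2 or X3 was too brief to idealize (undersampled fast level), and
    ``truncated`` one cut off by the end of the trace.
    """

    kind: str  # "A" | "B"
    levels: list  # of (label, LevelSegment)
    truncated: bool = False
    missing_level: bool = False

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.levels]


@dataclass
class TranslocationEvent:
    """A parsed capture-to-exit episode."""

    spike: LevelSegment | None
    features: list  # of UnitFeature
    direction: str  # "C_first" | "N_first" | "mixed" | "unknown"
    complete: bool
    residue: list = field(default_factory=list)  # unparsed (label, LevelSegment)
    event_id: int = -1

    @property
    def n_repeats(self) -> int:
        return len(self.features)


def _validate_bands(band_table: dict) -> list[tuple[str, float, float]]:
    bands = sorted(((lab, lo, hi) for lab, (lo, hi) in band_table.items()), key=lambda t: t[1])
    for (la, lo_a, hi_a), (lb, lo_b, hi_b) in zip(bands, bands[1:]):
        if lo_b < hi_a:  # shared endpoints allowed, interior overlap not
            raise ValueError(f"bands {la} and {lb} overlap")
    return bands


def classify_level(
    segment: LevelSegment, baseline: float, band_table: dict | None = None
) -> str:
    """Label a segment by the residual-current band containing its mean.

    A value on a shared band boundary is assigned to the lower band.
    Returns ``"unassigned"`` when no band contains the value.
    """
    bands = _validate_bands(band_table or DEFAULT_BANDS)
    ires = segment.mean_pA / baseline * 100.0
    for lab, lo, hi in bands:
        if lo <= ires <= hi:
            return lab
    return "unassigned"


def calibrate_bands(
    ires_values: np.ndarray, labels_by_rank: list[str], random_state: int = 0
) -> dict:
    """Derive a band table from a level-mean histogram by 1-D k-means.

    Clusters the observed I_res% values into ``len(labels_by_rank)`` classes
    and labels the clusters by ascending center; band edges are midpoints
    between adjacent centers (outermost edges padded by one cluster sd).
    """
    from sklearn.cluster import KMeans

    x = np.asarray(ires_values, dtype=float).reshape(-1, 1)
    k = len(labels_by_rank)
    km = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit(x)
    centers = np.sort(km.cluster_centers_.ravel())
    edges = np.empty(k + 1)
    edges[1:-1] = (centers[:-1] + centers[1:]) / 2
    pad = np.median(np.diff(centers)) / 2 if k > 1 else 5.0
    edges[0] = max(centers[0] - pad, 0.0)
    edges[-1] = centers[-1] + pad
    return {lab: (float(edges[i]), float(edges[i + 1])) for i, lab in enumerate(labels_by_rank)}


def parse_event(
    labelled_levels: list[tuple[str, LevelSegment]],
    complete: bool = True,
    event_id: int = -1,
) -> TranslocationEvent:
    """Greedy left-to-right parse of time-ordered labelled levels.

    The optional spike is taken from the levels before the first X1: the
    deepest one shorter than :data:`SPIKE_MAX_DWELL_MS` (filtering can lift
    a true spike out of its nominal band, so terminal-band and unassigned
    labels qualify there too). Each feature is anchored on an X1 level and
    greedily absorbs X2 then X3 of the same kind; sub-dead-time segments
    encountered mid-feature are filter-edge artifacts, recorded as residue
    and skipped without ending the feature. A feature missing its X2 or X3
    (undersampled fast level) is kept and flagged ``missing_level``; an
    (X1,) or (X1, X2) prefix at the end of a trace-truncated event is kept
    as a truncated feature and makes the event incomplete. Everything else
    is parse residue, never silently dropped.
    """
    if not labelled_levels:
        raise ValueError("empty level list")
    residue: list = []
    levels = list(labelled_levels)
    n = len(levels)

    # spike: scan up to the first X1 anchor
    spike = None
    i = 0
    lead: list[tuple[str, LevelSegment]] = []
    while i < n and levels[i][0] not in ("A1", "B1"):
        lead.append(levels[i])
        i += 1
    for pool in (
        [seg for lab, seg in lead if lab == "spike"],
        [seg for lab, seg in lead
         if lab in ("A3", "B3", "unassigned") and not seg.sub_dead_time
         and seg.dwell_ms < SPIKE_MAX_DWELL_MS],
    ):
        if pool:
            spike = min(pool, key=lambda s: s.mean_pA)
            break
    residue.extend((lab, seg) for lab, seg in lead if seg is not spike)

    # Features are anchored on a full-size X1 — or a full-size X2 when the
    # X1 itself was undersampled (an X2 level cannot occur outside a
    # repeat). Sub-dead-time segments never anchor: they are mostly
    # filter-edge artifacts whose means land in arbitrary bands.
    features: list[UnitFeature] = []
    truncated_final = False
    while i < n:
        lab, seg = levels[i]
        full_size = not getattr(seg, "sub_dead_time", False)
        if not (full_size and lab in ("A1", "B1", "A2", "B2")):
            residue.append((lab, seg))
            i += 1
            continue
        kind = lab[0]
        got = [(lab, seg)]
        i += 1
        expect = [f"{kind}2", f"{kind}3"] if lab[1] == "1" else [f"{kind}3"]
        while expect and i < n:
            lab2, seg2 = levels[i]
            if lab2 == expect[0]:
                got.append((lab2, seg2))
                expect.pop(0)
                i += 1
            elif len(expect) == 2 and lab2 == expect[1]:
                got.append((lab2, seg2))  # X2 missing, X3 present
                expect.clear()
                i += 1
            elif getattr(seg2, "sub_dead_time", False):
                residue.append((lab2, seg2))  # filter-edge artifact
                i += 1
            else:
                break
        at_end = i >= n
        if len(got) == 3:
            features.append(UnitFeature(kind, got))
        elif not complete and at_end:
            features.append(UnitFeature(kind, got, truncated=True))
            truncated_final = True
        else:
            features.append(UnitFeature(kind, got, missing_level=True))

    kinds = [f.kind for f in features]
    if not kinds:
        direction = "unknown"
    elif all(k == "A" for k in kinds):
        direction = "C_first"
    elif all(k == "B" for k in kinds):
        direction = "N_first"
    elif kinds == sorted(kinds):  # A-block then B-block (A < B)
        direction = "mixed"
    else:
        direction = "unknown"

    return TranslocationEvent(
        spike=spike,
        features=features,
        direction=direction,
        complete=complete and not truncated_final,
        residue=residue,
        event_id=event_id,
    )


def parse_idealization(ideal, band_table: dict | None = None) -> list[TranslocationEvent]:
    """Label and parse every event of an :class:`~poregram.idealize.Idealization`."""
    events = []
    for eid, (win, segs) in enumerate(zip(ideal.event_windows, ideal.segments)):
        if not segs:
            continue
        labelled = [
            (classify_level(s, ideal.baseline_pA, band_table), s) for s in segs
        ]
        events.append(parse_event(labelled, complete=win.complete, event_id=eid))
    return events


def repeat_census(events: list[TranslocationEvent]):
    """Histogram of repeat counts by direction, plus the C:N ratio.

    Returns ``(counts_df, ratio_info)`` where ``counts_df`` has columns
    (direction, n_repeats, count) and ``ratio_info`` is a dict with the
    C-first:N-first ratio and its 95% binomial (Wilson) confidence interval.
    A zero N-first count yields an infinite ratio with ``undefined=True``.
    """
    import pandas as pd

    rows: dict = {}
    for ev in events:
        key = (ev.direction, ev.n_repeats)
        rows[key] = rows.get(key, 0) + 1
    counts = pd.DataFrame(
        [(d, r, c) for (d, r), c in sorted(rows.items())],
        columns=["direction", "n_repeats", "count"],
    )
    n_c = sum(1 for ev in events if ev.direction == "C_first")
    n_n = sum(1 for ev in events if ev.direction == "N_first")
    info = {"n_C": n_c, "n_N": n_n, "undefined": False}
    if n_c + n_n == 0:
        info.update(ratio=math.nan, ci=(math.nan, math.nan), undefined=True)
    elif n_n == 0:
        lo, _ = proportion_confint(n_c, n_c + n_n, alpha=0.05, method="wilson")
        info.update(ratio=math.inf, ci=(lo / (1 - lo) if lo < 1 else math.inf, math.inf),
                    undefined=True)
    else:
        p = n_c / (n_c + n_n)
        lo, hi = proportion_confint(n_c, n_c + n_n, alpha=0.05, method="wilson")
        info.update(
            ratio=p / (1 - p),
            ci=(lo / (1 - lo), hi / (1 - hi) if hi < 1 else math.inf),
        )
    return counts, info
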