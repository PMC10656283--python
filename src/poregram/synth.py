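"""Synthetic single-channel recordings of co-translocational unfolding events.

Simulates the current signature of an anion-selective alpha-hemolysin pore
threading a thioredoxin(Trx)-linker concatemer under electro-osmotic flow:
an open-pore baseline with Gaussian noise, Poisson capture at rate k*C,
and per-event level sequences following the translocation grammar — an
initial spike to ~0 pA (the first unit passing rapidly), then up to n-1
three-level repeat features, feature A for C-terminus-first threading or
feature B for N-terminus-first. Post-translational modifications on a chosen
unit deepen that unit's A1/B1 blockade and raise its noise.

The generated piecewise-constant signal is passed through a 4-pole low-pass
Bessel filter emulating the recording amplifier's analog filter, then
"sampled" on the acquisition grid. Ground-truth level boundaries are emitted
in sample coordinates after compensating the filter's group delay.

Randomness: one ``numpy.random.Generator`` stream drives every draw, in a
fixed documented order (per event: inter-event wait, direction, spike depth;
then per feature: level dwells with the A3 mixture component drawn first;
finally one vectorized Gaussian noise draw per segment, in signal order).
Fixed seed + fixed inputs -> bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .trace_io import Trace

SPIKE_DWELL_MS = 0.5  # fixed default spike duration
SPIKE_MAX_FRAC = 0.02  # spike depth drawn uniformly on [0, 2%] of open current

# Construct geometry: thioredoxin repeat unit (C32S/C35S) and inter-unit
# linker lengths, the contour length per residue of an extended chain, and
# the length of the alpha-hemolysin lumen the linker must span.
TRX_LENGTH_AA = 108
LINKER_LENGTH_AA = 29
CONTOUR_NM_PER_AA = 0.35
PORE_LUMEN_NM = 10.0


def concatemer_length_aa(n_units: int, has_C_terminal_linker: bool = False) -> int:
    """Total residues of an n-unit Trx-linker concatemer."""
    n_linkers = n_units if has_C_terminal_linker else n_units - 1
    return n_units * TRX_LENGTH_AA + n_linkers * LINKER_LENGTH_AA


def linker_span_nm() -> float:
    """Contour length of one fully extended linker."""
    return LINKER_LENGTH_AA * CONTOUR_NM_PER_AA


@dataclass
class ChannelModel:
    """Open-pore and capture properties of the engineered nanopore."""

    open_current: float = 100.0  # pA at +140 mV
    open_rms: float = 1.5  # pA, pre-filter white-noise sd
    voltage: float = 140.0  # mV (trans)
    capture_rate_per_uM: float = 2.50  # events s^-1 uM^-1
    analyte_conc: float = 0.81  # uM

    def __post_init__(self) -> None:
        if self.open_current <= 0:
            raise ValueError("open_current must be > 0")
        if self.capture_rate_per_uM < 0:
            raise ValueError("capture_rate_per_uM must be >= 0")

    @property
    def event_rate(self) -> float:
        """Expected captures per second of open-pore time (k * C)."""
        return self.capture_rate_per_uM * self.analyte_conc


@dataclass
class UnitModel:
    """Per-unit level currents (as % of open pore) and dwell-time law.

    A-feature levels: A1 a threaded linker, A2 the partly unfolded Trx
    C-terminal segment, A3 the final unfolding/passage (near 0 pA).
    B-feature levels describe N-terminus-first threading and default to
    values distinct from A. A3 dwell times follow a two-component
    exponential mixture; the final feature of an event uses its own mixture
    (long-lived final A3) with a heavier slow component.
    """

    ires_A1: float = 15.0
    ires_A2: float = 30.0
    ires_A3: float = 3.5
    ires_B1: float = 21.0
    ires_B2: float = 40.0
    ires_B3: float = 7.0
    mean_dwell_A1: float = 10.0  # ms, single exponential
    mean_dwell_A2: float = 5.0  # ms, single exponential
    dwell_A3_mixture: list = field(default_factory=lambda: [(0.97, 0.69), (0.03, 320.0)])
    dwell_A3_mixture_final: list | None = field(
        default_factory=lambda: [(0.75, 0.69), (0.25, 320.0)]
    )
    direction_prob_C_first: float = 10.0 / 11.0

    def __post_init__(self) -> None:
        for name in ("ires_A1", "ires_A2", "ires_A3", "ires_B1", "ires_B2", "ires_B3"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be within [0, 100], got {v}")
        if not 0 <= self.direction_prob_C_first <= 1:
            raise ValueError("direction_prob_C_first must be a probability")
        for mix in (self.dwell_A3_mixture, self.dwell_A3_mixture_final):
            if mix is None:
                continue
            ws = [w for w, _ in mix]
            if any(w < 0 for w in ws):
                raise ValueError("mixture weights must be >= 0")
            if abs(sum(ws) - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must sum to 1, got {sum(ws)}")

    def level_ires(self, kind: str) -> tuple[float, float, float]:
        if kind == "A":
            return self.ires_A1, self.ires_A2, self.ires_A3
        if kind == "B":
            return self.ires_B1, self.ires_B2, self.ires_B3
        raise ValueError(f"unknown feature kind {kind!r}")


@dataclass
class PTMModel:
    """Effect of a post-translational modification on the A1/B1 level."""

    species: str  # "P" | "GSH" | "SLN"
    delta_ires: float  # percentage-point reduction of the A1 residual current
    rms_boost: float  # pA of extra white noise, added in quadrature
    nominal_mass: float  # Da

    def __post_init__(self) -> None:
        if self.delta_ires < 0:
            raise ValueError("delta_ires must be >= 0")
        if self.rms_boost < 0:
            raise ValueError("rms_boost must be >= 0")


# Synthetic calibration presets. The per-species blockade increments are
# chosen to rise with modification mass (phosphate < glutathione <
# 6'-sialyllactosamine), as observed for real recordings; absolute values
# are this package's defaults, not measured constants.
PTM_PRESETS = {
    "P": PTMModel("P", delta_ires=1.2, rms_boost=3.0, nominal_mass=80.0),
    "GSH": PTMModel("GSH", delta_ires=2.2, rms_boost=4.0, nominal_mass=305.3),
    "SLN": PTMModel("SLN", delta_ires=3.8, rms_boost=5.5, nominal_mass=656.6),
}


@dataclass
class ConcatemerPlan:
    """Construct layout: number of Trx-linker units and optional PTM site."""

    n_units: int = 8
    ptm_unit_index: int | None = None  # 1-based, counted in threading order
    has_C_terminal_linker: bool = False

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.ptm_unit_index is not None and not 1 <= self.ptm_unit_index <= self.n_units:
            raise ValueError("ptm_unit_index out of range")


@dataclass
class LevelSpec:
    """One planned constant-current stretch (pre-noise, pre-filter)."""

    label: str  # "open" | "spike" | "A1".."A3" | "B1".."B3"
    feature_idx: int  # 1-based feature number; 0 for spike/open
    mean_pA: float
    rms_pA: float
    dwell_ms: float


@dataclass
class GTEvent:
    direction: str  # "C_first" | "N_first"
    levels: list  # of GTLevel
    ptm_unit_index: int | None
    complete: bool


@dataclass
class GTLevel:
    label: str
    feature_idx: int
    start_idx: int
    end_idx: int  # half-open
    mean_pA: float
    rms_pA: float
    dwell_ms: float


@dataclass
class GroundTruth:
    """Per-event truth emitted alongside a simulated trace."""

    events: list  # of GTEvent
    open_time_s: float  # total open-pore (inter-event) time generated

    def to_frame(self):
        import pandas as pd

        rows = []
        for eid, ev in enumerate(self.events):
            for lv in ev.levels:
                rows.append(
                    dict(
                        event_id=eid,
                        direction=ev.direction,
                        complete=ev.complete,
                        ptm_unit_index=-1 if ev.ptm_unit_index is None else ev.ptm_unit_index,
                        label=lv.label,
                        feature_idx=lv.feature_idx,
                        start_idx=lv.start_idx,
                        end_idx=lv.end_idx,
                        mean_pA=lv.mean_pA,
                        rms_pA=lv.rms_pA,
                        dwell_ms=lv.dwell_ms,
                    )
                )
        cols = [
            "event_id", "direction", "complete", "ptm_unit_index", "label",
            "feature_idx", "start_idx", "end_idx", "mean_pA", "rms_pA", "dwell_ms",
        ]
        return pd.DataFrame(rows, columns=cols)


def inject_ptm_level(
    feature_levels: list[LevelSpec],
    ptm: PTMModel,
    open_pA: float,
    unit_is_modified: bool,
) -> list[LevelSpec]:
    """Apply a PTM's signature to the A1/B1 level of one feature.

    The A1 mean is lowered by ``delta_ires`` percentage points of the open
    current and the level noise becomes ``sqrt(rms^2 + rms_boost^2)``; the
    other levels are untouched. With ``unit_is_modified=False`` (or a null
    modification) the input is returned unchanged.
    """
    if not any(lv.label in ("A1", "B1") for lv in feature_levels):
        raise ValueError("feature has no A1/B1 level")
    if not unit_is_modified:
        return list(feature_levels)
    out = []
    for lv in feature_levels:
        if lv.label in ("A1", "B1"):
            new_mean = lv.mean_pA - ptm.delta_ires / 100.0 * open_pA
            if new_mean < 0:
                raise ValueError(
                    f"delta_ires={ptm.delta_ires} drives {lv.label} below 0 pA"
                )
            new_rms = float(np.hypot(lv.rms_pA, ptm.rms_boost))
            out.append(replace(lv, mean_pA=new_mean, rms_pA=new_rms))
        else:
            out.append(lv)
    return out


def sample_a3_dwell(rng: np.random.Generator, mixture) -> tuple[float, int]:
    """Draw one dwell (ms) from an exponential mixture; returns (dwell, component)."""
    weights = np.array([w for w, _ in mixture])
    comp = int(rng.choice(len(mixture), p=weights / weights.sum()))
    return float(rng.exponential(mixture[comp][1])), comp


def draw_inter_event_waits(rng: np.random.Generator, rate: float, n: int) -> np.ndarray:
    """Exponential inter-event open-pore waits (s) at capture rate ``rate`` (s^-1)."""
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, size=n)


def _plan_event(
    rng: np.random.Generator,
    channel: ChannelModel,
    unit: UnitModel,
    plan: ConcatemerPlan,
    ptm: PTMModel | None,
    force_direction: str | None,
) -> tuple[str, list[LevelSpec]]:
    """Draw one event's level sequence. Draw order: direction, spike depth,
    then per feature the three dwells (A3 mixture component first)."""
    if force_direction is not None:
        direction = force_direction
    else:
        direction = "C_first" if rng.random() < unit.direction_prob_C_first else "N_first"
    kind = "A" if direction == "C_first" else "B"
    spike_pA = rng.uniform(0.0, SPIKE_MAX_FRAC) * channel.open_current
    levels = [LevelSpec("spike", 0, spike_pA, channel.open_rms, SPIKE_DWELL_MS)]
    n_feat = plan.n_units - 1
    i1, i2, i3 = unit.level_ires(kind)
    final_mix = unit.dwell_A3_mixture_final or unit.dwell_A3_mixture
    for f in range(1, n_feat + 1):
        mix = final_mix if f == n_feat else unit.dwell_A3_mixture
        d3, _ = sample_a3_dwell(rng, mix)
        d1 = float(rng.exponential(unit.mean_dwell_A1))
        d2 = float(rng.exponential(unit.mean_dwell_A2))
        feat = [
            LevelSpec(f"{kind}1", f, i1 / 100 * channel.open_current, channel.open_rms, d1),
            LevelSpec(f"{kind}2", f, i2 / 100 * channel.open_current, channel.open_rms, d2),
            LevelSpec(f"{kind}3", f, i3 / 100 * channel.open_current, channel.open_rms, d3),
        ]
        # The spike consumes the first threaded unit, so feature f maps to
        # unit f+1 in threading order.
        if ptm is not None and plan.ptm_unit_index is not None:
            feat = inject_ptm_level(
                feat, ptm, channel.open_current, unit_is_modified=(f + 1 == plan.ptm_unit_index)
            )
        levels.extend(feat)
    return direction, levels


def analog_filter_sos(cutoff_hz: float, sample_rate: float):
    """4-pole low-pass Bessel (magnitude-normalized) as second-order sections."""
    return _sig.bessel(4, cutoff_hz, fs=sample_rate, output="sos", norm="mag")


def analog_group_delay_samples(cutoff_hz: float, sample_rate: float) -> int:
    """Low-frequency group delay of the analog-emulation filter, in samples."""
    sos = analog_filter_sos(cutoff_hz, sample_rate)
    b, a = _sig.sos2tf(sos)
    w, gd = _sig.group_delay((b, a), w=np.array([1e-4]))
    return int(round(float(gd[0])))


def simulate_trace(
    channel: ChannelModel,
    unit: UnitModel,
    plan: ConcatemerPlan,
    ptm: PTMModel | None = None,
    duration: float = 10.0,
    sample_rate: float = 50_000.0,
    analog_cutoff: float = 10_000.0,
    seed: int = 0,
    force_direction: str | None = None,
) -> tuple[Trace, GroundTruth]:
    """Simulate a recording of ``duration`` seconds.

    The trace alternates open-pore stretches (exponential waits at rate
    ``k * C``; the capture clock pauses during events) with translocation
    events drawn from the concatemer plan. The full piecewise signal plus
    white Gaussian noise is low-pass filtered at ``analog_cutoff`` (4-pole
    Bessel) and returned at ``sample_rate``; ground-truth boundaries are
    shifted by the filter's group delay so they index the filtered trace.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if sample_rate <= 2 * analog_cutoff:
        raise ValueError("sample_rate must exceed twice the analog cutoff")

    rng = np.random.default_rng(seed)
    n_total = int(round(duration * sample_rate))
    rate = channel.event_rate

    segs: list[LevelSpec] = []  # in signal order
    gt_events: list[GTEvent] = []
    seg_event: list[int] = []  # event id per segment, -1 for open pore
    pos = 0
    open_samples = 0
    while pos < n_total:
        wait_s = float(draw_inter_event_waits(rng, rate, 1)[0])
        n_open = n_total - pos if not np.isfinite(wait_s) else int(round(wait_s * sample_rate))
        n_open = min(max(n_open, 1), n_total - pos)
        segs.append(LevelSpec("open", 0, channel.open_current, channel.open_rms, n_open / sample_rate * 1e3))
        seg_event.append(-1)
        pos += n_open
        open_samples += n_open
        if pos >= n_total:
            break
        direction, levels = _plan_event(rng, channel, unit, plan, ptm, force_direction)
        eid = len(gt_events)
        gt_levels = []
        complete = True
        for lv in levels:
            n_lv = max(int(round(lv.dwell_ms / 1e3 * sample_rate)), 1)
            if pos + n_lv > n_total:
                n_lv = n_total - pos
                complete = False
            if n_lv <= 0:
                complete = False
                break
            segs.append(replace(lv, dwell_ms=n_lv / sample_rate * 1e3))
            seg_event.append(eid)
            gt_levels.append(
                GTLevel(lv.label, lv.feature_idx, pos, pos + n_lv, lv.mean_pA, lv.rms_pA,
                        n_lv / sample_rate * 1e3)
            )
            pos += n_lv
        gt_events.append(GTEvent(direction, gt_levels, plan.ptm_unit_index, complete))

    # assemble signal; one vectorized noise draw per segment, in order
    x = np.empty(n_total)
    cursor = 0
    for lv in segs:
        n_lv = int(round(lv.dwell_ms / 1e3 * sample_rate))
        x[cursor : cursor + n_lv] = lv.mean_pA + rng.normal(0.0, lv.rms_pA, size=n_lv)
        cursor += n_lv
    assert cursor == n_total

    sos = analog_filter_sos(analog_cutoff, sample_rate)
    zi = _sig.sosfilt_zi(sos) * x[0]
    y, _ = _sig.sosfilt(sos, x, zi=zi)

    gd = analog_group_delay_samples(analog_cutoff, sample_rate)
    for ev in gt_events:
        for lv in ev.levels:
            lv.start_idx = min(lv.start_idx + gd, n_total)
            lv.end_idx = min(lv.end_idx + gd, n_total)
        ev.levels = [lv for lv in ev.levels if lv.end_idx > lv.start_idx]

    meta = dict(
        open_current_pA=channel.open_current,
        open_rms_pA=channel.open_rms,
        voltage_mv=channel.voltage,
        analyte_conc_uM=channel.analyte_conc,
        capture_rate_per_uM=channel.capture_rate_per_uM,
        analog_cutoff_hz=analog_cutoff,
        temperature_C=24.0,
        chaotrope="750 mM GdnHCl",
        units="pA",
        seed=seed,
    )
    trace = Trace(y, sample_rate, meta)
    return trace, GroundTruth(gt_events, open_samples / sample_rate)
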