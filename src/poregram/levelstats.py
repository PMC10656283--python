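"""Per-level statistics: I_res%, quadrature-corrected rms noise, dIres%.

Definitions
-----------
* ``I_res% = level_mean / I_open * 100`` — residual current as a percentage
  of the open-pore current.
* Corrected rms noise: ``rms_corr = sqrt(rms_level^2 - rms_open^2)``, both
  measured on the 2 kHz post-filtered signal; clipped to 0 (and flagged)
  when the open-pore noise exceeds the level noise.
* ``dIres%`` of a candidate feature: mean I_res%(A1) of the OTHER features
  of the same event minus the candidate's I_res%(A1). Never pooled across
  events.
* Exclusion rule: an A3/B3 level with dwell < 1 ms is excluded from the
  I_res% analysis (possible undersampling); A1/A2 levels are never
  dwell-excluded.

White noise injected at the acquisition rate is attenuated by the analog
and post-recording filters; :func:`noise_attenuation_factor` computes the
variance transfer of that chain analytically so an injected noise boost can
be reported on its pre-filter scale (:func:`estimate_rms_boost`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .grammar import TranslocationEvent
from .trace_io import Trace

EXCLUDE_DWELL_MS = 1.0  # A3/B3 dwell threshold for the undersampling exclusion
MEAN_GUARD_MS = 0.1  # edge guard when measuring level means (acquisition BW)
RMS_GUARD_MS = 0.3  # edge guard when measuring rms on the 2 kHz signal


def residual_current_pct(level_mean_pA: float, open_pA: float) -> float:
    """Residual current as a percentage of the open-pore current."""
    if open_pA <= 0:
        raise ValueError("open-pore current must be > 0")
    return level_mean_pA / open_pA * 100.0


def rms_corrected(level_rms_pA: float, open_rms_pA: float) -> tuple[float, bool]:
    """Quadrature subtraction of open-pore noise; returns (rms, clipped).

    ``clipped`` is True when the level noise is below the open-pore noise,
    in which case 0 is returned instead of an imaginary value.
    """
    if level_rms_pA < 0 or open_rms_pA < 0:
        raise ValueError("rms inputs must be >= 0")
    d = level_rms_pA**2 - open_rms_pA**2
    if d < 0:
        return 0.0, True
    return float(np.sqrt(d)), False


def noise_attenuation_factor(
    sample_rate: float, analog_cutoff: float = 10_000.0, post_cutoff: float | None = 2_000.0
) -> float:
    """Variance transfer of white noise through the acquisition/analysis chain.

    The chain is the causal 4-pole Bessel analog-emulation filter at
    ``analog_cutoff`` followed (optionally) by the zero-phase 4-pole Bessel
    post-filter at ``post_cutoff`` (forward-backward, hence |H|^4 in power).
    Returns the ratio of output to input noise variance.
    """
    w = np.linspace(0, np.pi, 4096)
    sos1 = _sig.bessel(4, analog_cutoff, fs=sample_rate, output="sos", norm="mag")
    _, h1 = _sig.sosfreqz(sos1, worN=w)
    g = np.abs(h1) ** 2
    if post_cutoff is not None:
        sos2 = _sig.bessel(4, post_cutoff, fs=sample_rate, output="sos", norm="mag")
        _, h2 = _sig.sosfreqz(sos2, worN=w)
        g = g * np.abs(h2) ** 4
    return float(np.mean(g))


def estimate_rms_boost(
    rms_corr_pA: float,
    sample_rate: float,
    analog_cutoff: float = 10_000.0,
    post_cutoff: float = 2_000.0,
) -> float:
    """Pre-filter white-noise boost implied by a measured corrected rms."""
    a = noise_attenuation_factor(sample_rate, analog_cutoff, post_cutoff)
    return rms_corr_pA / np.sqrt(a)


def _guarded(x: np.ndarray, start: int, end: int, guard: int) -> np.ndarray:
    g = guard if end - start > 2 * guard + 2 else 0
    return x[start + g : end - g]


def mean_variance_inflation(sample_rate: float, analog_cutoff: float = 10_000.0) -> float:
    """Inflation of var(level mean) due to noise correlation from the analog filter.

    For white noise of post-filter variance s^2 observed through a low-pass
    filter H, the variance of an n-sample mean is ``s^2/n * |H(0)|^2 /
    mean(|H|^2)`` rather than ``s^2/n``. Returns that inflation factor.
    """
    return 1.0 / noise_attenuation_factor(sample_rate, analog_cutoff, post_cutoff=None)


def open_pore_rms(trace2k: Trace, event_windows, guard_ms: float = RMS_GUARD_MS) -> float:
    """Rms noise of the open pore on the post-filtered trace.

    Measured on inter-event stretches, with a guard margin around each event.
    """
    fs = trace2k.sample_rate
    guard = int(round(guard_ms / 1e3 * fs))
    mask = np.ones(trace2k.samples.size, dtype=bool)
    for w in event_windows:
        s, e = w.start_idx, w.end_idx
        mask[max(s - guard, 0) : min(e + guard, mask.size)] = False
    sel = trace2k.samples[mask]
    if sel.size < 10:
        raise ValueError("no open-pore stretches available for rms measurement")
    return float(np.std(sel))


def annotate_events(
    events: list[TranslocationEvent],
    trace: Trace,
    trace2k: Trace,
    baseline_pA: float,
    open_rms2k_pA: float,
) -> pd.DataFrame:
    """Per-level statistics table for parsed events.

    One row per level (spike, feature levels, residue). Level means are
    measured on the acquisition-bandwidth trace with a small edge guard;
    rms is measured on the 2 kHz post-filtered trace with a wider guard and
    corrected by quadrature subtraction of the open-pore noise.
    """
    fs = trace.sample_rate
    analog_cutoff = float(trace.metadata.get("analog_cutoff_hz", 10_000.0))
    infl = mean_variance_inflation(fs, analog_cutoff)
    g_mean = int(round(MEAN_GUARD_MS / 1e3 * fs))
    g_rms = int(round(RMS_GUARD_MS / 1e3 * fs))
    rows = []

    def level_row(eid, fidx, label, seg, direction, complete):
        xm = _guarded(trace.samples, seg.start_idx, seg.end_idx, g_mean)
        xr = _guarded(trace2k.samples, seg.start_idx, seg.end_idx, g_rms)
        mean = float(np.mean(xm))
        rms2k = float(np.std(xr))
        rcorr, clipped = rms_corrected(rms2k, open_rms2k_pA)
        excluded = label in ("A3", "B3") and seg.dwell_ms < EXCLUDE_DWELL_MS
        sem = float(np.std(xm)) * np.sqrt(infl / max(xm.size, 1))
        rows.append(
            dict(
                event_id=eid,
                feature_idx=fidx,
                level_label=label,
                start_s=seg.start_idx / fs,
                dwell_ms=seg.dwell_ms,
                mean_pA=mean,
                ires_pct=residual_current_pct(mean, baseline_pA),
                sem_ires=residual_current_pct(sem, baseline_pA),
                rms_pA=seg.rms_pA,
                rms2k_pA=rms2k,
                rms_corr_pA=rcorr,
                rms_clipped=clipped,
                excluded=excluded,
                direction=direction,
                complete=complete,
            )
        )

    for ev in events:
        if ev.spike is not None:
            level_row(ev.event_id, 0, "spike", ev.spike, ev.direction, ev.complete)
        for fidx, feat in enumerate(ev.features, start=1):
            for label, seg in feat.levels:
                level_row(ev.event_id, fidx, label, seg, ev.direction, ev.complete)
        for label, seg in ev.residue:
            level_row(ev.event_id, -1, f"residue:{label}", seg, ev.direction, ev.complete)
    cols = [
        "event_id", "feature_idx", "level_label", "start_s", "dwell_ms",
        "mean_pA", "ires_pct", "sem_ires", "rms_pA", "rms2k_pA",
        "rms_corr_pA", "rms_clipped", "excluded", "direction", "complete",
    ]
    return pd.DataFrame(rows, columns=cols)


def a1_table(stats: pd.DataFrame, event_id: int) -> pd.DataFrame:
    """Unexcluded A1/B1 rows of one event, ordered by feature index."""
    sel = stats[
        (stats.event_id == event_id)
        & stats.level_label.isin(["A1", "B1"])
        & (~stats.excluded)
    ]
    return sel.sort_values("feature_idx")


def delta_ires(stats: pd.DataFrame, event_id: int, candidate_feature_idx: int) -> float:
    """dIres% of one feature: mean of the other A1 levels minus its own.

    Uses only same-event A1/B1 levels; excluded levels do not enter the
    mean. Raises when the event has fewer than two usable A1 levels or the
    candidate is absent.
    """
    a1 = a1_table(stats, event_id)
    if len(a1) < 2:
        raise ValueError("event needs >= 2 features with usable A1 levels")
    own = a1[a1.feature_idx == candidate_feature_idx]
    if own.empty:
        raise ValueError(f"no usable A1 level at feature {candidate_feature_idx}")
    others = a1[a1.feature_idx != candidate_feature_idx]
    if others.empty:
        raise ValueError("no non-candidate A1 levels to average")
    return float(others.ires_pct.mean() - own.ires_pct.iloc[0])
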