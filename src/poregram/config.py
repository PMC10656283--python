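"""Simulation/analysis configuration: documented keys, JSON round-trip.

A simulation config is a JSON object with keys mirroring the simulator's
model types (every key optional; defaults shown by :func:`default_config`):

``channel``   open_current_pA, open_rms_pA, voltage_mv, capture_rate_per_uM,
              analyte_conc_uM
``unit``      ires_A1..ires_B3 (% of open current), mean_dwell_A1_ms,
              mean_dwell_A2_ms, dwell_A3_mixture / dwell_A3_mixture_final
              (lists of [weight, mean_ms]), direction_prob_C_first
``plan``      n_units, ptm_unit_index (1-based or null),
              has_C_terminal_linker
``ptm``       null, a preset name ("P" | "GSH" | "SLN"), or an object with
              species, delta_ires, rms_boost, nominal_mass
``acquisition`` duration_s, sample_rate_hz, analog_cutoff_hz

Dumping and re-loading a config is bit-exact (sorted keys, plain JSON).
"""

from __future__ import annotations

import json

from .synth import PTM_PRESETS, ChannelModel, ConcatemerPlan, PTMModel, UnitModel


def default_config() -> dict:
    ch, un, pl = ChannelModel(), UnitModel(), ConcatemerPlan()
    return {
        "channel": {
            "open_current_pA": ch.open_current,
            "open_rms_pA": ch.open_rms,
            "voltage_mv": ch.voltage,
            "capture_rate_per_uM": ch.capture_rate_per_uM,
            "analyte_conc_uM": ch.analyte_conc,
        },
        "unit": {
            "ires_A1": un.ires_A1,
            "ires_A2": un.ires_A2,
            "ires_A3": un.ires_A3,
            "ires_B1": un.ires_B1,
            "ires_B2": un.ires_B2,
            "ires_B3": un.ires_B3,
            "mean_dwell_A1_ms": un.mean_dwell_A1,
            "mean_dwell_A2_ms": un.mean_dwell_A2,
            "dwell_A3_mixture": [list(t) for t in un.dwell_A3_mixture],
            "dwell_A3_mixture_final": [list(t) for t in un.dwell_A3_mixture_final],
            "direction_prob_C_first": un.direction_prob_C_first,
        },
        "plan": {
            "n_units": pl.n_units,
            "ptm_unit_index": pl.ptm_unit_index,
            "has_C_terminal_linker": pl.has_C_terminal_linker,
        },
        "ptm": None,
        "acquisition": {
            "duration_s": 10.0,
            "sample_rate_hz": 50_000.0,
            "analog_cutoff_hz": 10_000.0,
        },
    }


def _merged(defaults: dict, user: dict) -> dict:
    out = dict(defaults)
    for k, v in user.items():
        if k not in defaults:
            raise KeyError(f"unknown config key {k!r}")
        out[k] = v
    return out


def parse_config(cfg: dict):
    """Build (channel, unit, plan, ptm, acquisition) from a config dict."""
    base = default_config()
    ch = _merged(base["channel"], cfg.get("channel", {}))
    un = _merged(base["unit"], cfg.get("unit", {}))
    pl = _merged(base["plan"], cfg.get("plan", {}))
    acq = _merged(base["acquisition"], cfg.get("acquisition", {}))
    channel = ChannelModel(
        open_current=ch["open_current_pA"],
        open_rms=ch["open_rms_pA"],
        voltage=ch["voltage_mv"],
        capture_rate_per_uM=ch["capture_rate_per_uM"],
        analyte_conc=ch["analyte_conc_uM"],
    )
    unit = UnitModel(
        ires_A1=un["ires_A1"], ires_A2=un["ires_A2"], ires_A3=un["ires_A3"],
        ires_B1=un["ires_B1"], ires_B2=un["ires_B2"], ires_B3=un["ires_B3"],
        mean_dwell_A1=un["mean_dwell_A1_ms"],
        mean_dwell_A2=un["mean_dwell_A2_ms"],
        dwell_A3_mixture=[tuple(t) for t in un["dwell_A3_mixture"]],
        dwell_A3_mixture_final=[tuple(t) for t in un["dwell_A3_mixture_final"]],
        direction_prob_C_first=un["direction_prob_C_first"],
    )
    plan = ConcatemerPlan(
        n_units=pl["n_units"],
        ptm_unit_index=pl["ptm_unit_index"],
        has_C_terminal_linker=pl["has_C_terminal_linker"],
    )
    raw_ptm = cfg.get("ptm")
    if raw_ptm is None:
        ptm = None
    elif isinstance(raw_ptm, str):
        ptm = PTM_PRESETS[raw_ptm]
    else:
        ptm = PTMModel(
            species=raw_ptm["species"],
            delta_ires=raw_ptm["delta_ires"],
            rms_boost=raw_ptm["rms_boost"],
            nominal_mass=raw_ptm["nominal_mass"],
        )
    return channel, unit, plan, ptm, acq


def load_config(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)


def dump_config(cfg: dict, path: str) -> None:
    with open(path, "w", newline="\n") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
        fh.write("\n")
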