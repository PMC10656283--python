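"""PTM localization and species classification."""

import numpy as np
import pandas as pd
import pytest

from poregram import pipeline, ptm_caller, synth
from poregram.ptm_caller import (
    ClassModel,
    classify_species,
    locate_modified_unit,
    mass_monotonicity_report,
)


def a1_frame(ires_values, sem=0.05, dwell=5.0):
    n = len(ires_values)
    return pd.DataFrame(
        dict(
            event_id=[0] * n,
            feature_idx=list(range(1, n + 1)),
            level_label=["A1"] * n,
            ires_pct=list(ires_values),
            sem_ires=[sem] * n,
            rms_corr_pA=[1.0] * n,
            dwell_ms=[dwell] * n,
            excluded=[False] * n,
        )
    )


class TestLocateModifiedUnit:
    def test_all_equal_gives_none(self):
        call = locate_modified_unit(a1_frame([15.0] * 8), 0)
        assert call.modified_feature_idx is None
        assert call.species_call == "none"

    def test_clear_outlier_is_found(self):
        vals = [15.0, 15.1, 14.9, 12.0, 15.0, 14.95, 15.05, 15.0]
        call = locate_modified_unit(a1_frame(vals), 0)
        assert call.modified_feature_idx == 4
        assert call.delta_ires == pytest.approx(np.mean(vals[:3] + vals[4:]) - 12.0)
        assert call.score > 3

    def test_shallower_blockade_never_called(self):
        # outlier with HIGHER residual current must not be a PTM call
        call = locate_modified_unit(a1_frame([15.0, 15.1, 14.9, 18.0, 15.0]), 0)
        assert call.modified_feature_idx is None

    def test_too_few_features_rejected(self):
        with pytest.raises(ValueError):
            locate_modified_unit(a1_frame([15.0, 14.0]), 0)

    def test_two_outliers_flag_multi_candidate(self):
        vals = [15.0, 11.9, 15.1, 14.9, 12.0, 15.05, 14.95, 15.0]
        call = locate_modified_unit(a1_frame(vals), 0)
        assert call.modified_feature_idx in (2, 5)
        assert call.multi_candidate

    @pytest.mark.parametrize("unit_idx", [2, 5, 8])
    def test_localization_invariant_to_ptm_position(self, unit_idx):
        """Calls land on the true unit wherever the PTM sits in the nonamer."""
        ch = synth.ChannelModel(analyte_conc=4.0)
        plan = synth.ConcatemerPlan(n_units=9, ptm_unit_index=unit_idx)
        tr, gt = synth.simulate_trace(
            ch, synth.UnitModel(), plan, ptm=synth.PTM_PRESETS["GSH"],
            duration=8.0, seed=17, force_direction="C_first",
        )
        events, stats = pipeline.stats_from_ground_truth(tr, gt)
        called = correct = 0
        for ev in events:
            if not ev.complete or ev.n_repeats != 8:
                continue
            try:
                c = locate_modified_unit(stats, ev.event_id)
            except ValueError:  # too few usable A1 levels
                continue
            if c.modified_feature_idx is not None:
                called += 1
                correct += c.modified_feature_idx == unit_idx - 1
        assert called >= 10
        assert correct / called > 0.95

    def test_false_call_rate_on_unmodified_events(self, octamer_recording):
        trace, gt = octamer_recording
        events, stats = pipeline.stats_from_ground_truth(trace, gt)
        n = false = 0
        for ev in events:
            if not ev.complete or ev.n_repeats != 7:
                continue
            try:
                call = locate_modified_unit(stats, ev.event_id)
            except ValueError:  # too few usable A1 levels in this event
                continue
            n += 1
            false += call.modified_feature_idx is not None
        assert n >= 5
        assert false == 0  # small cohort: any false call is anomalous


def two_species_model(sep=5.0):
    return ClassModel(
        species=["GSH", "SLN"],
        means={"GSH": np.array([2.0, 1.0]), "SLN": np.array([2.0 + sep, 1.0 + sep])},
        covs={"GSH": np.eye(2), "SLN": np.eye(2)},
        masses={"GSH": 305.3, "SLN": 656.6},
    )


class TestClassifySpecies:
    def test_point_at_class_mean(self):
        model = two_species_model()
        assert classify_species(2.0, 1.0, model) == "GSH"

    def test_midpoint_of_overlapping_clouds_is_ambiguous(self):
        model = two_species_model(sep=1.0)
        assert classify_species(2.5, 1.5, model) == "ambiguous"

    def test_unfitted_model_rejected(self):
        empty = ClassModel([], {}, {}, {})
        with pytest.raises(ValueError):
            classify_species(1.0, 1.0, empty)

    def test_fit_and_roundtrip(self):
        rng = np.random.default_rng(1)
        pts = pd.DataFrame(
            dict(
                species=["GSH"] * 30 + ["SLN"] * 30,
                delta_ires=np.r_[rng.normal(2.2, 0.2, 30), rng.normal(3.8, 0.2, 30)],
                rms_corr=np.r_[rng.normal(1.0, 0.1, 30), rng.normal(1.4, 0.1, 30)],
            )
        )
        model = ClassModel.fit(pts, {"GSH": 305.3, "SLN": 656.6})
        back = ClassModel.from_dict(model.to_dict())
        assert back.species == model.species
        np.testing.assert_allclose(back.means["GSH"], model.means["GSH"])
        assert classify_species(3.8, 1.4, back) == "SLN"

    def test_discrimination_of_separated_species(self, nonamer_gsh_recording):
        """GSH vs SLN at the same site: >90% correct when means >=3 SD apart."""
        ch = synth.ChannelModel(analyte_conc=4.0)
        plan = synth.ConcatemerPlan(n_units=9, ptm_unit_index=5)
        pts, truth = [], []
        for sp, seed in (("GSH", 7), ("SLN", 8)):
            tr, gt = synth.simulate_trace(
                ch, synth.UnitModel(), plan, ptm=synth.PTM_PRESETS[sp],
                duration=4.0, seed=seed, force_direction="C_first",
            )
            events, stats = pipeline.stats_from_ground_truth(tr, gt)
            for ev in events:
                if not ev.complete or ev.n_repeats != 8:
                    continue
                try:
                    c = locate_modified_unit(stats, ev.event_id)
                except ValueError:  # too few usable A1 levels
                    continue
                if c.modified_feature_idx == 4:
                    pts.append((c.delta_ires, c.rms_corr))
                    truth.append(sp)
        df = pd.DataFrame(
            dict(species=truth, delta_ires=[p[0] for p in pts], rms_corr=[p[1] for p in pts])
        )
        model = ClassModel.fit(df, {"GSH": 305.3, "SLN": 656.6})
        gap = np.linalg.norm(model.means["GSH"] - model.means["SLN"])
        spread = max(np.sqrt(np.trace(model.covs[s]) / 2) for s in model.species)
        assert gap / spread >= 3.0
        calls = [classify_species(d, r, model) for d, r in pts]
        acc = np.mean([c == t for c, t in zip(calls, truth)])
        assert acc > 0.90


class TestMassMonotonicity:
    def make_calls(self, deltas, n=12):
        rows = []
        for sp, d in deltas.items():
            for i in range(n):
                rows.append(
                    dict(event_id=i, modified_feature_idx=4, delta_ires=d + 0.01 * i,
                         rms_corr=1.0, species_call=sp, score=5.0, multi_candidate=False)
                )
        return pd.DataFrame(rows)

    MASSES = {"P": 80.0, "GSH": 305.3, "SLN": 656.6}

    def test_perfect_mass_ordering_gives_rho_1(self):
        calls = self.make_calls({"P": 1.2, "GSH": 2.2, "SLN": 3.8})
        table, rho = mass_monotonicity_report(calls, self.MASSES)
        assert rho == pytest.approx(1.0)
        assert list(table.species) == ["P", "GSH", "SLN"]

    def test_single_species_rejected(self):
        calls = self.make_calls({"P": 1.2})
        with pytest.raises(ValueError, match=">= 2 species"):
            mass_monotonicity_report(calls, self.MASSES)

    def test_tied_deltas_handled_with_midranks(self):
        calls = self.make_calls({"P": 2.0, "GSH": 2.0, "SLN": 2.0})
        calls["delta_ires"] = 2.0  # exactly tied species means
        table, rho = mass_monotonicity_report(calls, self.MASSES)
        assert np.isnan(rho) or abs(rho) <= 1.0
        assert len(table) == 3
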