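"""Generator tests: kinetics closed forms, rendering, star artifact, seeding."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tuberfield import synthetic_staining as ss
from tuberfield.synthetic_staining import (
    KineticsParams,
    RenderParams,
    StarParams,
    apply_star_distortion,
    melanin_area_at,
    red_area_at,
    resize_mask_to_area,
)

KIN = KineticsParams()


class TestKinetics:
    def test_melanin_zero_before_onset(self):
        assert melanin_area_at(3.0, 0.0, KIN) == 0.0
        assert melanin_area_at(3.0, KIN.melanin_onset_h, KIN) == 0.0

    def test_melanin_saturates_to_final_area(self):
        assert melanin_area_at(3.0, 1e6, KIN) == pytest.approx(3.0, rel=1e-9)

    def test_melanin_one_tau_after_onset(self):
        t = KIN.melanin_onset_h + KIN.melanin_tau_h
        assert melanin_area_at(2.0, t, KIN) == pytest.approx(
            2.0 * (1 - math.exp(-1)), rel=1e-12
        )

    def test_melanin_negative_time_rejected(self):
        with pytest.raises(ValueError):
            melanin_area_at(1.0, -1.0, KIN)

    def test_red_identity_at_zero_delay(self):
        assert red_area_at(1.7, 0.0, KIN) == pytest.approx(1.7)

    def test_red_one_tau(self):
        assert red_area_at(1.0, KIN.red_decay_tau_h, KIN) == pytest.approx(
            math.exp(-1), rel=1e-12
        )

    def test_red_vanishes_by_21_hours(self):
        """At the default 6-h decay constant the 21-h staining delay leaves
        e^-3.5 (about 3%) of the initial annulus — 'not observed'."""
        frac = red_area_at(1.0, 21.0, KIN)
        assert frac == pytest.approx(math.exp(-3.5), rel=1e-12)
        assert frac < 0.05

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(t1=st.floats(0, 100), t2=st.floats(0, 100))
    def test_melanin_kinetics_monotone(self, t1, t2):
        lo, hi = sorted((t1, t2))
        assert melanin_area_at(1.0, lo, KIN) <= melanin_area_at(1.0, hi, KIN)


class TestResizeMaskToArea:
    def test_exact_target_counts(self):
        mask = np.zeros((80, 80), bool)
        mask[20:60, 20:60] = True
        for target in (400, 1600, 2500):
            out = resize_mask_to_area(mask, target)
            assert int(out.sum()) == target

    def test_shrink_is_subset_interior(self):
        mask = np.zeros((60, 60), bool)
        mask[10:50, 10:50] = True
        out = resize_mask_to_area(mask, 800)
        assert np.all(mask[out])


class TestStarDistortion:
    @staticmethod
    def _disk(r=60, n=201):
        Y, X = np.ogrid[:n, :n]
        return (X - n // 2) ** 2 + (Y - n // 2) ** 2 <= r * r

    def test_zero_amplitude_is_identity(self):
        mask = self._disk()
        out = apply_star_distortion(mask, 0.0, 5, seed=1)
        assert np.array_equal(out, mask)

    def test_area_preserved_within_three_percent(self):
        mask = self._disk()
        out = apply_star_distortion(mask, 0.3, 5, seed=3)
        assert out.sum() == pytest.approx(mask.sum(), rel=0.03)

    def test_shape_actually_changes(self):
        mask = self._disk()
        out = apply_star_distortion(mask, 0.3, 5, seed=3)
        assert (out ^ mask).sum() > 0.05 * mask.sum()

    def test_same_seed_same_output(self):
        mask = self._disk()
        a = apply_star_distortion(mask, 0.25, 5, seed=11)
        b = apply_star_distortion(mask, 0.25, 5, seed=11)
        assert np.array_equal(a, b)

    def test_amplitude_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            apply_star_distortion(self._disk(), 1.0, 5, seed=0)

    def test_two_lobes_distorted_independently(self):
        """A disconnected region must not be bridged by the distortion."""
        mask = np.zeros((200, 200), bool)
        Y, X = np.ogrid[:200, :200]
        mask |= (X - 60) ** 2 + (Y - 100) ** 2 <= 400
        mask |= (X - 140) ** 2 + (Y - 100) ** 2 <= 400
        out = apply_star_distortion(mask, 0.3, 5, seed=5)
        assert out.sum() == pytest.approx(mask.sum(), rel=0.05)
        # the gap between the lobes stays empty
        assert not out[95:105, 95:105].any()


class TestRenderTTC:
    def test_noiseless_render_uses_only_palette_colors(self, zones_900):
        params = RenderParams(noise_sigma=0.0)
        bundle = ss.render_ttc(zones_900, params=params, seed=1)
        colors = {tuple(c) for c in
                  np.unique(bundle.image.reshape(-1, 3), axis=0)}
        palette = {params.background_color, params.white_core_color,
                   params.deep_red_color, (250, 250, 250), (10, 10, 10)}
        assert colors <= palette

    def test_truth_matches_zone_areas(self, zones_900):
        bundle = ss.render_ttc(zones_900, seed=1)
        assert bundle.truth_areas["white"] == pytest.approx(
            zones_900.ire_area, rel=0.02
        )
        # red annulus at a 5-min delay is essentially the full RE band
        assert bundle.truth_areas["red"] == pytest.approx(
            zones_900.re_area, rel=0.03
        )

    def test_truth_area_equals_mask_count_exactly(self, zones_900):
        bundle = ss.render_ttc(zones_900, seed=2)
        for name, mask in bundle.truth_masks.items():
            assert bundle.truth_areas[name] == int(mask.sum()) / 100.0 / 100.0

    def test_seeded_determinism(self, zones_900):
        a = ss.render_ttc(zones_900, seed=9)
        b = ss.render_ttc(zones_900, seed=9)
        assert np.array_equal(a.image, b.image)
        c = ss.render_ttc(zones_900, seed=10)
        assert not np.array_equal(a.image, c.image)

    def test_staining_delay_shrinks_red_annulus(self, zones_900):
        early = ss.render_ttc(zones_900, seed=1, staining_delay_h=5 / 60)
        late = ss.render_ttc(zones_900, seed=1, staining_delay_h=21.0)
        assert late.truth_areas["red"] < 0.05 * early.truth_areas["red"]
        assert late.truth_areas["white"] == early.truth_areas["white"]


class TestRenderMelanin:
    def test_time_zero_renders_no_melanin(self, zones_900):
        bundle = ss.render_melanin(zones_900, 0.0, seed=1)
        assert bundle.truth_areas["melanin"] == 0.0
        assert not bundle.truth_masks["melanin"].any()

    def test_area_follows_kinetics_closed_form(self, zones_900):
        """Rendered melanin truth equals the closed-form kinetics value
        (up to single-pixel rounding of the target count)."""
        bundle = ss.render_melanin(zones_900, 12.0, seed=1,
                                   star=None, area_jitter=1.0)
        final = ss.render_ttc(zones_900, seed=1,
                              area_jitter=(1.0, 1.0)).truth_areas["white"]
        expected = melanin_area_at(final, 12.0, KIN)
        assert bundle.truth_areas["melanin"] == pytest.approx(expected,
                                                              abs=2e-4)

    def test_converges_to_ttc_area_by_48_hours(self, zones_900):
        mel = ss.render_melanin(zones_900, 48.0, seed=1, area_jitter=1.0)
        ttc = ss.render_ttc(zones_900, seed=1).truth_areas["white"]
        ratio = mel.truth_areas["melanin"] / ttc
        assert 0.95 <= ratio <= 1.05

    def test_melanin_area_non_decreasing_in_time(self, zones_900):
        areas = [
            ss.render_melanin(zones_900, t, seed=4).truth_areas["melanin"]
            for t in (0.0, 3.0, 12.0, 24.0, 48.0)
        ]
        assert all(a <= b for a, b in zip(areas, areas[1:]))


class TestGenerateExperiment:
    def test_default_cardinality(self, default_experiment):
        assert len(default_experiment.bundles) == 30
        assert len(default_experiment.truth_table) == 30
        assert len(default_experiment.electrical_table) == 15

    def test_zero_replicate_noise_gives_identical_truth(self, zones_by_voltage):
        exp = ss.generate_experiment(
            conditions=[(900.0, "ttc", ss.TTC_DEFAULT_DELAY_H)],
            reps=3,
            kin=KineticsParams(rep_noise_cv=0.0),
            master_seed=5,
            zones_by_voltage=zones_by_voltage,
        )
        whites = exp.truth_table["truth_ire_cm2"].to_numpy()
        assert np.all(whites == whites[0])

    def test_regeneration_is_byte_identical(self, zones_by_voltage):
        conditions = [(600.0, "ttc", ss.TTC_DEFAULT_DELAY_H),
                      (600.0, "melanin", 48.0)]
        a = ss.generate_experiment(conditions=conditions, reps=2,
                                   master_seed=7,
                                   zones_by_voltage=zones_by_voltage)
        b = ss.generate_experiment(conditions=conditions, reps=2,
                                   master_seed=7,
                                   zones_by_voltage=zones_by_voltage)
        for ba, bb in zip(a.bundles, b.bundles):
            assert np.array_equal(ba.image, bb.image)
        assert a.truth_table.equals(b.truth_table)

    def test_truth_ire_area_increasing_across_voltages(self, default_experiment):
        ttc = default_experiment.truth_table.query("modality == 'ttc'")
        means = ttc.groupby("voltage_vcm")["truth_ire_cm2"].mean()
        assert np.all(np.diff(means.to_numpy()) > 0)

    def test_empty_condition_list_rejected(self):
        with pytest.raises(ValueError):
            ss.generate_experiment(conditions=[], reps=3)


class TestMeasurementTable:
    def test_shape_and_columns(self, zones_by_voltage):
        tab = ss.generate_measurement_table(master_seed=3,
                                            zones_by_voltage=zones_by_voltage)
        assert len(tab) == 15
        for col in ("melanin_area_cm2", "ttc_white_area_cm2",
                    "ttc_red_area_cm2", "current_A", "conductivity_ratio"):
            assert col in tab.columns

    def test_melanin_tracks_white_through_kinetics(self, zones_by_voltage):
        tab = ss.generate_measurement_table(
            master_seed=3, kin=KineticsParams(rep_noise_cv=0.0),
            zones_by_voltage=zones_by_voltage,
        )
        frac = 1 - math.exp(-(48.0 - KIN.melanin_onset_h) / KIN.melanin_tau_h)
        assert np.allclose(tab["melanin_area_cm2"],
                           tab["ttc_white_area_cm2"] * frac, rtol=1e-9)
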