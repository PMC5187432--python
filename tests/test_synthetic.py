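"""Generator contract: reproducibility, component structure, outline
round-trips and fossil-like truncation."""

import time

import numpy as np
import pandas as pd
import pytest

from leafmorph import geometry as geom
from leafmorph.errors import ConfigurationError, InfeasibleShapeError
from leafmorph.morphometry import (
    DESCRIPTOR_NAMES,
    ShapeParameters,
    compute_parameters,
    extrapolate_tip,
    measure_outline,
)
from leafmorph.synthetic import (
    SyntheticPopulationConfig,
    draw_shape_parameters,
    synthesize_outline,
    truncate_tip,
)

from conftest import ellipse_outline


class TestDrawShapeParameters:
    def test_zero_mixing_fraction_yields_no_mimics(self):
        cfg = SyntheticPopulationConfig(n_species=40, mixing_fraction=0.0,
                                        n_pterochrozinae=0, rng_seed=5)
        table = draw_shape_parameters(cfg)
        assert len(table) == 40
        assert table["is_mimicking"].sum() == 0

    def test_deterministic_group_allocation(self):
        cfg = SyntheticPopulationConfig(n_species=253, mixing_fraction=0.3,
                                        rng_seed=9)
        table = draw_shape_parameters(cfg)
        assert table["is_mimicking"].sum() == round(0.3 * 253)
        assert table["is_pterochrozinae"].sum() == cfg.n_pterochrozinae
        # every Pterochrozinae row is mimicking
        assert table.loc[table["is_pterochrozinae"], "is_mimicking"].all()
        assert (table.loc[table["is_pterochrozinae"], "subfamily"]
                == "Pterochrozinae").all()

    def test_same_seed_is_bit_identical(self):
        a = draw_shape_parameters(SyntheticPopulationConfig(rng_seed=77))
        b = draw_shape_parameters(SyntheticPopulationConfig(rng_seed=77))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = draw_shape_parameters(SyntheticPopulationConfig(rng_seed=1))
        b = draw_shape_parameters(SyntheticPopulationConfig(rng_seed=2))
        assert not a["ratio_wl"].equals(b["ratio_wl"])

    @pytest.mark.parametrize("field,value", [
        ("mixing_fraction", 1.5),
        ("mixing_fraction", -0.1),
        ("n_species", 0),
        ("n_pterochrozinae", 500),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = SyntheticPopulationConfig(**{field: value})
        with pytest.raises(ConfigurationError) as err:
            cfg.validate()
        assert field.split("_")[0] in str(err.value)

    def test_circularity_mean_above_one_rejected(self):
        cfg = SyntheticPopulationConfig()
        cfg.mimicking.mean["circularity_anterior"] = 1.2
        with pytest.raises(ConfigurationError, match="circularity"):
            cfg.validate()

    def test_component_moments_converge(self):
        cfg = SyntheticPopulationConfig(n_species=5000, mixing_fraction=0.5,
                                        n_pterochrozinae=100, rng_seed=31)
        table = draw_shape_parameters(cfg)
        for flag, comp in ((True, cfg.mimicking), (False, cfg.non_mimicking)):
            sub = table[table["is_mimicking"] == flag]
            n = len(sub)
            for name in DESCRIPTOR_NAMES:
                mu, sd = comp.mean[name], comp.sd[name]
                se_mean = sd / np.sqrt(n)
                assert abs(sub[name].mean() - mu) < 3 * se_mean
                se_sd = sd / np.sqrt(2 * (n - 1))
                assert abs(sub[name].std(ddof=1) - sd) < 3 * se_sd

    def test_raw_measurements_are_consistent_with_descriptors(self):
        table = draw_shape_parameters(
            SyntheticPopulationConfig(n_species=60, n_pterochrozinae=10,
                                      rng_seed=3))
        np.testing.assert_allclose(
            table["width_mid"] / table["length_max"], table["ratio_wl"])
        np.testing.assert_allclose(
            table["width_anterior_field"] / table["width_posterior_field"],
            table["ratio_field_width"])
        np.testing.assert_allclose(
            table["area_anterior"] / table["area_posterior"],
            table["ratio_field_area"])
        np.testing.assert_allclose(
            4 * np.pi * table["area_anterior"]
            / table["perimeter_anterior"] ** 2,
            table["circularity_anterior"])

    def test_generator_runtime_budget(self):
        start = time.monotonic()
        draw_shape_parameters(SyntheticPopulationConfig(rng_seed=0))
        assert time.monotonic() - start < 10.0


class TestSynthesizeOutline:
    def test_round_trip_recovers_descriptors(self):
        # 100 random shapes from the feasible neighbourhood of the defaults
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            params = ShapeParameters(
                ratio_wl=rng.uniform(0.18, 0.40),
                ratio_field_width=rng.uniform(0.5, 1.3),
                ratio_field_area=rng.uniform(0.5, 1.3),
                circularity_anterior=rng.uniform(0.12, 0.32),
            )
            try:
                outline = synthesize_outline(params, rng.uniform(20, 60))
            except InfeasibleShapeError:
                continue
            got = compute_parameters(measure_outline(outline))
            for name in DESCRIPTOR_NAMES:
                target = getattr(params, name)
                assert abs(getattr(got, name) - target) < 1e-3 * target
            checked += 1

    def test_outlines_are_simple_with_positive_area(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            params = ShapeParameters(rng.uniform(0.2, 0.38),
                                     rng.uniform(0.6, 1.2),
                                     rng.uniform(0.6, 1.2),
                                     rng.uniform(0.15, 0.30))
            try:
                outline = synthesize_outline(params, 40.0)
            except InfeasibleShapeError:
                continue
            geom.check_simple(outline.vertices)
            assert abs(geom.polygon_area(outline.vertices)) > 0

    def test_symmetric_targets_give_symmetric_outline(self):
        params = ShapeParameters(0.5, 1.0, 1.0, 0.30)
        outline = synthesize_outline(params, 10.0)
        verts = outline.vertices
        # mirror about the split chord (y = 0) maps the outline onto itself
        mirrored = verts.copy()
        mirrored[:, 1] *= -1
        from shapely.geometry import Polygon
        p1, p2 = Polygon(verts), Polygon(mirrored)
        assert p1.symmetric_difference(p2).area < 1e-9 * p1.area

    def test_isoperimetric_violation_is_infeasible(self):
        params = ShapeParameters(0.36, 1.0, 1.0, 1.2)
        with pytest.raises(InfeasibleShapeError):
            synthesize_outline(params, 40.0)

    def test_unreachable_circularity_reports_range(self):
        params = ShapeParameters(0.36, 1.0, 1.0, 0.9)
        with pytest.raises(InfeasibleShapeError) as err:
            synthesize_outline(params, 40.0)
        lo, hi = err.value.achievable
        assert 0.0 <= lo < hi < 0.9


class TestTruncateTip:
    def test_clipping_reduces_area_monotonically(self, tegmen_outline):
        full_area = abs(geom.polygon_area(tegmen_outline.vertices))
        prev = full_area
        for fraction in (0.05, 0.15, 0.3, 0.45):
            part = truncate_tip(tegmen_outline, fraction)
            area = abs(geom.polygon_area(part.vertices))
            assert area < prev
            prev = area

    @pytest.mark.parametrize("fraction", [0.0, 0.5, -0.1, 1.0])
    def test_fraction_bounds_enforced(self, tegmen_outline, fraction):
        with pytest.raises(ConfigurationError):
            truncate_tip(tegmen_outline, fraction)

    def test_ellipse_clip_matches_closed_form(self):
        a, b, fraction = 2.0, 1.0, 0.1
        outline = ellipse_outline(a=a, b=b, n=2048)
        part = truncate_tip(outline, fraction)
        clipped_area = abs(geom.polygon_area(part.vertices))
        # segment beyond x0 = a*(1 - 2f): area = a*b*(t - sin t cos t)
        x0 = a * (1.0 - 2.0 * fraction)
        t = np.arccos(x0 / a)
        expected = np.pi * a * b - a * b * (t - np.sin(t) * np.cos(t))
        assert abs(clipped_area - expected) < 5e-3 * expected

    def test_truncate_then_extrapolate_round_trip(self, tegmen_outline):
        full = measure_outline(tegmen_outline)
        part = truncate_tip(tegmen_outline, 0.10)
        _, (chord, extrap) = extrapolate_tip(part)
        # circular completion of a superelliptic apex: area to ~2%,
        # length to ~6%; extrapolation must strictly improve on chord
        # closure on both
        assert abs(extrap.area_total - full.area_total) < 0.03 * full.area_total
        assert abs(extrap.length_max - full.length_max) < 0.08 * full.length_max
        assert (abs(extrap.area_total - full.area_total)
                < abs(chord.area_total - full.area_total))
        assert (abs(extrap.length_max - full.length_max)
                < abs(chord.length_max - full.length_max))

    def test_open_endpoints_sit_on_cut_line(self, tegmen_outline):
        part = truncate_tip(tegmen_outline, 0.2)
        assert part.completeness == "tip_missing"
        xs = part.open_endpoints[:, 0]
        assert abs(xs[0] - xs[1]) < 1e-9
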