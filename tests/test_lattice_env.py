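"""Metabolite transport: diffusion, advection, feeding, well-mixed mode."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from gutlattice.lattice_env import (
    FeedSchedule,
    LatticeGeometry,
    MetaboliteField,
    default_geometry,
    effective_diffusion_cm2_s,
    fixture_geometry,
    gos_composition,
    kernel_displacement_variance,
    large_geometry,
    small_geometry,
    tracer_transit_hours,
)


def _point_field(geometry, row, col, amount=1.0, met="x"):
    f = MetaboliteField(geometry, unlimited=(), non_advected=())
    f.amount(met)[row, col] = amount
    return f


class TestDiffusion:
    def test_interior_point_mass_single_substep(self):
        g = LatticeGeometry(width=5, height=5, diffusion_substeps=1)
        f = _point_field(g, 2, 2)
        f.diffuse()
        arr = f.amount("x")
        assert arr[2, 2] == pytest.approx(1 - 4 * 0.1425)
        for r, c in ((1, 2), (3, 2), (2, 1), (2, 3)):
            assert arr[r, c] == pytest.approx(0.1425)

    def test_wall_mass_stays_in_place(self):
        g = LatticeGeometry(width=3, height=3, diffusion_substeps=1)
        f = _point_field(g, 0, 0)  # corner: only 2 neighbours
        f.diffuse()
        arr = f.amount("x")
        assert arr[0, 0] == pytest.approx(1 - 2 * 0.1425)
        assert arr.sum() == pytest.approx(1.0)

    def test_uniform_field_is_invariant(self):
        g = fixture_geometry(10, 4)
        f = MetaboliteField(g, unlimited=(), non_advected=())
        f.amount("x")[:] = 0.7
        for _ in range(5):
            f.diffuse()
        assert np.allclose(f.amount("x"), 0.7, atol=1e-12)

    @given(
        arr=hnp.arrays(
            float, (4, 9),
            elements=st.floats(0, 100, allow_nan=False),
        )
    )
    def test_mass_conserved_to_machine_precision(self, arr):
        g = LatticeGeometry(width=9, height=4)
        f = MetaboliteField(g, unlimited=(), non_advected=())
        f.amount("x")[:] = arr
        total = f.total("x")
        f.diffuse()
        assert f.total("x") == pytest.approx(total, rel=1e-13, abs=1e-12)


class TestAdvection:
    def test_shift_and_distal_removal(self):
        g = fixture_geometry(6, 2)
        f = _point_field(g, 0, 3)
        removed = f.advect(0)
        assert f.amount("x")[0, 4] == 1.0 and f.amount("x")[0, 3] == 0.0
        assert removed["x"] == 0.0
        for t in (1, 2):
            removed = f.advect(t)
        assert removed["x"] == 1.0
        assert f.total("x") == 0.0

    def test_oxygen_is_exempt(self):
        g = fixture_geometry(6, 2)
        f = MetaboliteField(g, unlimited=(), non_advected=("o2_e",))
        f.amount("o2_e")[:, :] = 0.1
        f.advect(0)
        assert np.all(f.amount("o2_e") == 0.1)

    def test_empty_field_is_noop(self):
        f = MetaboliteField(fixture_geometry(6, 2))
        assert f.advect(0) == {}

    def test_coarse_lattice_advects_every_second_step(self):
        g = small_geometry()
        f = _point_field(g, 0, 10)
        f.advect(1)  # off-phase step
        assert f.amount("x")[0, 10] == 1.0
        f.advect(2)
        assert f.amount("x")[0, 11] == 1.0

    def test_fine_lattice_advects_two_columns(self):
        g = large_geometry()
        f = _point_field(g, 0, 10)
        f.advect(0)
        assert f.amount("x")[0, 12] == 1.0


class TestFeeding:
    def test_default_dose_divided_over_48_proximal_sites(self):
        g = default_geometry()
        f = MetaboliteField(g)
        f.feed(FeedSchedule({"lcts_e": 211.0}), t=0)
        arr = f.amount("lcts_e")
        assert arr[0, 0] == pytest.approx(211.0 / 48)
        assert arr[:, :6].sum() == pytest.approx(211.0)
        assert arr[:, 6:].sum() == 0.0

    def test_off_period_steps_do_not_feed(self):
        f = MetaboliteField(default_geometry())
        f.feed(FeedSchedule({"lcts_e": 211.0}), t=30)
        assert f.total("lcts_e") == 0.0

    def test_gos_split_64_28_8(self):
        comp = gos_composition(211.0)
        assert comp["gosdp3_e"] == pytest.approx(135.04)
        assert comp["gosdp4_e"] == pytest.approx(59.08)
        assert comp["gosdp5_e"] == pytest.approx(16.88)
        assert sum(comp.values()) == pytest.approx(211.0)

    def test_negative_feed_amount_rejected(self):
        with pytest.raises(ValueError):
            FeedSchedule({"lcts_e": -1.0})


class TestOxygenAndWellMixed:
    def test_initial_oxygen_total(self):
        f = MetaboliteField(default_geometry())
        f.init_oxygen(0.1)
        assert f.total("o2_e") == pytest.approx(180.0)

    def test_no_oxygen_variant(self):
        f = MetaboliteField(default_geometry())
        f.init_oxygen(0.0)
        assert f.total("o2_e") == 0.0

    def test_negative_oxygen_rejected(self):
        with pytest.raises(ValueError):
            MetaboliteField(default_geometry()).init_oxygen(-0.1)

    def test_field_snapshot_exports_tidy_rows(self, tmp_path):
        import pandas as pd

        f = MetaboliteField(fixture_geometry(4, 2))
        f.amount("lcts_e")[1, 2] = 0.5
        path = str(tmp_path / "snap.csv")
        f.to_csv(path)
        df = pd.read_csv(path)
        assert df.to_dict("records") == [
            {"row": 1, "col": 2, "metabolite": "lcts_e", "umol": 0.5}
        ]

    def test_well_mixed_redistributes_equally_and_conserves(self):
        g = default_geometry()
        f = _point_field(g, 0, 0, amount=48.0)
        f.well_mixed_redistribute()
        assert np.allclose(f.amount("x"), 48.0 / 1800)
        assert f.total("x") == pytest.approx(48.0)


class TestGeometry:
    def test_site_volume_from_total_colon_volume(self):
        # 90 mL over 1800 sites
        g = default_geometry()
        assert g.site_volume_ml == pytest.approx(0.05)
        assert g.n_sites * g.site_volume_ml == pytest.approx(90.0)

    @pytest.mark.parametrize("geometry", [
        default_geometry(), small_geometry(), large_geometry(),
    ])
    def test_effective_diffusion_constant_across_variants(self, geometry):
        # the variant scalings keep D at 6.33e-5 cm^2/s
        D = effective_diffusion_cm2_s(geometry)
        assert D == pytest.approx(6.333e-5, rel=1e-3)

    def test_kernel_variance_matches_closed_form(self):
        g = default_geometry()
        var = kernel_displacement_variance(g)
        expected = 2 * g.diffusion_substeps * g.diffusion_fraction * g.site_side_cm**2
        assert var == pytest.approx(expected, rel=1e-12)


class TestTransit:
    def test_tracer_pulse_exits_in_about_eleven_hours(self):
        hours = tracer_transit_hours()
        assert hours == pytest.approx(11.0, rel=0.10)

    def test_monte_carlo_tracer_matches_kernel_variance(self):
        """Random walkers driven by the hop kernel reproduce the analytic
        displacement variance (the MSD route to the diffusion constant)."""
        g = default_geometry()
        rng = np.random.default_rng(1234)
        n, steps = 100_000, 10
        x = np.zeros(n)
        p = g.diffusion_fraction
        for _ in range(steps * g.diffusion_substeps):
            u = rng.random(n)
            x += (u < p) * 1.0 - ((u >= p) & (u < 2 * p)) * 1.0
        var_per_step = x.var() * g.site_side_cm**2 / steps
        assert var_per_step == pytest.approx(
            kernel_displacement_variance(g), rel=0.02
        )
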