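"""Simulator correctness: closed-form ensemble statistics and determinism."""

import numpy as np
import pytest

from melanotrack import (
    AcquisitionSettings,
    SimulationParams,
    add_localization_noise,
    generate_cell_geometry,
    generate_population,
    quantize_to_pixels,
    simulate,
)
from melanotrack.errors import InvalidParameterError

from conftest import brownian


def ensemble_msd_at_lag(trajs, m):
    vals = []
    for t in trajs:
        d = t.positions[m:] - t.positions[:-m]
        vals.append(np.mean(d[:, 0] ** 2 + d[:, 1] ** 2))
    return np.asarray(vals)


class TestBrownian:
    def test_zero_diffusion_is_stationary(self, settings):
        t = brownian(0.0, settings, seed=0, origin=(1.5, -2.0))
        assert np.all(t.positions == [1.5, -2.0])

    def test_seeded_determinism(self, settings):
        a = brownian(0.01, settings, seed=42)
        b = brownian(0.01, settings, seed=42)
        assert np.array_equal(a.positions, b.positions)
        c = brownian(0.01, settings, seed=43)
        assert not np.array_equal(a.positions, c.positions)

    def test_ensemble_msd_matches_4Dtau(self, settings):
        """Ensemble-mean MSD(τ)/(Dτ) = 4 for 2D diffusion, several lags."""
        D = 0.01
        trajs = generate_population(
            [(SimulationParams("brownian", D=D), 2000)], settings, seed=11
        )
        for m in (1, 2, 20):
            tau = m * settings.frame_interval
            vals = ensemble_msd_at_lag(trajs, m)
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - 4 * D * tau) < 3 * se

    def test_negative_D_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimulationParams("brownian", D=-1e-3)

    def test_too_few_frames_rejected(self):
        with pytest.raises(InvalidParameterError):
            AcquisitionSettings(n_frames=1)


class TestDirectional:
    def test_zero_speed_is_stationary(self, settings):
        t = simulate(SimulationParams("directional", V=0.0), settings)
        assert np.all(t.positions == 0.0)

    def test_final_displacement_arithmetic(self, settings):
        t = simulate(SimulationParams("directional", V=0.04, heading=0.0), settings)
        assert t.positions[-1, 0] == pytest.approx(0.04 * 300.0, abs=1e-12)
        assert t.positions[-1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_msd_is_exactly_v2_tau2(self, settings):
        V = 0.05
        t = simulate(SimulationParams("directional", V=V, heading=1.1), settings)
        for m in (1, 7, 150):
            tau = m * settings.frame_interval
            d = t.positions[m:] - t.positions[:-m]
            msd = np.mean(d[:, 0] ** 2 + d[:, 1] ** 2)
            assert msd == pytest.approx(V**2 * tau**2, rel=1e-12)


class TestTethered:
    def test_long_lag_plateau_is_4D_over_k(self, settings):
        """OU stationary variance D/k per coordinate ⇒ 2D MSD plateau 4D/k."""
        D, k = 0.01, 0.5
        trajs = generate_population(
            [(SimulationParams("tethered", D=D, k=k), 400)], settings, seed=5
        )
        m = 200  # τ=100 s ≫ 1/k=2 s
        vals = ensemble_msd_at_lag(trajs, m)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 4 * D / k) < 3 * se

    def test_stiff_tether_gives_flat_msd(self, settings):
        """kΔt ≫ 1: successive positions ~independent, MSD flat across lags."""
        D, k = 0.01, 50.0
        trajs = generate_population(
            [(SimulationParams("tethered", D=D, k=k), 300)], settings, seed=6
        )
        short = ensemble_msd_at_lag(trajs, 1).mean()
        long = ensemble_msd_at_lag(trajs, 100).mean()
        assert short == pytest.approx(4 * D / k, rel=0.05)
        assert long == pytest.approx(short, rel=0.05)

    def test_soft_tether_limit_reproduces_brownian_increments(self, settings):
        """kΔt → 0: per-step variance → 2DΔt per coordinate to first order."""
        D, k = 0.01, 1e-4
        trajs = generate_population(
            [(SimulationParams("tethered", D=D, k=k), 300)], settings, seed=7
        )
        steps = np.concatenate([np.diff(t.positions, axis=0) for t in trajs])
        var = steps.var()
        assert var == pytest.approx(2 * D * settings.frame_interval, rel=0.02)

    def test_zero_diffusion_stays_at_origin(self, settings):
        t = simulate(SimulationParams("tethered", D=0.0, k=2.0), settings)
        assert np.all(t.positions == 0.0)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimulationParams("tethered", D=0.01, k=0.0)


class TestConfined:
    def test_positions_stay_inside_box(self, settings):
        L = 0.5
        t = simulate(
            SimulationParams("confined", D=0.05, box_side=L, seed=1), settings
        )
        assert np.all(np.abs(t.positions) <= L / 2 + 1e-12)

    def test_long_lag_plateau_is_L2_over_3(self, settings):
        """Uniform equilibrium in the box ⇒ 2D plateau 2·(2·L²/12) = L²/3."""
        D, L = 0.01, 0.5
        trajs = generate_population(
            [(SimulationParams("confined", D=D, box_side=L), 400)], settings, seed=8
        )
        vals = ensemble_msd_at_lag(trajs, 300)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - L**2 / 3) < 3 * se

    def test_huge_box_indistinguishable_from_free_brownian(self, settings):
        D = 0.01
        free = generate_population(
            [(SimulationParams("brownian", D=D), 300)], settings, seed=9
        )
        boxed = generate_population(
            [(SimulationParams("confined", D=D, box_side=1000.0), 300)], settings, seed=9
        )
        for m in (1, 50):
            a = ensemble_msd_at_lag(free, m).mean()
            b = ensemble_msd_at_lag(boxed, m).mean()
            assert b == pytest.approx(a, rel=0.1)

    def test_origin_outside_box_rejected(self, settings):
        with pytest.raises(InvalidParameterError):
            simulate(
                SimulationParams(
                    "confined", D=0.01, box_side=1.0,
                    origin=(5.0, 0.0), box_center=(0.0, 0.0),
                ),
                settings,
            )


class TestNoiseAndQuantization:
    def test_zero_sigma_is_identity(self, settings):
        t = brownian(0.01, settings, seed=3)
        noisy = add_localization_noise(t, 0.0)
        assert np.array_equal(noisy.positions, t.positions)
        assert noisy is not t

    def test_input_unmodified(self, settings):
        t = brownian(0.01, settings, seed=3)
        before = t.positions.copy()
        add_localization_noise(t, 0.05, seed=1)
        assert np.array_equal(t.positions, before)

    def test_stationary_plus_noise_msd_is_4_sigma2(self, settings):
        sigma = 0.05
        base = SimulationParams("brownian", D=0.0)
        trajs = [
            add_localization_noise(simulate(base, settings), sigma, seed=s)
            for s in range(500)
        ]
        vals = ensemble_msd_at_lag(trajs, 3)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 4 * sigma**2) < 3 * se

    def test_noise_offset_adds_to_brownian_msd(self, settings):
        """MSD(process + noise) = MSD(process) + 4σ² in expectation."""
        D, sigma, m = 0.005, 0.05, 4
        tau = m * settings.frame_interval
        trajs = generate_population(
            [(SimulationParams("brownian", D=D, noise_sigma=sigma), 800)],
            settings,
            seed=12,
        )
        vals = ensemble_msd_at_lag(trajs, m)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - (4 * D * tau + 4 * sigma**2)) < 3 * se

    def test_negative_sigma_rejected(self, settings):
        t = brownian(0.01, settings, seed=3)
        with pytest.raises(InvalidParameterError):
            add_localization_noise(t, -0.1)

    def test_quantize_rounds_to_nearest_pixel(self):
        from conftest import make_trajectory

        t = make_trajectory([[0.07, 0.09], [0.0, 0.0]])
        q = quantize_to_pixels(t)
        assert q.positions[0] == pytest.approx([0.0, 0.16])

    def test_quantize_idempotent_and_bounded(self, settings):
        t = brownian(0.01, settings, seed=4)
        q1 = quantize_to_pixels(t)
        q2 = quantize_to_pixels(q1)
        assert np.array_equal(q1.positions, q2.positions)
        assert np.max(np.abs(q1.positions - t.positions)) <= 0.08 + 1e-12


class TestPopulation:
    def test_counts_and_labels(self, settings):
        spec = [
            (SimulationParams("brownian", D=0.001), 60),
            (SimulationParams("directional", V=0.04), 15),
        ]
        trajs = generate_population(spec, settings, seed=1)
        assert len(trajs) == 75
        procs = [t.provenance.process for t in trajs]
        assert procs.count("brownian") == 60
        assert procs.count("directional") == 15

    def test_determinism_and_shuffle(self, settings):
        spec = [
            (SimulationParams("brownian", D=0.001), 10),
            (SimulationParams("directional", V=0.04), 5),
        ]
        a = generate_population(spec, settings, seed=2)
        b = generate_population(spec, settings, seed=2)
        assert [t.track_id for t in a] == [t.track_id for t in b]
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.positions, tb.positions)
        # shuffled: not grouped by process
        procs = [t.provenance.process for t in a]
        assert procs != sorted(procs) or procs != procs  # order is seed-derived

    def test_empty_spec_rejected(self, settings):
        with pytest.raises(InvalidParameterError):
            generate_population([], settings, seed=0)


class TestCellGeometryGenerator:
    def test_centred_nucleus_inside_cell(self):
        g = generate_cell_geometry(nucleus_radius=5.0, cell_radius=15.0)
        assert g.cell.contains(g.nucleus)

    def test_disjoint_geometry_allowed(self):
        g = generate_cell_geometry(nucleus_radius=2.0, cell_radius=3.0, nucleus_offset=10.0)
        assert not g.cell.intersects(g.nucleus)

    def test_wobbled_outline_reproducible(self):
        a = generate_cell_geometry(5.0, 15.0, seed=3, wobble=0.05)
        b = generate_cell_geometry(5.0, 15.0, seed=3, wobble=0.05)
        assert a.nucleus.equals(b.nucleus)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_cell_geometry(0.0, 15.0)
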