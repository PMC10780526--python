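"""Unit-level physics of the 2D TMz solver (fast, small grids).

The heavier validation suite (analytic oracle, PML reflection, energy
conservation, reciprocity at the reduced grid) lives in test_acceptance.py.
"""

import numpy as np
import pytest

from mwtomo.config import C0, EPS0, MU0, ConfigError, DomainConfig, SolverConfig
from mwtomo.fdtd import (
    AntennaArray,
    CourantError,
    PulseWaveform,
    build_simulation,
    design_pulse,
    homogeneous_phantom,
    measure_band_edges,
    run_multistatic,
    run_single_tx,
    scattered_field,
    step,
)
from mwtomo.phantoms import ShapeSpec, compose_phantom


@pytest.fixture
def tiny_domain():
    """60-cell grid at 2 mm for single-step and symmetry checks."""
    return DomainConfig(
        domain_size=120.0, cell_size=2.0, imaging_radius=40.0, antenna_radius=50.0,
        axis_range=(20.0, 50.0),
    )


class TestPulse:
    def test_default_band_edges(self):
        """-10 dB power points at 0.5 and 2 GHz within 5%."""
        p = design_pulse(0.5e9, 2.0e9, 4.72e-12, 5000)
        lo, hi = measure_band_edges(p.samples, 4.72e-12)
        assert lo == pytest.approx(0.5e9, rel=0.05)
        assert hi == pytest.approx(2.0e9, rel=0.05)

    def test_no_truncation_transient(self):
        p = design_pulse(0.5e9, 2.0e9, 4.72e-12, 5000)
        peak = np.abs(p.samples).max()
        assert abs(p.samples[0]) < 1e-4 * peak
        assert abs(p.samples[-1]) < 1e-4 * peak
        assert p.delay >= 4 / (2 * np.pi * p.spectral_width)

    def test_spectrum_symmetric_about_center(self):
        """Log-power spectrum is symmetric around the center frequency."""
        dt = 4.72e-12
        p = design_pulse(0.5e9, 2.0e9, dt, 8192)
        spec = np.abs(np.fft.rfft(p.samples))
        freqs = np.fft.rfftfreq(8192, dt)
        sel = (freqs > 0.6e9) & (freqs < 1.25e9)
        f_lo = freqs[sel]
        lo_db = 20 * np.log10(np.interp(f_lo, freqs, spec))
        hi_db = 20 * np.log10(np.interp(2 * p.center_frequency - f_lo, freqs, spec))
        assert np.allclose(lo_db, hi_db, atol=0.1)

    def test_doubling_envelope_halves_bandwidth(self):
        """Fourier uncertainty: spectral width scales as 1/tau."""
        dt = 4.72e-12
        p1 = design_pulse(0.5e9, 2.0e9, dt, 8192)
        lo1, hi1 = measure_band_edges(p1.samples, dt)
        # double the envelope width == halve the designed band half-width
        p2 = design_pulse(0.875e9, 1.625e9, dt, 8192)
        lo2, hi2 = measure_band_edges(p2.samples, dt)
        assert (hi2 - lo2) == pytest.approx((hi1 - lo1) / 2, rel=0.05)

    def test_nyquist_guard(self):
        with pytest.raises(ConfigError):
            design_pulse(0.5e9, 2.0e9, 1e-9, 100)


class TestAntennaArray:
    def test_sixteen_antennas_evenly_spaced(self, domain):
        arr = AntennaArray.from_domain(domain)
        assert arr.n_antennas == 16
        ang = np.degrees(np.arctan2(arr.positions[:, 1], arr.positions[:, 0]))
        dif = np.diff(np.unwrap(np.radians(ang)))
        assert np.allclose(np.degrees(dif), 22.5)
        assert np.allclose(np.hypot(*arr.positions.T), 150.0)


class TestBuildSimulation:
    def test_courant_accepts_matching_medium(self, tiny_domain):
        """eps_min = 40 admits the default 4.72 ps step (limit ~29.8 ps)."""
        cfg = SolverConfig(n_steps=10)
        assert cfg.courant_limit(40.0) == pytest.approx(29.8e-12, rel=0.01)
        ph = homogeneous_phantom(tiny_domain)
        build_simulation(ph, AntennaArray.from_domain(tiny_domain), cfg)

    def test_courant_rejects_vacuum_cell(self, tiny_domain):
        """One eps_r = 1 cell pushes the limit to ~4.714 ps < 4.72 ps."""
        ph = homogeneous_phantom(tiny_domain)
        ph.eps_map[5, 5] = 1.0
        cfg = SolverConfig(n_steps=10)
        assert cfg.courant_limit(1.0) == pytest.approx(4.714e-12, rel=0.01)
        with pytest.raises(CourantError, match="eps_min"):
            build_simulation(ph, AntennaArray.from_domain(tiny_domain), cfg)

    def test_courant_accepts_eps_10(self, tiny_domain):
        ph = homogeneous_phantom(tiny_domain, eps_r=10.0)
        build_simulation(ph, AntennaArray.from_domain(tiny_domain), SolverConfig(n_steps=10))

    def test_lossless_gives_ca_one(self, tiny_domain):
        ph = homogeneous_phantom(tiny_domain, eps_r=40.0, sigma=0.0)
        sim = build_simulation(ph, AntennaArray.from_domain(tiny_domain), SolverConfig(n_steps=10))
        assert (sim.ca == 1.0).all()

    def test_update_coefficients_formula(self, tiny_domain):
        """Ca and Cb match the lossy-dielectric expressions cell by cell."""
        ph = homogeneous_phantom(tiny_domain, eps_r=40.0, sigma=0.8)
        cfg = SolverConfig(n_steps=10)
        sim = build_simulation(ph, AntennaArray.from_domain(tiny_domain), cfg)
        eps = 40.0 * EPS0
        loss = 0.8 * cfg.dt / (2 * eps)
        assert np.allclose(sim.ca, (1 - loss) / (1 + loss))
        assert np.allclose(sim.cb, (cfg.dt / (eps * cfg.dx)) / (1 + loss))


class TestStep:
    def test_null_dynamics(self, tiny_domain):
        ph = homogeneous_phantom(tiny_domain)
        sim = build_simulation(ph, AntennaArray.from_domain(tiny_domain), SolverConfig(n_steps=10))
        for _ in range(5):
            step(sim)
        assert (sim.ez == 0).all() and (sim.hx == 0).all() and (sim.hy == 0).all()

    def test_single_cell_curl_hand_computed(self, tiny_domain):
        """One nonzero Ez cell: after one step only the four adjacent
        staggered H edges change, by -/+ mh * Ez."""
        ph = homogeneous_phantom(tiny_domain, sigma=0.0)
        cfg = SolverConfig(n_steps=10)
        sim = build_simulation(ph, AntennaArray.from_domain(tiny_domain), cfg)
        i, j = 30, 31
        sim.ez[i, j] = 2.5
        step(sim)
        # hand evaluation: dHx/dt = -(1/mu) dEz/dy, dHy/dt = +(1/mu) dEz/dx;
        # with Ez only at (i,j): d_ez_y = +2.5 at row i-1, -2.5 at row i;
        # d_ez_x = +2.5 at col j-1, -2.5 at col j.
        mh = cfg.dt / (MU0 * cfg.dx)
        expect_hx = np.zeros_like(sim.hx)
        expect_hx[i - 1, j] = -mh * 2.5
        expect_hx[i, j] = +mh * 2.5
        expect_hy = np.zeros_like(sim.hy)
        expect_hy[i, j - 1] = +mh * 2.5
        expect_hy[i, j] = -mh * 2.5
        assert np.allclose(sim.hx, expect_hx)
        assert np.allclose(sim.hy, expect_hy)
        assert np.count_nonzero(sim.hx) == 2 and np.count_nonzero(sim.hy) == 2


class TestSingleTx:
    def test_equidistant_receivers_identical(self):
        """Symmetric receivers about the source see identical traces.

        Uses an odd-size grid so the source cell sits on the exact
        mirror axis of the discrete domain.
        """
        dom = DomainConfig(
            domain_size=122.0, cell_size=2.0, imaging_radius=40.0,
            antenna_radius=50.0, axis_range=(20.0, 50.0),
        )
        ph = homogeneous_phantom(dom)
        cfg = SolverConfig(n_steps=300)
        sim = build_simulation(ph, AntennaArray.from_domain(dom), cfg)
        pulse = design_pulse(0.5e9, 2e9, cfg.dt, cfg.n_steps)
        c = dom.n_cells // 2  # 30 on a 61-cell grid: exact center

        class _Arr:
            grid_indices = ((c, c - 8), (c, c + 8), (c, c))
            n_antennas = 3

        traces = run_single_tx(sim, _Arr(), 2, pulse)
        assert np.allclose(traces[0], traces[1], rtol=0, atol=1e-13)

    def test_loss_attenuates_peak(self, tiny_domain):
        cfg = SolverConfig(n_steps=300)
        pulse = design_pulse(0.5e9, 2e9, cfg.dt, cfg.n_steps)
        peaks = []
        for sig in (0.0, 0.1):
            ph = homogeneous_phantom(tiny_domain, eps_r=40.0, sigma=sig)
            sim = build_simulation(ph, AntennaArray.from_domain(tiny_domain), cfg)
            n = tiny_domain.n_cells
            c = n // 2

            class _Arr:
                grid_indices = ((c, c), (c, c + 10))
                n_antennas = 2

            tr = run_single_tx(sim, _Arr(), 0, pulse)
            peaks.append(np.abs(tr[1]).max())
        assert peaks[1] < peaks[0]

    def test_ascii_trace_export(self, tmp_path):
        from mwtomo.fdtd import export_trace_ascii

        trace = np.array([0.0, 1.5, -0.5])
        path = tmp_path / "trace.txt"
        export_trace_ascii(trace, 4.72e-12, path)
        loaded = np.loadtxt(path)
        assert np.allclose(loaded[:, 0], [0, 4.72e-12, 9.44e-12])
        assert np.allclose(loaded[:, 1], trace)

    def test_bad_tx_index(self, tiny_domain):
        ph = homogeneous_phantom(tiny_domain)
        cfg = SolverConfig(n_steps=10)
        sim = build_simulation(ph, AntennaArray.from_domain(tiny_domain), cfg)
        arr = AntennaArray.from_domain(tiny_domain)
        with pytest.raises(ConfigError):
            run_single_tx(sim, arr, 99, design_pulse(0.5e9, 2e9, cfg.dt, 10))


class TestMultistatic:
    def test_tensor_shape_and_determinism(self, tiny_domain):
        shape = ShapeSpec(
            kind="ellipse", center=(5.0, 0.0), major_axis=30.0, minor_axis=20.0,
            rotation=15.0, eps_value=60.0, sigma_value=1.0,
        )
        ph = compose_phantom([shape], tiny_domain)
        cfg = SolverConfig(n_steps=120)
        arr = AntennaArray.from_domain(tiny_domain)
        t1 = run_multistatic(ph, arr, cfg)
        t2 = run_multistatic(ph, arr, cfg)
        assert t1.data.shape == (16, 16, 120)
        assert (t1.data == t2.data).all()
        assert np.isfinite(t1.data).all()

    def test_scatterer_changes_late_signal(self, tiny_domain):
        """A scatterer perturbs the tensor, mostly after the direct
        wave has crossed the domain."""
        cfg = SolverConfig(n_steps=400)
        arr = AntennaArray.from_domain(tiny_domain)
        empty = run_multistatic(homogeneous_phantom(tiny_domain), arr, cfg)
        shape = ShapeSpec(
            kind="ellipse", center=(0.0, 0.0), major_axis=40.0, minor_axis=40.0,
            rotation=0.0, eps_value=75.0, sigma_value=2.0,
        )
        total = run_multistatic(compose_phantom([shape], tiny_domain), arr, cfg)
        scat = scattered_field(total, empty)
        assert np.abs(scat.data).max() > 0
        # opposite pair (0, 8): scattered energy cannot precede the
        # straight-line travel time through the fastest (eps=10) medium
        v_max = C0 / np.sqrt(10.0)
        d = 2 * tiny_domain.antenna_radius * 1e-3
        n_min = int(d / v_max / cfg.dt)
        trace = scat.data[0, 8]
        assert np.abs(trace[:n_min]).max() <= 1e-9 * np.abs(trace).max() + 1e-300
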