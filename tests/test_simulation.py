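import numpy as np
import pytest

from lassokit.shapes import shape_record
from lassokit.simulation import (
    KB,
    N_SMALL,
    InsufficientSamplingError,
    SimConfig,
    TooSmallLoopError,
    build_system,
    check_threading,
    chord_correlation,
    potential_energy,
    run_simulation,
    winding_number,
)

from oracles import triangle_boltzmann_bond_pdf, winding_number_ray_crossings


def brute_force_energy(coords, config, thread):
    """Direct double-loop sum over all interaction terms."""
    n = len(coords)
    e = 0.0
    for i in range(n):
        r = np.linalg.norm(coords[(i + 1) % n] - coords[i])
        e += 0.5 * config.k_bond * (r - config.r0) ** 2
    for i in range(n):
        for j in range(i + 1, n):
            if (j - i) == 1 or (i == 0 and j == n - 1):
                continue
            r2 = ((coords[j] - coords[i]) ** 2).sum()
            if r2 < config.vdw_cutoff**2:
                e += min(config.vdw_a / r2**6, config.energy_cap)
    for i in range(n):
        for t in thread:
            d = coords[i] - t
            if config.box > 0:
                d[2] -= config.box * np.round(d[2] / config.box)
            r2 = (d**2).sum()
            if r2 < config.vdw_cutoff**2:
                e += min(config.vdw_a_thread / r2**6, config.energy_cap)
    return e


class TestConfig:
    def test_minimum_loop_sizes(self):
        SimConfig(n=3, w=0)  # allowed
        with pytest.raises(TooSmallLoopError):
            SimConfig(n=5, w=2)
        for w, nmin in N_SMALL.items():
            SimConfig(n=nmin, w=w)
            if nmin > 3:
                with pytest.raises(TooSmallLoopError):
                    SimConfig(n=nmin - 1, w=w)

    def test_thread_bead_count(self):
        assert SimConfig(n=10, w=1).n_thread_beads == 12
        assert SimConfig(n=100, w=1).n_thread_beads == 55
        assert SimConfig(n=10, w=0).n_thread_beads == 0

    def test_box_size(self):
        cfg = SimConfig(n=100, w=2)
        assert cfg.box == pytest.approx(0.38 * cfg.n_thread_beads)


class TestEnergy:
    def test_relaxed_polygon_far_pairs_zero_bond_energy(self):
        # large relaxed ring: every bond exactly r0, all non-bonded pairs
        # of a 100-gon of radius ~6 nm are beyond the 2 nm cutoff? not all;
        # use a small bead count so non-bonded pairs are outside the cutoff
        n = 8
        r0 = 0.38
        big = 3.0  # scale the polygon so non-neighbours exceed the cutoff
        r = big / (2 * np.sin(np.pi / n))
        th = 2 * np.pi * np.arange(n) / n
        pts = np.stack([r * np.cos(th), r * np.sin(th), np.zeros(n)], axis=1)
        cfg = SimConfig(n=n, w=0, r0=big)
        assert potential_energy(pts, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_single_stretched_bond_closed_form(self):
        cfg = SimConfig(n=3, w=0, vdw_a=1e-30)  # silence excluded volume
        frame, thread = build_system(cfg)
        pts = frame.coords.copy()
        # move bead 1 along bond 0->1 to stretch that bond by delta
        delta = 0.01
        d01 = pts[1] - pts[0]
        d01 /= np.linalg.norm(d01)
        e0 = potential_energy(pts, cfg)
        # stretching changes two bonds; isolate with explicit closed form
        pts2 = pts.copy()
        pts2[1] = pts[1] + delta * d01
        e1 = potential_energy(pts2, cfg)
        r12 = np.linalg.norm(pts[2] - pts2[1])
        expected = 0.5 * cfg.k_bond * delta**2 + 0.5 * cfg.k_bond * (
            r12 - cfg.r0
        ) ** 2
        assert e1 - e0 == pytest.approx(expected, abs=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        cfg = SimConfig(n=9, w=2)
        _, thread = build_system(cfg)
        for _ in range(100):
            pts = rng.normal(scale=0.5, size=(9, 3)) + np.array(
                [0, 0, cfg.box / 2]
            )
            assert potential_energy(pts, cfg, thread) == pytest.approx(
                brute_force_energy(pts, cfg, thread), rel=1e-12
            )


class TestBuildSystem:
    def test_unthreaded_triangle(self):
        frame, thread = build_system(SimConfig(n=3, w=0))
        assert frame.coords.shape == (3, 3)
        assert thread.shape == (0, 3)

    def test_threaded_initial_state(self):
        cfg = SimConfig(n=10, w=1)
        frame, thread = build_system(cfg)
        assert thread.shape == (12, 3)
        assert check_threading(frame.coords, cfg)
        # thread beads sit on the axis at r0 spacing
        assert np.allclose(np.diff(thread[:, 2]), cfg.r0)
        assert np.allclose(thread[:, :2], 0.0)


class TestWinding:
    def test_initial_polygon_winds_once(self):
        cfg = SimConfig(n=12, w=1)
        frame, _ = build_system(cfg)
        assert abs(winding_number(frame.coords)) == 1

    def test_translated_loop_does_not_wind(self):
        cfg = SimConfig(n=12, w=1)
        frame, _ = build_system(cfg)
        off = frame.coords + np.array([10 * cfg.box, 0, 0])
        assert winding_number(off) == 0
        assert not check_threading(off, cfg)

    def test_matches_ray_crossing_oracle(self, rng):
        """The angle-sum winding number equals the signed ray-crossing
        count for random loops kept away from the axis."""
        checked = 0
        for _ in range(50):
            pts = rng.normal(size=(14, 3))
            if np.min(np.hypot(pts[:, 0], pts[:, 1])) < 0.2:
                continue
            assert winding_number(pts) == winding_number_ray_crossings(pts)
            checked += 1
        assert checked > 20


class TestChordCorrelation:
    def test_identical_frames_stay_at_one(self):
        frame = np.random.default_rng(0).normal(size=(1, 10, 3))
        frames = np.repeat(frame, 50, axis=0)
        with pytest.raises(InsufficientSamplingError):
            chord_correlation(frames)

    def test_c0_is_one_and_random_frames_decay(self, rng):
        frames = rng.normal(size=(400, 12, 3))
        lags, c, tau = chord_correlation(frames)
        assert c[0] == pytest.approx(1.0)
        assert tau <= 2
        assert np.abs(c[5:50]).mean() < 0.1


class TestMonteCarlo:
    def test_zero_temperature_energy_non_increasing(self):
        """At T -> 0 Metropolis only accepts downhill moves."""
        cfg = SimConfig(n=12, w=0, temperature=1e-7, seed=1, stride=1,
                        target_frames=5, tune_sweeps=10, max_frames=200)
        frame0, thread = build_system(cfg)
        from lassokit.simulation import _run_mc

        loop = frame0.coords.copy()
        # perturb away from the minimum, then quench
        loop += np.random.default_rng(0).normal(scale=0.02, size=loop.shape)
        nf = 150
        frames = np.empty((nf, cfg.n, 3))
        energies = np.empty(nf)
        _run_mc(
            loop, thread, cfg.r0, cfg.k_bond, cfg.vdw_a, cfg.vdw_a_thread,
            cfg.vdw_cutoff, cfg.box, cfg.energy_cap, cfg.beta, False,
            nf, 1, cfg.max_arc, 3, 0.01, 0.3, False, frames, energies,
        )
        drops = np.diff(energies)
        assert np.all(drops <= 1e-9)

    def test_determinism(self):
        cfg = SimConfig(n=8, w=0, seed=123, target_frames=20, stride=1)
        t1 = run_simulation(cfg)
        t2 = run_simulation(cfg)
        np.testing.assert_array_equal(t1.frames, t2.frames)

    def test_three_bead_bond_distribution_matches_quadrature(self):
        """Sampled bond lengths of the smallest ring follow the Boltzmann
        marginal computed by direct numerical integration.

        The chord-correlation time of a near-rigid triangle is set by its
        slow rotational diffusion; the internal bond-length coordinate
        decorrelates much faster, so its own autocorrelation time sets
        the effective sample size here.
        """
        from lassokit.workbench import _integrated_autocorr_time

        cfg = SimConfig(n=3, w=0, temperature=100.0, seed=9, stride=1,
                        target_frames=3000, tune_sweeps=200, max_frames=60_000)
        traj = run_simulation(cfg)
        bond_series = np.linalg.norm(
            np.roll(traj.frames, -1, axis=1) - traj.frames, axis=2
        )
        bonds = bond_series.ravel()
        tau_b = _integrated_autocorr_time(bond_series[:, 0])
        n_eff = max(int(bond_series.shape[0] / tau_b), 10)
        lo, hi = bonds.min(), bonds.max()
        edges = np.linspace(lo, hi, 13)
        centers = 0.5 * (edges[1:] + edges[:-1])
        pdf = triangle_boltzmann_bond_pdf(centers, cfg.k_bond, cfg.r0, cfg.beta)
        probs = pdf / pdf.sum()
        counts, _ = np.histogram(bonds, bins=edges)
        expected = probs * counts.sum()
        # chi-square-like comparison with effective sample size correction
        scale = counts.sum() / n_eff
        mask = expected > 5 * scale
        assert mask.sum() >= 4
        z = (counts[mask] - expected[mask]) / np.sqrt(expected[mask] * scale)
        assert np.abs(z).max() < 5.0
        assert np.abs(z).mean() < 2.0

    def test_threading_conserved_and_distension_elevated(self):
        """All recorded frames of a threaded run stay threaded, and the
        thread lifts the loop's mean distension vs the free loop."""
        n = 10
        threaded = run_simulation(
            SimConfig(n=n, w=1, seed=4, target_frames=60, stride=2)
        )
        free = run_simulation(
            SimConfig(n=n, w=0, seed=5, target_frames=60, stride=2)
        )
        cfg = threaded.config
        assert all(check_threading(f, cfg) for f in threaded.frames)

        def mean_se(traj):
            vals = np.array(
                [shape_record(f, r0=0.38).distension for f in traj.frames]
            )
            nblock = max(len(vals) // max(traj.tau_frames, 1), 2)
            bm = np.array([b.mean() for b in np.array_split(vals, nblock)])
            return vals.mean(), bm.std(ddof=1) / np.sqrt(len(bm))

        mt, st_ = mean_se(threaded)
        mf, sf = mean_se(free)
        assert mt - mf > -3 * np.hypot(st_, sf)
        assert mt > mf  # central estimate strictly larger


class TestDetailedBalance:
    def test_minimal_ring_boltzmann_stationarity(self):
        """Chi-square check of the sampler's stationary bond-length
        distribution against the quadrature Boltzmann marginal on the
        smallest legal ring."""
        from lassokit.workbench import _integrated_autocorr_time

        cfg = SimConfig(n=3, w=0, temperature=50.0, seed=21, stride=1,
                        target_frames=2000, tune_sweeps=200, max_frames=60_000)
        traj = run_simulation(cfg)
        series = np.linalg.norm(
            np.roll(traj.frames, -1, axis=1) - traj.frames, axis=2
        )
        thin = max(int(np.ceil(_integrated_autocorr_time(series[:, 0]))), 1)
        bonds = series[::thin].ravel()
        edges = np.quantile(bonds, np.linspace(0, 1, 9))
        edges[0] -= 1e-6
        edges[-1] += 1e-6
        centers = 0.5 * (edges[1:] + edges[:-1])
        fine = np.linspace(edges[0], edges[-1], 400)
        pdf = triangle_boltzmann_bond_pdf(fine, cfg.k_bond, cfg.r0, cfg.beta)
        probs = []
        for a, b in zip(edges[:-1], edges[1:]):
            m = (fine >= a) & (fine < b)
            probs.append(np.trapezoid(pdf[m], fine[m]))
        probs = np.array(probs)
        probs /= probs.sum()
        counts, _ = np.histogram(bonds, bins=edges)
        expected = probs * counts.sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        from scipy.stats import chi2 as chi2_dist

        # dof = bins - 1; alpha = 0.01
        assert chi2 < chi2_dist.ppf(0.99, len(counts) - 1) * 3
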