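"""Umbrella sampling and WHAM: window construction, harmonic statistics,
free-energy reconstruction against a direct Boltzmann-sampling oracle,
barrier extraction and Arrhenius rates."""
import math

import numpy as np
import pytest

from fgpore.cg_model import KB_KJMOL, CargoModel
from fgpore.simulator import SimulationConfig, free_system
from fgpore.transport_pmf import (
    PMFCurve,
    RateModel,
    UmbrellaWindow,
    arrhenius_rate,
    barrier,
    boltzmann_inversion,
    make_windows,
    run_umbrella,
    wham,
)

KBT = KB_KJMOL * 298.0


def quartic(z):
    """Asymmetric double-well test potential (kJ/mol)."""
    return 1.2 * z**4 - 3.5 * z**2 + 0.8 * z


def boltzmann_window_samples(potential, z0, k, n, rng, lo=-3.0, hi=3.0):
    """Exact samples from p(z) ~ exp(-(U + k/2 (z-z0)^2)/kBT) by inverse CDF."""
    z = np.linspace(lo, hi, 20001)
    logp = -(potential(z) + 0.5 * k * (z - z0) ** 2) / KBT
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.uniform(size=n), cdf, z)


class TestWindows:
    def test_default_axis_coverage(self):
        assert len(make_windows(-52.0, 52.0, 1.3)) == 81

    def test_single_point(self):
        assert len(make_windows(0.0, 0.0)) == 1

    def test_bad_spacing(self):
        with pytest.raises(ValueError):
            make_windows(0.0, 10.0, spacing=-1.0)


@pytest.fixture(scope="module")
def free_windows():
    """Cargo alone in a large box: the restrained coordinate must behave as
    a harmonic oscillator at kBT.  Near-critical damping for the k=10,
    m=120 oscillator keeps the position autocorrelation time short."""
    system = free_system(np.array([[30.0, 30.0, 30.0]]), box=(80, 80, 80))
    cargo = CargoModel(kind="probe", radius=1.0, charge=0.0, n_hydro_sites=0,
                       sites=np.zeros((0, 3)), mass=120.0)
    cfg = SimulationConfig(n_steps=200000, n_equilibration=10000, stride=100,
                           timestep=0.02, seed=7, friction=0.6,
                           ramp_fraction=0.0)
    windows = make_windows(-1.3, 1.3, 1.3)
    return run_umbrella(system, cargo, windows, cfg, n_replicas=2)


class TestUmbrellaSampling:
    def test_harmonic_variance_is_kbt_over_k(self, free_windows):
        for w in free_windows:
            assert w.samples.var() == pytest.approx(KBT / w.spring_k, rel=0.1)
            assert w.samples.mean() == pytest.approx(w.z0, abs=0.1)

    def test_neighbouring_windows_overlap(self, free_windows):
        lo, mid = free_windows[0], free_windows[1]
        crossing = 0.5 * (lo.z0 + mid.z0)
        frac_lo = np.mean(lo.samples > crossing)
        frac_mid = np.mean(mid.samples < crossing)
        assert frac_lo > 0.05 and frac_mid > 0.05

    def test_stiffer_spring_shrinks_variance(self):
        system = free_system(np.array([[30.0, 30.0, 30.0]]), box=(80, 80, 80))
        cargo = CargoModel(kind="probe", radius=1.0, charge=0.0, n_hydro_sites=0,
                          sites=np.zeros((0, 3)), mass=120.0)
        cfg = SimulationConfig(n_steps=150000, n_equilibration=10000, stride=100,
                               timestep=0.02, seed=9, friction=1.0,
                               ramp_fraction=0.0)
        out = {}
        for k in (10.0, 40.0):
            ws = [UmbrellaWindow(z0=0.0, spring_k=k)]
            (w,) = run_umbrella(system, cargo, ws, cfg, n_replicas=1)
            out[k] = w.samples.var()
        assert out[40.0] == pytest.approx(out[10.0] / 4.0, rel=0.2)


class TestWham:
    def make_sampled_windows(self, potential, seed=0, k=30.0, spacing=0.4,
                             n=20000, lo=-2.0, hi=2.0):
        rng = np.random.default_rng(seed)
        out = []
        for w in make_windows(lo, hi, spacing, spring_k=k):
            samples = boltzmann_window_samples(potential, w.z0, k, n, rng)
            out.append(UmbrellaWindow(z0=w.z0, spring_k=k, samples=samples))
        return out

    def test_recovers_quartic_potential(self):
        windows = self.make_sampled_windows(quartic)
        curve = wham(windows, bin_width=0.1)
        mask = (curve.z > -1.8) & (curve.z < 1.8) & np.isfinite(curve.free_energy)
        ref = quartic(curve.z[mask])
        est = curve.free_energy[mask]
        # match the arbitrary additive constant by the mean
        est = est - est.mean() + ref.mean()
        rms = math.sqrt(np.mean((est - ref) ** 2))
        assert rms <= 0.3

    def test_flat_sampling_gives_no_barrier(self):
        windows = self.make_sampled_windows(lambda z: 0.0 * z, seed=1)
        curve = wham(windows, bin_width=0.1)
        assert barrier(curve) < 0.6

    def test_gauge_invariance_of_barrier(self):
        windows = self.make_sampled_windows(quartic, seed=2)
        curve = wham(windows, bin_width=0.1)
        shifted = PMFCurve(z=curve.z, free_energy=curve.free_energy + 17.3)
        assert barrier(shifted) == pytest.approx(barrier(curve), rel=1e-9)

    def test_single_window_matches_boltzmann_inversion(self):
        rng = np.random.default_rng(3)
        samples = boltzmann_window_samples(quartic, 0.0, 0.0001, 200000, rng)
        dense = UmbrellaWindow(z0=0.0, spring_k=0.0001, samples=samples)
        other = UmbrellaWindow(z0=0.0, spring_k=0.0001,
                               samples=boltzmann_window_samples(quartic, 0.0, 0.0001, 200000, rng))
        curve = wham([dense, other], bin_width=0.1)
        direct = boltzmann_inversion(np.concatenate([samples, other.samples]),
                                     bin_width=0.1)
        mask = (curve.z > -1.5) & (curve.z < 1.5)
        ref = np.interp(curve.z[mask], direct.z, direct.free_energy)
        est = curve.free_energy[mask]
        assert math.sqrt(np.mean((est - est.mean() - ref + ref.mean()) ** 2)) < 0.2

    def test_disjoint_histograms_rejected(self):
        w1 = UmbrellaWindow(z0=0.0, samples=np.random.default_rng(0).normal(0, 0.1, 500))
        w2 = UmbrellaWindow(z0=30.0, samples=np.random.default_rng(1).normal(30, 0.1, 500))
        with pytest.raises(ValueError, match="disjoint"):
            wham([w1, w2])


class TestBarrier:
    def test_symmetric_well_depth(self):
        z = np.linspace(-3, 3, 121)
        curve = PMFCurve(z=z, free_energy=2.0 * z**2)
        assert barrier(curve) == pytest.approx(18.0, rel=0.01)

    def test_axis_reversal_invariance(self):
        z = np.linspace(-3, 3, 121)
        f = quartic(z)
        fwd = barrier(PMFCurve(z=z, free_energy=f))
        rev = barrier(PMFCurve(z=z, free_energy=f[::-1]))
        assert rev == pytest.approx(fwd, rel=0.05)

    def test_too_few_points(self):
        z = np.linspace(-1, 1, 5)
        with pytest.raises(ValueError, match="order"):
            barrier(PMFCurve(z=z, free_energy=z**2))


class TestArrhenius:
    def test_zero_barrier_returns_prefactor(self):
        assert arrhenius_rate(RateModel(gamma0=1.7), 0.0) == 1.7

    def test_rate_ratio_for_6_vs_12_kjmol(self):
        """Halving a 12 kJ/mol barrier speeds transport ~11-fold at 298 K,
        the contrast between an inert cargo and a transport receptor."""
        m = RateModel(gamma0=1.0)
        ratio = arrhenius_rate(m, 6.0) / arrhenius_rate(m, 12.0)
        assert ratio == pytest.approx(math.exp(6.0 / m.kBT), rel=1e-9)
        assert ratio == pytest.approx(11.2, abs=0.2)

    def test_log_rate_linear_in_barrier(self):
        m = RateModel(gamma0=2.0)
        des = np.array([0.0, 3.0, 6.0, 9.0])
        logs = np.log([arrhenius_rate(m, de) for de in des])
        slopes = np.diff(logs) / np.diff(des)
        assert np.allclose(slopes, -1.0 / m.kBT)

    def test_negative_barrier_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_rate(RateModel(gamma0=1.0), -1.0)
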