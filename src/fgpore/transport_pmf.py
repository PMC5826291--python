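"""Umbrella sampling along the pore axis, WHAM, barriers and event rates.

A cargo sphere is restrained by a harmonic spring (default 10 kJ/mol/nm^2)
at axial positions spaced 1.3 nm apart.  The biased z histograms are
combined into a potential of mean force with the weighted histogram
analysis method (WHAM).  The transport barrier is the difference between
the maximum and the minimum of the PMF after smoothing the z < 0 and z > 0
branches with independent sixth-order polynomials, and translocation rates
follow the Arrhenius relation Gamma = Gamma0 * exp(-dE / kBT).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cg_model import KB_KJMOL
from .simulator import RestraintSpec, SimulationConfig, run_dynamics


@dataclass
class UmbrellaWindow:
    z0: float                       # nm
    spring_k: float = 10.0          # kJ/mol/nm^2
    samples: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def bias(self, z: np.ndarray) -> np.ndarray:
        return 0.5 * self.spring_k * (np.asarray(z, float) - self.z0) ** 2


@dataclass
class PMFCurve:
    z: np.ndarray                   # nm
    free_energy: np.ndarray         # kJ/mol, defined up to a constant
    smoothed: np.ndarray | None = None

    def smooth(self, order: int = 6) -> "PMFCurve":
        """Fit z<0 and z>0 branches with independent polynomials.

        The branches are fitted separately and concatenated, mirroring how
        transport barriers are read off measured profiles.
        """
        valid = np.isfinite(self.free_energy)
        z, f = self.z[valid], self.free_energy[valid]
        out = np.full(len(self.z), np.nan)
        branches = [(z <= 0, self.z <= 0), (z >= 0, self.z >= 0)]
        if not any(sel.sum() > order for sel, _ in branches):
            raise ValueError(f"fewer PMF points than polynomial order {order}")
        for sel_fit, sel_eval in branches:
            if sel_fit.sum() <= order:
                continue  # one-sided profile
            coef = np.polynomial.polynomial.polyfit(z[sel_fit], f[sel_fit], order)
            # evaluate only inside the fitted span (no polynomial extrapolation)
            span = sel_eval & (self.z >= z[sel_fit].min()) & (self.z <= z[sel_fit].max())
            out[span] = np.polynomial.polynomial.polyval(self.z[span], coef)
        return PMFCurve(z=self.z, free_energy=self.free_energy, smoothed=out)


@dataclass
class RateModel:
    gamma0: float                  # Hz, bare-pore event frequency scale
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.gamma0 < 0:
            raise ValueError("gamma0 must be >= 0")

    @property
    def kBT(self) -> float:
        return KB_KJMOL * self.temperature


def make_windows(
    z_min: float, z_max: float, spacing: float = 1.3, spring_k: float = 10.0
) -> list[UmbrellaWindow]:
    """Regularly spaced umbrella windows covering [z_min, z_max]."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if z_max < z_min:
        raise ValueError("z_max must be >= z_min")
    n = int(math.floor((z_max - z_min) / spacing)) + 1
    return [UmbrellaWindow(z0=z_min + i * spacing, spring_k=spring_k) for i in range(n)]


def run_umbrella(
    system,
    cargo,
    windows: list[UmbrellaWindow],
    config: SimulationConfig,
    ff=None,
    n_replicas: int = 2,
) -> list[UmbrellaWindow]:
    """Sample each window with the restrained cargo; fills window samples.

    ``n_replicas`` independent starting configurations per window (different
    seeds) are pooled.  A window whose sample mean deviates from its target
    by more than three thermal widths is flagged with a warning.
    """
    out = []
    for w_i, w in enumerate(windows):
        samples = []
        for rep in range(n_replicas):
            cfg = SimulationConfig(**{**vars(config), "seed": config.seed + 1000 * w_i + rep})
            traj = run_dynamics(
                system, cfg, ff=ff, cargo=cargo,
                cargo_start=np.array([0.0, 0.0, w.z0]),
                restraint=RestraintSpec(z0=w.z0, spring_k=w.spring_k),
            )
            samples.append(traj.cargo_positions[:, 2])
        z = np.concatenate(samples)
        thermal = math.sqrt(KB_KJMOL * config.temperature / w.spring_k)
        if abs(z.mean() - w.z0) > 3.0 * thermal:
            warnings.warn(
                f"window at z0={w.z0}: mean deviates from target by more than "
                "3 thermal widths (poor restraint or strong mean force)"
            )
        out.append(UmbrellaWindow(z0=w.z0, spring_k=w.spring_k, samples=z))
    return out


def wham(
    windows: list[UmbrellaWindow],
    bin_width: float = 0.1,
    temperature: float = 298.0,
    tolerance: float = 1e-6,
    max_iter: int = 100000,
    min_bin_count: int = 10,
) -> PMFCurve:
    """Weighted histogram analysis of biased umbrella samples.

    Iterates the self-consistent WHAM equations until the window offsets
    change by less than ``tolerance`` (kJ/mol).  Raises if the windows do
    not overlap into a single connected profile.  Bins visited fewer than
    ``min_bin_count`` times in total are reported as NaN (their free
    energies would be sampling noise).
    """
    filled = [w for w in windows if w.n_samples > 0]
    if len(filled) < 2:
        raise ValueError("need at least two windows with samples")
    kBT = KB_KJMOL * temperature
    z_lo = min(w.samples.min() for w in filled)
    z_hi = max(w.samples.max() for w in filled)
    edges = np.arange(z_lo - bin_width, z_hi + 2 * bin_width, bin_width)
    centers = 0.5 * (edges[1:] + edges[:-1])
    n_bins = len(centers)
    n_win = len(filled)
    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in filled])
    n_i = counts.sum(axis=1).astype(float)

    # overlap connectivity: grow the reachable support from window 0
    support = counts > 0
    reached = support[0].copy()
    changed = True
    while changed:
        changed = False
        for i in range(n_win):
            if np.any(support[i] & reached) and np.any(support[i] & ~reached):
                reached |= support[i]
                changed = True
    if not all(np.any(support[i] & reached) for i in range(n_win)):
        raise ValueError("disjoint umbrella histograms: no overlap path")

    bias = np.stack([w.bias(centers) for w in filled])  # (n_win, n_bins)
    f = np.zeros(n_win)
    total = counts.sum(axis=0)
    for _ in range(max_iter):
        # P(z_b) ~ total_b / sum_i N_i exp((f_i - w_ib)/kBT)
        denom = np.einsum("i,ib->b", n_i, np.exp((f[:, None] - bias) / kBT))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        w_new = -kBT * np.log(np.einsum("b,ib->i", p, np.exp(-bias / kBT)))
        w_new -= w_new[0]
        if np.max(np.abs(w_new - f)) < tolerance:
            f = w_new
            break
        f = w_new
    denom = np.einsum("i,ib->b", n_i, np.exp((f[:, None] - bias) / kBT))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, total / denom, np.nan)
        free = -kBT * np.log(p)
    free[total < min_bin_count] = np.nan
    free -= np.nanmin(free)
    return PMFCurve(z=centers, free_energy=free)


def barrier(curve: PMFCurve, order: int = 6) -> float:
    """Transport barrier dE = max - min of the smoothed PMF (kJ/mol)."""
    smoothed = curve.smoothed
    if smoothed is None:
        smoothed = curve.smooth(order=order).smoothed
    s = smoothed[np.isfinite(smoothed)]
    return float(s.max() - s.min())


def arrhenius_rate(model: RateModel, delta_e: float) -> float:
    """Gamma = Gamma0 * exp(-dE / kBT), in Hz."""
    if delta_e < 0:
        raise ValueError("barrier must be >= 0")
    return model.gamma0 * math.exp(-delta_e / model.kBT)


def boltzmann_inversion(
    z_samples: np.ndarray, bin_width: float = 0.1, temperature: float = 298.0
) -> PMFCurve:
    """PMF from unbiased dense sampling: F = -kBT ln p(z).

    The single-window limit that WHAM must agree with.
    """
    kBT = KB_KJMOL * temperature
    edges = np.arange(z_samples.min(), z_samples.max() + bin_width, bin_width)
    h, _ = np.histogram(z_samples, bins=edges, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    with np.errstate(divide="ignore"):
        f = -kBT * np.log(h)
    f -= np.nanmin(f[np.isfinite(f)])
    return PMFCurve(z=centers, free_energy=f)


def write_pmf(curve: PMFCurve, path) -> None:
    with open(path, "w") as fh:
        fh.write("z_nm\tF_kJmol\n")
        for z, f in zip(curve.z, curve.free_energy):
            fh.write(f"{z:.4f}\t{f:.6f}\n")
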