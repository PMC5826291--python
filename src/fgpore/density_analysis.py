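"""Time-averaged mass-density fields and their cylindrical reductions.

Trajectories are binned onto a 3D grid of (0.5 nm)^3 cells (particle-in-
cell counting, no kernel smoothing); the per-cell number density averaged
over frames is multiplied by the bead masses to give a mass density, stored
in mg/ml (1 Da/nm^3 = 1.66054 mg/ml).  The grid is reduced azimuthally to
(r, z) maps and further to radial profiles for the pore window
(|z| < 10 nm, twenty 1 nm slices for the standard 20 nm membrane) and the
access windows (10 nm < |z| < 40 nm).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: mg/ml per Da/nm^3
DA_PER_NM3_TO_MG_PER_ML = 1.66054

PORE_WINDOW = (-10.0, 10.0)
ACCESS_WINDOW = (10.0, 40.0)  # applied to |z|


@dataclass
class DensityGrid3D:
    edges: tuple[np.ndarray, np.ndarray, np.ndarray]  # bin edges, nm
    density: np.ndarray                               # mg/ml, (nx, ny, nz)
    n_frames: int
    cell: float = 0.5

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    def total_mass(self) -> float:
        """Total chain mass represented by the grid, in Da (frame average)."""
        return float(self.density.sum() * self.cell**3 / DA_PER_NM3_TO_MG_PER_ML)


@dataclass
class DensityMapRZ:
    r_edges: np.ndarray
    z_edges: np.ndarray
    density: np.ndarray        # (nr, nz), mg/ml, azimuthal mean

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[1:] + self.r_edges[:-1])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[1:] + self.z_edges[:-1])

    def total_mass(self) -> float:
        dr = np.diff(self.r_edges)
        dz = np.diff(self.z_edges)
        annulus = 2.0 * math.pi * self.r_centers * dr
        return float((self.density * annulus[:, None] * dz[None, :]).sum()
                     / DA_PER_NM3_TO_MG_PER_ML)


@dataclass
class RadialProfile:
    r: np.ndarray              # bin centres, nm
    rho: np.ndarray            # z-averaged density, mg/ml
    z_window: tuple[float, float]
    per_slice: np.ndarray | None = None   # (n_z_slices, nr)
    z_slices: np.ndarray | None = None


def accumulate_grid(
    traj,
    masses: np.ndarray | None = None,
    cell: float = 0.5,
    box: tuple[float, float, float] | None = None,
) -> DensityGrid3D:
    """Bin trajectory frames into a time-averaged 3D mass-density grid."""
    masses = traj.masses if masses is None else np.asarray(masses, float)
    if box is None:
        span = np.abs(traj.frames).max(axis=(0, 1)) + cell
        half = np.ceil(span / cell) * cell
    else:
        half = np.asarray(box, float) / 2.0
    edges = tuple(np.arange(-h, h + cell / 2, cell) for h in half)
    shape = tuple(len(e) - 1 for e in edges)
    acc = np.zeros(shape)
    for fi, frame in enumerate(traj.frames):
        if np.any(np.abs(frame) > half):
            bad = int(np.argmax(np.any(np.abs(frame) > half, axis=1)))
            raise ValueError(f"bead {bad} outside box in frame {fi}")
        h, _ = np.histogramdd(frame, bins=edges, weights=masses)
        acc += h
    acc /= len(traj.frames)
    rho = acc / cell**3 * DA_PER_NM3_TO_MG_PER_ML
    return DensityGrid3D(edges=edges, density=rho, n_frames=len(traj.frames), cell=cell)


def rz_average(grid: DensityGrid3D, r_bin: float | None = None) -> DensityMapRZ:
    """Azimuthal mean of the grid about the pore (z) axis.

    Each cubic cell contributes its density at the radius of its centre;
    since all cells share a volume, the plain mean over the cells of an
    annulus is the correctly volume-weighted azimuthal average.
    """
    cx, cy, cz = grid.centers
    if not (cx.min() < 0 < cx.max() and cy.min() < 0 < cy.max()):
        raise ValueError("pore axis (x=y=0) not inside the grid")
    r_bin = r_bin or grid.cell
    rr = np.hypot(cx[:, None], cy[None, :])
    r_max = min(cx.max(), cy.max())
    r_edges = np.arange(0.0, r_max + r_bin / 2, r_bin)
    idx = np.clip(np.digitize(rr.ravel(), r_edges) - 1, 0, len(r_edges) - 2)
    nr, nz = len(r_edges) - 1, len(cz)
    out = np.zeros((nr, nz))
    counts = np.bincount(idx, minlength=nr)
    inside = rr.ravel() <= r_edges[-1]
    for k in range(nz):
        sums = np.bincount(idx[inside], weights=grid.density[:, :, k].ravel()[inside],
                           minlength=nr)
        cnt = np.bincount(idx[inside], minlength=nr)
        out[:, k] = np.where(cnt > 0, sums / np.maximum(cnt, 1), 0.0)
    return DensityMapRZ(r_edges=r_edges, z_edges=grid.edges[2], density=out)


def radial_profile(
    grid: DensityGrid3D,
    z_window: tuple[float, float] | str = "pore",
    slice_thickness: float = 1.0,
    r_bin: float = 0.5,
) -> RadialProfile:
    """Radial density curves per z slice and their z average.

    ``z_window`` may be ``"pore"`` (|z| < 10 nm, sliced into 1 nm discs),
    ``"access"`` (10 nm < |z| < 40 nm, both sides pooled) or an explicit
    (z_lo, z_hi) pair.
    """
    rz = rz_average(grid, r_bin=r_bin)
    zc = rz.z_centers
    if z_window == "pore":
        lo, hi = PORE_WINDOW
        mask = (zc > lo) & (zc < hi)
    elif z_window == "access":
        lo, hi = ACCESS_WINDOW
        mask = (np.abs(zc) > lo) & (np.abs(zc) < hi)
    else:
        lo, hi = z_window
        mask = (zc > lo) & (zc < hi)
    if not np.any(mask):
        raise ValueError(f"empty z window {z_window!r}")
    sel = rz.density[:, mask]
    z_sel = zc[mask]
    # group into slices of the requested thickness
    slice_ids = np.floor((z_sel - z_sel.min()) / slice_thickness).astype(int)
    occupied = [s for s in range(slice_ids.max() + 1) if np.any(slice_ids == s)]
    per_slice = np.zeros((len(occupied), sel.shape[0]))
    z_slices = np.zeros(len(occupied))
    for k, s in enumerate(occupied):
        cols = slice_ids == s
        per_slice[k] = sel[:, cols].mean(axis=1)
        z_slices[k] = z_sel[cols].mean()
    window = (lo, hi) if not isinstance(z_window, str) else (
        PORE_WINDOW if z_window == "pore" else ACCESS_WINDOW
    )
    return RadialProfile(
        r=rz.r_centers, rho=sel.mean(axis=1), z_window=window,
        per_slice=per_slice, z_slices=z_slices,
    )


def central_density(profile: RadialProfile, r_max: float = 5.0) -> float:
    """Mean density within ``r_max`` of the pore axis (mg/ml)."""
    mask = profile.r <= r_max
    return float(profile.rho[mask].mean())


def mean_pore_density(grid: DensityGrid3D, radius: float, height: float = 20.0) -> float:
    """Mean density inside the pore cylinder (mg/ml).

    This is the characteristic in-pore protein density: total chain mass
    found inside the cylinder divided by the cylinder volume.
    """
    cx, cy, cz = grid.centers
    rr = np.hypot(cx[:, None], cy[None, :])
    in_r = rr <= radius
    in_z = np.abs(cz) <= height / 2.0
    vals = grid.density[in_r][:, in_z]
    return float(vals.mean())


def write_profile(profile: RadialProfile, path) -> None:
    header = (f"# radial density profile; z window {profile.z_window} nm\n"
              "r_nm\trho_mg_ml\n")
    with open(path, "w") as fh:
        fh.write(header)
        for r, rho in zip(profile.r, profile.rho):
            fh.write(f"{r:.3f}\t{rho:.6f}\n")


def read_profile(path) -> RadialProfile:
    data = np.loadtxt(path, skiprows=2)
    return RadialProfile(r=data[:, 0], rho=data[:, 1], z_window=(math.nan, math.nan))
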