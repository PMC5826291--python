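"""Energy minimisation and Langevin dynamics of bead assemblies.

The integrator is a BAOAB-split Langevin scheme over the coarse-grained
force field, self-contained and bit-reproducible for a given seed (single
thread).  Units: kJ/mol, nm, Da and ps, so kB T = 2.479 kJ/mol at 298 K and
a bead of mass m with friction gamma (1/ps) diffuses with D = kBT/(m gamma)
in nm^2/ps.

Long-range (hydrophobic-attraction and electrostatic) prefactors are ramped
linearly from zero over a warm-up window after minimisation, mirroring the
usual gradual switch-on protocol for dense grafted systems.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .cg_model import COULOMB_KJMOL_NM, KB_KJMOL, CargoModel, ForceField
from .pore_builder import SystemAssembly


@dataclass
class SimulationConfig:
    timestep: float = 0.01          # ps
    friction: float = 0.5           # 1/ps
    temperature: float = 298.0      # K
    n_steps: int = 20000
    n_equilibration: int = 2000     # discarded steps (default 10% of run)
    stride: int = 100               # output every this many steps
    seed: int = 0
    ramp_fraction: float = 0.05     # warm-up window for long-range forces
    skin: float = 0.3               # nm, neighbour-list skin
    check_every: int = 10           # displacement-criterion check interval
    tether_k: float = 400.0         # kJ/mol/nm^2, anchor tether spring
    container_k: float = 100.0      # kJ/mol/nm^2, box/membrane walls
    max_neighbors: int = 140        # pair-list capacity per bead

    def __post_init__(self) -> None:
        if self.n_equilibration >= self.n_steps:
            raise ValueError("n_equilibration must be smaller than n_steps")
        if self.n_equilibration % self.stride:
            raise ValueError("n_equilibration must be a multiple of stride")

    @property
    def kBT(self) -> float:
        return KB_KJMOL * self.temperature


@dataclass
class RestraintSpec:
    """Harmonic axial restraint on the cargo centre (umbrella window)."""

    z0: float                      # nm
    spring_k: float = 10.0         # kJ/mol/nm^2

    def __post_init__(self) -> None:
        if self.spring_k <= 0:
            raise ValueError("restraint spring constant must be positive")


@dataclass
class Trajectory:
    times: np.ndarray              # ps, post-equilibration frames
    frames: np.ndarray             # (F, N_mobile, 3)
    wall_positions: np.ndarray
    kinetic: np.ndarray            # kJ/mol per frame
    potential: np.ndarray
    masses: np.ndarray             # per mobile bead
    chains: list
    config: SimulationConfig
    cargo_positions: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def kinetic_temperature(self) -> float:
        """Equipartition estimate of the sampled temperature (K)."""
        ndof = 3 * self.frames.shape[1] + (3 if self.cargo_positions is not None else 0)
        return float(2.0 * np.mean(self.kinetic) / (ndof * KB_KJMOL))

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f["times"] = self.times
            f["frames"] = self.frames
            f["wall_positions"] = self.wall_positions
            f["kinetic"] = self.kinetic
            f["potential"] = self.potential
            f["masses"] = self.masses
            f["chains"] = np.asarray(self.chains, dtype=np.int64).reshape(-1, 2)
            if self.cargo_positions is not None:
                f["cargo_positions"] = self.cargo_positions
            for k, v in vars(self.config).items():
                f.attrs[k] = v

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            cfg = SimulationConfig(**{k: f.attrs[k].item() if hasattr(f.attrs[k], "item") else f.attrs[k] for k in f.attrs})
            return cls(
                times=f["times"][:],
                frames=f["frames"][:],
                wall_positions=f["wall_positions"][:],
                kinetic=f["kinetic"][:],
                potential=f["potential"][:],
                masses=f["masses"][:],
                chains=[tuple(r) for r in f["chains"][:]],
                config=cfg,
                cargo_positions=f["cargo_positions"][:] if "cargo_positions" in f else None,
            )


def free_system(
    positions: np.ndarray,
    box: tuple[float, float, float],
    mass: float = 120.0,
    charge: float = 0.0,
    hydrophobicity: float = 0.0,
    diameter: float = 0.6,
    bonds: np.ndarray | None = None,
) -> SystemAssembly:
    """A wall-less system of identical beads (test/benchmark helper)."""
    positions = np.atleast_2d(np.asarray(positions, float))
    n = len(positions)
    empty = np.zeros((0,), np.int64)
    return SystemAssembly(
        geometry=None,
        sequence_id="free",
        wall_positions=np.zeros((0, 3)),
        positions=positions,
        mass=np.full(n, float(mass)),
        charge=np.full(n, float(charge)),
        hydrophobicity=np.full(n, float(hydrophobicity)),
        diameter=np.full(n, float(diameter)),
        chains=[(0, n)],
        bonds=(np.zeros((0, 2), np.int64) if bonds is None else np.asarray(bonds, np.int64)),
        angles=np.zeros((0, 3), np.int64),
        torsions=np.zeros((0, 4), np.int64),
        tether_index=empty,
        tether_sites=np.zeros((0, 3)),
        box=np.asarray(box, float),
    )


def _exclusions(n: int, bonds: np.ndarray, angles: np.ndarray):
    """CSR exclusion lists for bonded 1-2 and 1-3 partners."""
    ex = [[] for _ in range(n)]
    for i, j in bonds:
        ex[i].append(j)
        ex[j].append(i)
    for i, _, k in angles:
        ex[i].append(k)
        ex[k].append(i)
    ptr = np.zeros(n + 1, np.int64)
    idx = []
    for i in range(n):
        s = sorted(set(ex[i]))
        idx.extend(s)
        ptr[i + 1] = len(idx)
    return ptr, np.asarray(idx, np.int64) if idx else np.zeros(0, np.int64)


def _pack(system: SystemAssembly, ff: ForceField):
    # wall beads are represented in the kernels by an equivalent analytic
    # cylindrical confinement (inert, purely repulsive), so only mobile
    # beads enter the pair list
    n_m = len(system.positions)
    ptr, idx = _exclusions(n_m, system.bonds, system.angles)
    ang_x, ang_c = ff.bending.coefficients()
    tor_x, tor_c = ff.torsion.coefficients()
    geom = system.geometry
    wall_contact = 0.0
    if geom is not None:
        wall_contact = geom.radius - 0.5 * float(np.mean(system.diameter))
    return dict(
        pos=system.positions.copy(), mass=system.mass.astype(float),
        charge=system.charge.astype(float),
        lam=system.hydrophobicity.astype(float),
        sigma=system.diameter.astype(float),
        fixed=np.zeros(n_m, np.uint8),
        excl_ptr=ptr, excl_idx=idx,
        ang_x=ang_x, ang_c=np.ascontiguousarray(ang_c),
        tor_x=tor_x, tor_c=np.ascontiguousarray(tor_c),
        angles_on=bool(np.any(ff.bending.y != 0.0)) and len(system.angles) > 0,
        torsions_on=bool(np.any(ff.torsion.y != 0.0)) and len(system.torsions) > 0,
        box_half=system.box / 2.0,
        membrane_on=geom is not None,
        memb_half_h=(geom.height / 2.0 if geom else 0.0),
        memb_r=(geom.radius if geom else 0.0),
        wall_r_contact=wall_contact,
        n_mobile=n_m,
    )


def potential_energy(
    system: SystemAssembly, ff: ForceField | None = None, tether_k: float = 400.0
) -> tuple[float, np.ndarray]:
    """Potential energy (kJ/mol) and forces on all beads (mobile + wall)."""
    ff = ff or ForceField()
    p = _pack(system, ff)
    n = len(p["pos"])
    cutoff = max(ff.cutoff_elec, ff.cutoff_lj, p["sigma"].max() * 2 ** (1 / 6))
    pairs = np.zeros((n * 200, 2), np.int64)
    n_pairs = _kernels.build_pairs(p["pos"], p["fixed"], cutoff, p["excl_ptr"], p["excl_idx"], pairs)
    forces = np.zeros((n, 3))
    epot = _kernels.compute_forces(
        p["pos"], p["charge"], p["lam"], p["sigma"], pairs, n_pairs, 1.0,
        system.bonds, ff.bond_k, ff.bond_length,
        system.angles, p["ang_x"], p["ang_c"], p["angles_on"],
        system.torsions, p["tor_x"], p["tor_c"], p["torsions_on"],
        system.tether_index, system.tether_sites, tether_k,
        p["box_half"], 100.0,
        p["membrane_on"], p["memb_half_h"], p["memb_r"], p["wall_r_contact"],
        ff.epsilon0, ff.cutoff_lj, ff.cutoff_elec, ff.switch_fraction, ff.kappa,
        ff.eps_contact, ff.eps_bulk, ff.eps_midpoint, ff.eps_width, COULOMB_KJMOL_NM,
        forces)
    return float(epot), forces


def minimize(
    system: SystemAssembly,
    ff: ForceField | None = None,
    max_iter: int = 500,
    force_tol: float = 50.0,
) -> SystemAssembly:
    """Steepest-descent energy minimisation of the mobile beads.

    Stops when the maximum residual force drops below ``force_tol``
    (kJ/mol/nm) or at the iteration cap; the energy never increases.
    """
    ff = ff or ForceField()
    sys2 = replace(system, positions=system.positions.copy())
    n_m = len(sys2.positions)
    e0, forces = potential_energy(sys2, ff)
    alpha = 0.002
    for it in range(max_iter):
        f_m = forces[:n_m]
        fmax = np.abs(f_m).max() if n_m else 0.0
        if fmax < force_tol:
            break
        step = np.clip(alpha * f_m, -0.05, 0.05)
        trial = replace(sys2, positions=sys2.positions + step)
        e1, f1 = potential_energy(trial, ff)
        if e1 <= e0:
            sys2, e0, forces = trial, e1, f1
            alpha = min(alpha * 1.2, 0.05)
        else:
            alpha *= 0.5
            if alpha < 1e-8:
                break
    if not np.isfinite(e0):
        raise RuntimeError("energy diverged during minimisation")
    return sys2


def run_dynamics(
    system: SystemAssembly,
    config: SimulationConfig,
    ff: ForceField | None = None,
    cargo: CargoModel | None = None,
    cargo_start: np.ndarray | None = None,
    restraint: RestraintSpec | None = None,
) -> Trajectory:
    """Langevin dynamics; returns post-equilibration frames.

    With a ``cargo`` the rigid sphere translates under the bead forces and
    the optional axial umbrella ``restraint``; rotation is not sampled
    (binding sites are distributed homogeneously).
    """
    ff = ff or ForceField()
    # stability bound for the stiffest harmonic term
    m_min = system.mass.min() if len(system.mass) else 120.0
    dt_max = 0.5 / math.sqrt(ff.bond_k / m_min) if len(system.bonds) else math.inf
    if config.timestep > dt_max:
        raise ValueError(
            f"timestep {config.timestep} ps exceeds stability bound {dt_max:.4f} ps"
        )
    p = _pack(system, ff)
    n = len(p["pos"])
    rng = np.random.default_rng(config.seed)
    vel = rng.normal(size=(n, 3)) * np.sqrt(config.kBT / p["mass"])[:, None]
    vel[p["fixed"] == 1] = 0.0
    pos = p["pos"].copy()

    cargo_on = cargo is not None
    cargo_pos = np.zeros(3) if cargo_start is None else np.asarray(cargo_start, float).copy()
    cargo_vel = np.zeros(3)
    if cargo_on:
        cargo_vel = rng.normal(size=3) * math.sqrt(config.kBT / cargo.mass)
    sites = cargo.sites if cargo_on else np.zeros((0, 3))
    r_z0 = restraint.z0 if restraint else 0.0
    r_k = restraint.spring_k if restraint else 0.0

    total_frames = config.n_steps // config.stride
    frames = np.zeros((total_frames, n, 3))
    cargo_frames = np.zeros((total_frames, 3))
    ekin = np.zeros(total_frames)
    epot = np.zeros(total_frames)
    ramp_steps = int(config.ramp_fraction * config.n_steps)
    max_pairs = max(n * config.max_neighbors, 10000)

    wrote = _kernels.run_md(
        pos, vel, p["mass"], p["charge"], p["lam"], p["sigma"], p["fixed"],
        system.bonds, ff.bond_k, ff.bond_length,
        system.angles, p["ang_x"], p["ang_c"], p["angles_on"],
        system.torsions, p["tor_x"], p["tor_c"], p["torsions_on"],
        system.tether_index, system.tether_sites, config.tether_k,
        p["excl_ptr"], p["excl_idx"],
        p["box_half"], config.container_k,
        p["membrane_on"], p["memb_half_h"], p["memb_r"], p["wall_r_contact"],
        ff.epsilon0, ff.cutoff_lj, ff.cutoff_elec, ff.switch_fraction, ff.kappa,
        ff.eps_contact, ff.eps_bulk, ff.eps_midpoint, ff.eps_width, COULOMB_KJMOL_NM,
        cargo_on, cargo_pos, cargo_vel,
        cargo.mass if cargo_on else 1.0,
        cargo.radius if cargo_on else 1.0,
        cargo.charge if cargo_on else 0.0,
        sites,
        cargo.site_epsilon if cargo_on else 0.0,
        cargo.site_lambda_threshold if cargo_on else 1.0,
        r_z0, r_k,
        config.timestep, config.friction, config.kBT,
        config.n_steps, ramp_steps, config.stride,
        config.skin, config.check_every, config.seed & 0x7FFFFFFF, max_pairs,
        frames, cargo_frames, ekin, epot)
    if wrote < 0:
        raise FloatingPointError(
            f"NaN coordinates at step {int(ekin[0])}: timestep instability"
        )
    keep = slice(config.n_equilibration // config.stride, wrote)
    times = (np.arange(total_frames) + 1.0) * config.stride * config.timestep
    n_m = p["n_mobile"]
    return Trajectory(
        times=times[keep],
        frames=frames[keep, :n_m],
        wall_positions=system.wall_positions,
        kinetic=ekin[keep],
        potential=epot[keep],
        masses=system.mass,
        chains=system.chains,
        config=config,
        cargo_positions=cargo_frames[keep] if cargo_on else None,
    )


def chain_observables(traj: Trajectory, selection: np.ndarray | slice) -> dict:
    """Time-averaged radius of gyration and Kirkwood Stokes radius (nm).

    The hydrodynamic (Stokes) radius uses the Kirkwood double-sum
    approximation 1/R_S = <sum_{i != j} 1/r_ij> / N^2 over the ensemble.
    """
    sub = traj.frames[:, selection]
    if sub.shape[1] == 0:
        raise ValueError("empty selection")
    if traj.n_frames < 50:
        warnings.warn("fewer than 50 frames: Rg/Rs estimates may be correlated")
    m = traj.masses[selection] if isinstance(selection, np.ndarray) else traj.masses[selection]
    w = m / m.sum()
    com = np.einsum("fnd,n->fd", sub, w)
    dev = sub - com[:, None, :]
    rg = math.sqrt(float(np.mean(np.einsum("fnd,fnd,n->f", dev, dev, w))))
    n = sub.shape[1]
    inv_sum = 0.0
    for f in range(sub.shape[0]):
        d = np.linalg.norm(sub[f][:, None] - sub[f][None, :], axis=-1)
        iu = np.triu_indices(n, 1)
        inv_sum += np.sum(1.0 / d[iu]) * 2.0
    mean_inv = inv_sum / sub.shape[0] / n**2
    return {"Rg": rg, "Rs": 1.0 / mean_inv}
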