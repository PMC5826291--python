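"""One-bead-per-amino-acid force field.

Each residue is a single bead carrying an average residue mass, an integer
charge (D, E: -1; K, R: +1 at pH 7.4) and a hydrophobicity ``lambda`` in
[0, 1] obtained by min-max normalising experimental octanol partition
energies (Fauchere-Pliska scale; a reconstruction, replaceable via the
parameter table in ``fgpore/data/residues.tsv``).

Interactions
------------
bonds      stiff harmonic springs, equilibrium length 0.38 nm
bending    tabulated potential in the bond angle (cubic-spline interpolated)
torsion    tabulated potential in the dihedral (default: zero)
nonbonded  Ashbaugh-Hatch lambda-scaled Lennard-Jones: a repulsive core for
           every pair plus an attractive well whose depth scales with
           sqrt(lambda_i * lambda_j) and vanishes when either bead is fully
           hydrophilic; smoothly switched to zero at the cutoff (C1)
charges    screened Coulomb q_i q_j exp(-kappa r) / (4 pi eps0 eps(r) r)
           with a sigmoidal distance-dependent dielectric eps(r) and Debye
           constant kappa = 1.27 1/nm for 150 mM KCl
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy import constants as const
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize

# Coulomb prefactor e^2/(4 pi eps0) in kJ/mol * nm / e^2
COULOMB_KJMOL_NM = 138.935458
#: Boltzmann constant in kJ/mol/K
KB_KJMOL = const.R / 1000.0


def load_bead_table() -> dict[str, "BeadSpec"]:
    """Per-residue bead parameters from the packaged table."""
    text = resources.files("fgpore.data").joinpath("residues.tsv").read_text()
    table: dict[str, BeadSpec] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("code"):
            continue
        code, mass, charge, lam, diam = line.split("\t")
        table[code] = BeadSpec(
            code=code,
            mass=float(mass),
            charge=int(charge),
            hydrophobicity=float(lam),
            diameter=float(diam),
        )
    return table


@dataclass(frozen=True)
class BeadSpec:
    code: str
    mass: float            # Da
    charge: int            # e, in {-1, 0, +1}
    hydrophobicity: float  # lambda in [0, 1]
    diameter: float        # nm, excluded-volume diameter

    def __post_init__(self) -> None:
        if not 0.0 <= self.hydrophobicity <= 1.0:
            raise ValueError(f"lambda out of [0,1] for bead {self.code!r}")


@dataclass
class TabulatedPotential:
    """Cubic-spline tabulated potential on a fixed grid of angles (rad)."""

    x: np.ndarray
    y: np.ndarray
    periodic: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        bc = "periodic" if self.periodic else "natural"
        if self.periodic and self.y[0] != self.y[-1]:
            raise ValueError("periodic table must have matching endpoints")
        self._spline = CubicSpline(self.x, self.y, bc_type=bc)

    def energy(self, angle: float | np.ndarray) -> float | np.ndarray:
        return self._spline(angle)

    def derivative(self, angle: float | np.ndarray) -> float | np.ndarray:
        return self._spline(angle, 1)

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """(breakpoints, 4 x n-1 coefficient array) for compiled kernels."""
        return self._spline.x, self._spline.c

    @classmethod
    def zero(cls, lo: float, hi: float, n: int = 73, periodic: bool = False):
        return cls(np.linspace(lo, hi, n), np.zeros(n), periodic=periodic)


def default_bending_table(k_theta: float = 4.0, theta0: float = 1.85) -> TabulatedPotential:
    """Mild harmonic-like bending table about ~106 deg (reconstruction)."""
    th = np.linspace(0.0, math.pi, 73)
    return TabulatedPotential(th, 0.5 * k_theta * (th - theta0) ** 2)


def default_torsion_table() -> TabulatedPotential:
    return TabulatedPotential.zero(-math.pi, math.pi, periodic=True)


@dataclass
class ForceField:
    """Parameter container; all energies kJ/mol, lengths nm."""

    bond_length: float = 0.38
    bond_k: float = 8000.0             # kJ/mol/nm^2
    epsilon0: float = 2.0              # kJ/mol, full-strength LJ well depth
                                       # (calibrated so the isolated Nsp1 head
                                       # reproduces its ~3.2 nm Stokes radius)
    sigma_lj: float = 0.6              # nm (default bead diameter)
    cutoff_lj: float = 1.8             # nm
    cutoff_elec: float = 2.4           # nm
    switch_fraction: float = 0.8       # switch starts at fraction * cutoff
    kappa: float = 1.27                # 1/nm Debye screening
    eps_contact: float = 10.0          # dielectric at contact
    eps_bulk: float = 80.0             # dielectric in bulk
    eps_midpoint: float = 0.4          # nm, sigmoid midpoint
    eps_width: float = 0.15            # nm, sigmoid width
    min_separation: float = 0.05       # nm, below this energies are refused
    bending: TabulatedPotential = field(default_factory=default_bending_table)
    torsion: TabulatedPotential = field(default_factory=default_torsion_table)

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    def dielectric(self, r: float | np.ndarray) -> float | np.ndarray:
        """Sigmoidal distance-dependent dielectric constant."""
        return self.eps_contact + (self.eps_bulk - self.eps_contact) / (
            1.0 + np.exp(-(np.asarray(r, float) - self.eps_midpoint) / self.eps_width)
        )


def debye_constant(
    ionic_strength: float, temperature: float = 298.0, relative_permittivity: float = 78.5
) -> float:
    """Inverse Debye length (1/nm) for a 1:1 electrolyte.

    Parameters are the molar ionic strength (mol/L), temperature (K) and the
    solvent's relative permittivity (default 78.5, water near 298 K).
    """
    if ionic_strength < 0 or temperature <= 0 or relative_permittivity <= 0:
        raise ValueError("ionic strength must be >= 0 and T, eps_r > 0")
    n = ionic_strength * 1000.0 * const.N_A  # ions per m^3 of each species
    kappa_sq = (
        2.0 * n * const.e**2
        / (const.epsilon_0 * relative_permittivity * const.k * temperature)
    )
    return math.sqrt(kappa_sq) * 1e-9


def _switch(r: float, rs: float, rc: float) -> tuple[float, float]:
    """C1 smoothstep from 1 at rs to 0 at rc; returns (w, dw/dr)."""
    if r <= rs:
        return 1.0, 0.0
    if r >= rc:
        return 0.0, 0.0
    x = (r - rs) / (rc - rs)
    return 1.0 - x * x * (3.0 - 2.0 * x), -6.0 * x * (1.0 - x) / (rc - rs)


def pair_hydrophobicity(lam_i: float, lam_j: float) -> float:
    """Geometric-mean combination rule; zero when either bead is hydrophilic."""
    return math.sqrt(lam_i * lam_j)


def hydrophobic_energy(
    r: float, sigma: float, lam_pair: float, ff: ForceField
) -> tuple[float, float]:
    """Ashbaugh-Hatch scaled LJ energy and dU/dr at separation r."""
    rc = ff.cutoff_lj
    if r >= rc:
        return 0.0, 0.0
    s6 = (sigma / r) ** 6
    ulj = 4.0 * ff.epsilon0 * (s6 * s6 - s6)
    dulj = -24.0 * ff.epsilon0 * (2.0 * s6 * s6 - s6) / r
    rmin = sigma * 2.0 ** (1.0 / 6.0)
    if r < rmin:
        u, du = ulj + (1.0 - lam_pair) * ff.epsilon0, dulj
    else:
        u, du = lam_pair * ulj, lam_pair * dulj
    w, dw = _switch(r, ff.switch_fraction * rc, rc)
    return u * w, du * w + u * dw


def electrostatic_energy(
    r: float, q_i: float, q_j: float, ff: ForceField
) -> tuple[float, float]:
    """Screened Coulomb energy and dU/dr with the sigmoidal dielectric."""
    rc = ff.cutoff_elec
    qq = q_i * q_j
    if r >= rc or qq == 0.0:
        return 0.0, 0.0
    eps = float(ff.dielectric(r))
    # d(eps)/dr of the sigmoid
    ex = math.exp(-(r - ff.eps_midpoint) / ff.eps_width)
    deps = (ff.eps_bulk - ff.eps_contact) * ex / (ff.eps_width * (1.0 + ex) ** 2)
    u = COULOMB_KJMOL_NM * qq * math.exp(-ff.kappa * r) / (eps * r)
    du = u * (-ff.kappa - 1.0 / r - deps / eps)
    w, dw = _switch(r, ff.switch_fraction * rc, rc)
    return u * w, du * w + u * dw


def nonbonded_energy(
    bead_i: BeadSpec, bead_j: BeadSpec, r: float, ff: ForceField
) -> float:
    """Total nonbonded pair energy (kJ/mol) at separation r (nm)."""
    if r < ff.min_separation:
        raise ValueError(
            f"separation {r} nm below minimum for pair "
            f"{bead_i.code}-{bead_j.code}"
        )
    sigma = 0.5 * (bead_i.diameter + bead_j.diameter)
    lam = pair_hydrophobicity(bead_i.hydrophobicity, bead_j.hydrophobicity)
    u_h, _ = hydrophobic_energy(r, sigma, lam, ff)
    u_e, _ = electrostatic_energy(r, bead_i.charge, bead_j.charge, ff)
    return u_h + u_e


def nonbonded_force(
    bead_i: BeadSpec, bead_j: BeadSpec, r: float, ff: ForceField
) -> float:
    """-dU/dr for the nonbonded pair (kJ/mol/nm), for derivative checks."""
    sigma = 0.5 * (bead_i.diameter + bead_j.diameter)
    lam = pair_hydrophobicity(bead_i.hydrophobicity, bead_j.hydrophobicity)
    _, du_h = hydrophobic_energy(r, sigma, lam, ff)
    _, du_e = electrostatic_energy(r, bead_i.charge, bead_j.charge, ff)
    return -(du_h + du_e)


# ---------------------------------------------------------------- bonded


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.acos(min(1.0, max(-1.0, cosang)))


def dihedral_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral of four points (IUPAC convention)."""
    b1, b2, b3 = b - a, c - b, d - c
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    b2u = b2 / np.linalg.norm(b2)
    return math.atan2(np.dot(np.cross(n1, n2), b2u), np.dot(n1, n2))


def bonded_energy(chain: np.ndarray, ff: ForceField) -> float:
    """Bond + bending + torsion energy of an ordered bead chain (kJ/mol)."""
    chain = np.asarray(chain, float)
    n = len(chain)
    if n < 2:
        raise ValueError("need at least two beads for bonded terms")
    e = 0.0
    for i in range(n - 1):
        r = np.linalg.norm(chain[i + 1] - chain[i])
        if r < 1e-9:
            raise ValueError(f"coincident bonded neighbours at index {i}")
        e += 0.5 * ff.bond_k * (r - ff.bond_length) ** 2
    for i in range(n - 2):
        e += float(ff.bending.energy(bond_angle(chain[i], chain[i + 1], chain[i + 2])))
    for i in range(n - 3):
        e += float(
            ff.torsion.energy(
                dihedral_angle(chain[i], chain[i + 1], chain[i + 2], chain[i + 3])
            )
        )
    return e


# ---------------------------------------------------------------- cargo


@dataclass
class CargoModel:
    """Rigid spherical cargo (transport receptor or inert control)."""

    kind: str
    radius: float                  # nm
    charge: float                  # e, smeared homogeneously
    n_hydro_sites: int
    sites: np.ndarray              # (n, 3) unit vectors scaled by radius
    site_epsilon: float = 8.0      # kJ/mol, per-site well depth
    site_lambda_threshold: float = 0.5
    mass: float = 100000.0         # Da
    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cargo radius must be positive")


def _thomson_sites(n: int) -> np.ndarray:
    """Deterministic repelling-point placement of n unit vectors."""
    if n == 0:
        return np.zeros((0, 3))
    # golden-spiral start, then minimize the Riesz 1/d energy
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = math.pi * (1.0 + 5**0.5) * k
    pts = np.c_[np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]

    def energy(flat):
        p = flat.reshape(n, 3)
        p = p / np.linalg.norm(p, axis=1, keepdims=True)
        d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
        iu = np.triu_indices(n, 1)
        return np.sum(1.0 / d[iu])

    res = minimize(energy, pts.ravel(), method="L-BFGS-B")
    p = res.x.reshape(n, 3)
    return p / np.linalg.norm(p, axis=1, keepdims=True)


_CARGO_PRESETS = {
    # inert control: similar size, no binding sites, neutral
    "tCherry": dict(radius=7.4, charge=0.0, n_hydro_sites=0, mass=104000.0),
    # transport receptor: 10 hydrophobic binding spots, net charge -43 e
    "Kap95": dict(radius=8.5, charge=-43.0, n_hydro_sites=10, mass=95000.0),
}


def build_cargo(kind: str, **overrides) -> CargoModel:
    """Build a preset cargo (``"tCherry"`` or ``"Kap95"``) or a custom one.

    Hydrophobic binding sites are placed deterministically by minimising
    their mutual Riesz energy on the sphere (homogeneous coverage).
    """
    if kind in _CARGO_PRESETS:
        spec = dict(_CARGO_PRESETS[kind])
    else:
        spec = {}
    spec.update(overrides)
    missing = {"radius", "charge", "n_hydro_sites"} - set(spec)
    if missing:
        raise KeyError(f"custom cargo {kind!r} missing fields {sorted(missing)}")
    sites = _thomson_sites(spec["n_hydro_sites"]) * spec["radius"]
    return CargoModel(kind=kind, sites=sites, **spec)
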