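"""Construction of biomimetic nanopores: wall, anchor lattice, grafted chains.

The pore is a cylinder of height 20 nm (the membrane thickness) whose inner
surface is tiled with inert, immobile beads of 3 nm diameter.  FG-domain
chains are grafted to anchor sites arranged in a close-packed triangular
lattice wrapped onto the cylinder (default spacing 5.7 nm, i.e. one chain
per ~28 nm^2).  The pore axis is z with the origin at the pore centre; all
coordinates are in nm.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cg_model import BeadSpec, load_bead_table
from .sequences import ProteinSequence

SQRT3_2 = math.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class PoreGeometry:
    diameter: float                       # nm, lumen diameter
    height: float = 20.0                  # nm, membrane thickness
    wall_bead_diameter: float = 3.0       # nm
    box: tuple[float, float, float] = (100.0, 100.0, 140.0)

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("pore diameter must be positive")
        if self.diameter + 2 * self.wall_bead_diameter > min(self.box[0], self.box[1]):
            raise ValueError("pore does not fit laterally inside the box")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def wall_radius(self) -> float:
        """Radius of the wall bead centres."""
        return self.radius + self.wall_bead_diameter / 2.0

    def lateral_area(self) -> float:
        return math.pi * self.diameter * self.height


@dataclass
class AnchorLattice:
    spacing: float                  # requested nm
    positions: np.ndarray           # (n, 3) sites on the cylinder surface
    n_columns: int
    n_rows: int
    realized_spacing: float         # mean nearest-neighbour distance
    area_per_site: float            # lateral area / site count

    def __len__(self) -> int:
        return len(self.positions)


def build_wall(geom: PoreGeometry, include_membrane: bool = False) -> np.ndarray:
    """Tile the inner cylinder surface with inert wall beads.

    Beads are stacked in offset rings (triangular tiling wrapped onto the
    cylinder).  The top/bottom membrane faces are, by default, handled as
    repulsive planes by the simulator; ``include_membrane=True`` adds
    explicit bead annuli on both faces instead.
    """
    wb = geom.wall_bead_diameter
    if geom.diameter < 2 * wb:
        raise ValueError("pore diameter smaller than two wall-bead diameters")
    rw = geom.wall_radius
    dz = wb * SQRT3_2
    n_rows = max(1, round(geom.height / dz))
    zs = -geom.height / 2.0 + (np.arange(n_rows) + 0.5) * geom.height / n_rows
    beads = []
    for j, z in enumerate(zs):
        n = max(3, round(2.0 * math.pi * rw / wb))
        ang = 2.0 * math.pi * (np.arange(n) + 0.5 * (j % 2)) / n
        ring = np.c_[rw * np.cos(ang), rw * np.sin(ang), np.full(n, z)]
        beads.append(ring)
    if include_membrane:
        half_l = geom.height / 2.0 + wb / 2.0
        r_max = min(geom.box[0], geom.box[1]) / 2.0 - wb / 2.0
        r = rw + wb
        while r < r_max:
            n = max(3, round(2.0 * math.pi * r / wb))
            ang = 2.0 * math.pi * np.arange(n) / n
            for z in (-half_l, half_l):
                beads.append(np.c_[r * np.cos(ang), r * np.sin(ang), np.full(n, z)])
            r += wb
    return np.vstack(beads)


def build_anchors(geom: PoreGeometry, spacing: float = 5.7) -> AnchorLattice:
    """Wrap a triangular lattice of anchor sites onto the cylinder surface.

    An exact triangular lattice cannot wrap a cylinder of arbitrary
    diameter; the number of circumferential columns is fixed to
    round(pi d / a) and the realized spacing is reported.  This preserves
    the target areal grafting density (1 site per (sqrt(3)/2) a^2).
    """
    circumference = math.pi * geom.diameter
    if spacing >= circumference:
        raise ValueError("spacing too large: no anchor column fits on the cylinder")
    n_cols = max(1, round(circumference / spacing))
    n_rows = max(1, round(geom.height / (spacing * SQRT3_2)))
    r = geom.radius
    zs = -geom.height / 2.0 + (np.arange(n_rows) + 0.5) * geom.height / n_rows
    sites = []
    for j, z in enumerate(zs):
        ang = 2.0 * math.pi * (np.arange(n_cols) + 0.5 * (j % 2)) / n_cols
        sites.append(np.c_[r * np.cos(ang), r * np.sin(ang), np.full(n_cols, z)])
    pos = np.vstack(sites)
    # mean nearest-neighbour distance (unwrapped surface metric is fine at
    # these curvatures; use 3D distances)
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    realized = float(np.mean(d.min(axis=1)))
    return AnchorLattice(
        spacing=spacing,
        positions=pos,
        n_columns=n_cols,
        n_rows=n_rows,
        realized_spacing=realized,
        area_per_site=geom.lateral_area() / len(pos),
    )


@dataclass
class SystemAssembly:
    """Wall beads plus grafted chains, ready for simulation."""

    geometry: PoreGeometry
    sequence_id: str
    wall_positions: np.ndarray          # (Nw, 3), immobile
    positions: np.ndarray               # (N, 3), mobile chain beads
    mass: np.ndarray                    # (N,)
    charge: np.ndarray                  # (N,)
    hydrophobicity: np.ndarray          # (N,)
    diameter: np.ndarray                # (N,)
    chains: list                        # [(start, stop), ...) index ranges
    bonds: np.ndarray                   # (M, 2)
    angles: np.ndarray                  # (Ma, 3)
    torsions: np.ndarray                # (Mt, 4)
    tether_index: np.ndarray            # anchor bead index per chain
    tether_sites: np.ndarray            # (n_chains, 3)
    box: np.ndarray                     # (3,)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def to_xyz(self, path, frame: np.ndarray | None = None) -> None:
        """Write the assembly (wall + chains) as an XYZ interchange file."""
        pos = self.positions if frame is None else frame
        with open(path, "w") as fh:
            fh.write(f"{len(pos) + len(self.wall_positions)}\n")
            fh.write(f"fgpore assembly {self.sequence_id} d={self.geometry.diameter} nm\n")
            for p in self.wall_positions:
                fh.write(f"W {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
            for p in pos:
                fh.write(f"C {p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")

    def write_topology(self, path) -> None:
        """Chain/bond lists as structured text."""
        with open(path, "w") as fh:
            fh.write(f"# fgpore topology: {self.sequence_id}\n")
            fh.write(f"n_beads {self.n_beads}\nn_chains {len(self.chains)}\n")
            fh.write("[chains]\n")
            for start, stop in self.chains:
                fh.write(f"{start} {stop}\n")
            fh.write("[bonds]\n")
            for i, j in self.bonds:
                fh.write(f"{i} {j}\n")


def _grow_chain(
    site: np.ndarray,
    n_beads: int,
    geom: PoreGeometry,
    occupied: dict,
    rng: np.random.Generator,
    bond: float,
    min_sep: float,
    cell: float,
    max_tries: int = 40,
    max_backtracks: int = 400,
) -> np.ndarray | None:
    """Self-avoiding persistent random walk starting at the anchor site.

    The walk is confined to the lumen while inside the membrane slab and may
    spill axially out of the pore mouth; a mild pull toward the axis keeps
    fresh chains off the wall.  Dead ends are resolved by backtracking.
    """
    # slight overlap with the wall-bead shell is tolerated here; the
    # energy minimisation step resolves it
    r_lumen = geom.radius - 0.1
    half_h = geom.height / 2.0
    half_box = np.asarray(geom.box) / 2.0 - 1.0
    own: dict = {}

    def neighbours(store, key0):
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for q in store.get((key0[0] + dx, key0[1] + dy, key0[2] + dz), ()):
                        yield q

    def ok(p) -> bool:
        if np.any(np.abs(p) > half_box):
            return False
        r_xy = math.hypot(p[0], p[1])
        if abs(p[2]) < half_h and r_xy > r_lumen:
            return False
        key0 = tuple((p // cell).astype(int))
        for q in neighbours(occupied, key0):
            if np.sum((p - q) ** 2) < min_sep * min_sep:
                return False
        for q in neighbours(own, key0):
            if np.sum((p - q) ** 2) < min_sep * min_sep:
                return False
        return True

    def push(p):
        own.setdefault(tuple((p // cell).astype(int)), []).append(p)

    def pop(p):
        own[tuple((p // cell).astype(int))].pop()

    chain = np.empty((n_beads, 3))
    chain[0] = site
    direction = -site / max(np.linalg.norm(site[:2]), 1e-9)
    direction[2] = 0.0
    backtracks = 0
    i = 1
    while i < n_beads:
        placed = False
        for _ in range(max_tries):
            prev = chain[i - 1]
            r_xy = math.hypot(prev[0], prev[1])
            inward = np.array([-prev[0], -prev[1], 0.0]) / max(r_xy, 1e-9)
            pull = 0.8 * max(0.0, (r_xy - 0.5 * r_lumen) / r_lumen)
            step = 0.5 * direction + rng.normal(size=3) + pull * inward
            step = step / np.linalg.norm(step) * bond
            p = prev + step
            if ok(p):
                chain[i] = p
                push(p)
                direction = step / bond
                placed = True
                i += 1
                break
        if not placed:
            backtracks += 1
            if backtracks > max_backtracks:
                return None
            back = min(5, i - 1)
            if back == 0:
                return None
            for _ in range(back):
                i -= 1
                pop(chain[i])
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
    return chain


def assemble_system(
    geom: PoreGeometry,
    lattice: AnchorLattice,
    seq: ProteinSequence,
    seed: int = 0,
    bead_table: dict[str, BeadSpec] | None = None,
    max_restarts: int = 25,
) -> SystemAssembly:
    """Graft one chain per anchor site as a non-overlapping random walk.

    The anchor-terminus bead (C-terminal for Nsp1/Nsp1-S) coincides with its
    site; the walk grows inward into the lumen.  Deterministic given the seed.
    """
    table = bead_table or load_bead_table()
    rng = np.random.default_rng(seed)
    wall = build_wall(geom)
    n_res = len(seq.residues)
    min_sep, cell = 0.32, 1.0
    occupied: dict = {}

    def register(points):
        for p in points:
            occupied.setdefault(tuple((p // cell).astype(int)), []).append(p)

    chains_xyz = []
    for site in lattice.positions:
        grown = None
        for restart in range(max_restarts):
            grown = _grow_chain(site, n_res, geom, occupied, rng, 0.38, min_sep, cell)
            if grown is not None:
                break
        if grown is None:
            raise RuntimeError(
                f"chain initialization failed at site {site} after "
                f"{max_restarts} restarts (overcrowded geometry)"
            )
        register(grown)
        chains_xyz.append(grown)

    # per-bead parameters: walk order follows the chain from the anchored
    # terminus inward, so for a C-anchored sequence the residue order is
    # reversed relative to the walk
    res_order = seq.residues[::-1] if seq.anchor_terminus == "C" else seq.residues
    specs = [table[r] for r in res_order]
    n_chains = len(chains_xyz)
    positions = np.vstack(chains_xyz)
    mass = np.tile([s.mass for s in specs], n_chains).astype(float)
    charge = np.tile([float(s.charge) for s in specs], n_chains)
    lam = np.tile([s.hydrophobicity for s in specs], n_chains)
    diam = np.tile([s.diameter for s in specs], n_chains)

    chains, bonds, angles, torsions, tether_idx = [], [], [], [], []
    for c in range(n_chains):
        start = c * n_res
        stop = start + n_res
        chains.append((start, stop))
        tether_idx.append(start)
        for i in range(start, stop - 1):
            bonds.append((i, i + 1))
        for i in range(start, stop - 2):
            angles.append((i, i + 1, i + 2))
        for i in range(start, stop - 3):
            torsions.append((i, i + 1, i + 2, i + 3))

    return SystemAssembly(
        geometry=geom,
        sequence_id=seq.id,
        wall_positions=wall,
        positions=positions,
        mass=mass,
        charge=charge,
        hydrophobicity=lam,
        diameter=diam,
        chains=chains,
        bonds=np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        angles=np.asarray(angles, dtype=np.int64).reshape(-1, 3),
        torsions=np.asarray(torsions, dtype=np.int64).reshape(-1, 4),
        tether_index=np.asarray(tether_idx, dtype=np.int64),
        tether_sites=lattice.positions.copy(),
        box=np.asarray(geom.box, float),
    )
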