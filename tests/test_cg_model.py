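"""Force-field unit tests: Debye screening, pair potentials, bonded terms,
cargo models.  Forces are validated against central-difference derivatives
of the energies (the C1 contract of every pair potential)."""
import math

import numpy as np
import pytest

from fgpore.cg_model import (
    ForceField,
    TabulatedPotential,
    bond_angle,
    bonded_energy,
    build_cargo,
    debye_constant,
    dihedral_angle,
    nonbonded_energy,
    nonbonded_force,
    pair_hydrophobicity,
)


class TestDebye:
    def test_150_mm_kcl_at_298k(self):
        # 150 mM KCl at 298 K screens with kappa ~ 1.27 1/nm
        assert debye_constant(0.150, 298.0) == pytest.approx(1.27, abs=0.01)
        assert debye_constant(0.150, 298.0, 80.0) == pytest.approx(1.27, abs=0.02)

    def test_no_salt_no_screening(self):
        assert debye_constant(0.0, 298.0) == 0.0

    @pytest.mark.parametrize("ionic", [0.01, 0.15, 1.0])
    def test_square_root_law(self, ionic):
        assert debye_constant(4 * ionic) / debye_constant(ionic) == pytest.approx(2.0)

    def test_negative_inputs(self):
        with pytest.raises(ValueError):
            debye_constant(-0.1)


class TestBeadTable:
    def test_charges_and_lambda_ranges(self, bead_table):
        assert set(bead_table) == set("ACDEFGHIKLMNPQRSTVWY")
        for code, spec in bead_table.items():
            assert 0.0 <= spec.hydrophobicity <= 1.0
            expected = {"D": -1, "E": -1, "K": 1, "R": 1}.get(code, 0)
            assert spec.charge == expected

    def test_mean_bead_mass_near_120_da(self, bead_table, nsp1):
        mean = np.mean([bead_table[r].mass for r in nsp1.residues])
        assert mean == pytest.approx(120.0, rel=0.15)


class TestNonbonded:
    def test_inert_pair_repulsive_and_decaying(self, bead_table, ff):
        g = bead_table["G"]  # low lambda, neutral
        zero = ForceField()
        spec = type(g)(code="X", mass=100, charge=0, hydrophobicity=0.0, diameter=0.6)
        assert nonbonded_energy(spec, spec, 0.62, zero) >= 0.0
        assert nonbonded_energy(spec, spec, 2.0, zero) == 0.0

    def test_like_charges_repulsive_tail(self, bead_table, ff):
        k = bead_table["K"]
        for r in np.linspace(0.8, 2.0, 10):
            assert nonbonded_energy(k, k, r, ff) > 0.0

    def test_ff_pair_at_lj_minimum_matches_hand_evaluation(self, bead_table, ff):
        """At r = 2^(1/6) sigma the scaled-LJ well bottoms out at
        -sqrt(lam_F^2) * eps0 and phenylalanine carries no charge."""
        f = bead_table["F"]
        r = ff.sigma_lj * 2 ** (1 / 6)
        expected = -f.hydrophobicity * ff.epsilon0
        assert nonbonded_energy(f, f, r, ff) == pytest.approx(expected, rel=1e-12)

    def test_exchange_symmetry_and_charge_sign(self, bead_table, ff):
        k, e, f = bead_table["K"], bead_table["E"], bead_table["F"]
        for r in (0.7, 1.0, 1.5):
            assert nonbonded_energy(k, e, r, ff) == nonbonded_energy(e, k, r, ff)
        # flipping one charge sign flips the electrostatic part
        lam0 = type(k)(code="k0", mass=1, charge=1, hydrophobicity=0.0, diameter=0.6)
        lam0m = type(k)(code="k1", mass=1, charge=-1, hydrophobicity=0.0, diameter=0.6)
        wca = nonbonded_energy(
            type(k)(code="n", mass=1, charge=0, hydrophobicity=0.0, diameter=0.6),
            lam0, 1.0, ff)
        upp = nonbonded_energy(lam0, lam0, 1.0, ff) - wca
        upm = nonbonded_energy(lam0, lam0m, 1.0, ff) - wca
        assert upm == pytest.approx(-upp, rel=1e-9)

    def test_force_matches_numerical_derivative(self, bead_table, ff):
        h = 1e-6
        for a, b in [("F", "F"), ("K", "E"), ("K", "K"), ("F", "S"), ("G", "G")]:
            bi, bj = bead_table[a], bead_table[b]
            for r in np.linspace(0.45, 2.6, 120):
                force = nonbonded_force(bi, bj, r, ff)
                num = -(nonbonded_energy(bi, bj, r + h, ff)
                        - nonbonded_energy(bi, bj, r - h, ff)) / (2 * h)
                assert force == pytest.approx(num, rel=1e-5, abs=1e-7)

    def test_below_minimum_separation_names_pair(self, bead_table, ff):
        with pytest.raises(ValueError, match="F-S"):
            nonbonded_energy(bead_table["F"], bead_table["S"], 0.01, ff)

    def test_geometric_combination_vanishes_with_hydrophilic_partner(self):
        assert pair_hydrophobicity(0.0, 1.0) == 0.0
        assert pair_hydrophobicity(0.64, 0.25) == pytest.approx(0.4)


class TestBonded:
    def test_zero_at_equilibrium_with_zeroed_tables(self):
        ff = ForceField(
            bending=TabulatedPotential.zero(0.0, math.pi),
            torsion=TabulatedPotential.zero(-math.pi, math.pi, periodic=True),
        )
        chain = np.array([[i * 0.38, 0.0, 0.0] for i in range(5)])
        assert bonded_energy(chain, ff) == pytest.approx(0.0, abs=1e-12)

    def test_stretched_bond_closed_form(self, ff):
        chain = np.array([[0.0, 0.0, 0.0], [0.40, 0.0, 0.0]])
        assert bonded_energy(chain, ff) == pytest.approx(
            0.5 * ff.bond_k * 0.02**2, rel=1e-9
        )

    def test_coincident_neighbours_rejected(self, ff):
        with pytest.raises(ValueError, match="coincident"):
            bonded_energy(np.zeros((2, 3)), ff)

    def test_torsion_table_evaluated_at_independent_dihedral(self):
        """Torsion energy equals the table interpolated at a dihedral that an
        independent geometric construction reports."""
        rng = np.random.default_rng(3)
        grid = np.linspace(-math.pi, math.pi, 91)
        values = np.sin(2 * grid) + 0.3 * np.cos(grid)
        values[-1] = values[0]
        ff = ForceField(
            bending=TabulatedPotential.zero(0.0, math.pi),
            torsion=TabulatedPotential(grid, values, periodic=True),
        )
        for _ in range(10):
            pts = rng.normal(size=(4, 3))
            # keep bonds near r0 so only the torsion term contributes meaningfully
            chain = np.zeros((4, 3))
            chain[0] = pts[0]
            for i in range(1, 4):
                step = pts[i] - pts[i - 1]
                chain[i] = chain[i - 1] + 0.38 * step / np.linalg.norm(step)
            # independent dihedral: project the outer bonds onto the plane
            # normal to the central bond (half-plane vectors -b1, b3)
            b1, b2, b3 = np.diff(chain, axis=0)
            b2u = b2 / np.linalg.norm(b2)
            q1 = -b1 + np.dot(b1, b2u) * b2u
            q3 = b3 - np.dot(b3, b2u) * b2u
            cosphi = np.dot(q1, q3) / (np.linalg.norm(q1) * np.linalg.norm(q3))
            sign = np.sign(np.dot(np.cross(q1, q3), b2u))
            phi_oracle = sign * math.acos(np.clip(cosphi, -1, 1))
            e_bonds = sum(
                0.5 * ff.bond_k * (np.linalg.norm(d) - 0.38) ** 2
                for d in np.diff(chain, axis=0)
            )
            expected = float(ff.torsion.energy(phi_oracle)) + e_bonds
            assert bonded_energy(chain, ff) == pytest.approx(expected, abs=1e-8)
            assert dihedral_angle(*chain) == pytest.approx(phi_oracle, abs=1e-10)


class TestCargo:
    def test_presets(self):
        tcherry = build_cargo("tCherry")
        assert tcherry.radius == 7.4
        assert tcherry.charge == 0.0
        assert tcherry.n_hydro_sites == 0
        kap = build_cargo("Kap95")
        assert kap.radius == 8.5
        assert kap.charge == -43.0
        assert kap.n_hydro_sites == 10

    def test_sites_on_surface_and_reproducible(self):
        kap = build_cargo("Kap95")
        radii = np.linalg.norm(kap.sites, axis=1)
        assert np.allclose(radii, 8.5)
        again = build_cargo("Kap95")
        assert np.array_equal(kap.sites, again.sites)

    def test_site_placement_no_worse_than_spiral_baseline(self):
        """The minimised placement must not reduce the smallest angular
        separation below the golden-spiral start it refines."""
        kap = build_cargo("Kap95")
        unit = kap.sites / 8.5

        def min_angle(p):
            cos = np.clip(p @ p.T, -1, 1)
            np.fill_diagonal(cos, -1)
            return np.degrees(np.arccos(cos.max()))

        k = np.arange(10) + 0.5
        phi = np.arccos(1 - 2 * k / 10)
        th = math.pi * (1 + 5**0.5) * k
        spiral = np.c_[np.sin(phi) * np.cos(th), np.sin(phi) * np.sin(th), np.cos(phi)]
        assert min_angle(unit) >= min_angle(spiral) - 1e-6

    def test_negative_radius(self):
        with pytest.raises(ValueError):
            build_cargo("custom", radius=-1.0, charge=0.0, n_hydro_sites=0)

    def test_incomplete_custom_spec(self):
        with pytest.raises(KeyError):
            build_cargo("mystery", radius=5.0)
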