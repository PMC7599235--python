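"""Energy model: native-contact construction, restraint, pulling term."""

import numpy as np
import pytest
from scipy import constants as sc

from dimerlab.constants import KCAL_PER_PN_ANGSTROM, kbt
from dimerlab.energy import (build_energy_model, native_contact_pairs,
                             pulling_energy, restraint_energy)
from dimerlab.structure import (AtomRecord, DimerConformation, MonomerStructure,
                                ResidueRecord)
from dimerlab.synth import InterfaceSpec, make_toy_dimer


def _ca_monomer(coords, chain="A"):
    residues = tuple(
        ResidueRecord(index=i + 1, aa="A",
                      atoms=(AtomRecord("CA", "C", np.asarray(c, float)),))
        for i, c in enumerate(coords))
    return MonomerStructure(chain_id=chain, residues=residues)


class TestUnitConversions:
    def test_pn_angstrom_to_kcal_per_mol(self):
        """Independent route: pN·Å → J → kcal/mol via Avogadro's number."""
        joules = 1e-12 * 1e-10
        expected = joules * sc.Avogadro / (sc.calorie * 1000.0)
        assert KCAL_PER_PN_ANGSTROM == pytest.approx(expected, rel=1e-12)
        assert KCAL_PER_PN_ANGSTROM == pytest.approx(0.01439, rel=1e-3)

    def test_kbt_at_300K(self):
        assert kbt(300.0) == pytest.approx(0.5961, rel=1e-3)


class TestBuildEnergyModel:
    def test_two_site_pair_extraction(self):
        """Two sites 5 Å apart give exactly one native contact at r₀ = 5."""
        coords = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        pairs = native_contact_pairs(coords, exclude=set(),
                                     same_residue=np.array([0, 1]), cutoff=8.0)
        assert pairs.tolist() == [[0, 1]]

    def test_too_few_sites_raises(self):
        conf = DimerConformation(monomer_a=_ca_monomer([[0, 0, 0], [3.8, 0, 0]]),
                                 monomer_b=_ca_monomer([[20, 0, 0], [23.8, 0, 0]], "B"))
        with pytest.raises(ValueError, match="3 sites"):
            build_energy_model(conf)

    def test_reference_energy_is_sum_of_well_minima(self, small_dimer):
        """At the reference: pair energy = −Σε (repulsion negligible), no
        restraint, and the pulling term equals −F·D_ca."""
        model = build_energy_model(small_dimer.conformation, site_level="heavy",
                                   force_pn=368.0)
        e_pair = model.pair_energy(model.ref_coords)
        assert e_pair == pytest.approx(-float(model.native_eps.sum()), abs=0.05)
        assert e_pair >= -float(model.native_eps.sum())  # repulsion tail is >= 0
        assert model.restraint_term(model.ref_coords) == pytest.approx(0.0, abs=1e-9)
        d = model.anchor_distance(model.ref_coords)
        assert model.pulling_term(model.ref_coords) == pytest.approx(
            -368.0 * KCAL_PER_PN_ANGSTROM * d)

    def test_native_list_equals_brute_force_scan(self):
        toy = make_toy_dimer(60, InterfaceSpec(3, 2, 2, seed=4))
        model = build_energy_model(toy.conformation, site_level="heavy")
        coords = model.ref_coords
        bond_set = {tuple(b) for b in model.bonds.tolist()}
        mono, res = model.site_monomer, []
        # rebuild the same-residue key the builder uses
        k = 0
        same = []
        for m, mon in enumerate(toy.conformation.monomers):
            for r in mon.residues:
                for a in r.atoms:
                    same.append((m, r.index))
                    k += 1
        expected = set()
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if (i, j) in bond_set or same[i] == same[j]:
                    continue
                if np.linalg.norm(coords[i] - coords[j]) <= 8.0:
                    expected.add((i, j))
        assert {tuple(p) for p in model.native_pairs.tolist()} == expected

    def test_interface_scale_multiplies_cross_wells(self, small_dimer):
        m1 = build_energy_model(small_dimer.conformation, site_level="heavy",
                                inter_monomer_scale=1.0)
        m2 = build_energy_model(small_dimer.conformation, site_level="heavy",
                                inter_monomer_scale=2.5)
        cross = m1.site_monomer[m1.native_pairs[:, 0]] != \
            m1.site_monomer[m1.native_pairs[:, 1]]
        assert cross.any()
        np.testing.assert_allclose(m2.native_eps[cross], 2.5 * m1.native_eps[cross])
        np.testing.assert_allclose(m2.native_eps[~cross], m1.native_eps[~cross])


class TestRestraintEnergy:
    def test_reference_is_zero(self, small_dimer):
        conf = small_dimer.conformation
        assert restraint_energy(conf, conf, k_rmsd=3.0) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_displacement_is_free(self, small_dimer):
        """Moving one monomer as a rigid body costs no restraint energy."""
        conf = small_dimer.conformation
        mon_a = conf.monomer_a
        coords = np.array([a.coords for r in mon_a.residues for a in r.atoms])
        shifted = mon_a.with_coords(coords + np.array([7.0, -3.0, 2.0]))
        moved = DimerConformation(monomer_a=shifted, monomer_b=conf.monomer_b,
                                  box_side=conf.box_side, periodic=conf.periodic)
        assert restraint_energy(moved, conf, k_rmsd=3.0) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_deformation_arithmetic(self):
        """Radial square expansion: RMSD_A = 1.5, RMSD_B = 0.5, k = 2 → 4.0."""
        def square(eps, chain):
            base = np.array([[1.0, 1, 0], [-1, 1, 0], [-1, -1, 0], [1, -1, 0]]) * 3.0
            radial = base / np.linalg.norm(base, axis=1, keepdims=True)
            return _ca_monomer(base + eps * radial, chain), _ca_monomer(base, chain)

        mon_a, ref_a = square(1.5, "A")
        mon_b, ref_b = square(0.5, "B")
        conf = DimerConformation(monomer_a=mon_a, monomer_b=mon_b)
        ref = DimerConformation(monomer_a=ref_a, monomer_b=ref_b)
        assert restraint_energy(conf, ref, k_rmsd=2.0) == pytest.approx(4.0, abs=1e-9)


class TestPullingEnergy:
    def _dimer_at(self, distance):
        a = _ca_monomer([[0.0, 0, 0]])
        b = _ca_monomer([[distance, 0, 0]], "B")
        return DimerConformation(monomer_a=a, monomer_b=b)

    def test_zero_force(self):
        assert pulling_energy(self._dimer_at(10.0), force_pn=0.0) == 0.0

    def test_unit_conversion_oracle(self):
        """368 pN over 10 Å: magnitude 368·10·0.01439 ≈ 52.96 kcal/mol."""
        e = pulling_energy(self._dimer_at(10.0), force_pn=368.0)
        joules = 368e-12 * 10e-10
        expected = -joules * sc.Avogadro / (sc.calorie * 1000.0)
        assert e == pytest.approx(expected, rel=1e-12)
        assert abs(e) == pytest.approx(52.96, abs=0.02)

    def test_linear_in_force(self):
        e1 = pulling_energy(self._dimer_at(10.0), force_pn=100.0)
        e2 = pulling_energy(self._dimer_at(10.0), force_pn=200.0)
        assert e2 == pytest.approx(2 * e1)

    def test_separation_favouring_sign(self):
        """The term decreases as the anchors separate: the force pulls apart."""
        assert pulling_energy(self._dimer_at(20.0), force_pn=100.0) < \
            pulling_energy(self._dimer_at(10.0), force_pn=100.0)

    def test_minimum_image_cap(self):
        """In a 120 Å box the anchor distance wraps: 119 Å apart reads as 1 Å."""
        e_near = pulling_energy(self._dimer_at(1.0), force_pn=100.0)
        e_wrapped = pulling_energy(self._dimer_at(119.0), force_pn=100.0)
        assert e_wrapped == pytest.approx(e_near, rel=1e-9)
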