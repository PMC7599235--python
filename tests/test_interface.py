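"""Interface analytics: contacts, typed interactions, affinity, decomposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dimerlab.constants import AFFINITY_COEFFS, CONTACT_CUTOFF
from dimerlab.interface import (TypedInteraction, affinity_from_profile,
                                binding_affinity, class_contact_counts,
                                classify_interactions, count_contacts,
                                ensemble_average, inter_monomer_contacts,
                                interface_profile, position_decomposition)
from dimerlab.structure import (AtomRecord, DimerConformation, MonomerStructure,
                                ResidueRecord)
from dimerlab.synth import InterfaceSpec, make_toy_dimer, perturb_ensemble


def _residue(index, aa, atoms):
    return ResidueRecord(index=index, aa=aa,
                         atoms=tuple(AtomRecord(n, e, np.asarray(c, dtype=float))
                                     for n, e, c in atoms))


def _dimer(residues_a, residues_b):
    return DimerConformation(
        monomer_a=MonomerStructure(chain_id="A", residues=tuple(residues_a)),
        monomer_b=MonomerStructure(chain_id="B", residues=tuple(residues_b)))


def _brute_force_contacts(conf, cutoff=CONTACT_CUTOFF):
    out = set()
    for ra in conf.monomer_a.residues:
        for rb in conf.monomer_b.residues:
            for aa in ra.atoms:
                if not aa.is_heavy:
                    continue
                for ab in rb.atoms:
                    if not ab.is_heavy:
                        continue
                    if np.linalg.norm(aa.coords - ab.coords) <= cutoff:
                        out.add((ra.index, rb.index))
    return out


class TestContacts:
    def test_cutoff_rule(self):
        """Closest heavy atoms at 5.4 Å are in contact; at 10 Å they are not."""
        a = [_residue(1, "A", [("CA", "C", [0, 0, 0])])]
        b_near = [_residue(1, "A", [("CA", "C", [5.4, 0, 0])])]
        b_far = [_residue(1, "A", [("CA", "C", [10.0, 0, 0])])]
        assert count_contacts(_dimer(a, b_near)) == 1
        assert count_contacts(_dimer(a, b_far)) == 0

    def test_planted_interface_recovered_exactly(self, toy_dimer):
        contacts = inter_monomer_contacts(toy_dimer.conformation)
        assert {(c.res_a, c.res_b) for c in contacts} == \
               {(a, b) for a, b, _ in toy_dimer.planted_contacts}

    def test_separated_monomers_no_contacts(self):
        toy = make_toy_dimer(12, InterfaceSpec(seed=3))
        assert count_contacts(toy.conformation) == 0

    def test_chain_swap_symmetry(self, toy_dimer):
        conf = toy_dimer.conformation
        swapped = DimerConformation(monomer_a=conf.monomer_b,
                                    monomer_b=conf.monomer_a,
                                    box_side=conf.box_side, periodic=conf.periodic)
        assert count_contacts(swapped) == count_contacts(conf)

    def test_global_rigid_transform_invariance(self, toy_dimer):
        conf = toy_dimer.conformation
        rot = Rotation.from_rotvec([0.4, 0.2, -0.9]).as_matrix()
        shift = np.array([3.0, -7.0, 11.0])

        def moved(mon):
            coords = np.array([a.coords for r in mon.residues for a in r.atoms])
            return mon.with_coords(coords @ rot.T + shift)

        transformed = DimerConformation(monomer_a=moved(conf.monomer_a),
                                        monomer_b=moved(conf.monomer_b))
        before = {(c.res_a, c.res_b) for c in inter_monomer_contacts(conf)}
        after = {(c.res_a, c.res_b) for c in inter_monomer_contacts(transformed)}
        assert before == after

    def test_neighbor_list_equals_brute_force(self, rng):
        """Tree-based contact search equals the O(n²) scan on noisy toys."""
        for k in range(15):
            toy = make_toy_dimer(14 + (k % 3) * 4,
                                 InterfaceSpec(k % 3, k % 2, (k + 1) % 3, seed=k))
            conf = perturb_ensemble(toy.conformation, 1.0, 1, seed=k)[0]
            ours = {(c.res_a, c.res_b) for c in inter_monomer_contacts(conf)}
            assert ours == _brute_force_contacts(conf)


class TestTypedInteractions:
    def test_constructed_salt_bridge(self):
        """Lys NZ within 3.5 Å of Glu OE1 across the interface is one ionic pair."""
        a = [_residue(1, "K", [("CA", "C", [0, 0, 0]), ("NZ", "N", [3.0, 0, 0])])]
        b = [_residue(1, "E", [("CA", "C", [9.5, 0, 0]), ("OE1", "O", [6.5, 0, 0])])]
        counts = classify_interactions(_dimer(a, b))
        assert counts["ionic"] == 1
        assert counts["hbond"] == 0  # salt bridges are not double-counted

    def test_apolar_contact_only(self):
        """A Leu/Ile van der Waals pair gives hydrophobic but no polar counts."""
        a = [_residue(1, "L", [("CA", "C", [0, 0, 0]), ("CD1", "C", [3.0, 0, 0])])]
        b = [_residue(1, "I", [("CA", "C", [10.5, 0, 0]), ("CD1", "C", [7.5, 0, 0])])]
        counts = classify_interactions(_dimer(a, b))
        assert counts["hydrophobic"] >= 1
        assert counts["ionic"] == 0 and counts["hbond"] == 0

    def test_planted_counts_recovered(self, toy_dimer):
        counts = classify_interactions(toy_dimer.conformation)
        assert counts == {"hbond": 3, "hydrophobic": 5, "ionic": 2, "cation_pi": 0}

    def test_cation_pi_geometry(self):
        """A cation straight above a Phe ring centroid within 6 Å counts."""
        ring = []
        for i, name in enumerate(("CG", "CD1", "CD2", "CE1", "CE2", "CZ")):
            ang = np.pi * i / 3.0
            ring.append((name, "C", [1.4 * np.cos(ang), 1.4 * np.sin(ang), 0.0]))
        a = [_residue(1, "F", [("CA", "C", [0, 0, -3.0])] + ring)]
        b = [_residue(1, "K", [("CA", "C", [0, 0, 9.0]), ("NZ", "N", [0, 0, 4.5])])]
        counts = classify_interactions(_dimer(a, b))
        assert counts["cation_pi"] == 1


class TestBindingAffinity:
    def test_intercept_case(self):
        dg = affinity_from_profile({k: 0 for k in ("cc", "cp", "ca", "pp", "pa", "aa")},
                                   0.0, 0.0)
        assert dg == AFFINITY_COEFFS["intercept"]

    def test_exact_linearity_in_each_class(self):
        """Finite differences equal the configured coefficients to machine precision."""
        base = {"cc": 2, "cp": 1, "ca": 4, "pp": 1, "pa": 3, "aa": 10}
        dg0 = affinity_from_profile(base, 30.0, 20.0)
        for key in base:
            bumped = dict(base)
            bumped[key] += 1
            diff = affinity_from_profile(bumped, 30.0, 20.0) - dg0
            assert diff == pytest.approx(AFFINITY_COEFFS[key], abs=1e-12)
        assert affinity_from_profile(base, 31.0, 20.0) - dg0 == \
               pytest.approx(AFFINITY_COEFFS["nis_apolar"], abs=1e-12)

    def test_hand_evaluated_dot_product(self):
        ic = {"cc": 2, "ca": 4, "pp": 1, "pa": 3, "aa": 10, "cp": 0}
        w = AFFINITY_COEFFS
        expected = (2 * w["cc"] + 4 * w["ca"] + 1 * w["pp"] + 3 * w["pa"]
                    + 10 * w["aa"] + 30.0 * w["nis_apolar"]
                    + 20.0 * w["nis_charged"] + w["intercept"])
        assert affinity_from_profile(ic, 30.0, 20.0) == pytest.approx(expected, abs=1e-12)

    def test_full_profile_consistency(self, toy_dimer):
        prof = interface_profile(toy_dimer.conformation)
        assert prof.n_c == sum(prof.class_counts.values())
        assert prof.dG == pytest.approx(
            affinity_from_profile(prof.class_counts, prof.nis_apolar,
                                  prof.nis_charged))
        assert 0.0 <= prof.nis_apolar <= 100.0
        assert 0.0 <= prof.nis_charged <= 100.0
        assert binding_affinity(toy_dimer.conformation) == pytest.approx(prof.dG)


class TestPositionDecomposition:
    def test_identical_profiles_zero(self):
        items = [TypedInteraction("ionic", 10, 12), TypedInteraction("hbond", 3, 5)]
        out = position_decomposition(items, list(items), {10, 3})
        for kind in out:
            assert out[kind]["total"] == 0 and out[kind]["subset"] == 0

    def test_two_ionic_at_one_position(self):
        """Differences of 2 ionic pairs at position 466 are fully attributed there."""
        x = [TypedInteraction("ionic", 466, 12), TypedInteraction("ionic", 466, 30),
             TypedInteraction("hbond", 100, 101)]
        y = [TypedInteraction("hbond", 100, 101)]
        out = position_decomposition(x, y, {200, 372, 466, 521})
        assert out["ionic"]["total"] == 2
        assert out["ionic"]["subset"] == 2
        per = {p.position: p.typed_deltas["ionic"] for p in out["ionic"]["per_position"]}
        assert per[466] == 2 and per[200] == per[372] == per[521] == 0
        assert out["hbond"]["total"] == 0

    def test_empty_position_set(self):
        x = [TypedInteraction("hydrophobic", 1, 2)]
        out = position_decomposition(x, [], set())
        assert out["hydrophobic"]["total"] == 1
        assert out["hydrophobic"]["subset"] == 0

    def test_double_counting_reported(self):
        x = [TypedInteraction("ionic", 466, 521)]
        out = position_decomposition(x, [], {466, 521})
        per_sum = sum(p.typed_deltas["ionic"] for p in out["ionic"]["per_position"])
        assert per_sum == 2  # both endpoints in the set
        assert out["ionic"]["subset"] == 1
        assert out["ionic"]["double_counted"] == 1
        assert per_sum >= out["ionic"]["subset"]


class TestEnsembleAverage:
    def test_single_snapshot_has_no_se(self, small_dimer):
        out = ensemble_average([[small_dimer.conformation]], "n_c")
        assert out.se is None
        assert out.mean == count_contacts(small_dimer.conformation)

    def test_constant_metric_zero_se(self, small_dimer):
        runs = [[small_dimer.conformation] * 3 for _ in range(4)]
        out = ensemble_average(runs, "n_c")
        assert out.se == 0.0

    def test_unknown_metric(self, small_dimer):
        with pytest.raises(KeyError):
            ensemble_average([[small_dimer.conformation]], "nope")

    def test_se_matches_gaussian_sampling(self, small_dimer):
        """SE over run means tracks σ/√(n_runs·n_snap) for i.i.d. Gaussian noise."""
        conf = small_dimer.conformation
        metric = lambda c: float(c.monomer_a.residues[0].atoms[0].coords[0])
        sigma, n_runs, n_snap = 0.5, 6, 4
        ses = []
        for rep in range(30):
            runs = [perturb_ensemble(conf, sigma, n_snap, seed=100 * rep + r)
                    for r in range(n_runs)]
            ses.append(ensemble_average(runs, metric).se)
        expected = sigma / np.sqrt(n_snap) / np.sqrt(n_runs)
        assert np.mean(ses) == pytest.approx(expected, rel=0.30)
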