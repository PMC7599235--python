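"""Metropolis Monte Carlo engine and the two simulation protocols.

Moves are single-site Cartesian displacements plus rigid-body translations
and rotations of whole monomers (relative reorientation of the monomers is
unconstrained). One MC cycle attempts one move per move slot: every site
once, plus one translation and one rotation per monomer. Energies are
updated incrementally per move; the cached totals are checked against a
full recomputation at periodic checkpoints and resynchronised.

The backbone-RMSD restraint is evaluated per move through a rank-1 update
of the Kabsch covariance (the covariance against a centred reference does
not depend on the instantaneous mean, so a single-site displacement is an
O(1) update followed by a 3×3 SVD).

The native-ensemble protocol equilibrates, then stores snapshots at a
uniform stride; the pulling protocol records the anchor–anchor distance
D_ca every cycle and reports the first-passage time over the dissociation
threshold. Independent runs use independent seed-sequence streams spawned
from (master seed, run index), so a run set is reproducible bit for bit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import constants as C
from .energy import EnergyModel
from .structure import DimerConformation

__all__ = ["SimulationConfig", "McState", "PullingTrajectory",
           "metropolis_accept", "run_native_ensemble", "run_pulling"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation protocol parameters (defaults are the published protocol)."""

    temperature: float = C.TEMPERATURE_K
    n_cycles: int = C.N_CYCLES
    burn_in: int = C.BURN_IN
    n_snapshots: int = C.N_SNAPSHOTS
    n_runs: int = C.N_RUNS
    seed: int = 0
    site_move_amplitude: float = 0.15    # Å
    rigid_trans_amplitude: float = 0.15  # Å
    rigid_rot_amplitude: float = 0.02    # rad
    check_interval: int = 1000           # cycles between full-energy checks

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_cycles:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_cycles")
        if self.n_snapshots > self.n_cycles - self.burn_in:
            raise ValueError("n_snapshots must be <= n_cycles - burn_in")

    @property
    def snapshot_stride(self) -> int:
        return (self.n_cycles - self.burn_in) // self.n_snapshots


@dataclass
class McState:
    """Current coordinates and cached per-term energies of a simulation."""

    coords: np.ndarray
    cycle: int
    pair_energy: float
    restraint: list
    pull: float

    @property
    def total_energy(self) -> float:
        return self.pair_energy + self.restraint[0] + self.restraint[1] + self.pull


@dataclass(frozen=True)
class PullingTrajectory:
    """D_ca time series of one pulling run with its first-passage result."""

    cycles: np.ndarray
    d_ca: np.ndarray
    energy: np.ndarray
    dissociated: bool
    t_dis: int | None

    def __post_init__(self):
        if self.dissociated and self.t_dis is None:
            raise ValueError("dissociated trajectory must define t_dis")
        if not self.dissociated and self.t_dis is not None:
            raise ValueError("censored trajectory must not define t_dis")


def _signed_singular_sum(cov: np.ndarray) -> float:
    """σ₁+σ₂+σ₃ of a 3×3 matrix, smallest σ negated if det < 0 (Kabsch).

    Uses the closed-form eigenvalues of the symmetric matrix covᵀcov
    (trigonometric method), which is much cheaper than an SVD call at this
    size and is exercised against numpy's SVD in the tests.
    """
    a, b, c = cov[0]
    d, e, f = cov[1]
    g, h, i = cov[2]
    det = a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)
    # B = cov^T cov (symmetric, PSD)
    b00 = a * a + d * d + g * g
    b11 = b * b + e * e + h * h
    b22 = c * c + f * f + i * i
    b01 = a * b + d * e + g * h
    b02 = a * c + d * f + g * i
    b12 = b * c + e * f + h * i
    p1 = b01 * b01 + b02 * b02 + b12 * b12
    q = (b00 + b11 + b22) / 3.0
    if p1 <= 1e-30:
        eigs = (b00, b11, b22)
    else:
        p2 = ((b00 - q) ** 2 + (b11 - q) ** 2 + (b22 - q) ** 2 + 2.0 * p1)
        p = math.sqrt(p2 / 6.0)
        inv_p = 1.0 / p
        m00 = (b00 - q) * inv_p
        m11 = (b11 - q) * inv_p
        m22 = (b22 - q) * inv_p
        m01 = b01 * inv_p
        m02 = b02 * inv_p
        m12 = b12 * inv_p
        detm = (m00 * (m11 * m22 - m12 * m12) - m01 * (m01 * m22 - m12 * m02)
                + m02 * (m01 * m12 - m11 * m02))
        r = min(1.0, max(-1.0, detm / 2.0))
        phi = math.acos(r) / 3.0
        e1 = q + 2.0 * p * math.cos(phi)
        e3 = q + 2.0 * p * math.cos(phi + 2.0943951023931953)  # + 2π/3
        e2 = 3.0 * q - e1 - e3
        eigs = (e1, e2, e3)
    s = sorted(math.sqrt(max(0.0, x)) for x in eigs)
    total = s[0] + s[1] + s[2]
    if det < 0.0:
        total -= 2.0 * s[0]
    return total


def metropolis_accept(delta_e: float, kbt: float, rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion: accept with probability min(1, e^(−ΔE/kT))."""
    if not math.isfinite(delta_e):
        warnings.warn("non-finite energy change; move rejected", stacklevel=2)
        return False
    if delta_e <= 0.0:
        return True
    return rng.random() < math.exp(-delta_e / kbt)


class _Engine:
    """Incremental-energy MC engine over an EnergyModel."""

    def __init__(self, model: EnergyModel, config: SimulationConfig,
                 rng: np.random.Generator):
        self.m = model
        self.cfg = config
        self.rng = rng
        self.kbt = C.kbt(config.temperature)
        self.coords = model.ref_coords.copy()
        self.box = model.box_side
        self.half_box = model.box_side / 2.0
        self.periodic = model.periodic
        n = model.n_sites

        # unified per-site partner tables: [native..., repulsive..., bonded...]
        nat_j = [[] for _ in range(n)]
        nat_r0 = [[] for _ in range(n)]
        nat_eps = [[] for _ in range(n)]
        for (i, j), r0, eps in zip(model.native_pairs, model.native_r0, model.native_eps):
            nat_j[i].append(j); nat_r0[i].append(r0); nat_eps[i].append(eps)
            nat_j[j].append(i); nat_r0[j].append(r0); nat_eps[j].append(eps)
        rep_j = [[] for _ in range(n)]
        for i, j in model.repulsive_pairs:
            rep_j[i].append(j); rep_j[j].append(i)
        bnd_j = [[] for _ in range(n)]
        bnd_r0 = [[] for _ in range(n)]
        for (i, j), r0 in zip(model.bonds, model.bond_r0):
            bnd_j[i].append(j); bnd_r0[i].append(r0)
            bnd_j[j].append(i); bnd_r0[j].append(r0)
        self.j_all = [np.array(nat_j[i] + rep_j[i] + bnd_j[i], dtype=int) for i in range(n)]
        self.n_nat = [len(nat_j[i]) for i in range(n)]
        self.n_rep = [len(rep_j[i]) for i in range(n)]
        self.nat_r0 = [np.array(v) for v in nat_r0]
        self.nat_eps = [np.array(v) for v in nat_eps]
        self.bnd_r0 = [np.array(v) for v in bnd_r0]

        # cross-monomer pair tables for rigid moves
        mono = model.site_monomer
        if len(model.native_pairs):
            cr = mono[model.native_pairs[:, 0]] != mono[model.native_pairs[:, 1]]
            self.cross_nat = model.native_pairs[cr]
            self.cross_nat_r0 = model.native_r0[cr]
            self.cross_nat_eps = model.native_eps[cr]
        else:
            self.cross_nat = np.empty((0, 2), dtype=int)
            self.cross_nat_r0 = np.empty(0)
            self.cross_nat_eps = np.empty(0)
        if len(model.repulsive_pairs):
            cr = mono[model.repulsive_pairs[:, 0]] != mono[model.repulsive_pairs[:, 1]]
            self.cross_rep = model.repulsive_pairs[cr]
        else:
            self.cross_rep = np.empty((0, 2), dtype=int)
        if len(model.bonds):
            cb = mono[model.bonds[:, 0]] != mono[model.bonds[:, 1]]
            self.cross_bonds = model.bonds[cb]
            self.cross_bond_r0 = model.bond_r0[cb]
        else:
            self.cross_bonds = np.empty((0, 2), dtype=int)
            self.cross_bond_r0 = np.empty(0)

        self.mono_sites = (np.where(mono == 0)[0], np.where(mono == 1)[0])
        # restraint bookkeeping: centred reference, covariance, sums
        self.restraint_of_site = np.full(n, -1, dtype=int)
        self.site_row = np.full(n, -1, dtype=int)
        self.ref_centred, self.ref_ss, self.n_restr = [], [], []
        self.cov = [None, None]
        self.sum_x = [None, None]
        self.ss_x = [0.0, 0.0]
        for mdx, sites in enumerate(model.restraint_sites):
            rc = model.ref_coords[sites] - model.ref_coords[sites].mean(axis=0)
            self.ref_centred.append(rc)
            self.ref_ss.append(float((rc * rc).sum()))
            self.n_restr.append(len(sites))
            for row, s in enumerate(sites):
                self.restraint_of_site[s] = mdx
                self.site_row[s] = row
            self._sync_restraint(mdx)

        self.is_anchor = np.zeros(n, dtype=bool)
        self.is_anchor[list(model.anchors)] = True
        self.f_eff = model.force_pn * C.KCAL_PER_PN_ANGSTROM
        self.sigma12 = model.excluded_volume_radius ** 12
        self.inv_2w2 = 1.0 / (2.0 * model.well_width ** 2)

        self.state = McState(
            coords=self.coords, cycle=0,
            pair_energy=model.pair_energy(self.coords),
            restraint=[self._rmsd_energy(0), self._rmsd_energy(1)],
            pull=model.pulling_term(self.coords))
        self.accepted = {"site": 0, "trans": 0, "rot": 0}
        self.attempted = {"site": 0, "trans": 0, "rot": 0}
        self.max_drift = 0.0

    # --- restraint bookkeeping ----------------------------------------------

    def _sync_restraint(self, mdx: int):
        sites = self.m.restraint_sites[mdx]
        x = self.coords[sites]
        self.cov[mdx] = x.T @ self.ref_centred[mdx]
        self.sum_x[mdx] = x.sum(axis=0)
        self.ss_x[mdx] = float((x * x).sum())

    def _rmsd_from(self, mdx: int, cov, sum_x, ss_x) -> float:
        n = self.n_restr[mdx]
        xc_ss = ss_x - float(sum_x @ sum_x) / n
        s_sum = _signed_singular_sum(cov)
        rss = xc_ss + self.ref_ss[mdx] - 2.0 * s_sum
        return math.sqrt(max(0.0, rss) / n)

    def _rmsd_energy(self, mdx: int) -> float:
        if self.m.k_rmsd == 0:
            return 0.0
        return self.m.k_rmsd * self._rmsd_from(mdx, self.cov[mdx], self.sum_x[mdx],
                                               self.ss_x[mdx])

    # --- energy pieces ------------------------------------------------------

    def _mi(self, d: np.ndarray) -> np.ndarray:
        if self.periodic and np.abs(d).max() > self.half_box:
            d = d - self.box * np.round(d / self.box)
        return d

    def _site_pair_one(self, i: int, r2: np.ndarray) -> float:
        """Pair energy of site i from squared partner distances."""
        nn, nr = self.n_nat[i], self.n_rep[i]
        e = 0.0
        if nn:
            dr = np.sqrt(r2[:nn]) - self.nat_r0[i]
            e -= float((self.nat_eps[i] * np.exp(-dr * dr * self.inv_2w2)).sum())
        if nr:
            rr6 = np.maximum(r2[nn:nn + nr], 0.01) ** 6
            e += self.sigma12 * float((1.0 / rr6).sum())
        if len(r2) > nn + nr:
            db = np.sqrt(r2[nn + nr:]) - self.bnd_r0[i]
            e += self.m.bond_k * float((db * db).sum())
        return e

    def _site_pair_energies(self, i: int, xi_old: np.ndarray, xi_new: np.ndarray):
        """(E_old, E_new) of all pair terms involving site i."""
        j = self.j_all[i]
        if len(j) == 0:
            return 0.0, 0.0
        x = self.coords[j]
        d_old = self._mi(x - xi_old)
        d_new = self._mi(x - xi_new)
        r2_old = np.einsum("ij,ij->i", d_old, d_old)
        r2_new = np.einsum("ij,ij->i", d_new, d_new)
        return self._site_pair_one(i, r2_old), self._site_pair_one(i, r2_new)

    def _cross_energy(self) -> float:
        e = 0.0
        if len(self.cross_nat):
            d = self._mi(self.coords[self.cross_nat[:, 0]] - self.coords[self.cross_nat[:, 1]])
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            dr = r - self.cross_nat_r0
            e -= float((self.cross_nat_eps * np.exp(-dr * dr * self.inv_2w2)).sum())
        if len(self.cross_rep):
            d = self._mi(self.coords[self.cross_rep[:, 0]] - self.coords[self.cross_rep[:, 1]])
            r = np.maximum(np.sqrt(np.einsum("ij,ij->i", d, d)), 0.1)
            e += float((self.sigma12 / (r ** 6) ** 2).sum())
        if len(self.cross_bonds):
            d = self._mi(self.coords[self.cross_bonds[:, 0]]
                         - self.coords[self.cross_bonds[:, 1]])
            r = np.sqrt(np.einsum("ij,ij->i", d, d))
            db = r - self.cross_bond_r0
            e += self.m.bond_k * float((db * db).sum())
        return e

    def _pull(self) -> float:
        if self.f_eff == 0.0:
            return 0.0
        d = self._mi(self.coords[self.m.anchors[0]] - self.coords[self.m.anchors[1]])
        return -self.f_eff * float(np.linalg.norm(d))

    # --- moves --------------------------------------------------------------

    def _try_site(self, i: int, step: np.ndarray, u: float):
        self.attempted["site"] += 1
        xi_old = self.coords[i]
        xi_new = xi_old + step
        e_old, e_new = self._site_pair_energies(i, xi_old, xi_new)
        delta = e_new - e_old

        mdx = self.restraint_of_site[i]
        new_restraint = cov_new = sum_new = ss_new = None
        if mdx >= 0 and self.m.k_rmsd > 0:
            row = self.site_row[i]
            cov_new = self.cov[mdx] + np.outer(step, self.ref_centred[mdx][row])
            sum_new = self.sum_x[mdx] + step
            ss_new = self.ss_x[mdx] + float(xi_new @ xi_new) - float(xi_old @ xi_old)
            new_restraint = self.m.k_rmsd * self._rmsd_from(mdx, cov_new, sum_new, ss_new)
            delta += new_restraint - self.state.restraint[mdx]

        new_pull = None
        if self.is_anchor[i] and self.f_eff != 0.0:
            other = self.m.anchors[1] if i == self.m.anchors[0] else self.m.anchors[0]
            d = self._mi(xi_new - self.coords[other])
            new_pull = -self.f_eff * float(np.linalg.norm(d))
            delta += new_pull - self.state.pull

        if delta <= 0.0 or (math.isfinite(delta) and u < math.exp(-delta / self.kbt)):
            self.coords[i] = xi_new
            self.state.pair_energy += e_new - e_old
            if new_restraint is not None:
                self.cov[mdx] = cov_new
                self.sum_x[mdx] = sum_new
                self.ss_x[mdx] = ss_new
                self.state.restraint[mdx] = new_restraint
            if new_pull is not None:
                self.state.pull = new_pull
            self.accepted["site"] += 1

    def _try_rigid(self, mdx: int, kind: str, params, u: float):
        self.attempted[kind] += 1
        sites = self.mono_sites[mdx]
        old = self.coords[sites].copy()
        cross_old = self._cross_energy()
        pull_old = self.state.pull
        if kind == "trans":
            new = old + params
        else:
            axis, angle = params
            centre = old.mean(axis=0)
            k = axis / np.linalg.norm(axis)
            v = old - centre
            new = centre + (v * math.cos(angle)
                            + np.cross(k, v) * math.sin(angle)
                            + np.outer(v @ k, k) * (1.0 - math.cos(angle)))
        self.coords[sites] = new
        cross_new = self._cross_energy()
        pull_new = self._pull()
        delta = (cross_new - cross_old) + (pull_new - pull_old)
        if delta <= 0.0 or (math.isfinite(delta) and u < math.exp(-delta / self.kbt)):
            self.state.pair_energy += cross_new - cross_old
            self.state.pull = pull_new
            if self.m.k_rmsd > 0:
                self._sync_restraint(mdx)  # RMSD unchanged, bookkeeping is not
            self.accepted[kind] += 1
        else:
            self.coords[sites] = old

    def run_cycle(self):
        n = self.m.n_sites
        steps = self.rng.normal(0.0, self.cfg.site_move_amplitude, size=(n, 3))
        us = self.rng.random(n + 4)
        order = self.rng.permutation(n)
        for k in range(n):
            self._try_site(int(order[k]), steps[k], us[k])
        for slot, mdx in enumerate((0, 1)):
            shift = self.rng.normal(0.0, self.cfg.rigid_trans_amplitude, size=3)
            self._try_rigid(mdx, "trans", shift, us[n + slot])
        for slot, mdx in enumerate((0, 1)):
            axis = self.rng.normal(size=3)
            angle = self.rng.normal(0.0, self.cfg.rigid_rot_amplitude)
            self._try_rigid(mdx, "rot", (axis, angle), us[n + 2 + slot])
        self.state.cycle += 1
        if self.cfg.check_interval and self.state.cycle % self.cfg.check_interval == 0:
            self._checkpoint()

    def _checkpoint(self):
        full_pair = self.m.pair_energy(self.coords)
        for mdx in (0, 1):
            self._sync_restraint(mdx)
        full_restraint = [self._rmsd_energy(0), self._rmsd_energy(1)]
        full_pull = self.m.pulling_term(self.coords)
        full = full_pair + sum(full_restraint) + full_pull
        drift = abs(full - self.state.total_energy)
        self.max_drift = max(self.max_drift, drift)
        self.state.pair_energy = full_pair
        self.state.restraint = full_restraint
        self.state.pull = full_pull

    def acceptance_rates(self) -> dict:
        return {k: (self.accepted[k] / a if (a := self.attempted[k]) else 0.0)
                for k in self.attempted}

    def anchor_distance(self) -> float:
        d = self._mi(self.coords[self.m.anchors[0]] - self.coords[self.m.anchors[1]])
        return float(np.linalg.norm(d))

    def snapshot(self) -> DimerConformation:
        return _coords_to_conformation(self.m, self.coords.copy())


def _coords_to_conformation(model: EnergyModel, coords: np.ndarray) -> DimerConformation:
    """Rebuild a (reduced) DimerConformation holding only the model sites."""
    from .structure import AtomRecord, MonomerStructure, ResidueRecord
    k = 0
    mons = []
    for mon in model.reference.monomers:
        residues = []
        for r in mon.residues:
            atoms = []
            for a in r.atoms:
                if model.site_level == "ca" and a.name != "CA":
                    continue
                if model.site_level == "heavy" and not a.is_heavy:
                    continue
                atoms.append(AtomRecord(name=a.name, element=a.element,
                                        coords=coords[k].copy()))
                k += 1
            if atoms:
                residues.append(ResidueRecord(index=r.index, aa=r.aa, atoms=tuple(atoms)))
        mons.append(MonomerStructure(chain_id=mon.chain_id, residues=tuple(residues)))
    return DimerConformation(monomer_a=mons[0], monomer_b=mons[1],
                             box_side=model.reference.box_side,
                             periodic=model.reference.periodic)


def _run_streams(config: SimulationConfig):
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(child) for child in ss.spawn(config.n_runs)]


def run_native_ensemble(model: EnergyModel, config: SimulationConfig,
                        return_engines: bool = False):
    """Independent native-state runs; returns snapshots per run.

    Snapshots are taken at a uniform stride after the burn-in, ``n_snapshots``
    per run. With the published protocol numbers (500,000 cycles, 200,000
    burn-in, 3,000 snapshots) the stride is 100 cycles.
    """
    stride = config.snapshot_stride
    runs, engines = [], []
    for run_idx, rng in enumerate(_run_streams(config)):
        engine = _Engine(model, config, rng)
        snapshots = []
        for cycle in range(1, config.n_cycles + 1):
            engine.run_cycle()
            if cycle > config.burn_in and (cycle - config.burn_in) % stride == 0 \
                    and len(snapshots) < config.n_snapshots:
                snapshots.append(engine.snapshot())
        logger.info("native run %d: acceptance %s", run_idx, engine.acceptance_rates())
        runs.append(snapshots)
        engines.append(engine)
    return (runs, engines) if return_engines else runs


def run_pulling(model: EnergyModel, config: SimulationConfig,
                d_threshold: float = C.DISSOCIATION_THRESHOLD,
                d_cap: float | None = None,
                record_stride: int = 1,
                pre_equilibration: int = 0) -> list[PullingTrajectory]:
    """Constant-force pulling runs with first-passage detection.

    Each run starts from the native reference; with ``pre_equilibration`` > 0
    that many unforced cycles are run first, so the force switches on from a
    sample of the restrained native ensemble rather than from the exact
    reference coordinates. D_ca (minimum-image anchor distance) is recorded
    every ``record_stride`` cycles; ``t_dis`` is the first cycle (counted
    from force switch-on) with D_ca > d_threshold. Each run stops at the
    threshold crossing (or at ``d_cap`` if given, letting the
    post-dissociation drift be observed) or runs to ``n_cycles`` and is then
    censored.
    """
    import dataclasses
    if model.force_pn <= 0:
        logger.warning("pulling with force <= 0: dissociation is not driven")
    unforced = dataclasses.replace(model, force_pn=0.0) if pre_equilibration else None
    out = []
    for run_idx, rng in enumerate(_run_streams(config)):
        engine = _Engine(model, config, rng)
        if pre_equilibration:
            pre = _Engine(unforced, config, rng)
            for _ in range(pre_equilibration):
                pre.run_cycle()
            engine.coords[:] = pre.coords
            engine._checkpoint()
            engine.max_drift = 0.0  # the resync above is not drift
        cycles, dca, energy = [], [], []
        t_dis = None
        for cycle in range(1, config.n_cycles + 1):
            engine.run_cycle()
            d = engine.anchor_distance()
            if cycle % record_stride == 0:
                cycles.append(cycle)
                dca.append(d)
                energy.append(engine.state.total_energy)
            if t_dis is None and d > d_threshold:
                t_dis = cycle
                if d_cap is None:
                    break
            if t_dis is not None and d_cap is not None and d > d_cap:
                break
        out.append(PullingTrajectory(
            cycles=np.array(cycles, dtype=int), d_ca=np.array(dca),
            energy=np.array(energy), dissociated=t_dis is not None, t_dis=t_dis))
        logger.info("pulling run %d: %s", run_idx,
                    f"t_dis={t_dis}" if t_dis else "censored")
    return out
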