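"""Desk-scale study protocols on synthetic dimers.

The full published protocol (24 runs × 500,000 cycles on >1000-residue
dimers) is cluster-scale; these protocols reproduce its logic on reduced
toy dimers at sizes a workstation handles in minutes. The choices below
were made once, against the same criteria the original protocol states,
and are fixed:

* The toy pulling system is a 10-residue-per-monomer dimer with a single
  planted hydrophobic contact at the chain centre. A central contact
  matters: with an off-centre contact a bound dimer can extend its
  anchor–anchor distance by pivoting about the contact, which contaminates
  the first-passage statistics with non-dissociation crossings.
* The pulling force (300 pN at interface well scale 7.5) is chosen the way
  the published force was: large enough that dissociation happens within a
  manageable number of cycles, small enough that the bound state survives
  for a significant time, so that escape is barrier-limited and the
  dissociation-time distribution is close to exponential.
* The dissociation threshold is 20 Å for the toy geometry (bound anchor
  distance ≈ 11–15 Å): the smallest distance that, once passed under
  force, is never re-crossed — the same criterion by which the published
  41 Å threshold was set for the full-size dimer. 41 Å stays the default
  for full-size structures.
* Each pulling run starts from a 100-cycle unforced equilibration of the
  restrained native state, so first-passage clocks start from the native
  ensemble rather than from one exact coordinate set.
"""

from __future__ import annotations

import numpy as np

from .dissociation import DissociationSample, sample_from_trajectories
from .energy import EnergyModel, build_energy_model
from .mc import SimulationConfig, run_pulling
from .synth import InterfaceSpec, ToyDimer, make_toy_dimer

__all__ = ["TOY_PULL", "toy_pulling_model", "toy_pulling_config",
           "run_toy_pulling", "toy_strength_series"]

#: Fixed conditions of the toy pulling studies (see module docstring).
TOY_PULL = {
    "n_res": 10,
    "spec": InterfaceSpec(n_hydrophobic_pairs=1, seed=7),
    "native_cutoff": 4.5,     # Å: native pairs are the planted contacts only
    "well_width": 0.3,        # Å
    "interface_scale": 7.5,   # dimensionless well-depth scale
    "force_pn": 300.0,
    "d_threshold": 20.0,      # Å
    "pre_equilibration": 100,  # cycles
    "n_cycles": 60_000,
    "rigid_trans_amplitude": 0.3,
}


def toy_pulling_model(force_pn: float | None = None,
                      interface_scale: float | None = None,
                      toy: ToyDimer | None = None) -> tuple[ToyDimer, EnergyModel]:
    """The fixed toy dimer and its pulling energy model."""
    if toy is None:
        toy = make_toy_dimer(TOY_PULL["n_res"], TOY_PULL["spec"])
    model = build_energy_model(
        toy.conformation, site_level="heavy",
        native_cutoff=TOY_PULL["native_cutoff"],
        well_width=TOY_PULL["well_width"],
        inter_monomer_scale=TOY_PULL["interface_scale"]
        if interface_scale is None else interface_scale,
        force_pn=TOY_PULL["force_pn"] if force_pn is None else force_pn)
    return toy, model


def toy_pulling_config(n_runs: int, seed: int) -> SimulationConfig:
    return SimulationConfig(n_cycles=TOY_PULL["n_cycles"], burn_in=0,
                            n_snapshots=1, n_runs=n_runs, seed=seed,
                            rigid_trans_amplitude=TOY_PULL["rigid_trans_amplitude"])


def run_toy_pulling(n_runs: int, seed: int, force_pn: float | None = None,
                    interface_scale: float | None = None) -> DissociationSample:
    """Pulling first-passage sample under the fixed toy protocol."""
    _, model = toy_pulling_model(force_pn=force_pn, interface_scale=interface_scale)
    trajs = run_pulling(model, toy_pulling_config(n_runs, seed),
                        d_threshold=TOY_PULL["d_threshold"],
                        pre_equilibration=TOY_PULL["pre_equilibration"])
    return sample_from_trajectories(trajs, run_length=TOY_PULL["n_cycles"])


#: Interface-strength multipliers of the weak/medium/strong dimer series,
#: relative to the fixed toy scale (planted ordering: weak < medium < strong).
STRENGTH_SERIES = (7.0 / 7.5, 1.0, 8.0 / 7.5)


def toy_strength_series() -> dict[str, float]:
    """Named interface well scales for the weak/medium/strong comparison."""
    base = TOY_PULL["interface_scale"]
    return {"weak": base * STRENGTH_SERIES[0],
            "medium": base * STRENGTH_SERIES[1],
            "strong": base * STRENGTH_SERIES[2]}
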