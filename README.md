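# dimerlab

Monte Carlo study of inter-monomer binding tightness in protein dimers:
native-state ensembles under a backbone-RMSD restraint, constant-force
pulling with first-passage dissociation kinetics, and ensemble-level
interface analytics with run-level statistics.

## The scientific problem

Many enzymes work only as dimers. The motivating system is the cytosolic
phosphoglucose isomerase (PgiC) of the grass *Festuca ovina*, which carries
two homologous *PgiC* genes — a native copy and one acquired by horizontal
gene transfer — whose products form two homodimers and a heterodimer. The
catalytic centres are composed of residues from *both* monomers, so how
tightly the monomers bind is directly functional, and differences in
binding tightness between the three dimers bear on why the foreign gene
persists. Absolute binding free energies of such large complexes are out of
reach, but *relative* tightness can be probed computationally in two
independent ways:

1. **Native-state ensembles.** Sample conformations around the folded
   reference under a restraint energy `E_RMSD = k·(RMSD_A + RMSD_B)` that
   keeps each monomer native-like while leaving their relative geometry
   free, then compare interface descriptors averaged over the ensemble:
   the number of inter-monomer residue-pair contacts `n_c` (any heavy-atom
   pair within 5.5 Å), typed interactions (hydrogen bonds, hydrophobic,
   ionic, cation–π), apolar solvent-accessible surface area, and a
   contact-based binding-affinity estimate
   `ΔG = Σ_k w_k·IC_k + w_a·%NIS_apolar + w_c·%NIS_charged + w₀`.
2. **Pulling simulations.** Add a constant-force term `−F·|x₁−x₂|` acting
   on the Cα atoms nearest each monomer's centre of mass and record the
   dissociation time `t_dis`, the first MC cycle at which the anchor
   distance `D_ca` crosses a threshold. Over independent runs the
   dissociated fraction follows the two-state law `P(t) = 1 − e^(−λt)`
   with `λ = 1/⟨t_dis⟩` — not fitted, just the inverse mean.

The sampler is Metropolis MC at 300 K in a periodic 120 Å box over a
structure-based (Gō-type) potential: Gaussian attractive wells on native
contacts, `r⁻¹²` excluded volume elsewhere, harmonic chain pseudo-bonds,
plus the restraint and pulling terms. Everything is testable offline: a
synthetic-data module generates two-chain toy dimers with exactly
controlled interface composition (planted hydrophobic / ionic /
hydrogen-bond pairs), native-like ensembles, and equal-length sequence
pairs with planted substitutions, so every analysis stage can be checked
against planted ground truth. See `docs/methods.md` for the model details
and the fixed desk-scale study conditions.

## Worked example

```python
import dimerlab as dl
from dimerlab.interface import interface_profile
from dimerlab.protocols import run_toy_pulling
from dimerlab.dissociation import fit_two_state

# a 42-residue-per-monomer toy dimer with a planted interface:
# 5 hydrophobic, 2 ionic and 3 hydrogen-bond pairs
toy = dl.make_toy_dimer(42, dl.InterfaceSpec(
    n_hydrophobic_pairs=5, n_ionic_pairs=2, n_hbond_pairs=3, seed=1))

prof = interface_profile(toy.conformation)
print(prof.n_c)            # 10   -> the 10 planted residue pairs, exactly
print(prof.typed_counts)   # {'hbond': 3, 'hydrophobic': 5, 'ionic': 2,
                           #  'cation_pi': 0}
print(round(prof.dG, 2))   # -1.8 kcal/mol (contact-based affinity model)

# 24 constant-force pulling runs of the fixed 10-residue toy protocol
sample = run_toy_pulling(n_runs=24, seed=1)
fit = fit_two_state(sample)
print(round(fit.mean_tdis))   # 844  MC cycles, mean dissociation time
print(f"{fit.rate:.2e}")      # 1.19e-03 per cycle  (lambda = 1/mean)
```

The contact and typed-interaction counts recover the planted interface
exactly — that closed loop (generate → analyse → recover) is the package's
core correctness check. The dissociation times come from genuine
first-passage events: each run holds together for a random, roughly
exponentially distributed number of cycles before the interface breaks and
`D_ca` runs away.

A thin CLI wraps the same stages:

```bash
dimerlab synth --n-res 42 --hydrophobic 5 --ionic 2 --hbond 3 --outdir toy/
dimerlab analyze-interface toy/dimer.pdb --outdir analysis/
dimerlab simulate pull toy/dimer.pdb --force 300 --site-level heavy
dimerlab dissociation simulation_out/t_dis.txt
dimerlab compare-seqs a.fasta b.fasta --trim 6 554
```

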