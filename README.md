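# enmfold

Elastic-network dynamics, coarse-grained unfolding simulation and
structural thermostability descriptors for comparing pairs of
homologous protein structures.

## What problem this addresses

Why is one enzyme much more heat-resistant than a close homolog with
the same fold?  The motivating system is the amylosucrase pair from
*Neisseria polysaccharea* (NpAS, mesostable) and *Deinococcus
geothermalis* (DgAS, the most thermostable amylosucrase characterized),
but every operation applies to any pair of homologous single-chain
structures.  The package answers the question along three axes:

1. **Structure** — the classic descriptor panel: solvent-accessible
   surface area split into hydrophilic / hydrophobic / other residue
   classes, hydrogen bonds (donor–acceptor ≤ 3.0 Å, D–H–A ≥ 150°,
   split into backbone–backbone and side-chain-involving), salt bridges
   (carboxylate O to basic N ≤ 3.5 Å), glycine φ+/φ− classification,
   per-domain proline census, burial and hydrogen-bond satisfaction of
   hydrophilic residues, and per-domain contact density (NCPR, number
   of contacts per residue).
2. **Dynamics** — Gaussian network model (GNM) and anisotropic network
   model (ANM).  The GNM places a node at every Cα and an identical
   spring on every pair within 7.0 Å; the pseudoinverse of the
   Kirchhoff matrix Γ gives fluctuations and correlations,
   ⟨ΔR_i·ΔR_j⟩ = 3k_BT [Γ⁺]_ij.  Slow modes report collective domain
   motions (cross-correlation maps, ANM direction fields); the fastest
   modes mark kinetically *hot spots* — residues whose square
   fluctuation over the 10 fastest modes exceeds 0.03 Å² on a scale
   calibrated against crystallographic B-factors.
3. **Unfolding** — the iterative GNM.  Interactions split into covalent
   backbone springs (strength c·γ, never broken) and non-covalent
   contacts (strength γ).  Each step computes every contact's distance
   fluctuation ⟨ΔR_ij²⟩ = ⟨ΔR_i²⟩ + ⟨ΔR_j²⟩ − 2⟨ΔR_i·ΔR_j⟩, breaks one
   contact chosen among the three largest (thermal noise), and repeats
   until no non-covalent contact remains.  Replicate ensembles yield
   per-domain unfolding curves, contact-map snapshots indexed by the
   number of lost native contacts (LNNC), and *weak regions* — spatial
   clusters of contacts broken in the first ~20% of steps, which are
   candidate sites for stabilizing mutations.

## Worked example

Every stage runs on synthetic structures with known properties.  The
dumbbell fixture — two dense clusters joined by a thin linker — is the
canonical test of the unfolding simulator's central claim, that the
most weakly supported contacts rupture first:

```python
import numpy as np
from enmfold import synthetic_data as sd
from enmfold.enm_core import build_kirchhoff, pseudo_inverse, mode_mass_fraction
from enmfold.unfolding import (IterativeENMParams, native_topology,
                               run_unfolding, mean_break_steps)

model = sd.make_dumbbell(n_core=15, n_linker=2, seed=0)
spec, cov = pseudo_inverse(build_kirchhoff(model))
print(f"residues: {len(model)}, nonzero GNM modes: {spec.n_nonzero}")
print(f"slowest-3 mode mass fraction: {mode_mass_fraction(spec, 3):.3f}")

params = IterativeENMParams(noise_top_k=3, replicates=20, seed=11)
topo = native_topology(model, params)
trajs = run_unfolding(model, params)
steps = mean_break_steps(trajs, topo)
linker = set(range(15, 17))
linker_steps = [s for p, s in steps.items() if set(p) & linker]
core_steps = [s for p, s in steps.items() if not set(p) & linker]
print(f"native non-covalent contacts: {topo.native_noncovalent_count}")
print(f"mean break step, linker contacts: {np.mean(linker_steps):.1f}")
print(f"mean break step, core contacts:   {np.mean(core_steps):.1f}")
```

prints

```
residues: 32, nonzero GNM modes: 31
slowest-3 mode mass fraction: 0.850
native non-covalent contacts: 116
mean break step, linker contacts: 3.0
mean break step, core contacts:   59.5
```

The three slowest modes carry 85% of the motion (the two cores hinging
and twisting about the linker), and across 20 stochastic replicates the
linker's junction contacts break on average at step 3 of 116 — the
weakest link goes first, far ahead of the core contacts.

A command-line interface wraps the same operations:

```bash
enmfold synth --kind dumbbell --n 30 --seed 3 --out fixture.pdb
enmfold unfold --pdb fixture.pdb --replicates 5 --seed 1 --top-k 3
enmfold metrics --pdb structure.pdb --domains examples/domains_1g5a.cfg
enmfold compare --config examples/compare_amylosucrases.yaml
```

`examples/` ships reconstructed domain maps for the two amylosucrases
(interval boundaries approximate, chosen to match the reported domain
lengths — see the file headers) and a ready-made comparison config.

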