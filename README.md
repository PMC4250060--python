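# oligoflex

Rigidity/flexibility analysis of oligomeric protein MD trajectories.

Thermophilic enzymes are commonly assumed to be more rigid than their
mesophilic orthologues at ambient conditions ("corresponding states").
Testing that idea on a real system — e.g. a tetrameric malate
dehydrogenase pair, mesophile vs thermophile, monomer vs tetramer,
300 K vs 360 K — requires quantifying rigidity at several length- and
time-scales from trajectory data. `oligoflex` packages that battery of
analyses for structural-bioinformatics users who have a topology (PDB)
and a coordinate trajectory (DCD/XTC, multi-model PDB, or XYZ) and
want comparable, unit-annotated numbers for two or more systems.

## What it computes

* **Collective variables** per frame: radius of gyration
  Rg = √⟨|rᵢ − r̄|²⟩ (unweighted); RMSD to a crystallographic reference
  after optimal Cα superposition (Kabsch); fraction of native contacts
  Q(t) = (1/N) Σᵢ mᵢ(t)/nᵢ over side-chain heavy atoms (native = within
  5 Å in the crystal, > 3 residues apart in sequence); fraction of
  native φ/ψ torsions A(t) within a circular tolerance window; and
  catalytic-pocket backbone RMSD against apo and holo reference
  conformers.
* **Windowed RMSF** (double time average): per-atom fluctuation about
  the block-mean position within windows τ_w of 0.1–5 ns, averaged
  over blocks, with block-to-block variability; temperature
  derivatives; and rigidity patterns — residues whose RMSF drops more
  than 30 % between the isolated monomer and the assembled oligomer.
* **Conformational substates**: leader-algorithm clustering on
  all-heavy-atom pairwise RMSD with cutoff (default 1.3 Å), and an
  exponential saturation fit n(t) = N∞(1 − e^(−t/τ)) giving the
  number of accessible substates and the time to visit them.
* **Internal diffusion**: D = ⟨δξ²⟩/τ_ξ for a CV ξ within the
  harmonic approximation, with τ_ξ from a single-exponential fit of
  the normalized autocorrelation function.
* **Interfaces** of a dimer-of-dimers tetramer (m = A–B + D–C, plus
  the two cross-dimer classes d and c): interdomain ion pairs and
  hydrogen bonds per frame, occupancies, occupancy-weighted ion-pair
  networks, hydrophobic/hydrophilic/mixed surface fractions from the
  Voronoi facets between chains, and hydrophobic proximity censuses.
* **Volumetrics**: per-atom Voronoi volumes (periodic box or
  probe-shell boundary) and the intrinsic compressibility
  β_T = ⟨δV²⟩/(k_B T ⟨V⟩) in 10⁻² GPa⁻¹.
* **Synthetic ground truth**: toy tetramers with designed interfacial
  contacts, exact-discretization Ornstein–Uhlenbeck dynamics, Markov
  hopping between conformers, and telegraph (two-state) contacts — so
  every stage is validated against closed-form expectations.

## Worked example

```python
import numpy as np
from oligoflex import synthetic as syn, fluctuations as fl, clustering as cl

# a toy system with known dynamics: OU fluctuations, sigma = 0.5 Å
structure = syn.make_tetramer(seed=7, chain_length=12)
traj = syn.make_ou_trajectory(structure, sigma=0.5, tau_c=20.0,
                              n_frames=20000, dt=1.0, seed=1)

prof = fl.rmsf_windowed(traj, "ca", window_ps=5000.0)
print(f"mean RMSF {fl.rmsf_average(prof):.3f} A")

t = np.linspace(0, 400, 120)
fit = cl.fit_saturation(t, 20 * (1 - np.exp(-t / 50)))
print(f"N_inf {fit.n_inf:.1f}, tau {fit.tau:.1f}")
```

prints

```
mean RMSF 0.494 A
N_inf 20.0, tau 50.0
```

The windowed RMSF recovers the generator's stationary fluctuation
amplitude (0.5 Å; the ~1 % deficit is the rigid-body degrees of
freedom absorbed by block superposition), and the saturation fit
returns the exact (N∞, τ) of a noiseless growth curve.

The same analyses run from the shell via the `oligoflex` command
(subcommands `synth`, `cv`, `rmsf`, `cluster`, `diffusion`,
`interface`, `volumetrics`, `run`, `compare`); `oligoflex run
-c config.yaml` drives the full battery over several systems and
writes per-stage CSV/JSON plus a side-by-side comparison table.

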