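# porepmf

Free-energy and hydration analysis of ion permeation through a constricted
potassium-channel pore.

Inward-rectifier (Kir) K⁺ channels carry a narrow "collar" of tyrosine side
chains at their intracellular mouth — an aperture too small for a fully
hydrated K⁺ ion. Whether such a constriction blocks conduction is a
free-energy question: what barrier does an ion face there, and does it pass
by shedding part of its hydration shell rather than by forcing the pore
open? `porepmf` packages the analysis chain used to answer it:

- **Umbrella-sampling PMF reconstruction.** A from-scratch 1D WHAM solver
  combines harmonically biased window histograms along the pore axis *z*
  into the potential of mean force *F(z) = −k_BT ln ρ(z)*, solving

  ρ(z_b) = Σᵢ hᵢᵦ / Σᵢ Nᵢ exp[(fᵢ − wᵢ(z_b))/k_BT],
  fᵢ = −k_BT ln Σᵦ ρ(z_b) exp[−wᵢ(z_b)/k_BT]

  self-consistently to a tolerance of 10⁻⁶, with per-bin SEM from a Bayesian
  bootstrap (Dirichlet reweighting of whole windows, 200 replicates).
- **2D reweighting** of (position, coordination-number) samples into an
  unbiased PMF over *z* and the number of coordinating oxygens.
- **Coordination-shell statistics**: oxygens within 3.0 Å of the ion,
  split water/hydroxyl, binned along *z* as normalized percentage
  histograms — the signature of partial dehydration is the modal count
  dropping from ~6 in the cavity to 3–4 at the collar.
- **Pore-aperture geometry**: diagonal O···O couplets between opposed
  collar hydroxyls, exchange symmetrization (D1,D2)→(D2,D1), van der Waals
  spacings, collar-crossing event extraction, and Kabsch Cα superposition /
  RMSD for PDB structures.
- **Blocker (spermine) energetics**: Boltzmann fold-ratios
  exp(ΔΔG/k_BT) between conditions, periodic unwrapping of the blocker
  coordinate, occupancy densities with central-80% intervals, and
  field-strength trends.
- **Liposome flux-assay analytics**: two-point normalization, first-order
  decay fits over the CCCP→valinomycin window, and a two-sided Dunnett
  many-to-one test with Monte-Carlo adjusted p-values.

Because converged all-atom sampling is far beyond a desktop, the package
ships a seeded Brownian-dynamics engine (`porepmf.landscape`) that plays the
role of the MD engine: an overdamped ion on an analytic free-energy surface
with a Gaussian collar barrier, a diffusing coordination coordinate coupled
to a z-dependent mean, umbrella/steering biases, a flat-bottom lateral
restraint and an optional axial field. Every analysis is validated by
parameter recovery against this known ground truth.

## Worked example

```python
import porepmf as pp
from porepmf import protocols

run = protocols.umbrella_run(6.0, seed=1)   # 101 windows, k = 30 kJ/mol/A^2
height, sem = protocols.recovered_barrier(run)
print(f"collar barrier {height:.2f} +/- {sem:.2f} kJ/mol")

dip = protocols.coordination_dip(run, seed=1)
print(f"modal coordination: cavity {dip['cavity_mode']}, "
      f"collar {dip['collar_mode']}")

print(f"10 kJ/mol block penalty -> "
      f"{pp.round_one_sig_fig(pp.boltzmann_fold_ratio(10.0)):.0f}-fold")
```

prints (seed 1):

```
collar barrier 5.87 +/- 0.96 kJ/mol
modal coordination: cavity 6, collar 4
10 kJ/mol block penalty -> 50-fold
```

The recovered barrier agrees with the programmed 6.0 kJ/mol ground truth
within its bootstrap SEM; the coordination histogram shows the
partial-dehydration dip (mode 6 → 4, the collar mode including one
tyrosine-hydroxyl contact); and a 10 kJ/mol PMF difference between two
conditions corresponds to a ~50-fold lower passage probability at 303.15 K.

The same pipeline is scriptable from the shell:

```sh
porepmf simulate --config configs/default.yaml --outdir RUN/
porepmf wham --windows RUN/ --tol 1e-6 --bootstraps 200 --seed 7 --out pmf.tsv
porepmf run --config configs/default.yaml --outdir RUN/   # full pipeline
```

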