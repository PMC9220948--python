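# raftsize

Equilibrium lipid-raft domain size from the competition between boundary
line tension and leaflet-dipole electrostatic repulsion.

## The problem

Ordered, sphingolipid/cholesterol/GM1-rich membrane domains ("lipid
rafts") are usually nanoscopic, but high-avidity ligation of
raft-resident receptors — e.g. by an NKG2D-anchored cytokine fusion on
CD8⁺ T cells — can reorganise them into micron-scale macrodomains that
concentrate TCR signalling machinery. A continuum energy model explains
the size transition: the boundary between ordered and disordered phases
costs line tension σ per unit length (favouring few large domains), while
the aligned permanent dipoles of raft lipids repel one another
(favouring many small domains). With the total raft area A_tot fixed,
N_D = A_tot/(πR_D²) circular domains of radius R_D have total energy

    E_total(R_D) = E_perim + E_elec
    E_perim      = N_D · 2π R_D σ = 2 A_tot σ / R_D
    E_elec       = N_D n² ⟨u_intra⟩ + N_D n² ⟨u_inter⟩,   n = π R_D²/A_L

where ⟨·⟩ averages the dipole–dipole pair energies (μ_d = ε ε₀ ΔV A_L per
lipid; r⁻³ repulsion within a leaflet from the closest approach d_min;
an h-offset kernel between leaflets) over the pair-distance distribution
of a disk. The equilibrium radius R\* minimises E_total; over the
physiological window of line tensions, ln R\* grows linearly in σ — a
small linear increase in line tension grows domains exponentially.

The package is aimed at membrane biophysicists and quantitative
immunologists who want to run the model, sweep line tension, infer σ from
an observed domain size, and run calibrated synthetic-data recovery
studies (including an affinity vs phospho-CD3ζ/phospho-STAT5 stage).

## Worked example

```python
import numpy as np
from raftsize import BilayerParams, minimize_total_energy, line_tension_sweep
from raftsize.units import PN

params = BilayerParams()            # 55 Å², h=3.5 nm, ε=8, ΔV=150 mV,
                                    # d_min=1.5 nm, A_tot=20 μm², σ=1 pN
res = minimize_total_energy(params)
print(f"R* = {res.R_star_nm:.2f} nm ({res.at_bound})")

sweep = line_tension_sweep(params, np.linspace(0.1, 3.0, 20) * PN)
print(sweep.table.head(3)[["sigma_pN", "R_star_nm"]])
print(f"ln R* vs sigma:  R² = {sweep.growth_fit.r_squared:.4f}, "
      f"slope = {sweep.growth_fit.slope:.2f} per pN")
print(f"R*  vs sigma:    R² = {sweep.comparison_fit.r_squared:.4f}")
```

prints

```
R* = 20.95 nm (none)
   sigma_pN  R_star_nm
0  0.100000   1.604008
1  0.252632   3.274191
2  0.405263   5.367589
ln R* vs sigma:  R² = 0.9935, slope = 2.11 per pN
R*  vs sigma:    R² = 0.6762
```

At the default parameters a 1 pN boundary tension sustains ~21 nm
nanodomains ("none" marks an interior, not bracket-pinned, minimum); by
3 pN the equilibrium radius is ≈1.6 μm — macrodomain scale. The
log-linear fit (R² = 0.99 vs 0.68 untransformed) is the exponential
growth law. The inverse map recovers the tension that produced an
observed size:

```python
from raftsize import infer_line_tension
from raftsize.units import NM
sigma = infer_line_tension(100 * NM, params, (0.05 * PN, 4.0 * PN))
print(f"sigma = {sigma / PN:.3f} pN")   # -> sigma = 1.781 pN
```

The same operations are available from a shell:

```bash
raftsize sweep --out-dir out/            # sweep.csv + sweep_fit.json
raftsize infer --r-obs-nm 100 --out-dir out/
raftsize affinity --seed 1 --out-dir out/
raftsize validate-params --config my_config.yaml
```

Each run writes a `resolved_config.yaml` beside its outputs, so every
artifact is reproducible from disk. Utility helpers round out the
package: `iu_to_molar(1000, 15e6, 15.5)` → 4.30 μM (the IL-2 activity →
molarity conversion used for equimolar dosing) and
`tumor_volume(4, 6)` → 65.45 mm³.

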