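# Methods

## The model

`raftsize` computes the equilibrium size of ordered ("raft") lipid
membrane domains from a competition of two energies. The bilayer carries
N_D identical circular ordered domains of radius R_D in a disordered
background, with the total ordered area fixed:

    N_D = A_tot / (π R_D²)

Two contributions make up the total energy:

* **Perimeter (line-tension) energy.** Each domain boundary costs σ per
  unit length:

      E_perim = N_D · 2π R_D · σ  =  2 A_tot σ / R_D.

  At fixed total area this falls as 1/R_D, so line tension favours a few
  large domains.

* **Dipole electrostatic energy.** Every lipid in the ordered phase
  carries an excess permanent dipole moment perpendicular to the membrane
  plane (the bilayer normal is the alignment reference). The moment per
  lipid is tied to the measurable dipole-potential contrast ΔV between the
  ordered and disordered phases by the parallel-plate relation

      μ_d = ε ε₀ ΔV A_L,

  with A_L the area per lipid and ε the local dielectric constant. Two
  parallel dipoles at in-plane separation r in the *same* leaflet repel
  with the point-dipole energy u_intra(r) = μ_d²/(4π ε ε₀ r³), integrated
  from the distance of closest approach d_min. A dipole pair split across
  the *two* leaflets is offset vertically by h, giving

      u_inter(r) = μ_d² (r² − 2h²) / (4π ε ε₀ (r² + h²)^{5/2}),

  attractive for r < √2·h, repulsive beyond, and finite at r = 0.

  The expected pair energy within a domain is the kernel averaged over
  the pair-distance distribution of a disk of radius R_D,

      p(r) = (2r/R²) [ (2/π) arccos(r/2R) − (r/πR) √(1 − r²/4R²) ],

  the classical density of the distance between two uniform points in a
  disk (support [0, 2R], closed-form CDF implemented alongside). With
  n = π R_D²/A_L dipoles per leaflet per domain, both the intra-leaflet
  count (two leaflets × n²/2 pairs) and the inter-leaflet count (n² pairs)
  reduce to the same scale N_D·n², so

      E_intra = N_D n² ∫_{d_min}^{2R} p(r) u_intra(r) dr,
      E_inter = N_D n² ∫_{0}^{2R}     p(r) u_inter(r) dr,
      E_elec  = E_intra + E_inter,
      E_total = E_perim + E_elec.

  Domains interact only through the shared area budget, not directly.

The equilibrium radius R* minimises E_total over the admissible range
(d_min-scale up to the single-domain radius √(A_tot/π)). Because E_perim
falls as 1/R_D while the repulsive expectation grows with domain size
(larger domains contain longer-range repulsive pairs), the minimum sits at
an interior radius over a window of line tensions, and in that window
ln R* is very nearly linear in σ — domain size grows *exponentially* with
a linear increase in line tension. That is the mechanism by which a
high-avidity surface ligand, by raising σ at raft boundaries, can tip
nanoscale rafts into micron-scale macrodomains.

## Parameters, units, defaults

All internal arithmetic is SI; constructors and the config format accept
the units practitioners quote (suffix-labelled keys, e.g. `A_L_A2`,
`h_nm`, `A_tot_um2`).

| symbol | meaning                               | default  | why |
|--------|---------------------------------------|----------|-----|
| σ      | line tension                          | 1 pN     | middle of the typical 0.1–3 pN range for Lo/Ld boundaries |
| A_L    | area per lipid                        | 55 Å²    | raft-phase (sphingolipid/GM1-rich) packing |
| h      | inter-leaflet dipole separation       | 3.5 nm   | mean of hydrocarbon and bilayer thickness: the carbonyl-glycerol level |
| ε      | local dielectric constant             | 8        | bilayer interior near the headgroup dipoles |
| ΔV     | ordered/disordered potential contrast | 150 mV   | measured Lo–Ld dipole-potential differences are ~100–300 mV; see below |
| d_min  | dipole closest approach               | 1.5 nm   | effective cutoff ≈ two headgroup spacings; see below |
| A_tot  | total ordered area                    | 20 μm²   | fixed raft budget of one cell surface |

ΔV and d_min have no single established value; they are configurable and
their defaults were chosen *jointly* so that the default line-tension
sweep (σ ∈ [0.1, 3] pN) lies entirely in the interior-minimum regime —
the regime the growth law concerns. The exponential growth rate scales as
1/(ε ε₀ ΔV²), so larger ΔV compresses the size range; 150 mV with a
1.5 nm cutoff keeps R* between ≈1.6 nm and ≈1.1 μm across the default
sweep with margin at both bracket edges. A bare headgroup-spacing cutoff
(≈0.8 nm) admits no ΔV with that property: the sweep always pins to a
bracket edge at one end or the other. A_L outside [30, 120] Å² warns but
does not fail, so exploratory sweeps are not blocked.

The model is athermal: energies are compared directly, with no entropic
or temperature term, and no curvature elasticity or inter-domain
electrostatics. N_D is continuous (a ratio of areas), keeping the
objective smooth for minimisation.

## Numerics

* **Quadrature.** All expectations over p(r) use adaptive quadrature
  (relative tolerance 1e-8, absolute floor 1e-30 J). Singular r⁻³
  kernels integrate from the d_min cutoff; the inter-leaflet kernel is
  regular at r = 0. Non-convergence raises an error carrying the achieved
  error estimate. The dipole prefactor μ_d²/(4π ε ε₀) multiplies the
  *result* of a purely geometric integral, so ΔV² scaling of E_elec is
  exact by construction rather than only to quadrature tolerance.
* **Minimisation.** E_elec is independent of σ, so it is tabulated once
  per parameter set at 400 log-spaced radii and interpolated with a cubic
  spline in ln R (the `ElectrostaticProfile`); one profile serves every
  sweep point, inversion and bootstrap resample. Minimisation scans the
  profile grid for the globally best cell (guarding against local
  minima), refines by bounded Brent on ln R (relative tolerance 1e-6),
  then polishes against the exact quadrature objective inside the winning
  cell. Solutions within two grid cells of a bracket edge are reported as
  bound solutions (`at_bound`), and the growth-law fit uses interior rows
  only.
* **Inversion.** σ → R* is monotone; `infer_line_tension` solves
  R*(σ) = R_obs by Brent root-finding to 1e-3 relative in σ, and reports
  the attainable radius range when an observation is outside it. For the
  bootstrap, a `LineTensionInverter` precomputes the map on a 64-point σ
  grid and inverts by monotone (PCHIP) interpolation; the map is nearly
  log-linear, so the interpolation error (~1e-4 relative) is far below
  the inversion tolerance. Bootstrap resamples falling outside the
  attainable range are mapped to the nearest bracket endpoint.
* **Ties and degeneracies.** ΔV = 0 pins R* to the upper bound (one
  maximal domain); σ = 0 pins it to the lower bound; both are reported
  explicitly rather than as spurious interior optima.

## Synthetic data: what it emulates, what it does not

* **Domain-radius observations** use multiplicative lognormal noise
  around R*(σ_true) — sizes are positive and microscopy spread is
  multiplicative. Defaults for the recovery study are n = 25 fields at
  log-sd 0.1 with a 200-resample percentile bootstrap at the 95% level.
  This emulates scatter in per-field macrodomain size estimates; it does
  *not* emulate segmentation bias, finite optical resolution, or
  domain-size distributions within a field (the model predicts a single
  deterministic equilibrium size).
* **Affinity–response datasets** draw Kd log-uniformly over 1 nM–10 μM
  (spanning high-affinity viral-ligand to weak cytokine-receptor binding)
  and generate a phospho-CD3ζ readout falling, and a phospho-STAT5
  readout rising, linearly in log10(Kd) with additive Gaussian noise —
  i.e. TCR phosphorylation rises and STAT5 phosphorylation falls as
  affinity increases. Response units are arbitrary (MFI-like; defaults:
  slopes ∓12 per decade, intercepts placing responses in a positive
  double-digit range, noise sd 5). The log scale is a modelling choice:
  linearity is asserted by the source observation without a scale, and
  constructs spanning affinity classes make the decade scale the natural
  one. No mechanistic link from Kd to line tension is modelled — the
  hypothesis that affinity raises σ motivates the inverse analysis but is
  not parameterised.

Passing recovery tests therefore show that the *analysis machinery* is
correct and well-calibrated under the stated noise model, not that real
microscopy or flow-cytometry data satisfy that noise model.

## Problem sizes in the shipped analyses

The test suite and `scripts/acceptance.py` use: 10⁶ Monte-Carlo pairs for
the distribution check (KS distance vs the closed-form CDF), 20 random
parameter sets against a 10⁴-point exhaustive grid argmin (grid energies
from an independent dense-trapezoid integrator), a 20-point default
sweep, 100 replicates × 200 bootstrap resamples for interval coverage,
and 500 replicates of n = 200 for affinity-slope bias. These sizes give
Monte-Carlo standard errors comfortably below the corresponding
tolerances.

## Known limitations

* Equations treat each domain as an isolated disk; the fixed-A_tot
  coupling is the only interaction. Near-contact domain arrangements
  would add repulsion not modelled here.
* The parallel-plate ΔV → μ_d mapping is a mean-field idealisation of a
  discrete dipole lattice; d_min absorbs the short-range structure it
  discards, which is why the cutoff is an *effective* parameter.
* The published arithmetic for the IL-2 dose equivalence (1000 U/μL,
  15×10⁶ U/mg, 15.5 kDa) gives 4.30 μM; the published figure of 4.4 μM
  appears to be rounded. `iu_to_molar` reports the computed value; the
  ~2% discrepancy is documented here rather than hard-coded.
* With the default A_tot = 20 μm², no choice of ΔV alone produces an
  interior regime across the whole 0.1–3 pN sweep at d_min ≈ 0.8 nm (one
  headgroup spacing); the effective 1.5 nm cutoff is part of the default
  calibration described above.
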