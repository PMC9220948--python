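"""Energy terms of the raft-size model.

The bilayer is covered by N_D identical circular ordered (raft) domains of
radius R_D embedded in a disordered phase, with the total raft area A_tot
fixed, so N_D = A_tot/(π·R_D²).  Two energies compete:

* a perimeter (line-tension) energy, E_perim = N_D·2π·R_D·σ, which favours
  few large domains, and
* an electrostatic energy of the permanent lipid headgroup dipoles, which
  favours many small domains because like-oriented dipoles in a domain
  repel.

Each lipid carries an excess dipole moment μ_d perpendicular to the
membrane plane (the bilayer normal is the alignment reference), related to
the measurable potential contrast ΔV between the ordered and disordered
phase by the parallel-plate relation μ_d = ε·ε₀·ΔV·A_L.  Within one
leaflet two such parallel dipoles at in-plane separation r interact with
the repulsive point-dipole energy

    u_intra(r) = μ_d² / (4π·ε·ε₀·r³),        r ≥ d_min,

and a dipole interacts with one in the opposing leaflet, vertically offset
by h, through

    u_inter(r) = μ_d²·(r² − 2h²) / (4π·ε·ε₀·(r² + h²)^{5/2}),

attractive at short range and repulsive beyond r = √2·h, and finite at
r = 0 because h > 0.  Summing over the π·R_D²/A_L dipoles per leaflet per
domain and averaging the pair separation over the disk pair-distance
distribution gives the expected total energies; domains are treated as
independent apart from sharing A_tot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .diskdist import expected_kernel_value
from .units import BilayerParams, joules_to_pn_nm

__all__ = [
    "DomainConfiguration",
    "EnergyBreakdown",
    "domain_count",
    "perimeter_energy",
    "dipole_moment_per_lipid",
    "intraleaflet_energy",
    "interleaflet_energy",
    "electrostatic_energy",
    "total_energy",
]


@dataclass(frozen=True)
class DomainConfiguration:
    """A candidate raft geometry: radius R_D (m) and domain count N_D.

    N_D is continuous (a ratio of areas, not an integer) so that the total
    energy is a smooth function of R_D; the area constraint
    N_D·π·R_D² = A_tot holds by construction.
    """

    R_D: float
    N_D: float
    A_tot: float

    @classmethod
    def from_radius(cls, R_D: float, A_tot: float) -> "DomainConfiguration":
        return cls(R_D=R_D, N_D=domain_count(R_D, A_tot), A_tot=A_tot)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components (J) of one domain configuration.

    E_total = E_perim + E_elec and E_elec = E_intra + E_inter hold
    exactly by construction.
    """

    E_perim: float
    E_intra: float
    E_inter: float
    E_elec: float
    E_total: float

    def to_dict(self) -> dict[str, float]:
        """Flat record for JSON/CSV serialisation (values in joules)."""
        return {
            "E_perim_J": self.E_perim,
            "E_intra_J": self.E_intra,
            "E_inter_J": self.E_inter,
            "E_elec_J": self.E_elec,
            "E_total_J": self.E_total,
        }

    def to_pn_nm(self) -> dict[str, float]:
        """Same record in pN·nm, the readable scale for membrane energies."""
        return {k.replace("_J", "_pN_nm"): joules_to_pn_nm(v) for k, v in self.to_dict().items()}


def domain_count(R_D: float, A_tot: float) -> float:
    """N_D = A_tot/(π·R_D²): how many radius-R_D domains tile the raft area.

    Continuous, not rounded.  ``R_D`` and ``A_tot`` in SI (m, m²).
    """
    if A_tot <= 0:
        raise ValueError("A_tot must be > 0")
    R_max = math.sqrt(A_tot / math.pi)
    if not 0 < R_D <= R_max * (1 + 1e-12):
        raise ValueError(
            f"R_D must lie in (0, sqrt(A_tot/pi)] = (0, {R_max:.4e} m], got {R_D!r}"
        )
    return A_tot / (math.pi * R_D**2)


def perimeter_energy(R_D: float, N_D: float, sigma: float) -> float:
    """Line-tension energy E_perim = N_D·2π·R_D·σ (J).

    With the area constraint substituted this is 2·A_tot·σ/R_D, strictly
    decreasing in the domain radius: line tension drives coalescence.
    """
    if R_D <= 0:
        raise ValueError("R_D must be > 0")
    if N_D < 1:
        raise ValueError("N_D must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return N_D * 2.0 * math.pi * R_D * sigma


def dipole_moment_per_lipid(delta_V: float, eps: float, eps0: float, A_L: float) -> float:
    """Excess dipole moment per lipid, μ_d = ε·ε₀·ΔV·A_L (C·m).

    Parallel-plate relation between a uniform dipole sheet of areal moment
    density μ_d/A_L and the potential jump ΔV it produces across the sheet.
    """
    if eps <= 0 or eps0 <= 0 or A_L <= 0:
        raise ValueError("eps, eps0 and A_L must be > 0")
    return eps * eps0 * delta_V * A_L


def _dipole_prefactor(params: BilayerParams) -> float:
    """μ_d²/(4π·ε·ε₀), the strength (J·m³) shared by both pair kernels."""
    mu = dipole_moment_per_lipid(params.delta_V, params.eps, params.eps0, params.A_L)
    return mu * mu / (4.0 * math.pi * params.eps * params.eps0)


def _pair_count_scale(R_D: float, params: BilayerParams) -> float:
    # N_D domains × 2 leaflets × n²/2 intra pairs == N_D domains × n² inter
    # pairs, n = π R_D²/A_L dipoles per leaflet; both reduce to the same
    # N_D·n² = A_tot·π·R_D²/A_L² scale.
    n = math.pi * R_D**2 / params.A_L
    return domain_count(R_D, params.A_tot) * n * n


def intraleaflet_energy(R_D: float, params: BilayerParams) -> float:
    """Expected dipole repulsion within the leaflets of all domains (J).

    Both leaflets of every domain contribute; pair separations are averaged
    over the disk distribution from the closest-approach cutoff d_min to
    the diameter.  Strictly positive for ΔV ≠ 0 and, at fixed A_tot,
    increasing in R_D — larger domains contain longer-range repulsive
    pairs, which is the mechanism capping raft size.
    """
    if params.delta_V == 0.0:
        return 0.0
    # geometric expectation first, dipole strength applied after: ΔV² then
    # scales the result exactly, independent of quadrature termination
    expectation = expected_kernel_value(R_D, lambda r: r**-3, r_lo=params.d_min)
    return _dipole_prefactor(params) * _pair_count_scale(R_D, params) * expectation


def interleaflet_energy(R_D: float, params: BilayerParams) -> float:
    """Expected dipole interaction between opposing leaflets (J).

    The effective separation of an opposing pair at in-plane distance r is
    √(r² + h²), so the kernel is finite at r = 0 and no cutoff is needed;
    its magnitude decays as the leaflet separation h grows.
    """
    if params.delta_V == 0.0:
        return 0.0
    h2 = params.h**2

    def kernel(r: float) -> float:
        r2 = r * r
        return (r2 - 2.0 * h2) / (r2 + h2) ** 2.5

    expectation = expected_kernel_value(R_D, kernel, r_lo=0.0)
    return _dipole_prefactor(params) * _pair_count_scale(R_D, params) * expectation


def electrostatic_energy(R_D: float, params: BilayerParams) -> float:
    """Combined electrostatic energy E_elec = E_intra + E_inter (J).

    Proportional to ΔV² (every pair energy carries μ_d²) and vanishing when
    the ordered and disordered phases have no dipole-potential contrast.
    """
    return intraleaflet_energy(R_D, params) + interleaflet_energy(R_D, params)


def total_energy(R_D: float, params: BilayerParams) -> EnergyBreakdown:
    """Full energy breakdown at radius R_D: E_total = E_perim + E_elec."""
    config = DomainConfiguration.from_radius(R_D, params.A_tot)
    e_perim = perimeter_energy(R_D, config.N_D, params.sigma)
    e_intra = intraleaflet_energy(R_D, params)
    e_inter = interleaflet_energy(R_D, params)
    e_elec = e_intra + e_inter
    return EnergyBreakdown(
        E_perim=e_perim,
        E_intra=e_intra,
        E_inter=e_inter,
        E_elec=e_elec,
        E_total=e_perim + e_elec,
    )
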