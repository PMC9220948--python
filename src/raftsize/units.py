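"""Physical parameters, unit discipline and small dosing/volume utilities.

The model mixes four length scales (ångström-scale lipid areas, nanometre
dipole separations, micrometre domains, piconewton line tensions), so every
quantity is stored internally in SI and converted exactly once, on input.
Constructors accept the mixed "lab" units that membrane biophysicists quote
(Å² per lipid, nm thicknesses, μm² total areas, pN line tensions, mV
potentials).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Any, Mapping

from scipy.constants import epsilon_0 as EPSILON_0

logger = logging.getLogger("raftsize")

# exact SI conversion factors
PN = 1e-12  # piconewton -> newton
NM = 1e-9  # nanometre -> metre
UM = 1e-6  # micrometre -> metre
ANG2 = 1e-20  # square ångström -> m²
UM2 = 1e-12  # square micrometre -> m²
MV = 1e-3  # millivolt -> volt
PN_NM = 1e-21  # piconewton·nanometre -> joule

#: physically sane guard range for the area per lipid, in m² (30–120 Å²)
A_L_GUARD_RANGE = (30 * ANG2, 120 * ANG2)


class ParameterError(ValueError):
    """A bilayer parameter violates a hard physical invariant."""


def joules_to_pn_nm(energy_j: float) -> float:
    """Convert an energy from joules to pN·nm (1 pN·nm = 1e-21 J)."""
    return energy_j / PN_NM


def pn_nm_to_joules(energy_pn_nm: float) -> float:
    return energy_pn_nm * PN_NM


@dataclass(frozen=True)
class BilayerParams:
    """All parameters of the raft-size energy model, stored in SI.

    Attributes
    ----------
    sigma : float
        Line tension of the ordered/disordered phase boundary, N.
    A_L : float
        Area per lipid, m² (default 55 Å²).
    h : float
        Separation between opposing-leaflet dipole planes, m (default
        3.5 nm, the mean of hydrocarbon and bilayer thickness, placing the
        dipoles at the carbonyl-glycerol level).
    eps : float
        Relative dielectric constant of the bilayer near the dipoles
        (default 8).
    eps0 : float
        Vacuum permittivity, F/m (fixed physical constant).
    delta_V : float
        Electrostatic potential difference between the raft domain and the
        surrounding disordered phase, V (default 0.15 V, in the measured range for
        ordered/disordered dipole-potential contrasts; see docs).
    d_min : float
        Distance of closest approach of two dipoles, m (default 1.5 nm, an
        effective cutoff of about two headgroup spacings); lower cutoff
        for the singular intra-leaflet kernel.
    A_tot : float
        Total area covered by all raft domains, m² (default 20 μm²).
    """

    sigma: float = 1.0 * PN
    A_L: float = 55.0 * ANG2
    h: float = 3.5 * NM
    eps: float = 8.0
    eps0: float = EPSILON_0
    delta_V: float = 0.15
    d_min: float = 1.5 * NM
    A_tot: float = 20.0 * UM2

    @classmethod
    def from_lab_units(
        cls,
        sigma_pN: float = 1.0,
        A_L_A2: float = 55.0,
        h_nm: float = 3.5,
        eps: float = 8.0,
        delta_V_mV: float = 150.0,
        d_min_nm: float = 1.5,
        A_tot_um2: float = 20.0,
    ) -> "BilayerParams":
        """Build parameters from the mixed units used at the bench."""
        return cls(
            sigma=sigma_pN * PN,
            A_L=A_L_A2 * ANG2,
            h=h_nm * NM,
            eps=eps,
            delta_V=delta_V_mV * MV,
            d_min=d_min_nm * NM,
            A_tot=A_tot_um2 * UM2,
        )

    @property
    def R_max(self) -> float:
        """Radius (m) of a single domain holding the whole raft area."""
        return math.sqrt(self.A_tot / math.pi)

    def with_sigma(self, sigma: float) -> "BilayerParams":
        """Copy with a different line tension (N)."""
        return replace(self, sigma=sigma)

    def to_lab_units(self) -> dict[str, float]:
        """Round-trip back to the quoted lab units (for config echoes)."""
        return {
            "sigma_pN": self.sigma / PN,
            "A_L_A2": self.A_L / ANG2,
            "h_nm": self.h / NM,
            "eps": self.eps,
            "delta_V_mV": self.delta_V / MV,
            "d_min_nm": self.d_min / NM,
            "A_tot_um2": self.A_tot / UM2,
        }


_CONFIG_KEYS = {
    "sigma_pN",
    "A_L_A2",
    "h_nm",
    "eps",
    "delta_V_mV",
    "d_min_nm",
    "A_tot_um2",
}


def bilayer_params_from_config(block: Mapping[str, Any]) -> BilayerParams:
    """Build validated params from a ``bilayer:`` config mapping.

    Keys carry explicit unit suffixes (``A_L_A2``, ``h_nm``, ``A_tot_um2``,
    ...); unknown keys are rejected so that silent typos cannot change a
    default.
    """
    unknown = set(block) - _CONFIG_KEYS
    if unknown:
        raise ParameterError(
            f"unknown bilayer config keys: {sorted(unknown)}; "
            f"allowed: {sorted(_CONFIG_KEYS)}"
        )
    for key, value in block.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ParameterError(f"bilayer config key {key!r} must be a number, got {value!r}")
    return validate_params(BilayerParams.from_lab_units(**dict(block)))


def validate_params(params: BilayerParams) -> BilayerParams:
    """Check hard invariants, warn on guard-range breaches, return the params.

    Raises
    ------
    ParameterError
        If a length, area or permittivity is non-positive, the line tension
        is negative, or the closest-approach distance cannot fit inside the
        largest admissible domain (d_min >= 2·R_max).
    """
    positive = ("A_L", "h", "eps", "eps0", "d_min", "A_tot")
    for name in positive:
        if not getattr(params, name) > 0:
            raise ParameterError(f"{name} must be strictly positive, got {getattr(params, name)!r}")
    if params.sigma < 0:
        raise ParameterError(f"sigma must be >= 0, got {params.sigma!r}")
    if not math.isfinite(params.delta_V):
        raise ParameterError(f"delta_V must be finite, got {params.delta_V!r}")
    if params.d_min >= 2.0 * params.R_max:
        raise ParameterError(
            f"d_min = {params.d_min / NM:.3g} nm must be smaller than the domain "
            f"diameter bound 2·R_max = {2 * params.R_max / NM:.3g} nm"
        )
    lo, hi = A_L_GUARD_RANGE
    if not (lo <= params.A_L <= hi):
        msg = (
            f"area per lipid A_L = {params.A_L / ANG2:.1f} Å² is outside the "
            f"physically typical range [30, 120] Å²"
        )
        logger.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    return params


def iu_to_molar(
    activity_per_uL: float,
    specific_activity_per_mg: float,
    molar_mass_kDa: float,
) -> float:
    """Convert a cytokine activity concentration to molarity (μM).

    Dosing cytokines "on an equimolar basis" requires translating units of
    biological activity into moles: an activity concentration (U/μL) divided
    by the specific activity (U/mg) gives a mass concentration, and dividing
    by the molar mass gives molarity.

    Parameters
    ----------
    activity_per_uL : units of activity per microlitre (U/μL).
    specific_activity_per_mg : units of activity per milligram (U/mg).
    molar_mass_kDa : molar mass in kilodaltons (kg/mol).

    Returns
    -------
    float
        Molar concentration in μM.

    Examples
    --------
    IL-2 with specific activity 15×10⁶ U/mg and molar mass 15.5 kDa:

    >>> round(iu_to_molar(1000.0, 15e6, 15.5), 2)
    4.3
    """
    if activity_per_uL < 0:
        raise ValueError("activity_per_uL must be >= 0")
    if specific_activity_per_mg <= 0 or molar_mass_kDa <= 0:
        raise ValueError("specific_activity_per_mg and molar_mass_kDa must be > 0")
    mg_per_uL = activity_per_uL / specific_activity_per_mg
    g_per_L = mg_per_uL * 1e3  # 1 mg/μL = 1e-3 g / 1e-6 L = 1e3 g/L
    mol_per_L = g_per_L / (molar_mass_kDa * 1e3)  # kDa -> g/mol
    return mol_per_L * 1e6  # mol/L -> μM


def tumor_volume(d1_mm: float, d2_mm: float) -> float:
    """Tumour volume (mm³) from two perpendicular calliper diameters.

    Uses the spherical estimate V = (4/3)·π·r³ with r taken as the mean
    radius of the two perpendicular diameters, r = (d1 + d2)/4.
    """
    if d1_mm < 0 or d2_mm < 0:
        raise ValueError("diameters must be >= 0")
    r = (d1_mm + d2_mm) / 4.0
    return (4.0 / 3.0) * math.pi * r**3
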