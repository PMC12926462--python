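"""Fractionation constants and atmospheric state for the isotope→iWUE chain.

All per-mil (‰) quantities are carbon isotope fractionations on the PDB
scale; pressures are in pascal; Γ*₂₅ is a mole fraction in µmol mol⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Any, Mapping


class Pathway(str, Enum):
    """Photosynthetic pathway of a sample."""

    C3 = "C3"
    C4 = "C4"


class Formulation(str, Enum):
    """Which discrimination model is inverted to obtain Ci (or Cc)."""

    SIMPLE = "simple"          # Δ = a + (b−a)·Ci/Ca
    PHOTORESP = "photoresp"    # adds the photorespiratory term f′·Γ*/pCa
    MESOPHYLL = "mesophyll"    # adds mesophyll drawdown via g_sc/g_m
    C4 = "c4"                  # PEP-carboxylase / bundle-sheath model


@dataclass(frozen=True)
class FractionationConstants:
    """Carbon-isotope fractionation constants and physical constants.

    Defaults are the standard values for the leaf-level discrimination
    models: diffusion in air ``a``, mesophyll transfer ``a_m``, Rubisco
    carboxylation ``b``, photorespiration ``f_prime``; for the C4 model,
    Rubisco ``b3``, PEP carboxylation plus preceding equilibria ``b4``,
    bundle-sheath leakage fractionation ``s`` and leakiness ``phi``.
    ``gsc_over_gm`` is the ratio of stomatal to mesophyll conductance to
    CO2.  ``photoresp_sign`` selects how the photorespiratory term enters
    the Ci inversion: ``"forward"`` (default) is algebraically consistent
    with the forward model Δ = a + (b−a)·Ci/Ca − f′·Γ*/pCa, ``"printed"``
    flips its sign (the form sometimes printed with a minus inside the
    numerator).
    """

    a: float = 4.4                 # ‰, diffusion of CO2 in air
    a_m: float = 1.8               # ‰, diffusion/dissolution across mesophyll
    b: float = 29.0                # ‰, Rubisco carboxylation (C3)
    f_prime: float = 12.0          # ‰, photorespiratory fractionation (±4)
    b3: float = 30.0               # ‰, Rubisco fractionation (C4 model)
    b4: float = -5.7               # ‰, PEP carboxylation + equilibria
    s: float = 1.8                 # ‰, bundle-sheath leakage
    phi: float = 0.21              # bundle-sheath leakiness, dimensionless
    gsc_over_gm: float = 0.79      # g_sc/g_m, dimensionless (±0.07)
    gamma_star_25: float = 42.75   # µmol mol⁻¹, CO2 compensation point @25°C
    delta_ha: float = 37830.0      # J mol⁻¹, activation energy of Γ*
    r_gas: float = 8.314           # J mol⁻¹ K⁻¹
    p0: float = 101325.0           # Pa, sea-level standard pressure
    # barometric (international standard atmosphere) coefficients
    lapse_rate: float = 0.0065     # K m⁻¹
    t_std: float = 288.15          # K, standard sea-level temperature
    baro_exponent: float = 5.2561
    photoresp_sign: str = "forward"  # "forward" | "printed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError(f"phi must lie in [0, 1], got {self.phi}")
        if self.photoresp_sign not in ("forward", "printed"):
            raise ValueError(
                "photoresp_sign must be 'forward' or 'printed', "
                f"got {self.photoresp_sign!r}"
            )

    # C4 model slope: dΔ/d(Ci/Ca) = b4 + (b3 − s)·φ − a
    @property
    def c4_slope(self) -> float:
        return self.b4 + (self.b3 - self.s) * self.phi - self.a

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "FractionationConstants":
        return cls(**dict(d))


DEFAULT_CONSTANTS = FractionationConstants()

#: Default atmospheric boundary conditions: ~2021 global means.  Isotope
#: surveys rarely report the δ13C of air or Ca they assumed, so these are
#: overridable configuration, not measurements, and every output records
#: the values used.
DEFAULT_DELTA13C_AIR = -8.5   # ‰ vs PDB
DEFAULT_CA_PPM = 415.0        # µmol mol⁻¹


@dataclass(frozen=True)
class AtmosphericState:
    """Atmospheric CO2 boundary condition at a site.

    ``patm`` and ``p_ca`` (partial pressure of CO2, = Ca·1e-6·Patm) are
    derived at construction from elevation via the barometric formula.
    """

    ca: float = DEFAULT_CA_PPM            # ppm
    delta13c_air: float = DEFAULT_DELTA13C_AIR  # ‰
    elevation: float = 0.0                # m
    temperature: float = 298.15           # K
    constants: FractionationConstants = field(default=DEFAULT_CONSTANTS)
    patm: float = field(init=False)       # Pa
    p_ca: float = field(init=False)       # Pa

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.ca <= 0:
            raise ValueError("Ca must be positive")
        from . import physio  # deferred: physio imports this module

        patm = float(physio.barometric_pressure(self.elevation, self.constants))
        object.__setattr__(self, "patm", patm)
        object.__setattr__(self, "p_ca", self.ca * 1e-6 * patm)
        if not 0 < self.patm <= self.constants.p0:
            raise ValueError("derived Patm outside (0, P0]")
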