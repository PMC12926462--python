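"""Isotope → discrimination → Ci/Cc → iWUE equation chain.

The chain runs, per sample::

    leaf δ13C ──(Δ13C)──> discrimination ──(model inversion)──> Ci or Cc
                                                       └──> iWUE = (Ca − C)/1.6

Three C3 formulations are provided — ``simple`` (diffusion + carboxylation
only), ``photoresp`` (adds the photorespiratory correction f′·Γ*/pCa, with
Γ* pressure- and temperature-corrected) and ``mesophyll`` (additionally
accounts for the drawdown between intercellular space and chloroplast via
the conductance ratio g_sc/g_m) — plus the C4 bundle-sheath model with
fixed leakiness φ.  Every inversion has an explicit forward model and the
pair round-trips to machine precision; forward models are exported so the
synthetic generator can run the chain in reverse.

Units: δ and Δ in ‰; Ca, Ci, Cc and Γ* in µmol mol⁻¹ (ppm); pressures in
Pa; iWUE in µmol CO2 mol⁻¹ H2O.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_CONSTANTS,
    AtmosphericState,
    Formulation,
    FractionationConstants,
    Pathway,
)

logger = logging.getLogger(__name__)

ArrayLike = Union[float, np.ndarray]


class InvalidInputError(ValueError):
    """An input value violates a physical precondition."""


class DegenerateConstantsError(ValueError):
    """The constant set makes a model inversion singular."""


class ConfigurationError(ValueError):
    """Incompatible configuration (e.g. pathway/formulation mismatch)."""


@dataclass(frozen=True)
class IsotopeSample:
    """One leaf isotope measurement."""

    sample_id: str
    site_id: str
    species_id: str
    pathway: Pathway
    delta13c_leaf: float          # ‰ vs PDB
    delta18o_leaf: Optional[float] = None  # ‰ vs SMOW, carried through

    def __post_init__(self) -> None:
        if not -40.0 <= self.delta13c_leaf <= -5.0:
            warnings.warn(
                f"sample {self.sample_id}: leaf δ13C {self.delta13c_leaf} ‰ "
                "outside the plausible range [-40, -5]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PhysioResult:
    """Output of the equation chain for one sample.

    ``ci`` is the intercellular CO2 mole fraction; ``cc`` (chloroplast) is
    populated only by the mesophyll formulation, where it is the operative
    concentration entering iWUE = (Ca − Cc)/1.6.  ``ci_over_ca`` and
    ``in_range`` refer to the operative concentration.
    """

    sample_id: str
    delta13c: float               # Δ13C, ‰
    ci: float                     # ppm
    cc: Optional[float]           # ppm, mesophyll formulation only
    ci_over_ca: float
    iwue: float                   # µmol CO2 mol⁻¹ H2O
    formulation: Formulation
    in_range: bool
    ca: float                     # ppm, boundary condition used
    delta13c_air: float           # ‰, boundary condition used


# --------------------------------------------------------------------------
# elementary operations


def ratio_to_delta(r_sample: ArrayLike, r_standard: ArrayLike) -> ArrayLike:
    """δ (‰) from an isotope ratio and its standard: (R/R_std − 1)·1000."""
    r_sample = np.asarray(r_sample, dtype=float)
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_sample <= 0) or np.any(r_standard <= 0):
        raise InvalidInputError("isotope ratios must be positive")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def discrimination(delta13c_air: ArrayLike, delta13c_plant: ArrayLike) -> ArrayLike:
    """Δ13C (‰) between atmospheric CO2 and plant tissue.

    Δ = (δa − δp)/(1 + δp/1000).
    """
    da = np.asarray(delta13c_air, dtype=float)
    dp = np.asarray(delta13c_plant, dtype=float)
    if np.any(dp <= -1000.0):
        raise InvalidInputError("plant δ13C must exceed -1000 ‰")
    out = (da - dp) / (1.0 + dp / 1000.0)
    return float(out) if out.ndim == 0 else out


def delta_plant_from_discrimination(
    delta13c_air: ArrayLike, delta13c4: ArrayLike
) -> ArrayLike:
    """Invert ``discrimination``: δp = (δa − Δ)/(1 + Δ/1000)."""
    da = np.asarray(delta13c_air, dtype=float)
    dd = np.asarray(delta13c4, dtype=float)
    out = (da - dd) / (1.0 + dd / 1000.0)
    return float(out) if out.ndim == 0 else out


def barometric_pressure(
    elevation: ArrayLike, constants: FractionationConstants = DEFAULT_CONSTANTS
) -> ArrayLike:
    """Atmospheric pressure (Pa) at elevation (m), standard-atmosphere form.

    P = P0·(1 − L·z/T_std)^k with L = 0.0065 K m⁻¹, T_std = 288.15 K,
    k = 5.2561; equals P0 at sea level and decreases monotonically.
    """
    z = np.asarray(elevation, dtype=float)
    if np.any(z < -500.0):
        raise InvalidInputError("elevation below -500 m is not supported")
    out = constants.p0 * (1.0 - constants.lapse_rate * z / constants.t_std) ** (
        constants.baro_exponent
    )
    return float(out) if out.ndim == 0 else out


def gamma_star(
    temperature: ArrayLike,
    patm: ArrayLike,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """CO2 compensation point Γ* (µmol mol⁻¹) at temperature (K), Patm (Pa).

    Γ* = Γ*₂₅ · (Patm/P0) · exp(ΔHa·(T − 298)/(R·T·298)); the pressure
    ratio rescales the 25 °C sea-level value, the Arrhenius factor applies
    the activation energy ΔHa.
    """
    t = np.asarray(temperature, dtype=float)
    p = np.asarray(patm, dtype=float)
    if np.any(t <= 0) or np.any(p <= 0):
        raise InvalidInputError("temperature and pressure must be positive")
    arrh = np.exp(constants.delta_ha * (t - 298.0) / (constants.r_gas * t * 298.0))
    out = constants.gamma_star_25 * (p / constants.p0) * arrh
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# C3 formulations: forward models (Δ from Ci) and their inversions


def _photoresp_term(
    gamma_star_ppm: ArrayLike, ca: ArrayLike, p_ca: ArrayLike
) -> ArrayLike:
    """Dimensionless ‰-scale photorespiratory correction f′·(pΓ*/pCa).

    Γ* (a mole fraction) is converted to a partial pressure with the same
    Patm implied by pCa and Ca, so the ratio reduces to Γ*/Ca; pCa is
    validated rather than consumed numerically.
    """
    p_ca = np.asarray(p_ca, dtype=float)
    if np.any(p_ca <= 0):
        raise InvalidInputError("pCa must be positive")
    return np.asarray(gamma_star_ppm, dtype=float) / np.asarray(ca, dtype=float)


def forward_simple_c3(
    ci: ArrayLike, ca: ArrayLike, constants: FractionationConstants = DEFAULT_CONSTANTS
) -> ArrayLike:
    """Δ = a + (b − a)·Ci/Ca."""
    ci = np.asarray(ci, dtype=float)
    out = constants.a + (constants.b - constants.a) * ci / np.asarray(ca, dtype=float)
    return float(out) if out.ndim == 0 else out


def ci_simple_c3(
    delta13c4: ArrayLike,
    ca: ArrayLike,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Ci = Ca·(Δ − a)/(b − a)."""
    if constants.b == constants.a:
        raise DegenerateConstantsError("b must differ from a")
    dd = np.asarray(delta13c4, dtype=float)
    out = np.asarray(ca, dtype=float) * (dd - constants.a) / (constants.b - constants.a)
    return float(out) if out.ndim == 0 else out


def forward_photoresp_c3(
    ci: ArrayLike,
    ca: ArrayLike,
    gamma_star_ppm: ArrayLike,
    p_ca: ArrayLike,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Δ = a + (b − a)·Ci/Ca − f′·Γ*/pCa (photorespiration lowers Δ)."""
    f = constants.f_prime * _photoresp_term(gamma_star_ppm, ca, p_ca)
    out = forward_simple_c3(ci, ca, constants) - np.asarray(f)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def ci_photoresp_c3(
    delta13c4: ArrayLike,
    ca: ArrayLike,
    gamma_star_ppm: ArrayLike,
    p_ca: ArrayLike,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Invert the photorespiration-corrected model for Ci.

    With ``photoresp_sign="forward"`` (default) the correction *adds* when
    solving for Ci, consistent with the forward model; ``"printed"``
    subtracts it instead.
    """
    if constants.b == constants.a:
        raise DegenerateConstantsError("b must differ from a")
    dd = np.asarray(delta13c4, dtype=float)
    ca_arr = np.asarray(ca, dtype=float)
    f = constants.f_prime * _photoresp_term(gamma_star_ppm, ca_arr, p_ca)
    sign = 1.0 if constants.photoresp_sign == "forward" else -1.0
    out = ca_arr * (dd - constants.a + sign * f) / (constants.b - constants.a)
    return float(out) if out.ndim == 0 else out


def forward_mesophyll_c3(
    cc: ArrayLike,
    ca: ArrayLike,
    gamma_star_ppm: ArrayLike,
    p_ca: ArrayLike,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Forward mesophyll model: Δ as a function of chloroplast CO2.

    Δ = a + (b − a)·Cc/Ca − (g_sc/g_m)(b − a_m)(1 − Cc/Ca) − f′·Γ*/pCa.
    The middle term is the drawdown between intercellular space and
    chloroplast, proportional to assimilation via Fick's law.
    """
    ca_arr = np.asarray(ca, dtype=float)
    x = np.asarray(cc, dtype=float) / ca_arr
    f = constants.f_prime * _photoresp_term(gamma_star_ppm, ca_arr, p_ca)
    m = constants.gsc_over_gm * (constants.b - constants.a_m)
    out = constants.a + (constants.b - constants.a) * x - m * (1.0 - x) - np.asarray(f)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def cc_mesophyll_c3(
    delta13c4: ArrayLike,
    ca: ArrayLike,
    gamma_star_ppm: ArrayLike,
    p_ca: ArrayLike,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Chloroplast CO2 from Δ under the mesophyll formulation.

    Cc = Ca·[1 − (b − Δ − f′·Γ*/pCa)/(b − a + (g_sc/g_m)(b − a_m))];
    collapses to ``ci_photoresp_c3`` as g_sc/g_m → 0.
    """
    denom = constants.b - constants.a + constants.gsc_over_gm * (
        constants.b - constants.a_m
    )
    if denom == 0:
        raise DegenerateConstantsError("mesophyll inversion denominator is zero")
    dd = np.asarray(delta13c4, dtype=float)
    ca_arr = np.asarray(ca, dtype=float)
    f = constants.f_prime * _photoresp_term(gamma_star_ppm, ca_arr, p_ca)
    out = ca_arr * (1.0 - (constants.b - dd - f) / denom)
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def ci_from_cc(
    cc: ArrayLike,
    ca: ArrayLike,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Intercellular CO2 implied by Cc through Ci − Cc = (g_sc/g_m)(Ca − Ci).

    Equal supply flux through stomata and mesophyll gives
    Ci = (Cc + r·Ca)/(1 + r) with r = g_sc/g_m; Cc < Ci whenever Cc < Ca.
    """
    r = constants.gsc_over_gm
    out = (np.asarray(cc, dtype=float) + r * np.asarray(ca, dtype=float)) / (1.0 + r)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# C4 model


def forward_c4(
    ci: ArrayLike, ca: ArrayLike, constants: FractionationConstants = DEFAULT_CONSTANTS
) -> ArrayLike:
    """Δ = a + (b4 + (b3 − s)·φ − a)·Ci/Ca for C4 leaves.

    At default constants the slope is negative (−4.178 ‰), so enriched
    leaves (small Δ) imply *high* Ci/Ca — the sign flip behind the
    diverging C3/C4 iWUE–elevation trends.
    """
    ci = np.asarray(ci, dtype=float)
    out = constants.a + constants.c4_slope * ci / np.asarray(ca, dtype=float)
    return float(out) if out.ndim == 0 else out


def ci_c4(
    delta13c4: ArrayLike,
    ca: ArrayLike,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
) -> tuple[ArrayLike, ArrayLike]:
    """Invert the C4 model; returns (Ci, in_range).

    ``in_range`` is False where Ci/Ca falls outside [0, 1] — the Δ lies
    outside the model's attainable band [a + slope, a].  Values are never
    clamped.
    """
    if constants.c4_slope == 0:
        raise DegenerateConstantsError("C4 slope b4 + (b3 − s)φ − a is zero")
    dd = np.asarray(delta13c4, dtype=float)
    ca_arr = np.asarray(ca, dtype=float)
    ci = ca_arr * (dd - constants.a) / constants.c4_slope
    ratio = ci / ca_arr
    in_range = (ratio >= 0.0) & (ratio <= 1.0)
    if ci.ndim == 0:
        return float(ci), bool(in_range)
    return ci, in_range


def iwue(ca: ArrayLike, ci: ArrayLike) -> ArrayLike:
    """Intrinsic water-use efficiency (Ca − Ci)/1.6, µmol CO2 mol⁻¹ H2O.

    1.6 is the ratio of the binary diffusivities of water vapour and CO2
    in air, converting stomatal conductance to water into conductance to
    CO2.
    """
    out = (np.asarray(ca, dtype=float) - np.asarray(ci, dtype=float)) / 1.6
    return float(out) if out.ndim == 0 else out


def ci_from_iwue(ca: ArrayLike, iwue_value: ArrayLike) -> ArrayLike:
    """Invert ``iwue``: Ci = Ca − 1.6·iWUE (used by the generator)."""
    out = np.asarray(ca, dtype=float) - 1.6 * np.asarray(iwue_value, dtype=float)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# composed per-sample chain


def compute_iwue(
    sample: IsotopeSample,
    atmosphere: AtmosphericState,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
    formulation: Formulation = Formulation.PHOTORESP,
) -> PhysioResult:
    """Run the full chain for one sample and return a ``PhysioResult``.

    The formulation must match the pathway: ``c4`` for C4 samples, any of
    the three C3 formulations for C3 samples.
    """
    formulation = Formulation(formulation)
    pathway = Pathway(sample.pathway)
    if (formulation == Formulation.C4) != (pathway == Pathway.C4):
        raise ConfigurationError(
            f"formulation {formulation.value!r} incompatible with pathway "
            f"{pathway.value!r}"
        )
    dd = discrimination(atmosphere.delta13c_air, sample.delta13c_leaf)
    ca = atmosphere.ca
    cc: Optional[float] = None
    if formulation == Formulation.SIMPLE:
        ci = ci_simple_c3(dd, ca, constants)
        operative = ci
    elif formulation == Formulation.PHOTORESP:
        gs = gamma_star(atmosphere.temperature, atmosphere.patm, constants)
        ci = ci_photoresp_c3(dd, ca, gs, atmosphere.p_ca, constants)
        operative = ci
    elif formulation == Formulation.MESOPHYLL:
        gs = gamma_star(atmosphere.temperature, atmosphere.patm, constants)
        cc = cc_mesophyll_c3(dd, ca, gs, atmosphere.p_ca, constants)
        ci = ci_from_cc(cc, ca, constants)
        operative = cc
    else:
        ci, _ = ci_c4(dd, ca, constants)
        operative = ci
    ratio = operative / ca
    in_range = 0.0 <= ratio <= 1.0
    if not in_range:
        logger.warning(
            "sample %s: %s/Ca = %.3f outside [0, 1] (Δ = %.3f ‰); retained unclamped",
            sample.sample_id,
            "Cc" if cc is not None else "Ci",
            ratio,
            dd,
        )
    return PhysioResult(
        sample_id=sample.sample_id,
        delta13c=float(dd),
        ci=float(ci),
        cc=None if cc is None else float(cc),
        ci_over_ca=float(ratio),
        iwue=float(iwue(ca, operative)),
        formulation=formulation,
        in_range=in_range,
        ca=ca,
        delta13c_air=atmosphere.delta13c_air,
    )


def compute_iwue_table(
    table: pd.DataFrame,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
    formulation: Formulation = Formulation.PHOTORESP,
    ca: float = None,
    delta13c_air: float = None,
    temperature_column: str = "mat_c",
    drop_out_of_range: bool = False,
) -> pd.DataFrame:
    """Vectorised chain over a tidy transect table.

    C3 rows use ``formulation`` (one of the three C3 variants); C4 rows
    always use the C4 model.  Site temperature (°C, ``temperature_column``)
    enters Γ* after conversion to kelvin; site elevation sets Patm.
    Adds columns Delta13C, Ci, Cc, ci_over_ca, iWUE, formulation,
    in_range, plus the Ca / δ13C_air actually used.  Out-of-range rows are
    warned about and retained unless ``drop_out_of_range``.
    """
    from .constants import DEFAULT_CA_PPM, DEFAULT_DELTA13C_AIR

    formulation = Formulation(formulation)
    if formulation == Formulation.C4:
        raise ConfigurationError(
            "pass a C3 formulation; C4 rows are routed to the C4 model automatically"
        )
    ca = DEFAULT_CA_PPM if ca is None else float(ca)
    delta13c_air = DEFAULT_DELTA13C_AIR if delta13c_air is None else float(delta13c_air)

    out = table.copy()
    dd = discrimination(delta13c_air, out["d13C_leaf"].to_numpy(float))
    patm = barometric_pressure(out["elevation_m"].to_numpy(float), constants)
    temp_k = out[temperature_column].to_numpy(float) + 273.15
    gs = gamma_star(temp_k, patm, constants)
    p_ca = ca * 1e-6 * patm

    is_c4 = out["pathway"].astype(str).str.upper().eq("C4").to_numpy()
    ci = np.empty(len(out))
    cc = np.full(len(out), np.nan)
    operative = np.empty(len(out))

    if (~is_c4).any():
        idx = ~is_c4
        if formulation == Formulation.SIMPLE:
            ci_c3 = np.asarray(ci_simple_c3(dd[idx], ca, constants))
        elif formulation == Formulation.PHOTORESP:
            ci_c3 = np.asarray(
                ci_photoresp_c3(dd[idx], ca, gs[idx], p_ca[idx], constants)
            )
        else:
            cc_c3 = np.asarray(
                cc_mesophyll_c3(dd[idx], ca, gs[idx], p_ca[idx], constants)
            )
            cc[idx] = cc_c3
            ci_c3 = np.asarray(ci_from_cc(cc_c3, ca, constants))
        ci[idx] = ci_c3
        operative[idx] = cc[idx] if formulation == Formulation.MESOPHYLL else ci_c3
    if is_c4.any():
        ci_4, _ = ci_c4(dd[is_c4], ca, constants)
        ci[is_c4] = np.asarray(ci_4)
        operative[is_c4] = np.asarray(ci_4)

    ratio = operative / ca
    in_range = (ratio >= 0.0) & (ratio <= 1.0)
    n_bad = int((~in_range).sum())
    if n_bad:
        logger.warning(
            "%d of %d samples have Ci/Ca outside [0, 1]; %s",
            n_bad,
            len(out),
            "dropped" if drop_out_of_range else "retained unclamped",
        )

    out["Delta13C"] = dd
    out["Ci"] = ci
    out["Cc"] = cc
    out["ci_over_ca"] = ratio
    out["iWUE"] = iwue(ca, operative)
    out["formulation"] = np.where(is_c4, Formulation.C4.value, formulation.value)
    out["in_range"] = in_range
    out["ca_used"] = ca
    out["delta13c_air_used"] = delta13c_air
    if drop_out_of_range:
        out = out.loc[in_range].reset_index(drop=True)
    return out
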