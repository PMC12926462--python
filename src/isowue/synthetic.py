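"""Seeded synthetic elevation-transect generator with known ground truth.

Emulates the statistical structure of a grassland transect spanning
40–3800 m: climate covariates co-varying with elevation (MAT, VPD
decreasing; aridity index increasing), pathway-specific iWUE–elevation
trends (rising for C3, weakly falling for C4), species-level random
intercepts, a hump-shaped leaf δ18O profile, and elevation-loaded leaf and
soil stoichiometry.  Leaf δ13C is produced by running the physiological
chain *in reverse*: a true iWUE is drawn per sample, converted to the
operative CO2 concentration, pushed through the pathway's forward
discrimination model and finally to δ13C — so at zero noise the analysis
chain recovers the truth exactly.

All randomness flows from a single integer seed through a fixed
``SeedSequence.spawn`` hierarchy (sites, species, samples, abundance), so
equal seeds give bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import physio
from .community import community_weighted_mean, site_community_metrics
from .constants import (
    DEFAULT_CA_PPM,
    DEFAULT_DELTA13C_AIR,
    Formulation,
    FractionationConstants,
    DEFAULT_CONSTANTS,
)


class TransectConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class LinearClimate:
    """Climate variable as intercept + slope·elev(km) + noise, then clipped."""

    intercept: float
    slope_per_km: float
    noise_sd: float
    lo: float
    hi: float

    def sample(self, elev_m: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        z = elev_m / 1000.0
        vals = self.intercept + self.slope_per_km * z
        if self.noise_sd > 0:
            vals = vals + rng.normal(0.0, self.noise_sd, size=len(z))
        return np.clip(vals, self.lo, self.hi)


@dataclass(frozen=True)
class TransectConfig:
    """Generator parameters; defaults emulate the study transect.

    Slopes are per 1000 m of elevation.  Climate defaults are chosen so
    the generated marginals stay inside the transect's observed ranges
    (MAT 7.6–23.6 °C, MAP 730–1760 mm, VPD 0.2–1.3 kPa, AI 0.4–1.7).
    iWUE trend defaults give the diverging pathway pattern: C3 rising
    strongly, C4 falling weakly, both with leaf δ13C increasing uphill.
    """

    n_sites: int = 98
    elevation_min: float = 40.0
    elevation_max: float = 3800.0
    n_species_c3: int = 12
    n_species_c4: int = 6
    replicates: int = 3
    min_species_per_site: int = 1
    max_species_per_site: int = 3

    # iWUE trend (µmol CO2 mol⁻¹ H2O)
    intercept_c3: float = 35.0
    true_slope_c3: float = 20.0     # per 1000 m
    intercept_c4: float = 200.0
    true_slope_c4: float = -6.0     # per 1000 m
    species_sd: float = 12.0        # random-intercept SD
    residual_sd: float = 20.0

    # probability a dominant-species slot is C4, logistic in elevation
    c4_prob_max: float = 0.75
    c4_prob_midpoint_m: float = 1500.0
    c4_prob_scale_m: float = 700.0

    mat: LinearClimate = LinearClimate(23.8, -4.25, 0.3, 7.6, 23.6)
    map: LinearClimate = LinearClimate(1770.0, -270.0, 30.0, 730.0, 1760.0)
    vpd: LinearClimate = LinearClimate(1.32, -0.29, 0.04, 0.2, 1.3)
    ai: LinearClimate = LinearClimate(0.38, 0.34, 0.05, 0.4, 1.7)

    # δ18O quadratic in elevation (m): c0 + c1·z + c2·z², peak interior
    d18o_c0: float = 22.0
    d18o_c1: float = 7.2e-3
    d18o_c2: float = -2.0e-6
    d18o_noise_sd: float = 1.5

    # leaf stoichiometry (mg g⁻¹), linear in elevation (km) + noise
    leaf_c_intercept: float = 420.0
    leaf_c_slope: float = 8.0
    leaf_c_sd: float = 15.0
    leaf_n_intercept: float = 22.0
    leaf_n_slope: float = -1.0
    leaf_n_sd: float = 2.0
    leaf_p_intercept: float = 1.8
    leaf_p_slope: float = -0.25
    leaf_p_sd: float = 0.15

    # soil, site level
    soc_intercept: float = 15.0     # g kg⁻¹
    soc_slope: float = 12.0
    soc_sd: float = 5.0
    soil_cn_intercept: float = 10.0
    soil_cn_slope: float = 0.8
    soil_cn_sd: float = 0.8

    # abundance sheet
    n_plots: int = 6
    background_richness_intercept: float = 8.0
    background_richness_slope: float = -1.2  # per km

    # atmosphere and chain
    ca: float = DEFAULT_CA_PPM
    delta13c_air: float = DEFAULT_DELTA13C_AIR
    c3_formulation: Formulation = Formulation.PHOTORESP
    out_of_range: str = "resample"  # or "flag"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 2:
            raise TransectConfigError("n_sites must be at least 2")
        if not self.elevation_min < self.elevation_max:
            raise TransectConfigError("elevation range must be non-degenerate")
        if self.out_of_range not in ("resample", "flag"):
            raise TransectConfigError("out_of_range must be 'resample' or 'flag'")

    def with_zero_noise(self) -> "TransectConfig":
        """Copy with every stochastic SD zeroed (chain-identity testing)."""
        return dataclasses.replace(
            self,
            species_sd=0.0,
            residual_sd=0.0,
            mat=dataclasses.replace(self.mat, noise_sd=0.0),
            map=dataclasses.replace(self.map, noise_sd=0.0),
            vpd=dataclasses.replace(self.vpd, noise_sd=0.0),
            ai=dataclasses.replace(self.ai, noise_sd=0.0),
            d18o_noise_sd=0.0,
            leaf_c_sd=0.0,
            leaf_n_sd=0.0,
            leaf_p_sd=0.0,
            soc_sd=0.0,
            soil_cn_sd=0.0,
        )


#: qualitative direction of association between each covariate and iWUE
#: implied by the generator's structure, per pathway (for recovery tests)
ATTRIBUTION_SIGNS = {
    "C3": {"elevation_m": 1, "mat_c": -1, "vpd_kpa": -1, "ai": 1, "map_mm": -1},
    "C4": {"elevation_m": -1, "mat_c": 1, "vpd_kpa": 1, "ai": -1, "map_mm": 1},
}


@dataclass
class GroundTruth:
    """Truth sidecar stored with every generated dataset."""

    true_slope_c3: float
    true_slope_c4: float
    intercept_c3: float
    intercept_c4: float
    species_intercepts: dict[str, float]
    attribution_signs: dict[str, dict[str, int]] = field(
        default_factory=lambda: {k: dict(v) for k, v in ATTRIBUTION_SIGNS.items()}
    )

    def to_json(self, path: Path) -> None:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_sites(config: TransectConfig, rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Site table: elevation plus climate and soil covariates.

    Elevations are uniform over the configured range; each climate
    variable is a deterministic linear function of elevation plus seeded
    noise, clipped to its observed marginal range.
    """
    if rng is None:
        rng = _rng_children(config.seed, 4)[0]
    z = np.sort(
        rng.uniform(config.elevation_min, config.elevation_max, size=config.n_sites)
    )
    z_km = z / 1000.0
    soc = config.soc_intercept + config.soc_slope * z_km
    soil_cn = config.soil_cn_intercept + config.soil_cn_slope * z_km
    if config.soc_sd > 0:
        soc = soc + rng.normal(0, config.soc_sd, len(z))
    if config.soil_cn_sd > 0:
        soil_cn = soil_cn + rng.normal(0, config.soil_cn_sd, len(z))
    soc = np.clip(soc, 1.0, None)
    soil_cn = np.clip(soil_cn, 5.0, None)
    return pd.DataFrame(
        {
            "site_id": [f"S{i:03d}" for i in range(config.n_sites)],
            "elevation_m": z,
            "mat_c": config.mat.sample(z, rng),
            "map_mm": config.map.sample(z, rng),
            "vpd_kpa": config.vpd.sample(z, rng),
            "ai": config.ai.sample(z, rng),
            "soil_soc": soc,
            "soil_stn": soc / soil_cn,
            "soil_cn": soil_cn,
        }
    )


def _species_pool(config: TransectConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"C3_sp{i:02d}" for i in range(config.n_species_c3)] + [
        f"C4_sp{i:02d}" for i in range(config.n_species_c4)
    ]
    pathways = ["C3"] * config.n_species_c3 + ["C4"] * config.n_species_c4
    intercepts = (
        rng.normal(0.0, config.species_sd, len(ids)) if config.species_sd > 0 else np.zeros(len(ids))
    )
    return pd.DataFrame(
        {"species_id": ids, "pathway": pathways, "species_effect": intercepts}
    )


def simulate_leaf_isotopes(
    sites: pd.DataFrame,
    config: TransectConfig,
    constants: FractionationConstants = DEFAULT_CONSTANTS,
    rng_species: Optional[np.random.Generator] = None,
    rng_samples: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-sample table with leaf δ13C/δ18O and stoichiometry, plus truth.

    For each sample a true iWUE is drawn (pathway trend + species
    intercept + residual), inverted to the operative CO2 concentration,
    run through the pathway's forward discrimination model at the site's
    pressure and temperature, and converted to leaf δ13C.  Residual draws
    implying a concentration outside [0, Ca] are redrawn
    (``out_of_range="resample"``, truncated residual) or kept and flagged
    (``"flag"``).
    """
    if rng_species is None or rng_samples is None:
        _, rng_sp, rng_samp, _ = _rng_children(config.seed, 4)
        rng_species = rng_species or rng_sp
        rng_samples = rng_samples or rng_samp
    rng_sp, rng_samp = rng_species, rng_samples
    species = _species_pool(config, rng_sp)
    truth = GroundTruth(
        true_slope_c3=config.true_slope_c3,
        true_slope_c4=config.true_slope_c4,
        intercept_c3=config.intercept_c3,
        intercept_c4=config.intercept_c4,
        species_intercepts=dict(
            zip(species["species_id"], species["species_effect"].astype(float))
        ),
    )

    c3_pool = species.loc[species.pathway == "C3"].reset_index(drop=True)
    c4_pool = species.loc[species.pathway == "C4"].reset_index(drop=True)
    iwue_max = config.ca / 1.6

    rows: list[dict] = []
    for site in sites.itertuples(index=False):
        z = site.elevation_m
        p_c4 = config.c4_prob_max / (
            1.0 + np.exp((z - config.c4_prob_midpoint_m) / config.c4_prob_scale_m)
        )
        n_sp = int(
            rng_samp.integers(config.min_species_per_site, config.max_species_per_site + 1)
        )
        chosen: set[str] = set()
        for _ in range(n_sp):
            pool = c4_pool if (len(c4_pool) and rng_samp.random() < p_c4) else c3_pool
            sp = pool.iloc[int(rng_samp.integers(len(pool)))]
            if sp.species_id in chosen:
                continue
            chosen.add(sp.species_id)
            z_km = z / 1000.0
            if sp.pathway == "C3":
                mean_iwue = config.intercept_c3 + config.true_slope_c3 * z_km
            else:
                mean_iwue = config.intercept_c4 + config.true_slope_c4 * z_km
            mean_iwue += sp.species_effect
            for rep in range(config.replicates):
                true_iwue = _draw_iwue(
                    mean_iwue, config.residual_sd, iwue_max, config.out_of_range, rng_samp
                )
                rows.append(
                    {
                        "site_id": site.site_id,
                        "species_id": sp.species_id,
                        "pathway": sp.pathway,
                        "replicate": rep,
                        "elevation_m": z,
                        "mat_c": site.mat_c,
                        "true_iwue": true_iwue,
                    }
                )
    samples = pd.DataFrame(rows)
    samples.insert(0, "sample_id", [f"L{i:05d}" for i in range(len(samples))])

    # reverse chain: true iWUE -> operative concentration -> Δ13C -> leaf δ13C
    ca = config.ca
    operative = physio.ci_from_iwue(ca, samples["true_iwue"].to_numpy())
    patm = np.asarray(
        physio.barometric_pressure(samples["elevation_m"].to_numpy(), constants)
    )
    gs = np.asarray(
        physio.gamma_star(samples["mat_c"].to_numpy() + 273.15, patm, constants)
    )
    p_ca = ca * 1e-6 * patm
    is_c4 = samples["pathway"].eq("C4").to_numpy()
    delta = np.empty(len(samples))
    form = Formulation(config.c3_formulation)
    if (~is_c4).any():
        i = ~is_c4
        if form == Formulation.SIMPLE:
            delta[i] = physio.forward_simple_c3(operative[i], ca, constants)
        elif form == Formulation.PHOTORESP:
            delta[i] = physio.forward_photoresp_c3(
                operative[i], ca, gs[i], p_ca[i], constants
            )
        else:
            delta[i] = physio.forward_mesophyll_c3(
                operative[i], ca, gs[i], p_ca[i], constants
            )
    if is_c4.any():
        delta[is_c4] = physio.forward_c4(operative[is_c4], ca, constants)
    samples["d13C_leaf"] = physio.delta_plant_from_discrimination(
        config.delta13c_air, delta
    )

    # phenomenological hump-shaped δ18O
    z = samples["elevation_m"].to_numpy()
    d18o = config.d18o_c0 + config.d18o_c1 * z + config.d18o_c2 * z**2
    if config.d18o_noise_sd > 0:
        d18o = d18o + rng_samp.normal(0, config.d18o_noise_sd, len(z))
    samples["d18O_leaf"] = d18o

    # leaf stoichiometry, elevation-loaded with per-sample noise
    z_km = z / 1000.0
    for col, (b0, b1, sd, lo) in {
        "leaf_c": (config.leaf_c_intercept, config.leaf_c_slope, config.leaf_c_sd, 200.0),
        "leaf_n": (config.leaf_n_intercept, config.leaf_n_slope, config.leaf_n_sd, 2.0),
        "leaf_p": (config.leaf_p_intercept, config.leaf_p_slope, config.leaf_p_sd, 0.2),
    }.items():
        vals = b0 + b1 * z_km
        if sd > 0:
            vals = vals + rng_samp.normal(0, sd, len(z_km))
        samples[col] = np.clip(vals, lo, None)
    samples["leaf_cn"] = samples["leaf_c"] / samples["leaf_n"]
    samples["leaf_np"] = samples["leaf_n"] / samples["leaf_p"]
    samples["leaf_cp"] = samples["leaf_c"] / samples["leaf_p"]
    return samples.drop(columns=["replicate"]), truth


def _draw_iwue(
    mean: float,
    sd: float,
    iwue_max: float,
    mode: str,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> float:
    if sd <= 0:
        return float(np.clip(mean, 0.0, iwue_max))
    for _ in range(max_tries):
        v = mean + rng.normal(0.0, sd)
        if 0.0 <= v <= iwue_max:
            return float(v)
        if mode == "flag":
            return float(v)
    raise TransectConfigError(
        f"could not draw an in-range iWUE around {mean:.1f} (sd {sd}); "
        "trend/noise parameters imply a physically impossible regime"
    )


def generate_abundance(
    sites: pd.DataFrame,
    samples: pd.DataFrame,
    config: TransectConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Long abundance sheet (site, plot, species, abundance).

    Dominant species (those actually sampled at the site) receive high
    cover; a Poisson number of background species — declining with
    elevation — fills out richness.  Species occur in each plot with
    probability 0.8.
    """
    if rng is None:
        rng = _rng_children(config.seed, 4)[3]
    recs = []
    dom_by_site = samples.groupby("site_id")["species_id"].unique()
    for site in sites.itertuples(index=False):
        dominants = list(dom_by_site.get(site.site_id, []))
        lam = max(
            0.5,
            config.background_richness_intercept
            + config.background_richness_slope * site.elevation_m / 1000.0,
        )
        n_bg = int(rng.poisson(lam))
        background = [f"BG_{site.site_id}_{j:02d}" for j in range(n_bg)]
        for sp, is_dom in [(s, True) for s in dominants] + [
            (s, False) for s in background
        ]:
            base = rng.gamma(2.0, 2.0) * (4.0 if is_dom else 1.0)
            for plot in range(config.n_plots):
                if rng.random() < 0.8:
                    recs.append(
                        {
                            "site_id": site.site_id,
                            "plot_id": f"{site.site_id}_P{plot}",
                            "species_id": sp,
                            "abundance": base * rng.uniform(0.5, 1.5),
                        }
                    )
    return pd.DataFrame.from_records(recs)


def assemble_dataset(
    sites: pd.DataFrame,
    samples: pd.DataFrame,
    abundance: pd.DataFrame,
) -> pd.DataFrame:
    """Tidy per-sample transect table with site covariates and community
    metrics (SR, Shannon, CWM leaf traits) merged in."""
    metrics = site_community_metrics(abundance)
    # CWM of leaf traits over dominant species, weighted by pooled abundance
    pooled = abundance.groupby(["site_id", "species_id"])["abundance"].sum()
    sp_traits = samples.groupby(["site_id", "species_id"])[
        ["leaf_c", "leaf_n", "leaf_p"]
    ].mean()
    cwm_rows = []
    for site_id, traits in sp_traits.groupby(level="site_id"):
        traits = traits.droplevel("site_id")
        weights = [pooled.get((site_id, sp), 0.0) for sp in traits.index]
        if sum(weights) <= 0:
            weights = [1.0] * len(traits)
        cwm_rows.append(
            {
                "site_id": site_id,
                "cwm_leaf_c": community_weighted_mean(traits["leaf_c"], weights),
                "cwm_leaf_n": community_weighted_mean(traits["leaf_n"], weights),
                "cwm_leaf_p": community_weighted_mean(traits["leaf_p"], weights),
            }
        )
    cwm = pd.DataFrame.from_records(cwm_rows)

    site_cols = sites.drop(columns=["mat_c"]).columns.tolist()  # keep one mat_c copy
    table = (
        samples.drop(columns=["elevation_m"])
        .merge(sites, on="site_id", how="left", validate="many_to_one")
        .merge(metrics, on="site_id", how="left", validate="many_to_one")
        .merge(cwm, on="site_id", how="left", validate="many_to_one")
    )
    if table[site_cols].isna().any().any():
        raise KeyError("site/sample key mismatch while assembling dataset")
    # one mat_c from the site table (the sample copy was a convenience)
    table = table.rename(columns={"mat_c_y": "mat_c"}).drop(columns=["mat_c_x"])
    return table


def generate_transect(
    config: TransectConfig = TransectConfig(),
    constants: FractionationConstants = DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Full generator: sites → samples → abundance → tidy table + truth."""
    rng_site, rng_sp, rng_samp, rng_ab = _rng_children(config.seed, 4)
    sites = generate_sites(config, rng_site)
    samples, truth = simulate_leaf_isotopes(
        sites, config, constants, rng_species=rng_sp, rng_samples=rng_samp
    )
    abundance = generate_abundance(sites, samples, config, rng_ab)
    table = assemble_dataset(sites, samples, abundance)
    return table, truth
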