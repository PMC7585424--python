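"""Seeded synthetic field campaigns with the lake's reported statistics.

Generates the four observation tables the pipeline consumes — water-column
profiles, sediment cores, PI incubations and floating-chamber flux series
— drawing each isotope pool from an independent normal with the reported
mean and SD, adding the stated analytical noise on top, and switching the
water column between a mixed mode (depth-constant) and a stratified mode
(distinct means above/below the halocline).  Porosity follows the fitted
log compaction law plus noise; TOC is uniform over its reported range; the
ebullitive share of methane degassing is a truncated normal on [0, 1].

All randomness flows through one ``numpy.random.default_rng(seed)``
(PCG64), so identical seeds give identical datasets on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .production import PICurveFit, pi_model
from .sediment import PorosityLaw, porosity

__all__ = [
    "GeneratorConfig",
    "FieldDataset",
    "gen_water_column",
    "gen_sediment_core",
    "gen_pi_incubation",
    "gen_chamber_series",
    "generate_campaign",
    "summarize",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Means, SDs and noise levels of every simulated pool.

    Natural variability (``*_sd``) and analytical reproducibility
    (``noise_*``) are separate draws; both default to the reported values.
    """

    seed: int = 0
    stratified: bool = False
    halocline_depth: float = 2.0  # m
    max_depth: float = 18.0  # m, water column

    delta_dic_mean: float = 12.1
    delta_dic_sd: float = 0.6
    delta_dic_above: float = 13.0  # stratified mode
    delta_dic_below: float = 11.0
    delta_poc_mean: float = -14.1
    delta_poc_sd: float = 0.8
    delta_carb_mean: float = 16.2
    delta_carb_sd: float = 1.1
    delta_org_mean: float = -14.5
    delta_org_sd: float = 0.7
    delta_ch4_pore_mean: float = -68.1
    delta_ch4_pore_sd: float = 2.4
    delta_ch4_water_mean: float = -71.0
    delta_ch4_water_sd: float = 6.0
    delta_ch4_deg_mean: float = -65.4
    delta_ch4_deg_sd: float = 0.7

    dic_above: float = 0.1  # mol L-1, above the chemocline (stratified)
    dic_below: float = 0.2
    dic_mixed: float = 0.2
    noise_dic_conc: float = 0.01  # mol L-1
    noise_dic_iso: float = 0.16  # permil
    noise_carb_iso: float = 0.2  # permil

    toc_low: float = 0.10
    toc_high: float = 0.20
    porosity_noise: float = 0.01
    porosity_law: PorosityLaw = field(default_factory=PorosityLaw)

    chamber_co2_mean: float = 123.0  # mmolC m-2 d-1
    chamber_co2_sd: float = 30.0
    chamber_ch4_mean: float = 77.0
    chamber_ch4_sd: float = 20.0
    ebullitive_mean: float = 0.18
    ebullitive_sd: float = 0.15

    pi_noise_frac: float = 0.05  # incubation noise as a fraction of Pmax

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name.endswith("_sd") and value < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class FieldDataset:
    water_profile: pd.DataFrame
    sediment_cores: pd.DataFrame
    pi_incubations: pd.DataFrame
    chamber_series: pd.DataFrame


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float, n: int):
    """Normal draws rejected outside [0, 1] (fractions of a whole)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=2 * (n - filled))
        good = draw[(draw >= 0.0) & (draw <= 1.0)]
        take = min(len(good), n - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def gen_water_column(
    config: GeneratorConfig, n: int = 40, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Water-column profile: DIC concentration and the dissolved isotope pools."""
    rng = config.rng() if rng is None else rng
    depth = np.linspace(0.0, config.max_depth, n)
    if config.stratified:
        above = depth < config.halocline_depth
        dic_mean = np.where(above, config.dic_above, config.dic_below)
        d13c_mean = np.where(above, config.delta_dic_above, config.delta_dic_below)
    else:
        dic_mean = np.full(n, config.dic_mixed)
        d13c_mean = np.full(n, config.delta_dic_mean)
    dic = np.clip(dic_mean + rng.normal(0, config.noise_dic_conc, n), 0, None)
    d13c_dic = (
        d13c_mean
        + rng.normal(0, config.delta_dic_sd, n)
        + rng.normal(0, config.noise_dic_iso, n)
    )
    d13c_poc = config.delta_poc_mean + rng.normal(0, config.delta_poc_sd, n)
    d13c_ch4 = config.delta_ch4_water_mean + rng.normal(0, config.delta_ch4_water_sd, n)
    return pd.DataFrame(
        {
            "depth_m": depth,
            "dic_mol_l": dic,
            "delta13c_dic": d13c_dic,
            "delta13c_poc": d13c_poc,
            "delta13c_ch4": d13c_ch4,
        }
    )


def gen_sediment_core(
    config: GeneratorConfig,
    depth_max: float = 0.6,
    n: int = 15,
    core_id: str = "C1",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """One sediment core on an even depth grid below the surface."""
    if depth_max <= 0:
        raise ValueError("depth_max must be > 0")
    rng = config.rng() if rng is None else rng
    law = config.porosity_law
    depth = np.linspace(depth_max / n, depth_max, n)
    phi = porosity(depth, law) + rng.normal(0, config.porosity_noise, n)
    phi = np.clip(phi, 1e-3, law.phi_surface_cap)
    toc = rng.uniform(config.toc_low, config.toc_high, n)
    d13c_org = config.delta_org_mean + rng.normal(0, config.delta_org_sd, n)
    d13c_carb = (
        config.delta_carb_mean
        + rng.normal(0, config.delta_carb_sd, n)
        + rng.normal(0, config.noise_carb_iso, n)
    )
    d13c_ch4_pore = config.delta_ch4_pore_mean + rng.normal(
        0, config.delta_ch4_pore_sd, n
    )
    return pd.DataFrame(
        {
            "core_id": core_id,
            "depth_m": depth,
            "porosity": phi,
            "toc_frac": toc,
            "carb_c_frac": toc * (1.9 / 5.5),  # carbonate C tracks organic C
            "delta13c_org": d13c_org,
            "delta13c_carb": d13c_carb,
            "delta13c_ch4_pore": d13c_ch4_pore,
        }
    )


def gen_pi_incubation(
    config: GeneratorConfig,
    true_fit: PICurveFit,
    light_levels=None,
    n_dark: int = 3,
    depth_m: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Bottle incubations along a light gradient, plus dark triplicates.

    Net rates are P(I) - resp_dark + noise; dark bottles read -resp_dark.
    """
    rng = config.rng() if rng is None else rng
    if light_levels is None:
        light_levels = np.linspace(25.0, 1500.0, 12)
    light_levels = np.asarray(light_levels, dtype=float)
    if np.any(light_levels < 0) or np.any(light_levels > 1500):
        raise ValueError("light levels must lie in [0, 1500] umol photons m-2 s-1")
    I = np.concatenate([np.zeros(n_dark), light_levels])
    noise_sd = config.pi_noise_frac * true_fit.pmax
    net = pi_model(I, true_fit) - true_fit.resp_dark + rng.normal(0, noise_sd, len(I))
    return pd.DataFrame(
        {
            "sample_id": [f"inc{i:02d}" for i in range(len(I))],
            "depth_m": depth_m,
            "par_umol_m2_s": I,
            "net_o2_rate": net,
            "dark_resp_rate": true_fit.resp_dark,
        }
    )


def gen_chamber_series(
    config: GeneratorConfig, n: int = 30, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Floating-chamber CO2/CH4 degassing fluxes and the ebullitive share."""
    rng = config.rng() if rng is None else rng
    co2 = np.clip(rng.normal(config.chamber_co2_mean, config.chamber_co2_sd, n), 0, None)
    ch4 = np.clip(rng.normal(config.chamber_ch4_mean, config.chamber_ch4_sd, n), 0, None)
    ebu = _truncnorm01(rng, config.ebullitive_mean, config.ebullitive_sd, n)
    d13c = config.delta_ch4_deg_mean + rng.normal(0, config.delta_ch4_deg_sd, n)
    return pd.DataFrame(
        {
            "deployment": np.arange(n),
            "co2_flux_mmolC_m2_d": co2,
            "ch4_flux_mmolC_m2_d": ch4,
            "ebullitive_frac": ebu,
            "delta13c_ch4_deg": d13c,
        }
    )


def generate_campaign(
    config: GeneratorConfig,
    true_fit: PICurveFit | None = None,
    n_water: int = 40,
    n_cores: int = 4,
    n_chambers: int = 30,
) -> FieldDataset:
    """A full campaign: one shared RNG stream in a fixed draw order."""
    rng = config.rng()
    if true_fit is None:
        from .production import exponential_fit

        # chosen so the default campaign integrates to the study's rates:
        # annual GPP ~ 404 and oxic-layer respiration ~ 214 mmolC m-2 d-1
        true_fit = exponential_fit(ps=95.0, alpha=0.31, beta=0.017, resp_dark=5.94)
    water = gen_water_column(config, n=n_water, rng=rng)
    cores = pd.concat(
        [
            gen_sediment_core(config, core_id=f"C{i + 1}", rng=rng)
            for i in range(n_cores)
        ],
        ignore_index=True,
    )
    incubations = gen_pi_incubation(config, true_fit, rng=rng)
    chambers = gen_chamber_series(config, n=n_chambers, rng=rng)
    return FieldDataset(
        water_profile=water,
        sediment_cores=cores,
        pi_incubations=incubations,
        chamber_series=chambers,
    )


def summarize(dataset: FieldDataset, stratified: bool = False,
              halocline_depth: float = 2.0) -> pd.DataFrame:
    """Mean +- SD per carbon pool, mirroring the campaign's summary figure."""
    rows = []

    def add(pool: str, layer: str, values) -> None:
        values = np.asarray(values, dtype=float)
        values = values[np.isfinite(values)]
        if len(values) == 0:
            import warnings

            warnings.warn(f"empty group {pool}/{layer}; omitted")
            return
        rows.append(
            {
                "pool": pool,
                "layer": layer,
                "mean": float(values.mean()),
                "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
                "n": len(values),
            }
        )

    water = dataset.water_profile
    if stratified:
        above = water["depth_m"] < halocline_depth
        add("delta13c_dic", "above_halocline", water.loc[above, "delta13c_dic"])
        add("delta13c_dic", "below_halocline", water.loc[~above, "delta13c_dic"])
        add("dic_mol_l", "above_halocline", water.loc[above, "dic_mol_l"])
        add("dic_mol_l", "below_halocline", water.loc[~above, "dic_mol_l"])
    else:
        add("delta13c_dic", "water_column", water["delta13c_dic"])
        add("dic_mol_l", "water_column", water["dic_mol_l"])
    add("delta13c_poc", "water_column", water["delta13c_poc"])
    add("delta13c_ch4_water", "water_column", water["delta13c_ch4"])
    cores = dataset.sediment_cores
    add("delta13c_carb", "sediment", cores["delta13c_carb"])
    add("delta13c_org", "sediment", cores["delta13c_org"])
    if "delta13c_ch4_pore" in cores:
        add("delta13c_ch4_pore", "sediment", cores["delta13c_ch4_pore"])
    add("toc_frac", "sediment", cores["toc_frac"])
    chambers = dataset.chamber_series
    add("co2_flux", "atmosphere", chambers["co2_flux_mmolC_m2_d"])
    add("ch4_flux", "atmosphere", chambers["ch4_flux_mmolC_m2_d"])
    add("ebullitive_frac", "atmosphere", chambers["ebullitive_frac"])
    return pd.DataFrame(rows)
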