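"""Methanogenesis flux partitioning and the derived isotope constraints.

Methanogenic degradation of sedimentary organic carbon (SOC) produces CO2
and CH4 in a fixed molar ratio r = CO2:CH4.  Of the CH4 produced, a
fraction escapes to the atmosphere (diffusive + ebullitive degassing) and
the remainder is oxidized back to DIC in the water column:

    f_meth     = f_co2_meth + f_ch4_meth          (production split)
    f_ch4_meth = f_oxy + f_ch4_deg                (fate of the CH4)

The companion isotope balances give the d13C of methanogenic CO2 from the
SOC and porewater-CH4 signatures,

    (1 + r) * d13C_SOC = r * d13C_CO2-meth + d13C_CH4-meth,

and the d13C of the oxidized CH4 from the produced and escaping CH4,

    f_ch4_meth * d13C_CH4-meth = f_ch4_deg * d13C_CH4-deg + f_oxy * d13C_oxy.

Enrichment factors are differences between these pools; with r = 1 the CO2
and CH4 enrichments relative to SOC are equal by symmetry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "MethanePartition",
    "MethaneIsotopes",
    "partition_fluxes",
    "partition_from_production",
    "delta_methanogenic_co2",
    "delta_oxidized_ch4",
    "enrichment_factors",
]


@dataclass(frozen=True)
class MethanePartition:
    """Carbon fluxes through the methanogenesis pathway (mmolC m-2 d-1)."""

    f_meth: float
    f_co2_meth: float
    f_ch4_meth: float
    f_ch4_deg: float
    f_oxy: float
    ratio_co2_ch4: float
    escape_frac: float

    def __post_init__(self) -> None:
        for name in ("f_meth", "f_co2_meth", "f_ch4_meth", "f_ch4_deg", "f_oxy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not math.isclose(
            self.f_meth, self.f_co2_meth + self.f_ch4_meth, rel_tol=1e-12, abs_tol=1e-12
        ):
            raise ValueError("f_meth must equal f_co2_meth + f_ch4_meth")
        if not math.isclose(
            self.f_ch4_meth, self.f_oxy + self.f_ch4_deg, rel_tol=1e-12, abs_tol=1e-12
        ):
            raise ValueError("f_ch4_meth must equal f_oxy + f_ch4_deg")


@dataclass(frozen=True)
class MethaneIsotopes:
    """d13C signatures (permil VPDB) and enrichment factors (permil) of the
    methanogenesis-related pools."""

    delta_soc: float
    delta_ch4_meth: float
    delta_ch4_deg: float
    delta_co2_meth: float
    delta_oxy: float
    eps_co2_meth: float
    eps_ch4_meth: float
    eps_oxy: float


def partition_fluxes(
    f_ch4_deg: float, escape_frac: float, ratio: float = 1.0
) -> MethanePartition:
    """Back out the methanogenesis fluxes from the measured CH4 degassing.

    ``escape_frac`` is the fraction of *produced* CH4 that reaches the
    atmosphere (e.g. 0.64 means 36% of the CH4 is oxidized); ``ratio`` is
    the CO2:CH4 production ratio r of the methanogenic pathway.
    """
    if f_ch4_deg < 0:
        raise ValueError("f_ch4_deg must be >= 0")
    if ratio <= 0:
        raise ValueError("CO2:CH4 production ratio must be > 0")
    if not 0.0 < escape_frac <= 1.0:
        if escape_frac == 0.0 and f_ch4_deg > 0.0:
            raise ValueError(
                "escape_frac = 0 is infeasible with a nonzero degassing flux"
            )
        raise ValueError("escape_frac must lie in (0, 1]")
    f_ch4_meth = f_ch4_deg / escape_frac
    f_oxy = f_ch4_meth - f_ch4_deg
    f_co2_meth = ratio * f_ch4_meth
    return MethanePartition(
        f_meth=f_co2_meth + f_ch4_meth,
        f_co2_meth=f_co2_meth,
        f_ch4_meth=f_ch4_meth,
        f_ch4_deg=f_ch4_deg,
        f_oxy=f_oxy,
        ratio_co2_ch4=ratio,
        escape_frac=escape_frac,
    )


def partition_from_production(
    f_meth: float, escape_frac: float, ratio: float = 1.0
) -> MethanePartition:
    """Partition a known total methanogenesis flux (scenario direction).

    Unlike :func:`partition_fluxes`, escape_frac = 0 is allowed here: all
    produced CH4 is then oxidized and nothing degasses.
    """
    if f_meth < 0:
        raise ValueError("f_meth must be >= 0")
    if ratio <= 0:
        raise ValueError("CO2:CH4 production ratio must be > 0")
    if not 0.0 <= escape_frac <= 1.0:
        raise ValueError("escape_frac must lie in [0, 1]")
    f_ch4_meth = f_meth / (1.0 + ratio)
    f_co2_meth = f_meth - f_ch4_meth
    f_ch4_deg = escape_frac * f_ch4_meth
    return MethanePartition(
        f_meth=f_meth,
        f_co2_meth=f_co2_meth,
        f_ch4_meth=f_ch4_meth,
        f_ch4_deg=f_ch4_deg,
        f_oxy=f_ch4_meth - f_ch4_deg,
        ratio_co2_ch4=ratio,
        escape_frac=escape_frac,
    )


def delta_methanogenic_co2(
    delta_soc: float, delta_ch4_meth: float, ratio: float = 1.0
) -> float:
    """d13C of methanogenic CO2 from the pathway isotope balance.

    Solves (1 + r) * d13C_SOC = r * d13C_CO2 + d13C_CH4 for d13C_CO2.
    """
    if ratio <= 0:
        raise ValueError("CO2:CH4 production ratio must be > 0")
    return ((1.0 + ratio) * delta_soc - delta_ch4_meth) / ratio


def delta_oxidized_ch4(
    partition: MethanePartition, delta_ch4_meth: float, delta_ch4_deg: float
) -> float:
    """d13C of the CH4 routed to oxidation, from the CH4 fate balance."""
    if partition.f_oxy <= 0:
        raise ZeroDivisionError(
            "f_oxy = 0 (100% escape): the oxidized-CH4 d13C is undefined and the "
            "oxidation term must be dropped from the box model"
        )
    return (
        partition.f_ch4_meth * delta_ch4_meth
        - partition.f_ch4_deg * delta_ch4_deg
    ) / partition.f_oxy


def enrichment_factors(iso: MethaneIsotopes) -> tuple[float, float, float]:
    """(eps_co2_meth, eps_ch4_meth, eps_oxy) as pool differences."""
    return (
        iso.delta_co2_meth - iso.delta_soc,
        iso.delta_soc - iso.delta_ch4_meth,
        iso.delta_ch4_meth - iso.delta_oxy,
    )


def isotopes_from_observations(
    partition: MethanePartition,
    delta_soc: float,
    delta_ch4_meth: float,
    delta_ch4_deg: float,
) -> MethaneIsotopes:
    """Derive all pathway d13C values and enrichment factors at once.

    With full escape (f_oxy = 0) the oxidized pool carries no carbon; its
    d13C is reported as the produced-CH4 value so that eps_oxy = 0 and the
    (vanishing) oxidation term stays well defined downstream.
    """
    delta_co2 = delta_methanogenic_co2(
        delta_soc, delta_ch4_meth, partition.ratio_co2_ch4
    )
    if partition.f_oxy > 0:
        delta_oxy = delta_oxidized_ch4(partition, delta_ch4_meth, delta_ch4_deg)
    else:
        delta_oxy = delta_ch4_meth
    return MethaneIsotopes(
        delta_soc=delta_soc,
        delta_ch4_meth=delta_ch4_meth,
        delta_ch4_deg=delta_ch4_deg,
        delta_co2_meth=delta_co2,
        delta_oxy=delta_oxy,
        eps_co2_meth=delta_co2 - delta_soc,
        eps_ch4_meth=delta_soc - delta_ch4_meth,
        eps_oxy=delta_ch4_meth - delta_oxy,
    )
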