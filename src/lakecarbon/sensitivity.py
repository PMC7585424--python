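"""Scenario sweeps: how the steady-state d13C_DIC responds to the fluxes.

The baseline network is rebuilt at full precision from the measured
anchors (GPP 404, respiration 214, CO2 degassing 123, carbonate burial
1.9, CH4 degassing 77 mmolC m-2 d-1; 64% CH4 escape; CO2:CH4 = 1:1;
measured d13C_DIC +12.1 permil), with the combined detrital + magmatic
input solved from the mass and isotope balances and split between its two
end-members (-26.7 and -2.7 permil).

Scenarios then vary, one at a time or jointly:

* the remineralization partition x = f_meth / (f_resp + f_meth), with the
  total remineralized carbon held at its baseline sum;
* the fraction of produced CH4 escaping to the atmosphere (0 to 0.85);
* the CO2:CH4 production ratio (1:1 baseline, 1.2:1, 1:1.2);
* photosynthesis scaled by +-20%;
* the organic-burial share of GPP (1.4% baseline vs 7%), reallocated
  against remineralization;
* the detrital/magmatic contribution split (solved baseline vs 68%/32%).

Within a scenario, only the combined detrital + magmatic input is adjusted
(at its fixed split) to keep the network mass balanced; photosynthesis,
degassing and carbonate outputs stay put.  Grid points that would need a
negative detrital + magmatic flux are flagged infeasible, not raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .boxmodel import BoxModelSpec, FluxTerm, forward_delta_dic, solve_unconstrained, split_two_endmembers
from .methane import (
    MethanePartition,
    isotopes_from_observations,
    partition_fluxes,
    partition_from_production,
)

__all__ = [
    "BaselineAnchors",
    "Scenario",
    "SweepResult",
    "baseline_network",
    "build_network",
    "sweep_remineralization",
    "sweep_escape",
    "scenario_suite",
]


@dataclass(frozen=True)
class BaselineAnchors:
    """Measured anchors and assumptions defining the baseline network."""

    f_ph: float = 404.0
    f_resp: float = 214.0
    f_deg: float = 123.0
    f_carb: float = 1.9
    f_ch4_deg: float = 77.0
    escape_frac: float = 0.64
    ratio_co2_ch4: float = 1.0
    eps_ph: float = 26.2
    eps_resp: float = 0.0
    eps_deg: float = 6.2
    eps_carb: float = 4.1
    delta_det: float = -26.7
    delta_mag: float = -2.7
    delta_soc: float = -14.5
    delta_ch4_meth: float = -68.1
    delta_ch4_deg: float = -65.4
    measured_delta_dic: float = 12.1
    burial_org: float = 5.5  # mmolC m-2 d-1, organic burial at baseline


@dataclass(frozen=True)
class Baseline:
    """The solved baseline: network, methane partition and derived splits."""

    anchors: BaselineAnchors
    spec: BoxModelSpec
    partition: MethanePartition
    f_nc: float
    delta_nc: float
    f_det: float
    f_mag: float
    remin_total: float
    remin_meth_frac: float

    @property
    def det_share(self) -> float:
        return self.f_det / self.f_nc


@dataclass(frozen=True)
class Scenario:
    """One point (or curve template) of the sensitivity design."""

    name: str = "baseline"
    remin_meth_frac: float | None = None  # None -> baseline partition
    escape_frac: float = 0.64
    ratio_co2_ch4: float = 1.0
    ph_scale: float = 1.0
    burial_frac_gpp: float | None = None  # None -> baseline 5.5/404
    det_mag_split: tuple[float, float] | None = None  # None -> solved baseline

    def __post_init__(self) -> None:
        if not 0.0 <= self.escape_frac <= 1.0:
            raise ValueError("escape_frac must lie in [0, 1]")
        if self.remin_meth_frac is not None and not 0.0 <= self.remin_meth_frac <= 1.0:
            raise ValueError("remin_meth_frac must lie in [0, 1]")
        if self.ph_scale <= 0 or self.ratio_co2_ch4 <= 0:
            raise ValueError("multipliers must be > 0")
        if self.det_mag_split is not None:
            a, b = self.det_mag_split
            if a < 0 or b < 0 or abs(a + b - 1.0) > 1e-9:
                raise ValueError("det_mag_split must be nonnegative and sum to 1")


@dataclass(frozen=True)
class SweepResult:
    """A labelled grid of scenarios with the modelled d13C_DIC at each."""

    table: pd.DataFrame  # columns: scenario, x, escape_frac, ratio, ph_scale,
    #                                delta_dic_permil, feasible


def baseline_network(anchors: BaselineAnchors = BaselineAnchors()) -> Baseline:
    """Rebuild the reference network from the measured anchors.

    The methane chain runs at full precision (f_CH4-meth = 77/0.64 =
    120.3125 etc.), after which the combined detrital + magmatic input is
    solved at the measured d13C_DIC and split between its end-members.
    """
    part = partition_fluxes(anchors.f_ch4_deg, anchors.escape_frac, anchors.ratio_co2_ch4)
    iso = isotopes_from_observations(
        part, anchors.delta_soc, anchors.delta_ch4_meth, anchors.delta_ch4_deg
    )
    terms = [
        FluxTerm("respiration", "input", anchors.f_resp,
                 epsilon=-anchors.eps_ph + anchors.eps_resp),
        FluxTerm("co2_methanogenic", "input", part.f_co2_meth,
                 epsilon=-anchors.eps_ph + iso.eps_co2_meth, constrained="derived"),
        FluxTerm("ch4_oxidation", "input", part.f_oxy,
                 epsilon=-anchors.eps_ph - iso.eps_ch4_meth - iso.eps_oxy,
                 constrained="derived"),
        FluxTerm("detrital", "input", 0.0, delta=anchors.delta_det,
                 constrained="free"),
        FluxTerm("magmatic", "input", 0.0, delta=anchors.delta_mag,
                 constrained="free"),
        FluxTerm("photosynthesis", "output", anchors.f_ph, epsilon=-anchors.eps_ph),
        FluxTerm("co2_degassing", "output", anchors.f_deg, epsilon=-anchors.eps_deg),
        # carbonate precipitates isotopically heavier than the DIC pool
        FluxTerm("carbonate", "output", anchors.f_carb, epsilon=+anchors.eps_carb),
    ]
    open_spec = BoxModelSpec(
        terms=tuple(terms),
        eps_ph=anchors.eps_ph,
        eps_ch4_meth=iso.eps_ch4_meth,
        measured_delta_dic=anchors.measured_delta_dic,
    )
    f_nc, delta_nc = solve_unconstrained(open_spec, anchors.measured_delta_dic)
    f_det, f_mag = split_two_endmembers(
        f_nc, delta_nc, anchors.delta_det, anchors.delta_mag
    )
    spec = BoxModelSpec(
        terms=tuple(
            replace(t, flux=f_det if t.name == "detrital" else f_mag,
                    constrained="derived")
            if t.name in ("detrital", "magmatic")
            else t
            for t in terms
        ),
        eps_ph=anchors.eps_ph,
        eps_ch4_meth=iso.eps_ch4_meth,
        measured_delta_dic=anchors.measured_delta_dic,
    )
    remin_total = anchors.f_resp + part.f_meth
    return Baseline(
        anchors=anchors,
        spec=spec,
        partition=part,
        f_nc=f_nc,
        delta_nc=delta_nc,
        f_det=f_det,
        f_mag=f_mag,
        remin_total=remin_total,
        remin_meth_frac=part.f_meth / remin_total,
    )


def build_network(
    scenario: Scenario, baseline: Baseline
) -> tuple[BoxModelSpec | None, bool]:
    """Realize one scenario as a balanced flux network.

    Returns (spec, feasible).  The total remineralization flux is held at
    its baseline sum (adjusted by any burial reallocation) and split
    (1 - x) : x between respiration and methanogenesis; the methanogenesis
    products follow the partition chain; the detrital + magmatic input
    rebalances the network at its fixed split.  A scenario needing a
    negative rebalancing flux is infeasible (returns (None, False)).
    """
    anc = baseline.anchors
    if (
        scenario.remin_meth_frac is None
        and scenario.burial_frac_gpp is None
        and scenario.det_mag_split is None
        and scenario.escape_frac == anc.escape_frac
        and scenario.ratio_co2_ch4 == anc.ratio_co2_ch4
        and scenario.ph_scale == 1.0
    ):
        return baseline.spec, True  # identity scenario IS the baseline
    x = (
        baseline.remin_meth_frac
        if scenario.remin_meth_frac is None
        else scenario.remin_meth_frac
    )
    # the remineralized pool tracks the production it degrades, so the
    # photosynthesis multiplier scales both; burial in excess of the
    # baseline share is reallocated out of remineralization
    b_base = anc.burial_org / anc.f_ph
    b = b_base if scenario.burial_frac_gpp is None else scenario.burial_frac_gpp
    remin_total = scenario.ph_scale * (
        baseline.remin_total - (b - b_base) * anc.f_ph
    )
    if remin_total < 0:
        return None, False
    f_resp = (1.0 - x) * remin_total
    f_meth = x * remin_total
    part = partition_from_production(
        f_meth, scenario.escape_frac, scenario.ratio_co2_ch4
    )
    iso = isotopes_from_observations(
        part, anc.delta_soc, anc.delta_ch4_meth, anc.delta_ch4_deg
    )
    f_ph = anc.f_ph * scenario.ph_scale
    terms = [
        FluxTerm("respiration", "input", f_resp, epsilon=-anc.eps_ph + anc.eps_resp),
        FluxTerm("photosynthesis", "output", f_ph, epsilon=-anc.eps_ph),
        FluxTerm("co2_degassing", "output", anc.f_deg, epsilon=-anc.eps_deg),
        FluxTerm("carbonate", "output", anc.f_carb, epsilon=+anc.eps_carb),
    ]
    if part.f_co2_meth > 0:
        terms.append(
            FluxTerm("co2_methanogenic", "input", part.f_co2_meth,
                     epsilon=-anc.eps_ph + iso.eps_co2_meth, constrained="derived")
        )
    if part.f_oxy > 0:  # 100% escape: the oxidation term is dropped entirely
        terms.append(
            FluxTerm("ch4_oxidation", "input", part.f_oxy,
                     epsilon=-anc.eps_ph - iso.eps_ch4_meth - iso.eps_oxy,
                     constrained="derived")
        )
    f_in = sum(t.flux for t in terms if t.direction == "input")
    f_out = sum(t.flux for t in terms if t.direction == "output")
    f_nc = f_out - f_in
    if f_nc < -1e-9 * max(f_out, 1.0):
        return None, False
    f_nc = max(f_nc, 0.0)
    if scenario.det_mag_split is None:
        p_det = baseline.det_share
    else:
        p_det = scenario.det_mag_split[0]
    terms.append(
        FluxTerm("detrital", "input", p_det * f_nc, delta=anc.delta_det,
                 constrained="derived")
    )
    terms.append(
        FluxTerm("magmatic", "input", (1.0 - p_det) * f_nc, delta=anc.delta_mag,
                 constrained="derived")
    )
    spec = BoxModelSpec(
        terms=tuple(terms),
        eps_ph=anc.eps_ph,
        eps_ch4_meth=iso.eps_ch4_meth,
        measured_delta_dic=anc.measured_delta_dic,
    )
    return spec, True


def _evaluate(scenario: Scenario, baseline: Baseline) -> dict:
    spec, feasible = build_network(scenario, baseline)
    delta = np.nan
    if feasible:
        try:
            delta = forward_delta_dic(spec)
        except ValueError:
            feasible = False
    return {
        "scenario": scenario.name,
        "x": (
            baseline.remin_meth_frac
            if scenario.remin_meth_frac is None
            else scenario.remin_meth_frac
        ),
        "escape_frac": scenario.escape_frac,
        "ratio": scenario.ratio_co2_ch4,
        "ph_scale": scenario.ph_scale,
        "delta_dic_permil": delta,
        "feasible": feasible,
    }


def sweep_remineralization(
    x_grid: Iterable[float], template: Scenario, baseline: Baseline | None = None
) -> SweepResult:
    """d13C_DIC along the respiration/methanogenesis partition axis."""
    base = baseline or baseline_network()
    rows = [
        _evaluate(replace(template, remin_meth_frac=float(x)), base) for x in x_grid
    ]
    return SweepResult(table=pd.DataFrame(rows))


def sweep_escape(
    escape_grid: Iterable[float], template: Scenario, baseline: Baseline | None = None
) -> SweepResult:
    """d13C_DIC along the methane escape-fraction axis (0 to 0.85)."""
    base = baseline or baseline_network()
    grid = [float(e) for e in escape_grid]
    if any(e < 0 or e > 0.85 for e in grid):
        raise ValueError("escape grid must lie within [0, 0.85]")
    rows = [_evaluate(replace(template, escape_frac=e), base) for e in grid]
    return SweepResult(table=pd.DataFrame(rows))


def scenario_suite(
    baseline: Baseline | None = None, x_grid: Sequence[float] | None = None
) -> SweepResult:
    """The six reference curve families as one labelled sweep table.

    Curves: baseline (64% escape); escape-fraction variants (0, 30%, 85%);
    photosynthesis +-20%; organic burial at 7% of GPP; the 68%/32%
    detrital/magmatic split; and the CO2:CH4 ratio variants 1.2:1 and
    1:1.2 — each swept along the remineralization partition x.
    """
    base = baseline or baseline_network()
    if x_grid is None:
        x_grid = np.linspace(0.0, 1.0, 41)
    scenarios = [
        Scenario(name="baseline"),
        Scenario(name="escape_0", escape_frac=0.0),
        Scenario(name="escape_30", escape_frac=0.30),
        Scenario(name="escape_85", escape_frac=0.85),
        Scenario(name="photosynthesis_-20", ph_scale=0.8),
        Scenario(name="photosynthesis_+20", ph_scale=1.2),
        Scenario(name="burial_7pct", burial_frac_gpp=0.07),
        Scenario(name="detmag_68_32", det_mag_split=(0.68, 0.32)),
        Scenario(name="ratio_1.2_1", ratio_co2_ch4=1.2),
        Scenario(name="ratio_1_1.2", ratio_co2_ch4=1.0 / 1.2),
    ]
    tables = [sweep_remineralization(x_grid, s, base).table for s in scenarios]
    return SweepResult(table=pd.concat(tables, ignore_index=True))
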