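"""Steady-state carbon-isotope box model of a lake DIC pool.

The dissolved inorganic carbon (DIC) pool exchanges carbon with a set of
input and output fluxes (respiration, methanogenic CO2, methane oxidation,
detrital and magmatic inputs; photosynthesis, CO2 degassing, carbonate
precipitation).  At steady state both total carbon and 13C are conserved:

    sum(f_in) = sum(f_out)
    sum(f_in * d13C_in) = sum(f_out * d13C_out)

Each term's isotopic composition is either an absolute d13C (permil, VPDB)
or is tied to the DIC pool through a net enrichment offset ``epsilon`` so
that d13C_term = d13C_DIC + epsilon.  With that convention the isotope
balance is linear in d13C_DIC and admits a closed-form solution, which is
what :func:`forward_delta_dic` evaluates.  The inverse problem — solving
for the one unconstrained input flux and its isotopic signature given a
measured d13C_DIC — is handled by :func:`solve_unconstrained`, and a
combined flux can be apportioned between two end-members with
:func:`split_two_endmembers`.

Units: fluxes in mmolC m-2 d-1, isotopic values in permil (VPDB).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import pandas as pd
import yaml

__all__ = [
    "FluxTerm",
    "BoxModelSpec",
    "BalanceSolution",
    "BalanceError",
    "DegenerateNetworkError",
    "InfeasibleNetworkError",
    "NegativeFluxError",
    "forward_delta_dic",
    "solve_unconstrained",
    "split_two_endmembers",
    "balance_residuals",
    "load_network",
    "network_to_frame",
    "solution_to_frame",
]

REL_TOL = 1e-9

Direction = Literal["input", "output"]
Constraint = Literal["measured", "derived", "free"]


class BalanceError(ValueError):
    """The flux network is not mass-balanced where it needs to be."""


class DegenerateNetworkError(ValueError):
    """The isotope balance carries no information on d13C_DIC."""


class InfeasibleNetworkError(ValueError):
    """Closing the balance would require a negative flux."""


class NegativeFluxError(ValueError):
    """A solved flux came out negative; the mixing problem is infeasible."""


@dataclass(frozen=True)
class FluxTerm:
    """One carbon flux into or out of the DIC pool.

    Exactly one of ``epsilon`` (net offset relative to d13C_DIC, permil) and
    ``delta`` (absolute d13C, permil VPDB) must be given.  Free terms carry a
    placeholder flux of 0 until solved.
    """

    name: str
    direction: Direction
    flux: float
    epsilon: float | None = None
    delta: float | None = None
    constrained: Constraint = "measured"

    def __post_init__(self) -> None:
        if self.direction not in ("input", "output"):
            raise ValueError(f"term {self.name!r}: bad direction {self.direction!r}")
        if self.constrained not in ("measured", "derived", "free"):
            raise ValueError(f"term {self.name!r}: bad constraint {self.constrained!r}")
        if (self.epsilon is None) == (self.delta is None):
            raise ValueError(
                f"term {self.name!r}: exactly one of epsilon/delta must be set"
            )
        if not math.isfinite(self.flux) or self.flux < 0.0:
            raise NegativeFluxError(
                f"term {self.name!r}: flux must be finite and >= 0, got {self.flux}"
            )

    def delta_at(self, delta_dic: float) -> float:
        """d13C of this term when the DIC pool sits at ``delta_dic``."""
        if self.delta is not None:
            return self.delta
        return delta_dic + self.epsilon  # type: ignore[operator]


@dataclass(frozen=True)
class BoxModelSpec:
    """A DIC-centred flux network plus the shared fractionation factors.

    ``eps_ph`` (photosynthetic enrichment) and ``eps_ch4_meth`` (CH4
    depletion relative to sedimentary organic carbon) are carried for
    provenance; the per-term ``epsilon`` values already include them where
    the term derives from organic matter.
    """

    terms: tuple[FluxTerm, ...]
    eps_ph: float = 0.0
    eps_ch4_meth: float = 0.0
    measured_delta_dic: float | None = None

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate term names in network: {sorted(names)}")

    @property
    def inputs(self) -> tuple[FluxTerm, ...]:
        return tuple(t for t in self.terms if t.direction == "input")

    @property
    def outputs(self) -> tuple[FluxTerm, ...]:
        return tuple(t for t in self.terms if t.direction == "output")

    def term(self, name: str) -> FluxTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def free_terms(self) -> tuple[FluxTerm, ...]:
        return tuple(t for t in self.terms if t.constrained == "free")

    def fixed(self) -> "BoxModelSpec":
        """The network without its free terms."""
        return replace(
            self, terms=tuple(t for t in self.terms if t.constrained != "free")
        )

    def with_term(self, term: FluxTerm) -> "BoxModelSpec":
        """A copy with ``term`` replacing any existing term of the same name."""
        rest = tuple(t for t in self.terms if t.name != term.name)
        return replace(self, terms=rest + (term,))


@dataclass(frozen=True)
class BalanceSolution:
    """A solved network: the DIC signature plus closure diagnostics."""

    delta_dic: float
    residual_mass: float
    residual_isotope: float
    solved_terms: Mapping[str, tuple[float, float]] = field(default_factory=dict)


def _linear_coefficients(spec: BoxModelSpec) -> tuple[float, float, float, float]:
    """Coefficients (A_in, B_in, A_out, B_out) of the isotope balance.

    sum(f * d13C) over a side equals A * d13C_DIC + B, where epsilon-type
    terms contribute flux to A and flux*epsilon to B, and absolute-delta
    terms contribute only flux*delta to B.
    """
    a_in = b_in = a_out = b_out = 0.0
    for t in spec.terms:
        if t.epsilon is not None:
            a, b = t.flux, t.flux * t.epsilon
        else:
            a, b = 0.0, t.flux * t.delta  # type: ignore[operator]
        if t.direction == "input":
            a_in += a
            b_in += b
        else:
            a_out += a
            b_out += b
    return a_in, b_in, a_out, b_out


def _flux_scale(spec: BoxModelSpec) -> float:
    return max(sum(t.flux for t in spec.terms), 1.0)


def balance_residuals(
    spec: BoxModelSpec, delta_dic: float
) -> tuple[float, float]:
    """Mass and isotope residuals (inputs minus outputs) at ``delta_dic``.

    Both vanish (to 1e-9 relative) iff the network is at steady state with
    the DIC pool at ``delta_dic``.  Units: mmolC m-2 d-1 and
    permil * mmolC m-2 d-1.
    """
    mass = sum(t.flux for t in spec.inputs) - sum(t.flux for t in spec.outputs)
    iso = sum(t.flux * t.delta_at(delta_dic) for t in spec.inputs) - sum(
        t.flux * t.delta_at(delta_dic) for t in spec.outputs
    )
    return mass, iso


def forward_delta_dic(spec: BoxModelSpec, mass_rtol: float = REL_TOL) -> float:
    """Closed-form steady-state d13C_DIC of a fully constrained network.

    Requires the network to be mass-balanced (relative tolerance 1e-9 by
    default; callers evaluating rounded published fluxes may state the
    data's coarser precision via ``mass_rtol``) and the isotope balance to
    be non-degenerate: the net flux carried by epsilon-type terms (inputs
    minus outputs) must be nonzero, otherwise d13C_DIC drops out of the
    balance.
    """
    if spec.free_terms:
        raise BalanceError("network has free terms; solve them first")
    scale = _flux_scale(spec)
    mass, _ = balance_residuals(spec, 0.0)
    if abs(mass) > mass_rtol * scale:
        raise BalanceError(
            f"network is not mass balanced: residual {mass:.6g} mmolC m-2 d-1"
        )
    a_in, b_in, a_out, b_out = _linear_coefficients(spec)
    denom = a_in - a_out
    if abs(denom) <= REL_TOL * scale:
        raise DegenerateNetworkError(
            "epsilon-weighted flux difference is zero; d13C_DIC is unconstrained"
        )
    return (b_out - b_in) / denom


def solve_network(spec: BoxModelSpec) -> BalanceSolution:
    """Forward-solve and package the result with closure diagnostics."""
    delta = forward_delta_dic(spec)
    mass, iso = balance_residuals(spec, delta)
    solved = {t.name: (t.flux, t.delta_at(delta)) for t in spec.terms}
    return BalanceSolution(
        delta_dic=delta, residual_mass=mass, residual_isotope=iso, solved_terms=solved
    )


def solve_unconstrained(
    spec: BoxModelSpec, measured_delta_dic: float
) -> tuple[float, float]:
    """Solve the single unconstrained input flux and its d13C.

    Given a network whose inputs are all fixed apart from the free term(s)
    — several free terms count as one combined unconstrained input, to be
    apportioned afterwards with :func:`split_two_endmembers` — return the
    flux ``f_nc`` that closes the mass balance and the signature
    ``delta_nc`` that closes the isotope balance at the measured d13C_DIC.
    ``delta_nc`` is NaN when ``f_nc`` is exactly zero.
    """
    fixed = spec.fixed()
    f_in = sum(t.flux for t in fixed.inputs)
    f_out = sum(t.flux for t in fixed.outputs)
    f_nc = f_out - f_in
    scale = _flux_scale(fixed)
    if f_nc < -REL_TOL * scale:
        raise InfeasibleNetworkError(
            f"constrained inputs exceed outputs by {-f_nc:.6g} mmolC m-2 d-1; "
            "the unconstrained input flux would be negative"
        )
    f_nc = max(f_nc, 0.0)
    iso_in = sum(t.flux * t.delta_at(measured_delta_dic) for t in fixed.inputs)
    iso_out = sum(t.flux * t.delta_at(measured_delta_dic) for t in fixed.outputs)
    if f_nc == 0.0:
        return 0.0, math.nan
    delta_nc = (iso_out - iso_in) / f_nc
    return f_nc, delta_nc


def split_two_endmembers(
    f_nc: float, delta_nc: float, delta_a: float, delta_b: float
) -> tuple[float, float]:
    """Apportion a combined flux between two isotopic end-members.

    Solves f_a + f_b = f_nc and f_a*delta_a + f_b*delta_b = f_nc*delta_nc.
    ``delta_nc`` must lie between the end-members, otherwise one flux would
    be negative.
    """
    if delta_a == delta_b:
        raise ValueError("end-members must have distinct d13C values")
    f_a = f_nc * (delta_nc - delta_b) / (delta_a - delta_b)
    f_b = f_nc - f_a
    tol = REL_TOL * max(abs(f_nc), 1.0)
    if f_a < -tol or f_b < -tol:
        raise NegativeFluxError(
            f"mixture d13C {delta_nc:.3f} lies outside the end-members "
            f"[{min(delta_a, delta_b):.3f}, {max(delta_a, delta_b):.3f}]"
        )
    return max(f_a, 0.0), max(f_b, 0.0)


# ---------------------------------------------------------------------------
# configuration and tabular I/O


def network_from_dict(cfg: Mapping) -> BoxModelSpec:
    """Build a network from a nested mapping (the YAML config layout).

    Layout::

        eps_ph: 26.2
        eps_ch4_meth: 53.6
        measured_delta_dic: 12.1
        terms:
          respiration: {direction: input, flux: 214.0, epsilon: -26.2,
                        constrained: measured}
          ...

    Per-term ``epsilon`` is the net offset to d13C_DIC (organic-derived
    terms already include -eps_ph).
    """
    terms = []
    for name, t in cfg["terms"].items():
        terms.append(
            FluxTerm(
                name=name,
                direction=t["direction"],
                flux=float(t.get("flux", 0.0)),
                epsilon=None if t.get("epsilon") is None else float(t["epsilon"]),
                delta=None if t.get("delta") is None else float(t["delta"]),
                constrained=t.get("constrained", "measured"),
            )
        )
    return BoxModelSpec(
        terms=tuple(terms),
        eps_ph=float(cfg.get("eps_ph", 0.0)),
        eps_ch4_meth=float(cfg.get("eps_ch4_meth", 0.0)),
        measured_delta_dic=(
            None
            if cfg.get("measured_delta_dic") is None
            else float(cfg["measured_delta_dic"])
        ),
    )


def load_network(path) -> BoxModelSpec:
    """Read a network definition from a YAML config file."""
    with open(path, "r", encoding="utf-8") as fh:
        return network_from_dict(yaml.safe_load(fh))


def network_to_frame(
    spec: BoxModelSpec, delta_dic: float | None = None
) -> pd.DataFrame:
    """Tabulate a network, optionally evaluating each term's d13C."""
    rows = []
    for t in spec.terms:
        rows.append(
            {
                "term": t.name,
                "direction": t.direction,
                "flux_mmolC_m2_d": t.flux,
                "delta_permil": (
                    t.delta if delta_dic is None else t.delta_at(delta_dic)
                ),
                "epsilon_permil": t.epsilon,
                "constrained": t.constrained,
            }
        )
    return pd.DataFrame(rows)


def solution_to_frame(spec: BoxModelSpec, solution: BalanceSolution) -> pd.DataFrame:
    return network_to_frame(spec, delta_dic=solution.delta_dic)
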