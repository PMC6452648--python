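"""Reaction thermodynamics for low-temperature iron-sulfide transformation.

The module covers the small reaction network that governs pyrite (FeS2)
formation from mackinawite (FeS) and dissolved sulfide, its coupling to
hydrogenotrophic methanogenesis, and the bioenergetic feasibility window of
the sulfide-to-zero-valent-sulfur step:

* polysulfide pathway       FeS + Sn(2-)      -> FeS2 + S(n-1)(2-)
* H2S pathway               FeS + H2S         -> FeS2 + H2
* scaled H2S pathway        4 FeS + 4 H2S     -> 4 FeS2 + 4 H2
* methanogenesis            CO2 + 4 H2        -> CH4 + 2 H2O
* syntrophic net reaction   4 FeS + 4 H2S + CO2 -> 4 FeS2 + CH4 + 2 H2O
* sulfide oxidation to S0   H2S               -> [S0] + H2

All Gibbs energies are biochemical-standard quantities (pH 7, 25 degC,
unit activities, "dG0'"), so protons never enter the reaction quotient.
Solids and water carry activity 1; aqueous activities are molar
concentrations and gas activities partial pressures in bar (no activity
coefficient model). Temperature enters only through the R*T ln Q term.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

log = logging.getLogger(__name__)

#: Gas constant in kJ mol-1 K-1.
R_KJ = 8.314e-3
#: Faraday constant in C mol-1.
FARADAY = 96485.0
#: Default temperature (K) for biochemical-standard evaluations.
T_STANDARD = 298.15


@dataclass(frozen=True)
class Species:
    """A chemical species taking part in a reaction.

    ``phase`` controls how the species enters the reaction quotient:
    solids and water are fixed at activity 1, aqueous species are
    referenced to 1 mol/L and gases to 1 bar.  ``elements`` holds the Fe
    and S content used for element-balance checks; the zero-valent-sulfur
    placeholder ``[S0]`` counts as one S.
    """

    name: str
    phase: str = "aqueous"
    charge: int = 0
    elements: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phase not in {"aqueous", "gas", "solid", "water"}:
            raise ValueError(f"unknown phase {self.phase!r} for {self.name}")

    def __hash__(self) -> int:  # elements dict is derived metadata
        return hash((self.name, self.phase, self.charge))

    @property
    def unit_activity(self) -> bool:
        return self.phase in {"solid", "water"}


@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction with a biochemical-standard Gibbs energy.

    ``stoichiometry`` maps species to signed rational coefficients
    (negative = consumed).  ``dg0_prime`` is kJ per formula unit of
    reaction as written.  ``dg0_prime_range`` optionally stores a printed
    (low, high) range; the scalar is then its midpoint.
    """

    id: str
    stoichiometry: Mapping[Species, Fraction]
    dg0_prime: float
    dg0_prime_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"{self.id}: empty stoichiometry")
        coeffs = list(self.stoichiometry.values())
        if not any(c < 0 for c in coeffs) or not any(c > 0 for c in coeffs):
            raise ValueError(f"{self.id}: need at least one reactant and one product")

    def species(self, name: str) -> Species:
        for sp in self.stoichiometry:
            if sp.name == name:
                return sp
        raise KeyError(f"{self.id}: no species named {name!r}")

    def element_imbalance(self, element: str) -> Fraction:
        """Net amount of ``element`` produced minus consumed (0 = balanced)."""
        total = Fraction(0)
        for sp, nu in self.stoichiometry.items():
            total += nu * sp.elements.get(element, 0)
        return total

    def is_balanced(self, elements: Sequence[str] = ("Fe", "S")) -> bool:
        return all(self.element_imbalance(e) == 0 for e in elements)

    def scaled(self, factor: Fraction | int) -> "Reaction":
        f = Fraction(factor)
        return Reaction(
            id=f"{self.id}*{f}",
            stoichiometry={sp: nu * f for sp, nu in self.stoichiometry.items()},
            dg0_prime=self.dg0_prime * float(f),
        )


@dataclass(frozen=True)
class ConditionSet:
    """Temperature, pH and species activities defining a reaction quotient.

    Unlisted aqueous/gas species default to activity 1 (biochemical
    standard state).  Activities supplied for solids or water are ignored
    with a warning, since those phases are fixed at unit activity.
    """

    temperature: float = T_STANDARD
    pH: float = 7.0
    activities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        for name, a in self.activities.items():
            if a <= 0:
                raise ValueError(f"activity of {name!r} must be positive, got {a}")

    def activity(self, sp: Species) -> float:
        if sp.unit_activity:
            if sp.name in self.activities:
                log.warning(
                    "activity given for %s (%s) is ignored: fixed at 1", sp.name, sp.phase
                )
            return 1.0
        return float(self.activities.get(sp.name, 1.0))

    def with_activity(self, name: str, value: float) -> "ConditionSet":
        acts = dict(self.activities)
        acts[name] = value
        return replace(self, activities=acts)


@dataclass(frozen=True)
class Constants:
    """Physical constants and the pH-7 hydrogen reference potential.

    ``E0_H2_pH7`` is the biochemical-standard potential of the 2H+/H2
    couple in mV; the default -414 mV corresponds to E0(H+/H2) = 0 mV
    shifted by -59.2 mV per pH unit at 25 degC.
    """

    R: float = R_KJ
    F: float = FARADAY
    E0_H2_pH7: float = -414.0


# --- species catalogue -----------------------------------------------------

FES = Species("FeS", "solid", elements={"Fe": 1, "S": 1})
FES2 = Species("FeS2", "solid", elements={"Fe": 1, "S": 2})
H2S = Species("H2S", "aqueous", elements={"S": 1})
H2 = Species("H2", "gas")
CO2 = Species("CO2", "gas")
CH4 = Species("CH4", "gas")
H2O = Species("H2O", "water")
S0 = Species("[S0]", "aqueous", elements={"S": 1})
POLYSULFIDE = Species("Sn2-", "aqueous", charge=-2)
POLYSULFIDE_M1 = Species("Sn-1_2-", "aqueous", charge=-2)


def standard_reactions() -> dict[str, Reaction]:
    """The six reactions of the pyrite/methanogenesis network, keyed eq1..eq6.

    dG0' values are biochemical-standard (pH 7, 25 degC).  eq1 carries a
    printed range and exposes its midpoint as the scalar; it participates
    in reporting only, not in the eq5 coupling.
    """
    f = Fraction
    eq1 = Reaction(
        "eq1",
        {FES: f(-1), POLYSULFIDE: f(-1), FES2: f(1), POLYSULFIDE_M1: f(1)},
        dg0_prime=-69.5,
        dg0_prime_range=(-75.0, -64.0),
    )
    eq2 = Reaction("eq2", {FES: f(-1), H2S: f(-1), FES2: f(1), H2: f(1)}, -41.0)
    eq3 = Reaction("eq3", {FES: f(-4), H2S: f(-4), FES2: f(4), H2: f(4)}, -164.0)
    eq4 = Reaction("eq4", {CO2: f(-1), H2: f(-4), CH4: f(1), H2O: f(2)}, -131.0)
    eq5 = Reaction(
        "eq5", {FES: f(-4), H2S: f(-4), CO2: f(-1), FES2: f(4), CH4: f(1), H2O: f(2)}, -295.0
    )
    eq6 = Reaction("eq6", {H2S: f(-1), S0: f(1), H2: f(1)}, +28.0)
    return {r.id: r for r in (eq1, eq2, eq3, eq4, eq5, eq6)}


def reaction_from_config(conf: Mapping) -> Reaction:
    """Build a reaction from a structured config mapping.

    Expected keys: ``id``, ``dg0_prime``, and ``species`` — a list of
    mappings with ``name``, ``coefficient`` (signed, rational strings like
    "1/2" allowed), and optional ``phase``, ``charge``, ``elements``.
    """
    stoich = {}
    for entry in conf["species"]:
        sp = Species(
            name=entry["name"],
            phase=entry.get("phase", "aqueous"),
            charge=int(entry.get("charge", 0)),
            elements=dict(entry.get("elements", {})),
        )
        stoich[sp] = Fraction(str(entry["coefficient"]))
    return Reaction(id=conf["id"], stoichiometry=stoich, dg0_prime=float(conf["dg0_prime"]))


def conditions_from_config(conf: Mapping) -> ConditionSet:
    """Build a condition set from config keys temperature/pH/activities."""
    return ConditionSet(
        temperature=float(conf.get("temperature", T_STANDARD)),
        pH=float(conf.get("pH", 7.0)),
        activities={k: float(v) for k, v in conf.get("activities", {}).items()},
    )


def reaction_quotient(rxn: Reaction, cond: ConditionSet) -> float:
    """Reaction quotient Q over non-solid, non-water species.

    Q = prod a_i ** nu_i with aqueous activities in mol/L and gas
    activities in bar; protons are excluded (pH 7 is baked into dG0').
    """
    log_q = 0.0
    for sp, nu in rxn.stoichiometry.items():
        if sp.unit_activity or nu == 0:
            continue
        a = cond.activity(sp)
        if a <= 0:
            raise ValueError(f"non-positive activity for species {sp.name!r}")
        log_q += float(nu) * math.log(a)
    return math.exp(log_q)


def delta_g(rxn: Reaction, cond: ConditionSet) -> float:
    """Gibbs energy of reaction (kJ per formula unit): dG = dG0' + R*T*ln Q."""
    q = reaction_quotient(rxn, cond)
    return rxn.dg0_prime + R_KJ * cond.temperature * math.log(q)


def couple(parts: Sequence[tuple[Reaction, Fraction | int | float]]) -> Reaction:
    """Linear combination of reactions with positive rational multipliers.

    Stoichiometries are added with exact rational arithmetic so that
    intermediates (for instance the H2 shuttled from FeS transformation to
    the methanogen) cancel exactly when their net coefficient is zero;
    dg0_prime adds multiplier-weighted.
    """
    if not parts:
        raise ValueError("couple() needs at least one reaction")
    stoich: dict[Species, Fraction] = {}
    dg0 = 0.0
    ids = []
    for rxn, mult in parts:
        m = Fraction(mult).limit_denominator(10**9) if isinstance(mult, float) else Fraction(mult)
        if m <= 0:
            raise ValueError("multipliers must be positive")
        ids.append(f"{m}*{rxn.id}" if m != 1 else rxn.id)
        for sp, nu in rxn.stoichiometry.items():
            stoich[sp] = stoich.get(sp, Fraction(0)) + m * nu
        dg0 += float(m) * rxn.dg0_prime
    stoich = {sp: nu for sp, nu in stoich.items() if nu != 0}
    return Reaction(id="+".join(ids), stoichiometry=stoich, dg0_prime=dg0)


def critical_activity(
    rxn: Reaction,
    cond: ConditionSet,
    free_species: Species | str,
    threshold: float,
) -> float:
    """Activity of ``free_species`` at which delta_g equals ``threshold`` kJ.

    Closed-form inversion of dG = dG0' + RT ln(Q_rest * a**nu):

        a* = exp[(threshold - dG0' - RT ln Q_rest) / (nu * R * T)]

    ``free_species`` must be absent from ``cond.activities``; the returned
    activity round-trips through :func:`delta_g` to the threshold within
    1e-9 kJ.
    """
    sp = rxn.species(free_species) if isinstance(free_species, str) else free_species
    nu = rxn.stoichiometry.get(sp, Fraction(0))
    if nu == 0:
        raise ValueError(f"{sp.name} has zero coefficient in {rxn.id}")
    if sp.unit_activity:
        raise ValueError(f"{sp.name} is a {sp.phase}: activity fixed at 1")
    if sp.name in cond.activities:
        raise ValueError(f"{sp.name} already has an activity in the condition set")
    rt = R_KJ * cond.temperature
    q_rest = reaction_quotient(rxn, cond)  # free species defaults to 1, contributes nothing
    return math.exp((threshold - rxn.dg0_prime - rt * math.log(q_rest)) / (float(nu) * rt))


def couple_potential(
    rxn_vs_h2: Reaction, n_electrons: int, constants: Constants = Constants()
) -> float:
    """Biochemical-standard redox potential (mV) of a couple written against H2.

    For a donor couple oxidized by protons (H2 as product, e.g. the
    FeS2/(H2S + FeS) couple via FeS + H2S -> FeS2 + H2):

        E0'(couple) = E0'(2H+/H2) + dG0' * 1e6 / (n * F)   [mV]

    with dG0' in kJ per formula unit and n electrons transferred (2 per H2).
    """
    if n_electrons <= 0:
        raise ValueError("n_electrons must be positive")
    if not any(sp.name == "H2" for sp in rxn_vs_h2.stoichiometry):
        raise ValueError("reaction must produce or consume H2")
    return constants.E0_H2_pH7 + rxn_vs_h2.dg0_prime * 1e6 / (n_electrons * constants.F)


def feasibility_report(
    rxn: Reaction, cond: ConditionSet, threshold: float = -11.0
) -> dict:
    """JSON-ready summary: Q, dG0', dG, and feasibility at a kJ threshold.

    The default threshold of -11 kJ/mol is the commonly cited minimum
    free-energy change for microbial energy conservation (about one third
    of an ATP equivalent under physiological conditions).
    """
    q = reaction_quotient(rxn, cond)
    dg = delta_g(rxn, cond)
    return {
        "reaction": rxn.id,
        "temperature_K": cond.temperature,
        "Q": q,
        "dG0_prime_kJ": rxn.dg0_prime,
        "dG_kJ": dg,
        "threshold_kJ": threshold,
        "feasible_at_threshold": dg <= threshold,
    }
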