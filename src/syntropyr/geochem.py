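"""Closed serum-bottle chemistry: sulfide speciation, Henry's-law headspace
partitioning, ideal-gas amounts, and the sulfide inventory mass balance.

The experimental unit is a 180-mL serum bottle with 70 mL of mineral
medium (110 mL headspace), incubated at 28 degC under ~1 bar.  Total
dissolved sulfide is the sum of H2S(aq) and HS-; S2- is negligible below
pH 12 and is ignored.  Headspace H2S is computed from the neutral aqueous
species with a dimensionless Henry constant k = c_gas / c_aq (0.093 for
H2S at 28 degC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Gas constant in L bar mol-1 K-1 (ideal-gas conversions).
R_LBAR = 0.0831446


@dataclass(frozen=True)
class BottleSystem:
    """Closed two-phase (liquid + headspace) serum-bottle geometry."""

    total_volume_mL: float = 180.0
    liquid_volume_mL: float = 70.0
    temperature_K: float = 301.15
    headspace_pressure_bar: float = 1.0
    headspace_composition: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.liquid_volume_mL <= 0 or self.total_volume_mL <= self.liquid_volume_mL:
            raise ValueError("need 0 < liquid volume < total volume")
        if self.headspace_composition:
            total = sum(self.headspace_composition.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"headspace mole fractions sum to {total}, not 1")

    @property
    def headspace_volume_mL(self) -> float:
        return self.total_volume_mL - self.liquid_volume_mL


@dataclass(frozen=True)
class SulfideInventory:
    """Total sulfide loaded into a bottle, as amount and per-liter concentration."""

    added_umol: float
    reductant_mM: float
    total_umol: float
    per_liter_mM: float


@dataclass(frozen=True)
class HenryConstant:
    """Dimensionless Henry constant k = c_gas / c_aq for a gas.

    Applied to the neutral aqueous species only (the convention used here
    for H2S; the ionized HS- fraction does not partition).
    """

    gas: str = "H2S"
    k_dimensionless: float = 0.093
    temperature_K: float = 301.15

    def __post_init__(self) -> None:
        if self.k_dimensionless <= 0:
            raise ValueError("Henry constant must be positive")


def sulfide_speciation(
    total_aq_mM: float, pH: float, pKa1: float = 7.0
) -> dict[str, float]:
    """Split total dissolved sulfide into H2S(aq) and HS- at a given pH.

    Fractions follow the first dissociation only:
    f(H2S) = 1 / (1 + 10**(pH - pKa1)); S2- is neglected (pKa2 > 12).
    Returns both fractions and the corresponding concentrations (mM).
    """
    if total_aq_mM < 0:
        raise ValueError("total sulfide must be non-negative")
    if not 0 < pH < 14:
        raise ValueError("pH out of range (0, 14)")
    f_h2s = 1.0 / (1.0 + 10.0 ** (pH - pKa1))
    f_hs = 1.0 - f_h2s
    return {
        "f_H2S_aq": f_h2s,
        "f_HS": f_hs,
        "H2S_aq_mM": f_h2s * total_aq_mM,
        "HS_mM": f_hs * total_aq_mM,
    }


def headspace_amount(
    c_aq_h2s_mM: float, k: HenryConstant, bottle: BottleSystem
) -> float:
    """Amount of gas (umol) in the headspace in equilibrium with the liquid.

    n_gas = k * c_aq(neutral species) * V_headspace.
    """
    if c_aq_h2s_mM < 0:
        raise ValueError("aqueous concentration must be non-negative")
    v_headspace_L = bottle.headspace_volume_mL / 1000.0
    return k.k_dimensionless * c_aq_h2s_mM * v_headspace_L * 1000.0  # mM * L -> umol


def initial_inventory(
    bottle: BottleSystem, added_umol: float = 350.0, reductant_mM: float = 1.0
) -> SulfideInventory:
    """Total sulfide inventory from the spiked amount plus medium reductant.

    With the defaults (350 umol H2S added to 70 mL of medium already
    containing 1 mM sulfide as reducing agent) the total is 420 umol,
    i.e. 6.0 mmol per liter of culture.
    """
    if added_umol < 0 or reductant_mM < 0:
        raise ValueError("amounts must be non-negative")
    v_liq_mL = bottle.liquid_volume_mL
    total = added_umol + reductant_mM * v_liq_mL
    return SulfideInventory(
        added_umol=added_umol,
        reductant_mM=reductant_mM,
        total_umol=total,
        per_liter_mM=total / v_liq_mL,
    )


def gas_moles(bottle: BottleSystem, gas: str) -> float:
    """Ideal-gas amount (mmol) of a headspace gas: n = P x V / (R T)."""
    if gas not in bottle.headspace_composition:
        raise KeyError(f"gas {gas!r} not in headspace composition")
    x = bottle.headspace_composition[gas]
    v_L = bottle.headspace_volume_mL / 1000.0
    n_mol = bottle.headspace_pressure_bar * x * v_L / (R_LBAR * bottle.temperature_K)
    return n_mol * 1000.0


def methane_per_liter_culture(
    ch4_headspace_fraction: float, bottle: BottleSystem
) -> float:
    """Headspace CH4 normalized to culture volume (mmol per L of culture).

    Dissolved CH4 is neglected (low solubility; headspace gas
    chromatography is the reporting convention).
    """
    if not 0.0 <= ch4_headspace_fraction <= 1.0:
        raise ValueError("mole fraction must be in [0, 1]")
    v_L = bottle.headspace_volume_mL / 1000.0
    n_mmol = (
        bottle.headspace_pressure_bar
        * ch4_headspace_fraction
        * v_L
        / (R_LBAR * bottle.temperature_K)
        * 1000.0
    )
    return n_mmol / (bottle.liquid_volume_mL / 1000.0)


def bottle_report(
    bottle: BottleSystem,
    added_umol: float = 350.0,
    reductant_mM: float = 1.0,
    pH: float = 7.3,
    pKa1: float = 7.0,
    k: HenryConstant | None = None,
) -> dict:
    """JSON-ready inventory report for one bottle configuration."""
    k = k or HenryConstant(temperature_K=bottle.temperature_K)
    inv = initial_inventory(bottle, added_umol, reductant_mM)
    spec = sulfide_speciation(inv.per_liter_mM, pH, pKa1)
    gas_umol = headspace_amount(spec["H2S_aq_mM"], k, bottle)
    return {
        "bottle": {
            "total_mL": bottle.total_volume_mL,
            "liquid_mL": bottle.liquid_volume_mL,
            "headspace_mL": bottle.headspace_volume_mL,
            "temperature_K": bottle.temperature_K,
        },
        "sulfide_inventory": {
            "added_umol": inv.added_umol,
            "reductant_mM": inv.reductant_mM,
            "total_umol": inv.total_umol,
            "per_liter_mM": inv.per_liter_mM,
        },
        "speciation": spec,
        "headspace_H2S_umol": gas_umol,
        "assumptions": {
            "henry_k_dimensionless": k.k_dimensionless,
            "henry_applies_to": "neutral H2S(aq) only",
            "pKa1": pKa1,
            "S2-_neglected": True,
            "ideal_gas": True,
        },
    }
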