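"""Seeded generator of culture trajectories emulating the incubation study.

Scenarios mirror the experimental design: the active enrichment (J5) in
which methane rises to a ~0.7 mmol/L plateau while FeS converts to
pyrite at the 4:1 FeS2:CH4 syntrophic coupling; a noninoculated abiotic
control; methanogenesis inhibition by BES; bacterial inhibition by
penicillin (with and without 79 % H2 in the headspace); and a 4-60 degC
temperature series peaking at 28 degC.

Functional forms are the generator's own choices — a normalized logistic
rise for methane and phase conversion, exponential cell growth — since
the study constrains endpoints and plateaus, not kinetics.  In noiseless
mode the trajectories obey exact iron and sulfur mass balance: phase
fractions always sum to 1 over constant total Fe, and dissolved sulfide
lost equals sulfide incorporated into pyrite (1 S per FeS2 from
solution) plus sulfur taken up by the metastable FeSx phase.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .mossbauer import PhaseComposition, Spectrum, simulate_spectrum, sites_for_composition
from .temperature import TemperatureProfile, cardinal_model

MODEL_VERSION = "1.0"

#: Default initial inventories (mmol per L of culture).
H2S_INITIAL_MM = 6.0
FE_TOTAL_MM = 5.0


@dataclass(frozen=True)
class ScenarioParams:
    """Endpoint targets and kinetic shape parameters for one scenario."""

    name: str
    duration_d: float = 207.0
    ch4_plateau_mmol_per_L: float = 0.0
    ch4_lag_d: float = 30.0
    h2s_final_mmol_per_L: float = 3.7
    final_phase_comp: dict[str, float] = field(default_factory=lambda: {"FeS": 1.0})
    cells_initial_per_mL: float = 0.0
    cells_final_per_mL: float = 0.0
    noise: float = 0.05
    seed: int = 0
    pyrite_coupled: bool = False
    total_fe_mM: float = FE_TOTAL_MM
    h2s_initial_mmol_per_L: float = H2S_INITIAL_MM
    n_points: int = 25
    headspace_h2_fraction: float = 0.0
    temperature_series: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.ch4_plateau_mmol_per_L < 0 or self.noise < 0:
            raise ValueError("plateau and noise must be non-negative")
        total = sum(self.final_phase_comp.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"final phase fractions sum to {total}, not 1")


@dataclass
class CultureTimeSeries:
    """A simulated closed-bottle incubation trajectory."""

    time_d: np.ndarray
    ch4_mmol_per_L: np.ndarray
    h2s_mmol_per_L: np.ndarray
    phases: dict[str, np.ndarray]  # fraction of total Fe per phase
    cells_per_mL: np.ndarray
    sulfide_to_pyrite_mM: np.ndarray
    sulfide_to_fesx_mM: np.ndarray
    metadata: dict

    def final_composition(self) -> PhaseComposition:
        final = {k: float(v[-1]) for k, v in self.phases.items()}
        total = sum(final.values())
        return PhaseComposition({k: v / total for k, v in final.items()})

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: one row per time point x observable."""
        rows = []
        obs = {
            "ch4_mmol_per_L": self.ch4_mmol_per_L,
            "h2s_mmol_per_L": self.h2s_mmol_per_L,
            "cells_per_mL": self.cells_per_mL,
        }
        obs.update({f"frac_{k}": v for k, v in self.phases.items()})
        for name, series in obs.items():
            for t, val in zip(self.time_d, series):
                rows.append({"time_d": t, "observable": name, "value": float(val)})
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        """TSV of the tidy trajectory plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(self.metadata, fh, indent=1, sort_keys=True)


def read_time_series(path: str | Path) -> pd.DataFrame:
    """Read a tidy or wide (time_d, ch4_mmol_per_L, h2s_mmol_per_L) TSV."""
    df = pd.read_csv(path, sep="\t")
    if {"observable", "value"}.issubset(df.columns):
        df = df.pivot_table(index="time_d", columns="observable", values="value").reset_index()
    return df


def scenario_presets() -> dict[str, ScenarioParams]:
    """The study's scenarios with their reported endpoint values.

    J5 endpoints: CH4 plateau 0.7 mmol/L; total sulfide 6 -> 0.04-1.1
    mmol/L (midpoint used); final phases FeS2 53-63 %, FeSx 31-39 %,
    Fe3S4 7-8 % with the pyrite fraction pinned to the 4:1 coupling
    (4 x 0.7 / 5 = 0.56); cells 2e5 -> 2-9e6 per mL.  Abiotic control:
    no methane, 3.7 mmol/L residual sulfide, FeS 64 % / FeSx 36 %.
    Inhibition: BES stops methane and pyrite completely; penicillin stops
    methane at 0.15 mmol/L with no pyrite; penicillin + 79 % H2 gives
    >10 mmol CH4/L and still no pyrite.
    """
    uninoculated = {"FeS": 0.64, "FeSx": 0.36}
    presets = {
        "J5": ScenarioParams(
            name="J5",
            ch4_plateau_mmol_per_L=0.7,
            h2s_final_mmol_per_L=0.57,
            final_phase_comp={"FeS2": 0.56, "FeSx": 0.365, "Fe3S4": 0.075},
            cells_initial_per_mL=2e5,
            cells_final_per_mL=4e6,
            pyrite_coupled=True,
        ),
        "abiotic": ScenarioParams(
            name="abiotic",
            ch4_plateau_mmol_per_L=0.0,
            h2s_final_mmol_per_L=3.7,
            final_phase_comp=dict(uninoculated),
        ),
        "BES": ScenarioParams(
            name="BES",
            ch4_plateau_mmol_per_L=0.0,
            h2s_final_mmol_per_L=3.7,
            final_phase_comp=dict(uninoculated),
            cells_initial_per_mL=2e5,
            cells_final_per_mL=2e5,
        ),
        "penicillin": ScenarioParams(
            name="penicillin",
            ch4_plateau_mmol_per_L=0.15,
            ch4_lag_d=5.0,
            h2s_final_mmol_per_L=3.7,
            final_phase_comp=dict(uninoculated),
            cells_initial_per_mL=2e5,
            cells_final_per_mL=2e5,
        ),
        "penicillin_H2": ScenarioParams(
            name="penicillin_H2",
            ch4_plateau_mmol_per_L=12.0,
            h2s_final_mmol_per_L=3.7,
            final_phase_comp=dict(uninoculated),
            cells_initial_per_mL=2e5,
            cells_final_per_mL=2e5,
            headspace_h2_fraction=0.79,
        ),
        "temperature_series": ScenarioParams(
            name="temperature_series",
            ch4_plateau_mmol_per_L=0.7,
            h2s_final_mmol_per_L=0.57,
            final_phase_comp={"FeS2": 0.56, "FeSx": 0.365, "Fe3S4": 0.075},
            pyrite_coupled=True,
            # pyrite fraction formed at each incubation temperature, from a
            # cardinal temperature response with T_min 4, T_opt 28, T_max 60
            # degC scaled to the 28-degC maximum: zero at the extremes,
            # intermediate activity at 16 and 46, maximum at 28.
            temperature_series=tuple(
                (tc, float(cardinal_model(np.array([tc]), 4.0, 28.0, 60.0, 0.56)[0]))
                for tc in (4.0, 16.0, 28.0, 46.0, 60.0)
            ),
        ),
    }
    return presets


def _progress(t: np.ndarray, lag_d: float, duration_d: float) -> np.ndarray:
    """Normalized logistic rising from exactly 0 at t=0 to exactly 1 at t=end."""
    if duration_d <= 0:
        return np.zeros_like(t)
    mid = lag_d + 0.25 * (duration_d - lag_d)
    rate = 8.0 / max(duration_d - lag_d, 1e-9)
    raw = 1.0 / (1.0 + np.exp(-rate * (t - mid)))
    r0 = 1.0 / (1.0 + np.exp(-rate * (0.0 - mid)))
    r1 = 1.0 / (1.0 + np.exp(-rate * (duration_d - mid)))
    return (raw - r0) / (r1 - r0)


def generate(scenario: ScenarioParams) -> CultureTimeSeries:
    """Simulate one incubation trajectory for a scenario.

    Noiseless mode (``noise = 0``) is fully deterministic and obeys exact
    mass balance and exact 4:1 pyrite:methane coupling in the biotic
    channel; with noise, multiplicative Gaussian perturbations (truncated
    at zero) are applied per observable from a seeded generator, and
    phase fractions are renormalized so iron is always conserved.
    """
    if scenario.duration_d <= 0:
        t = np.array([0.0])
    else:
        t = np.linspace(0.0, scenario.duration_d, scenario.n_points)
    p = _progress(t, scenario.ch4_lag_d, scenario.duration_d)

    ch4 = scenario.ch4_plateau_mmol_per_L * p
    fe = scenario.total_fe_mM

    # Phase trajectories interpolate from pure FeS to the final composition.
    final = dict(scenario.final_phase_comp)
    phases: dict[str, np.ndarray] = {}
    if scenario.pyrite_coupled and "FeS2" in final:
        # pyrite tracks methane exactly: delta FeS2 (mM) = 4 * delta CH4
        phases["FeS2"] = 4.0 * ch4 / fe
    elif "FeS2" in final:
        phases["FeS2"] = final["FeS2"] * p
    for label, frac in final.items():
        if label in ("FeS", "FeS2"):
            continue
        phases[label] = frac * p
    other = sum(phases.values()) if phases else np.zeros_like(t)
    phases["FeS"] = 1.0 - other  # remainder: unconverted mackinawite

    # Dissolved sulfide decays from the initial inventory to the residual
    # level along the same progress curve; the loss is partitioned between
    # pyrite formation (1 S per FeS2 from solution) and FeSx uptake.
    h2s0 = scenario.h2s_initial_mmol_per_L
    h2s = h2s0 - (h2s0 - scenario.h2s_final_mmol_per_L) * p
    s_uptake = h2s0 - h2s
    s_to_pyrite = phases.get("FeS2", np.zeros_like(t)) * fe
    s_to_fesx = s_uptake - s_to_pyrite

    if scenario.cells_initial_per_mL > 0 and scenario.cells_final_per_mL > 0:
        cells = scenario.cells_initial_per_mL * (
            scenario.cells_final_per_mL / scenario.cells_initial_per_mL
        ) ** p
    else:
        cells = np.zeros_like(t)

    if scenario.noise > 0:
        rng = np.random.default_rng(scenario.seed)

        def jitter(x: np.ndarray) -> np.ndarray:
            return np.clip(x * (1.0 + rng.normal(0.0, scenario.noise, x.shape)), 0.0, None)

        ch4, h2s, cells = jitter(ch4), jitter(h2s), jitter(cells)
        noisy = {k: jitter(v) for k, v in phases.items()}
        total = sum(noisy.values())
        phases = {k: np.where(total > 0, v / np.where(total == 0, 1, total), 0.0)
                  for k, v in noisy.items()}

    return CultureTimeSeries(
        time_d=t,
        ch4_mmol_per_L=ch4,
        h2s_mmol_per_L=h2s,
        phases=phases,
        cells_per_mL=cells,
        sulfide_to_pyrite_mM=s_to_pyrite,
        sulfide_to_fesx_mM=s_to_fesx,
        metadata={
            "scenario": scenario.name,
            "seed": scenario.seed,
            "noise": scenario.noise,
            "model_version": MODEL_VERSION,
            "total_fe_mM": fe,
            "h2s_initial_mmol_per_L": h2s0,
        },
    )


def spectrum_for(comp: PhaseComposition | dict[str, float], seed: int = 0,
                 noise_sd: float = 0.0) -> Spectrum:
    """Synthesize a Mössbauer spectrum for a phase composition.

    Uses the nominal site library (pyrite doublet, mackinawite singlet,
    greigite 32 T sextet, broad FeSx sextet) with the given area split.
    """
    sites = sites_for_composition(dict(comp))
    return simulate_spectrum(sites, noise_sd=noise_sd, seed=seed)


def temperature_profile(
    params: ScenarioParams | None = None,
    include_intermediate: bool = False,
    intermediate_fraction: float = 0.3,
    noise: float = 0.0,
    seed: int = 0,
) -> TemperatureProfile:
    """Build the pyrite-activity-vs-temperature profile of the study design.

    Activity is the pyrite fraction formed at each incubation temperature
    (zero at 4 and 60 degC, maximal at 28 degC).  The undefined
    "intermediate FeS2-FeS phase" observed at 16 and 46 degC can be
    counted toward pyrite activity via ``include_intermediate``.
    """
    if params is None or params.temperature_series is None:
        params = scenario_presets()["temperature_series"]
    temps = [pt[0] for pt in params.temperature_series]
    acts = [pt[1] for pt in params.temperature_series]
    if include_intermediate:
        acts = [
            a + (intermediate_fraction if 4.0 < tc < 60.0 and a < max(acts) else 0.0)
            for tc, a in zip(temps, acts)
        ]
    if noise > 0:
        rng = np.random.default_rng(seed)
        acts = list(np.clip(np.asarray(acts) + rng.normal(0.0, noise, len(acts)), 0.0, None))
    return TemperatureProfile(tuple(temps), tuple(float(a) for a in acts))
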