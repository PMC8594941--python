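"""Physical constants, recording-solution recipes and electrochemistry.

The package works in a coherent "patch-clamp" unit system throughout:
millivolts, picoamps, nanosiemens, picofarads and milliseconds.  These
combine without conversion factors (pA = nS * mV, ms = pF / nS,
fC = pA * ms), which keeps every numerical routine free of unit fiddling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

#: Gas constant, J mol^-1 K^-1
R_GAS = 8.31446261815324
#: Faraday constant, C mol^-1
FARADAY = 96485.33212
#: Elementary charge carried by one Ca2+ ion, in coulombs, as used for the
#: charge-to-ion conversion (2e with e rounded at the second decimal).
CA_ION_CHARGE_C = 3.8e-19

#: Calculated liquid junction potential (mV) between bath and pipette,
#: keyed by the pipette EGTA concentration in mM.
E_LJ_BY_EGTA = {10.0: 8.9, 0.5: 9.6}

#: Bath temperature range midpoint, deg C.
DEFAULT_TEMPERATURE_C = 31.0

#: Known charge (elementary units) per ion species used in recipes.
ION_CHARGES = {
    "Na+": 1, "K+": 1, "Cs+": 1, "TEA+": 1, "Ca2+": 2, "Mg2+": 2,
    "Cl-": -1, "CH3SO4-": -1, "GTP-": -1,
}


@dataclass(frozen=True)
class SolutionComponent:
    species: str
    mM: float
    ions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mM < 0:
            raise ValueError(f"negative concentration for {self.species}")
        charge = sum(ION_CHARGES.get(ion, 0) * n for ion, n in self.ions.items())
        if any(ion not in ION_CHARGES for ion in self.ions):
            unknown = [ion for ion in self.ions if ion not in ION_CHARGES]
            raise ValueError(f"unknown ion species {unknown} in {self.species}")
        if charge != 0:
            raise ValueError(
                f"component {self.species} is not electroneutral (net {charge:+d})"
            )


@dataclass(frozen=True)
class SolutionRecipe:
    """A named recording solution: an inventory of dissociating components."""

    name: str
    side: str  # "intracellular" or "extracellular"
    components: tuple[SolutionComponent, ...]
    temperature_C: float = DEFAULT_TEMPERATURE_C

    def __post_init__(self) -> None:
        if self.side not in ("intracellular", "extracellular"):
            raise ValueError(f"side must be intra/extracellular, got {self.side!r}")

    def total_ion(self, ion: str) -> float:
        """Total free concentration (mM) of *ion* summed over all components.

        Unknown species (never seen in any recipe and absent from the charge
        table) raise; a known ion absent from this recipe totals 0 mM.
        """
        if ion not in ION_CHARGES:
            raise ValueError(f"unknown ion species {ion!r}")
        return sum(c.mM * c.ions.get(ion, 0) for c in self.components)


def total_ion(solution: SolutionRecipe, ion: str) -> float:
    """Functional alias for :meth:`SolutionRecipe.total_ion`."""
    return solution.total_ion(ion)


@dataclass(frozen=True)
class RecordingConditions:
    """Fixed experimental conditions of a whole-cell recording."""

    egta_mM: float = 10.0
    holding_potential_mV: float = -70.0
    temperature_C: float = DEFAULT_TEMPERATURE_C
    ion_charge_C: float = CA_ION_CHARGE_C

    def __post_init__(self) -> None:
        if self.egta_mM not in E_LJ_BY_EGTA:
            raise ValueError(
                f"egta_mM must be one of {sorted(E_LJ_BY_EGTA)}, got {self.egta_mM}"
            )

    @property
    def e_lj_mV(self) -> float:
        return E_LJ_BY_EGTA[self.egta_mM]


def nernst(c_in_mM: float, c_out_mM: float, valence: int,
           temperature_C: float = DEFAULT_TEMPERATURE_C) -> float:
    """Nernst equilibrium potential, in mV.

    E = (RT / zF) * ln(c_out / c_in), with concentrations in any common
    unit (only the ratio enters).
    """
    import math

    if c_in_mM <= 0 or c_out_mM <= 0:
        raise ValueError("concentrations must be positive")
    if valence == 0:
        raise ValueError("valence must be non-zero")
    t_kelvin = temperature_C + 273.15
    return (R_GAS * t_kelvin / (valence * FARADAY)) * math.log(c_out_mM / c_in_mM) * 1e3


def correct_ljp(applied_mV: float, e_lj_mV: float) -> float:
    """Convert an applied command voltage to the actual membrane voltage."""
    return applied_mV - e_lj_mV


def _parse_recipe(name: str, raw: dict) -> SolutionRecipe:
    comps = tuple(
        SolutionComponent(c["species"], float(c["mM"]), dict(c.get("ions", {})))
        for c in raw["components"]
    )
    return SolutionRecipe(
        name=raw.get("name", name),
        side=raw["side"],
        components=comps,
        temperature_C=float(raw.get("temperature_C", DEFAULT_TEMPERATURE_C)),
    )


def load_solutions(path: str | None = None) -> dict[str, SolutionRecipe]:
    """Load solution recipes from YAML (packaged recipes by default)."""
    if path is None:
        text = (resources.files("rodribbon") / "data" / "solutions.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {key: _parse_recipe(key, val) for key, val in raw.items()}


def chloride_reversal(egta_mM: float = 0.5,
                      temperature_C: float = DEFAULT_TEMPERATURE_C) -> float:
    """E_Cl (mV) from the packaged recipes for the given pipette EGTA level."""
    sols = load_solutions()
    key = "intracellular_05egta" if egta_mM == 0.5 else "intracellular_10egta"
    c_in = sols[key].total_ion("Cl-")
    c_out = sols["extracellular"].total_ion("Cl-")
    return nernst(c_in, c_out, -1, temperature_C)
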