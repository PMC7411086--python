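"""Cellular energy allocation: available energy, consumption and CEA.

The cellular-energy-allocation model summarises an organism's net
energy budget from two measurable quantities, both standardised to
10^6 cells:

* Ea (available energy, mJ / 10^6 cells): carbohydrate, protein and
  lipid masses converted with their combustion energies
  (17,500 / 24,000 / 39,500 mJ per mg respectively);
* Ec (energy consumption, mJ / 10^6 cells / h): mitochondrial
  electron-transport-system (ETS) activity measured as INT reduction to
  formazan at 490 nm, converted to oxygen consumption via the 2:1
  formazan:O2 stoichiometry and to energy with the oxyenthalpic
  equivalent 480 kJ per mol O2.

CEA = Ea / Ec (hours).

The formazan extinction coefficient is quoted in the source protocol as
15,900 mM^-1 cm^-1, while the spectrophotometric literature for
INT-formazan reports the same digits per M.  Both interpretations are
supported through ``EnergyConstants.epsilon_unit``; the default follows
the protocol as printed ("mM").  The choice scales Ec (and hence CEA)
by 10^3, so it is always recorded in outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "EnergyConstants",
    "EnergyBudget",
    "available_energy",
    "ets_consumption",
    "cea",
    "energy_budget",
]


@dataclass(frozen=True)
class EnergyConstants:
    """Combustion equivalents, oxyenthalpic equivalent and ETS constants."""

    carb_mj_per_mg: float = 17_500.0
    protein_mj_per_mg: float = 24_000.0
    lipid_mj_per_mg: float = 39_500.0
    oxyenthalpic_kj_per_mol_o2: float = 480.0
    epsilon_formazan: float = 15_900.0
    epsilon_unit: str = "mM"         # "mM" (as printed) or "M"
    path_cm: float = 1.0
    reaction_volume_ml: float = 0.2
    formazan_per_o2: float = 2.0     # umol formazan per umol O2

    def __post_init__(self) -> None:
        if self.epsilon_unit not in ("mM", "M"):
            raise ValueError("epsilon_unit must be 'mM' or 'M'")
        for name in ("carb_mj_per_mg", "protein_mj_per_mg", "lipid_mj_per_mg",
                     "oxyenthalpic_kj_per_mol_o2", "epsilon_formazan",
                     "path_cm", "reaction_volume_ml", "formazan_per_o2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "EnergyConstants":
        return replace(self, **kw)


@dataclass
class EnergyBudget:
    """Per-10^6-cell energy budget of one replicate."""

    ea_mj: float                     # mJ / 10^6 cells
    ec_mj_per_h: float               # mJ / 10^6 cells / h
    cea_h: float                     # Ea / Ec; NaN with flag when Ec = 0
    carb_mg: float
    protein_mg: float
    lipid_mg: float
    undefined_cea: bool = False
    epsilon_unit: str = "mM"


def available_energy(
    carb_mg: float,
    protein_mg: float,
    lipid_mg: float,
    cells: float,
    constants: EnergyConstants = EnergyConstants(),
) -> float:
    """Ea (mJ per 10^6 cells) from component masses in the extracted pellet.

    Ea = (17,500*carb + 24,000*protein + 39,500*lipid) * 10^6 / cells.
    """
    if min(carb_mg, protein_mg, lipid_mg) < 0:
        raise ValueError("component masses must be non-negative")
    if cells <= 0:
        raise ValueError("cell count must be positive")
    total_mj = (constants.carb_mj_per_mg * carb_mg
                + constants.protein_mj_per_mg * protein_mg
                + constants.lipid_mj_per_mg * lipid_mg)
    return total_mj * 1e6 / cells


def ets_consumption(
    delta_a490_per_min: float,
    cells: float,
    constants: EnergyConstants = EnergyConstants(),
) -> float:
    """Ec (mJ per 10^6 cells per h) from the INT-formazan formation rate.

    formazan rate [umol/min] = dA/min / (epsilon * path) * V_reaction;
    O2 rate = formazan rate / 2; linearly extrapolated to one hour and
    converted with 480 kJ / mol O2 (= 480 mJ / umol O2).
    """
    if delta_a490_per_min < 0:
        raise ValueError("ETS formazan formation rate must be non-negative")
    if cells <= 0:
        raise ValueError("cell count must be positive")
    eps_mm = (constants.epsilon_formazan if constants.epsilon_unit == "mM"
              else constants.epsilon_formazan / 1e3)
    formazan_mm_per_min = delta_a490_per_min / (eps_mm * constants.path_cm)
    formazan_umol_per_min = formazan_mm_per_min * constants.reaction_volume_ml
    o2_umol_per_h = formazan_umol_per_min / constants.formazan_per_o2 * 60.0
    mj_per_umol_o2 = constants.oxyenthalpic_kj_per_mol_o2  # kJ/mol == mJ/umol
    return o2_umol_per_h * mj_per_umol_o2 * 1e6 / cells


def cea(ea_mj: float, ec_mj_per_h: float) -> tuple[float, bool]:
    """CEA = Ea / Ec (hours); (NaN, True) when Ec is zero, never infinity."""
    if ea_mj < 0 or ec_mj_per_h < 0:
        raise ValueError("Ea and Ec must be non-negative")
    if ec_mj_per_h == 0:
        return float("nan"), True
    return ea_mj / ec_mj_per_h, False


def energy_budget(
    carb_mg: float,
    protein_mg: float,
    lipid_mg: float,
    delta_a490_per_min: float,
    cells: float,
    constants: EnergyConstants = EnergyConstants(),
) -> EnergyBudget:
    """Convenience wrapper computing Ea, Ec and CEA for one replicate."""
    ea = available_energy(carb_mg, protein_mg, lipid_mg, cells, constants)
    ec = ets_consumption(delta_a490_per_min, cells, constants)
    ratio, undefined = cea(ea, ec)
    return EnergyBudget(ea_mj=ea, ec_mj_per_h=ec, cea_h=ratio,
                        carb_mg=carb_mg, protein_mg=protein_mg,
                        lipid_mg=lipid_mg, undefined_cea=undefined,
                        epsilon_unit=constants.epsilon_unit)
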