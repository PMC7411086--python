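"""Oxidative-stress assay conversions: TBARS/MDA, CAT, APX and SOD.

Endpoint and kinetic absorbance readings are converted to analyte
concentrations and protein-normalised enzyme activities via
Beer-Lambert arithmetic with the assay extinction coefficients:

* MDA (TBARS): A532 - A600, epsilon = 155 mM^-1 cm^-1
* catalase: H2O2 consumption at 240 nm, epsilon = 39.4 mM^-1 cm^-1
* ascorbate peroxidase: decrease at 290 nm, epsilon = 2.8 mM^-1 cm^-1
* superoxide dismutase: inhibition of pyrogallol autoxidation at
  325 nm; 1 U = 50% inhibition (Marklund convention).

Volume bookkeeping (reaction vs extract volume) is explicit in
:class:`AssayConstants` because the normalisation arithmetic depends on
assay composition, not only on the extinction coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AssayConstants",
    "KineticTrace",
    "EnzymeActivity",
    "mda_concentration",
    "kinetic_rate",
    "catalase_activity",
    "apx_activity",
    "sod_activity",
]


@dataclass(frozen=True)
class AssayConstants:
    """Extinction coefficients (mM^-1 cm^-1), path length and volumes."""

    epsilon_mda: float = 155.0     # 532-600 nm difference, mM^-1 cm^-1
    epsilon_cat: float = 39.4      # H2O2 at 240 nm
    epsilon_apx: float = 2.8       # 290 nm
    path_cm: float = 1.0
    reaction_volume_ml: float = 1.0
    extract_volume_ml: float = 0.1

    def __post_init__(self) -> None:
        for name in ("epsilon_mda", "epsilon_cat", "epsilon_apx", "path_cm",
                     "reaction_volume_ml", "extract_volume_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_(self, **kw) -> "AssayConstants":
        return replace(self, **kw)


@dataclass(frozen=True)
class KineticTrace:
    """Time course of absorbance during a rate assay."""

    times_s: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float = float("nan")
    assay: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or t.size < 3:
            raise ValueError("kinetic trace needs at least 3 points")
        if a.shape != t.shape:
            raise ValueError("times and absorbance must match")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "absorbance", a)


@dataclass
class EnzymeActivity:
    """Protein-normalised enzyme activity with its unit string."""

    value: float
    unit: str
    protein_mg: float
    flags: tuple[str, ...] = ()
    inhibition_pct: float | None = None  # SOD only


def mda_concentration(
    a532: float,
    a600: float,
    constants: AssayConstants = AssayConstants(),
    dilution: float = 1.0,
) -> tuple[float, bool]:
    """MDA concentration (uM) from the TBARS endpoint absorbances.

    C = (A532 - A600) / (epsilon_MDA * path) * dilution; the 600 nm
    reading corrects non-specific turbidity.  A negative corrected
    absorbance is reported as 0 with ``flagged=True``.
    """
    if dilution <= 0:
        raise ValueError("dilution factor must be positive")
    corrected = a532 - a600
    flagged = corrected < 0
    corrected = max(corrected, 0.0)
    conc_mm = corrected / (constants.epsilon_mda * constants.path_cm)
    return conc_mm * 1e3 * dilution, flagged  # mM -> uM


def kinetic_rate(trace: KineticTrace, window: tuple[float, float] | None = None) -> float:
    """Least-squares slope of absorbance vs time over a window, per minute.

    Sign is preserved (consumption assays give negative rates).  The
    window defaults to the full trace.
    """
    t, a = trace.times_s, trace.absorbance
    if window is not None:
        t0, t1 = window
        if t0 < t[0] - 1e-12 or t1 > t[-1] + 1e-12:
            raise ValueError("window outside the sampled trace")
        mask = (t >= t0) & (t <= t1)
        t, a = t[mask], a[mask]
    if t.size < 3:
        raise ValueError("fewer than 3 points in the kinetic window")
    slope_per_s = np.polyfit(t, a, 1)[0]
    return float(slope_per_s * 60.0)


def _rate_to_specific_activity(
    rate_abs_per_min: float,
    epsilon: float,
    constants: AssayConstants,
    protein_mg: float,
) -> float:
    """|dA/min| -> nmol substrate min^-1 mg protein^-1.

    |dA/min| / (epsilon * path) is the substrate turnover in mM min^-1
    inside the cuvette; times the reaction volume (mL) gives umol
    min^-1, scaled by the extract aliquot and the protein it carried.
    """
    turnover_mm_per_min = abs(rate_abs_per_min) / (epsilon * constants.path_cm)
    umol_per_min = turnover_mm_per_min * constants.reaction_volume_ml
    nmol_per_min = umol_per_min * 1e3
    return nmol_per_min / constants.extract_volume_ml / protein_mg


def catalase_activity(
    rate_abs_per_min: float,
    constants: AssayConstants = AssayConstants(),
    protein_mg: float = 1.0,
) -> EnzymeActivity:
    """Catalase activity from the 240 nm H2O2 consumption rate.

    Expects a negative (decreasing) rate; a positive rate is converted
    on its magnitude but flagged.
    """
    if protein_mg <= 0:
        raise ValueError("protein mass must be positive")
    flags = ("increasing_absorbance",) if rate_abs_per_min > 0 else ()
    value = _rate_to_specific_activity(rate_abs_per_min, constants.epsilon_cat,
                                       constants, protein_mg)
    return EnzymeActivity(value=value, unit="nmol H2O2 min^-1 mg protein^-1",
                          protein_mg=protein_mg, flags=flags)


def apx_activity(
    rate_abs_per_min: float,
    constants: AssayConstants = AssayConstants(),
    protein_mg: float = 1.0,
) -> EnzymeActivity:
    """Ascorbate peroxidase activity from the 290 nm consumption rate."""
    if protein_mg <= 0:
        raise ValueError("protein mass must be positive")
    flags = ("increasing_absorbance",) if rate_abs_per_min > 0 else ()
    value = _rate_to_specific_activity(rate_abs_per_min, constants.epsilon_apx,
                                       constants, protein_mg)
    return EnzymeActivity(value=value, unit="nmol ascorbate min^-1 mg protein^-1",
                          protein_mg=protein_mg, flags=flags)


def sod_activity(
    sample_rate: float,
    autoxidation_control_rate: float,
    protein_mg: float = 1.0,
) -> EnzymeActivity:
    """SOD activity as inhibition of pyrogallol autoxidation at 325 nm.

    inhibition% = (1 - sample_rate / control_rate) * 100; one unit is
    the amount causing 50% inhibition, reported per mg protein.
    Inhibition outside [0, 100] is clipped with a flag.
    """
    if autoxidation_control_rate <= 0:
        raise ValueError("autoxidation control rate must be positive")
    if protein_mg <= 0:
        raise ValueError("protein mass must be positive")
    inhibition = (1.0 - sample_rate / autoxidation_control_rate) * 100.0
    flags: tuple[str, ...] = ()
    if not 0.0 <= inhibition <= 100.0:
        flags = ("inhibition_clipped",)
        inhibition = min(max(inhibition, 0.0), 100.0)
    units = inhibition / 50.0  # 1 U = 50% inhibition
    return EnzymeActivity(value=units / protein_mg,
                          unit="U mg protein^-1 (1 U = 50% inhibition)",
                          protein_mg=protein_mg, flags=flags,
                          inhibition_pct=inhibition)
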