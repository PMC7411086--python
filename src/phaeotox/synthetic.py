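"""Synthetic dose-structured bioassay experiments with known ground truth.

Generates every input type the analysis stages consume -- cell-density
growth series, OJIP fluorescence transients, whole-cell absorbance
spectra, FAME peak tables, enzyme/TBARS assay readings and energy-budget
inputs -- for a multi-dose, multi-replicate design whose true effect
structure is known and recorded.  The default configuration emulates a
48 h diatom fluoxetine exposure: six doses (0, 0.3, 0.6, 20, 40,
80 ug/L), three replicates, initial density 2.7e5 cells/mL, a
log-logistic growth-inhibition curve with IC50 = 47.3 ug/L, and
monotone dose trends on the physiological endpoints whose default signs
mirror the correlations such experiments report (energy fluxes and
chlorophyll a down, C16:3 and lipid peroxidation up, ...).

All randomness flows from one master seed; each (dose, replicate) pair
owns an independent, order-insensitive substream.  With ``noise_cv = 0``
every generated table inverts exactly through the matching analysis
stage (growth -> IC50, transient -> JIP, spectrum -> pigments, ...).

The transient's parametric form is a sum of four sigmoidal rise phases
in log time (K, J, I, P), with amplitudes solved from a linear system
so that the noiseless curve passes *exactly* through (50 us, F0),
(300 us, F0 + VK*FV), (2 ms, F0 + VJ*FV), (30 ms, F0 + VI*FV) and ends
on the FM plateau.  The form is a modelling convenience that guarantees
the cardinal points by construction, not a mechanistic model of PSII
kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phaeotox.growth import GrowthSeries, log_logistic_inhibition
from phaeotox.ojip import FluorescenceTransient
from phaeotox.pigments import (
    AbsorbanceSpectrum,
    PigmentTemplateLibrary,
    default_library,
    model_spectrum,
)

__all__ = [
    "ExperimentConfig",
    "SyntheticBundle",
    "DEFAULT_EFFECT_SIGNS",
    "generate_growth",
    "generate_transient",
    "generate_spectrum",
    "generate_bundle",
]

# Default trend directions per generated endpoint (+1 up with dose, -1
# down, 0 flat), mirroring the dose-response correlations reported for
# fluoxetine-exposed P. tricornutum: energy fluxes, chlorophyll a,
# fucoxanthin, diadinoxanthin, C16:0/C16:1 down; quinone-pool turnover,
# pheophytin a, beta-carotene, C16:2/C16:3/C20:5, oxidative-stress
# markers, available energy and respiration up.
DEFAULT_EFFECT_SIGNS: dict[str, int] = {
    # OJIP primitives
    "f0": -1,          # ABS/CS proxy
    "fm": -1,          # stronger than f0 -> Fv/FM and TR0/DI0 decline
    "vj": -1,          # psi_E0/(1-psi_E0) rises
    "vi": +1,          # delta_R0/(1-delta_R0) declines
    "vk_ratio": +1,    # VK/VJ rises -> AOEC fraction declines
    "rise_shift": +1,  # slower rise -> larger S_M, N
    # pigments (template units)
    "chl_a": -1,
    "chl_c": +1,
    "pheophytin_a": +1,
    "beta_carotene": +1,
    "fucoxanthin": -1,
    "diadinoxanthin": -1,
    "diatoxanthin": 0,
    # fatty acids (relative %)
    "C14:0": 0,
    "C16:0": -1,
    "C16:1": -1,
    "C16:2n-7": +1,
    "C16:3": +1,
    "C16:4": 0,
    "C18:0": 0,
    "C18:3": 0,
    "C18:4": -1,
    "C20:4": 0,
    "C20:5": +1,
    # oxidative stress
    "mda_um": +1,
    "sod_inhibition_pct": +1,
    "apx_rate": +1,
    "cat_rate": 0,
    # energy budget
    "carb_mg_per_1e6": -1,
    "protein_mg_per_1e6": +1,
    "lipid_mg_per_1e6": +1,
    "ets_da490_per_min": +1,
}

# Relative change of each endpoint at 100% growth inhibition (fraction
# of its control value); fixed design constants of the generator.
_EFFECT_STRENGTH: dict[str, float] = {
    "f0": 0.35, "fm": 0.50, "vj": 0.20, "vi": 0.10, "vk_ratio": 0.30,
    "rise_shift": 0.30,
    "chl_a": 0.40, "chl_c": 0.50, "pheophytin_a": 1.50, "beta_carotene": 0.80,
    "fucoxanthin": 0.30, "diadinoxanthin": 0.40, "diatoxanthin": 0.0,
    "C14:0": 0.0, "C16:0": 0.25, "C16:1": 0.15, "C16:2n-7": 0.40,
    "C16:3": 0.50, "C16:4": 0.0, "C18:0": 0.0, "C18:3": 0.0, "C18:4": 0.30,
    "C20:4": 0.0, "C20:5": 0.10,
    "mda_um": 1.00, "sod_inhibition_pct": 1.20, "apx_rate": 0.80,
    "cat_rate": 0.0,
    "carb_mg_per_1e6": 0.30, "protein_mg_per_1e6": 0.30,
    "lipid_mg_per_1e6": 0.40, "ets_da490_per_min": 0.80,
}

# Control (zero-dose) values of each endpoint.
_BASELINE: dict[str, float] = {
    "f0": 500.0, "fm": 2500.0, "vj": 0.50, "vi": 0.85, "vk_ratio": 0.55,
    "rise_shift": 0.0,
    "chl_a": 1.00, "chl_c": 0.35, "pheophytin_a": 0.12, "beta_carotene": 0.12,
    "fucoxanthin": 0.60, "diadinoxanthin": 0.18, "diatoxanthin": 0.06,
    "C14:0": 7.0, "C16:0": 17.0, "C16:1": 23.0, "C16:2n-7": 7.0,
    "C16:3": 9.0, "C16:4": 1.5, "C18:0": 2.0, "C18:3": 1.0, "C18:4": 2.0,
    "C20:4": 1.5, "C20:5": 29.0,
    "mda_um": 0.50, "sod_inhibition_pct": 20.0, "apx_rate": 0.014,
    "cat_rate": 0.050,
    "carb_mg_per_1e6": 0.010, "protein_mg_per_1e6": 0.020,
    "lipid_mg_per_1e6": 0.015, "ets_da490_per_min": 0.030,
}

_FA_IDS = ["C14:0", "C16:0", "C16:1", "C16:2n-7", "C16:3", "C16:4",
           "C18:0", "C18:3", "C18:4", "C20:4", "C20:5"]

_CONTROL_GROWTH_RATE_PER_DAY = 0.9
_SAMPLE_TIMES_H = np.array([0.0, 24.0, 48.0, 72.0, 96.0])
_EXPOSURE_START_H = 48.0
_EXPOSURE_END_H = 96.0
_IS_MASS_UG = 10.0               # pentadecanoic acid added per sample
_SOD_CONTROL_RATE = 0.020        # pyrogallol autoxidation, dA325/min
_PROTEIN_MG = 0.50               # soluble protein per extract
_CULTURE_VOLUME_ML = 50.0        # harvested for the biochemical pellets
_ETS_ALIQUOT_FRACTION = 0.03     # 30 uL of a 1 mL homogenate


@dataclass(frozen=True)
class ExperimentConfig:
    """Design and ground-truth parameters of a synthetic experiment."""

    doses: tuple = (0.0, 0.3, 0.6, 20.0, 40.0, 80.0)
    n_replicates: int = 3
    true_ic50: float = 47.3
    hill_slope: float = 2.9
    initial_density: float = 2.7e5
    effect_signs: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIGNS))
    noise_cv: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        doses = tuple(sorted(float(d) for d in self.doses))
        if any(d < 0 for d in doses):
            raise ValueError("doses must be non-negative")
        if len(set(doses)) != len(doses):
            raise ValueError("doses must be distinct")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.true_ic50 <= 0:
            raise ValueError("true_ic50 must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.initial_density <= 0:
            raise ValueError("initial_density must be positive")
        unknown = set(self.effect_signs) - set(DEFAULT_EFFECT_SIGNS)
        if unknown:
            raise ValueError(f"unknown effect-sign endpoints: {sorted(unknown)}")
        if any(s not in (-1, 0, 1) for s in self.effect_signs.values()):
            raise ValueError("effect signs must be -1, 0 or +1")
        object.__setattr__(self, "doses", doses)
        signs = dict(DEFAULT_EFFECT_SIGNS)
        signs.update(self.effect_signs)
        object.__setattr__(self, "effect_signs", signs)

    def inhibition(self, dose: float) -> float:
        """Noiseless growth inhibition (%) at a dose."""
        return float(log_logistic_inhibition(np.array([dose]),
                                             self.true_ic50, self.hill_slope)[0])

    def endpoint_value(self, name: str, dose: float) -> float:
        """Noiseless ground-truth value of a generator endpoint at a dose."""
        sign = self.effect_signs[name]
        strength = _EFFECT_STRENGTH[name]
        base = _BASELINE[name]
        if name == "rise_shift":  # additive shift in log10 time, not relative
            return sign * strength * self.inhibition(dose) / 100.0
        return base * (1.0 + sign * strength * self.inhibition(dose) / 100.0)


@dataclass
class SyntheticBundle:
    """All generated tables of one experiment plus the generating truth.

    Per-replicate containers are dicts keyed by ``(dose, replicate)``.
    """

    config: ExperimentConfig
    growth: dict
    transients: dict
    spectra: dict
    fa_tables: dict
    assays: dict
    biochem: dict
    ground_truth: dict

    def replicates(self):
        return list(self.growth)


def _rng_for(config: ExperimentConfig, dose_idx: int, rep_idx: int,
             stream: int = 0) -> np.random.Generator:
    # substreams keyed by position in the design, not by iteration order
    ss = np.random.SeedSequence(entropy=config.seed,
                                spawn_key=(dose_idx, rep_idx, stream))
    return np.random.default_rng(ss)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# growth


def _noiseless_densities(config: ExperimentConfig, dose: float) -> np.ndarray:
    """Exponential growth; treated cultures reach a density reduced by the
    log-logistic inhibition fraction at the exposure endpoint."""
    mu = _CONTROL_GROWTH_RATE_PER_DAY / 24.0  # per hour
    n = config.initial_density * np.exp(mu * _SAMPLE_TIMES_H)
    inhib = config.inhibition(dose) / 100.0
    if inhib > 0:
        tau = np.clip((_SAMPLE_TIMES_H - _EXPOSURE_START_H)
                      / (_EXPOSURE_END_H - _EXPOSURE_START_H), 0.0, None)
        n = n * (1.0 - inhib) ** tau
    return n


def generate_growth(config: ExperimentConfig) -> dict:
    """Growth series for every (dose, replicate) of the design.

    Controls grow exponentially from ``initial_density``; treated
    replicates end the exposure window with a relative density
    reduction equal to the log-logistic inhibition at their dose.
    Multiplicative lognormal noise with CV ``noise_cv`` on every count.
    """
    out = {}
    for di, dose in enumerate(config.doses):
        clean = _noiseless_densities(config, dose)
        for ri in range(config.n_replicates):
            rng = _rng_for(config, di, ri, stream=0)
            noisy = clean * _lognormal_factor(rng, config.noise_cv, clean.shape)
            out[(dose, ri)] = GrowthSeries(
                times=_SAMPLE_TIMES_H.copy(), densities=noisy,
                treatment=dose, replicate_id=f"d{di}r{ri}",
            )
    return out


# ---------------------------------------------------------------------------
# OJIP transients

# log-spaced instrument grid with the cardinal times included exactly
_DEFAULT_TIMES = np.unique(np.concatenate([
    np.geomspace(1e-5, 2.0, 140), [50e-6, 300e-6, 2e-3, 30e-3]]))

# log10-time centers and widths of the K, J, I, P rise phases
_PHASE_CENTERS = (-3.8, -3.0, -2.1, -0.9)
_PHASE_WIDTHS = (0.18, 0.15, 0.18, 0.20)

_X_O, _X_K, _X_J, _X_I = math.log10(50e-6), math.log10(300e-6), \
    math.log10(2e-3), math.log10(30e-3)


def _sigmoid(x, c, w):
    return 1.0 / (1.0 + np.exp(-(np.asarray(x) - c) / w))


def generate_transient(
    target_params: dict,
    times: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate_id: str = "",
    treatment: float = 0.0,
) -> FluorescenceTransient:
    """One OJIP transient passing exactly through its cardinal points.

    ``target_params`` must contain ``f0``, ``fm``, ``vj``, ``vi``
    (0 < VJ <= VI <= 1, FM > F0); optional ``vk`` (default
    0.55 * VJ) and ``rise_shift`` (log10-time shift of the I and P
    phases, slowing the rise).  The noiseless curve is a sum of four
    log-time sigmoid phases whose amplitudes solve the interpolation
    conditions at O, K, J, I and the final plateau; Gaussian noise of
    standard deviation ``noise_sd`` is added when positive.
    """
    p = dict(target_params)
    f0, fm, vj, vi = (float(p["f0"]), float(p["fm"]),
                      float(p["vj"]), float(p["vi"]))
    vk = float(p.get("vk", 0.55 * vj))
    shift = float(p.get("rise_shift", 0.0))
    if not fm > f0 > 0:
        raise ValueError("need FM > F0 > 0")
    if not 0.0 < vj <= vi <= 1.0:
        raise ValueError("need 0 < VJ <= VI <= 1")
    if not 0.0 < vk < vj:
        raise ValueError("need 0 < VK < VJ")
    t = _DEFAULT_TIMES.copy() if times is None else np.asarray(times, dtype=float)
    x = np.log10(t)
    centers = list(_PHASE_CENTERS)
    centers[2] += shift
    centers[3] += shift

    knots = np.array([_X_O, _X_K, _X_J, _X_I, x[-1]])
    targets = np.array([0.0, vk, vj, vi, 1.0])
    design = np.column_stack(
        [_sigmoid(knots, c, w) for c, w in zip(centers, _PHASE_WIDTHS)]
        + [np.ones_like(knots)]
    )
    coeffs = np.linalg.solve(design, targets)

    v = sum(a * _sigmoid(x, c, w)
            for a, c, w in zip(coeffs[:4], centers, _PHASE_WIDTHS)) + coeffs[4]
    f = f0 + (fm - f0) * v
    if np.any(np.diff(f) < -1e-9 * (fm - f0)):
        raise ValueError("generated transient is not monotone; "
                         "adjust target parameters")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = np.maximum(f + rng.normal(0.0, noise_sd, f.shape), 1e-6)
    return FluorescenceTransient(times=t, fluorescence=f,
                                 replicate_id=replicate_id, treatment=treatment)


def _transient_params(config: ExperimentConfig, dose: float) -> dict:
    vj = config.endpoint_value("vj", dose)
    return {
        "f0": config.endpoint_value("f0", dose),
        "fm": config.endpoint_value("fm", dose),
        "vj": vj,
        "vi": config.endpoint_value("vi", dose),
        "vk": config.endpoint_value("vk_ratio", dose) * vj,
        "rise_shift": config.endpoint_value("rise_shift", dose),
    }


# ---------------------------------------------------------------------------
# spectra


def generate_spectrum(
    concentrations: dict,
    library: PigmentTemplateLibrary | None = None,
    baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate_id: str = "",
    treatment: float = 0.0,
) -> AbsorbanceSpectrum:
    """Forward-model an extract spectrum from pigment concentrations.

    spectrum = sum_p c_p template_p + baseline (+ Gaussian noise) on
    the standard 350-750 nm grid.  Raises KeyError for pigments absent
    from the library.
    """
    lib = library if library is not None else default_library()
    clean = model_spectrum(concentrations, lib, baseline)
    ab = clean.absorbance
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ab = ab + rng.normal(0.0, noise_sd, ab.shape)
    return AbsorbanceSpectrum(wavelengths=clean.wavelengths, absorbance=ab,
                              replicate_id=replicate_id, treatment=treatment)


# ---------------------------------------------------------------------------
# fatty acids, assays, biochemistry


def _fa_relative_pct(config: ExperimentConfig, dose: float) -> dict:
    weights = {fa: config.endpoint_value(fa, dose) for fa in _FA_IDS}
    total = sum(weights.values())
    return {fa: w / total * 100.0 for fa, w in weights.items()}


def _fa_peak_table(config: ExperimentConfig, dose: float,
                   rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    rel = _fa_relative_pct(config, dose)
    total_mass_ug = 25.0  # total identified FA mass per pellet
    is_area = 1e5
    rows = [{"fa_id": "C15:0", "peak_area": is_area}]
    truth_masses = {}
    for fa, pct in rel.items():
        mass = pct / 100.0 * total_mass_ug
        mass *= float(_lognormal_factor(rng, config.noise_cv))
        truth_masses[fa] = mass
        rows.append({"fa_id": fa,
                     "peak_area": mass / _IS_MASS_UG * is_area})
    return pd.DataFrame(rows), {"relative_pct": rel, "masses_ug": truth_masses}


def _assay_data(config: ExperimentConfig, dose: float,
                rng: np.random.Generator) -> tuple[dict, dict]:
    mda = config.endpoint_value("mda_um", dose) \
        * float(_lognormal_factor(rng, config.noise_cv))
    a600 = 0.020
    a532 = a600 + mda / 1e3 * 155.0  # 1 cm path, no dilution

    def trace(slope_per_min: float, assay: str, wl: float) -> pd.DataFrame:
        times = np.linspace(0.0, 180.0, 13)
        absorb = 0.5 + slope_per_min / 60.0 * times
        if config.noise_cv > 0:
            absorb = absorb + rng.normal(
                0.0, config.noise_cv * 0.002, absorb.shape)
        return pd.DataFrame({"time_s": times, "absorbance": absorb,
                             "assay": assay, "wavelength_nm": wl})

    cat_rate = -config.endpoint_value("cat_rate", dose) \
        * float(_lognormal_factor(rng, config.noise_cv))
    apx_rate = -config.endpoint_value("apx_rate", dose) \
        * float(_lognormal_factor(rng, config.noise_cv))
    sod_inhib = config.endpoint_value("sod_inhibition_pct", dose)
    sod_sample_rate = _SOD_CONTROL_RATE * (1.0 - sod_inhib / 100.0) \
        * float(_lognormal_factor(rng, config.noise_cv))

    data = {
        "a532": a532,
        "a600": a600,
        "protein_mg": _PROTEIN_MG,
        "traces": {
            "cat": trace(cat_rate, "cat", 240.0),
            "apx": trace(apx_rate, "apx", 290.0),
            "sod_sample": trace(sod_sample_rate, "sod_sample", 325.0),
            "sod_control": trace(_SOD_CONTROL_RATE, "sod_control", 325.0),
        },
    }
    truth = {"mda_um": mda, "cat_rate": cat_rate, "apx_rate": apx_rate,
             "sod_inhibition_pct": sod_inhib,
             "sod_sample_rate": sod_sample_rate,
             "sod_control_rate": _SOD_CONTROL_RATE}
    return data, truth


def _biochem_data(config: ExperimentConfig, dose: float, cells: float,
                  rng: np.random.Generator) -> tuple[dict, dict]:
    per_million = cells / 1e6
    carb = config.endpoint_value("carb_mg_per_1e6", dose) * per_million \
        * float(_lognormal_factor(rng, config.noise_cv))
    prot = config.endpoint_value("protein_mg_per_1e6", dose) * per_million \
        * float(_lognormal_factor(rng, config.noise_cv))
    lip = config.endpoint_value("lipid_mg_per_1e6", dose) * per_million \
        * float(_lognormal_factor(rng, config.noise_cv))
    ets = config.endpoint_value("ets_da490_per_min", dose) \
        * float(_lognormal_factor(rng, config.noise_cv))
    data = {"carb_mg": carb, "protein_mg": prot, "lipid_mg": lip,
            "ets_da490_per_min": ets, "cells": cells,
            "ets_cells": cells * _ETS_ALIQUOT_FRACTION}
    return data, dict(data)


def generate_bundle(config: ExperimentConfig) -> SyntheticBundle:
    """Generate the complete experiment: every input type, all replicates.

    Ground truth records, per dose: the inhibition percentage, every
    endpoint's noiseless value, and per-replicate realised values where
    noise applies.  Re-running with the same config is bit-identical.
    """
    growth = generate_growth(config)
    transients, spectra, fa_tables, assays, biochem = {}, {}, {}, {}, {}
    truth: dict = {
        "ic50": config.true_ic50,
        "hill_slope": config.hill_slope,
        "inhibition_pct": {d: config.inhibition(d) for d in config.doses},
        "endpoints": {
            name: {d: config.endpoint_value(name, d) for d in config.doses}
            for name in DEFAULT_EFFECT_SIGNS
        },
        "fa_relative_pct": {d: _fa_relative_pct(config, d)
                            for d in config.doses},
        "per_replicate": {},
    }
    lib = default_library()
    for di, dose in enumerate(config.doses):
        tp = _transient_params(config, dose)
        pig = {p: config.endpoint_value(p, dose) for p in
               ("chl_a", "chl_c", "pheophytin_a", "beta_carotene",
                "fucoxanthin", "diadinoxanthin", "diatoxanthin")}
        for ri in range(config.n_replicates):
            key = (dose, ri)
            rid = f"d{di}r{ri}"
            rng = _rng_for(config, di, ri, stream=1)
            child_seeds = rng.integers(0, 2**31 - 1, size=2)
            transients[key] = generate_transient(
                tp, noise_sd=config.noise_cv * 0.02 * tp["fm"],
                seed=int(child_seeds[0]), replicate_id=rid, treatment=dose)
            spectra[key] = generate_spectrum(
                pig, lib, baseline=(0.02, 0.01),
                noise_sd=config.noise_cv * 0.01,
                seed=int(child_seeds[1]), replicate_id=rid, treatment=dose)
            fa_tables[key], fa_truth = _fa_peak_table(config, dose, rng)
            assays[key], assay_truth = _assay_data(config, dose, rng)
            cells = growth[key].densities[-1] * _CULTURE_VOLUME_ML
            biochem[key], bio_truth = _biochem_data(config, dose, cells, rng)
            truth["per_replicate"][key] = {
                "transient_params": dict(tp),
                "pigments": dict(pig),
                "fa": fa_truth,
                "assays": assay_truth,
                "biochem": bio_truth,
            }
    return SyntheticBundle(config=config, growth=growth, transients=transients,
                           spectra=spectra, fa_tables=fa_tables, assays=assays,
                           biochem=biochem, ground_truth=truth)
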