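"""End-to-end orchestration: simulate -> per-stage analyses -> summary.

``run_pipeline`` executes the full analysis chain on either a synthetic
experiment (``simulate: true``) or user-supplied CSV tables, writing one
CSV per stage, a machine-readable ``summary.json`` and a run log that
records constants, switches, seeds, input hashes and software version.
Any stage failure aborts with a stage-scoped message; outputs of the
stages already completed are retained.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from phaeotox import __version__
from phaeotox.assays import (
    AssayConstants,
    KineticTrace,
    apx_activity,
    catalase_activity,
    kinetic_rate,
    mda_concentration,
    sod_activity,
)
from phaeotox.energy import EnergyConstants, energy_budget
from phaeotox.fatty_acids import quantify, saturation_summary
from phaeotox.growth import fit_ic50, relative_inhibition, specific_growth_rate
from phaeotox.io import (
    RunConfig,
    bundle_to_tables,
    growth_from_table,
    read_table,
    spectra_from_table,
    transients_from_table,
    write_table,
)
from phaeotox.multivariate import cap, kruskal_wallis_letters, spearman_dose
from phaeotox.ojip import (
    aoec_fraction,
    compute_jip,
    extract_cardinal_points,
    grouping_probability,
)
from phaeotox.pigments import fit_pigments
from phaeotox.synthetic import ExperimentConfig, generate_bundle

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("phaeotox")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_tables(config: RunConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    sep, dec = config.csv.get("sep", ","), config.csv.get("decimal", ".")
    if config.simulate:
        exp = ExperimentConfig(seed=config.seed, **config.synthetic)
        bundle = generate_bundle(exp)
        tables = bundle_to_tables(bundle)
        for kind, df in tables.items():
            write_table(df, outdir / "inputs" / f"{kind}.csv", sep, dec)
        return tables
    tables = {}
    for kind, path in config.inputs.items():
        df, errors = read_table(path, kind, sep=sep, decimal=dec)
        for e in errors:
            log.warning("%s line %d: %s", path, e.line, e.message)
        tables[kind] = df
    return tables


def _stage_growth(tables, config):
    t0, t1 = config.switches["growth_window_h"]
    series = growth_from_table(tables["growth"])
    rows = []
    for (dose, rid), s in series.items():
        rows.append({"dose_ug_per_l": dose, "replicate": rid,
                     "mu_per_day": specific_growth_rate(s, (t0, t1)),
                     "final_density": s.density_at(t1)})
    df = pd.DataFrame(rows)
    control = df[df["dose_ug_per_l"] == df["dose_ug_per_l"].min()]
    control_mean = control["final_density"].mean()
    df["inhibition_pct"] = [
        relative_inhibition(n, control_mean) for n in df["final_density"]]
    per_dose = df.groupby("dose_ug_per_l")["inhibition_pct"].mean()
    fit = fit_ic50(per_dose.index.to_numpy(), per_dose.to_numpy(),
                   method=config.switches["ic50_method"])
    summary = {"ic50_ug_per_l": fit.ic50, "hill_slope": fit.hill_slope,
               "method": fit.method, "reached": fit.reached,
               "stimulation_flag": fit.stimulation_flag}
    return df, summary


def _stage_jip(tables, config):
    transients = transients_from_table(tables["ojip"])
    doses = sorted({d for d, _ in transients})
    control_dose = doses[0]
    controls = [t for (d, _), t in transients.items() if d == control_dose]
    params = {k: compute_jip(extract_cardinal_points(t), t,
                             abs_cs_proxy=config.switches["abs_cs_proxy"])
              for k, t in transients.items()}
    control_params = [params[k] for k in params if k[0] == control_dose]
    # control reference for the comparative parameters: mean VK/VJ of the
    # control replicates; first control transient as the L-band reference
    import dataclasses as _dc
    ref = _dc.replace(control_params[0],
                      VK=float(np.mean([p.VK for p in control_params])),
                      VJ=float(np.mean([p.VJ for p in control_params])))
    ref_tr = controls[0]
    rows = []
    for (dose, rid), jp in params.items():
        row = {"dose_ug_per_l": dose, "replicate": rid, **jp.as_dict()}
        row["aoec"] = aoec_fraction(jp, ref)
        row["p_g"] = grouping_probability(transients[(dose, rid)], ref_tr)
        rows.append(row)
    return pd.DataFrame(rows), {"abs_cs_proxy": config.switches["abs_cs_proxy"],
                                "control_dose": control_dose}


def _stage_pigments(tables, config):
    spectra = spectra_from_table(tables["spectra"])
    rows = []
    for (dose, rid), sp in spectra.items():
        fit = fit_pigments(sp)
        rows.append({"dose_ug_per_l": dose, "replicate": rid,
                     **fit.concentrations,
                     "residual_norm": fit.residual_norm,
                     "converged": fit.converged})
    return pd.DataFrame(rows), {}


def _stage_fa(tables, config):
    df = tables["fa"]
    rows = []
    for (dose, rid), grp in df.groupby(["dose_ug_per_l", "replicate"]):
        profile = quantify(grp[["fa_id", "peak_area"]], is_mass=10.0,
                           replicate_id=str(rid), treatment=float(dose))
        summ = saturation_summary(profile)
        row = {"dose_ug_per_l": float(dose), "replicate": str(rid),
               **{f"pct_{fa}": p for fa, p in profile.relative_pct.items()},
               "sfa_pct": summ.sfa_pct, "mufa_pct": summ.mufa_pct,
               "pufa_pct": summ.pufa_pct, "ufa_pct": summ.ufa_pct,
               "sfa_ufa": summ.sfa_ufa, "pufa_sfa": summ.pufa_sfa,
               "dbi": summ.dbi}
        rows.append(row)
    return pd.DataFrame(rows), {}


def _stage_assays(tables, config):
    consts = AssayConstants(**config.constants.get("assay", {}))
    endpoints = tables["assay_endpoints"]
    kinetics = tables["assay_kinetics"]
    rows = []
    for (dose, rid), grp in kinetics.groupby(["dose_ug_per_l", "replicate"]):
        rates = {}
        for assay, trace in grp.groupby("assay"):
            trace = trace.sort_values("time_s")
            rates[assay] = kinetic_rate(KineticTrace(
                times_s=trace["time_s"].to_numpy(),
                absorbance=trace["absorbance"].to_numpy(), assay=str(assay)))
        end = endpoints[(endpoints["dose_ug_per_l"] == dose)
                        & (endpoints["replicate"] == rid)].iloc[0]
        protein = float(end["protein_mg"])
        mda, mda_flag = mda_concentration(float(end["a532"]),
                                          float(end["a600"]), consts)
        cat = catalase_activity(rates["cat"], consts, protein)
        apx = apx_activity(rates["apx"], consts, protein)
        sod = sod_activity(abs(rates["sod_sample"]), abs(rates["sod_control"]),
                           protein)
        rows.append({"dose_ug_per_l": float(dose), "replicate": str(rid),
                     "mda_um": mda, "mda_flagged": mda_flag,
                     "cat_activity": cat.value, "apx_activity": apx.value,
                     "sod_activity": sod.value,
                     "sod_inhibition_pct": sod.inhibition_pct})
    return pd.DataFrame(rows), {"constants": consts.__dict__}


def _stage_energy(tables, config):
    consts = EnergyConstants(
        epsilon_unit=config.switches["formazan_epsilon_unit"],
        **config.constants.get("energy", {}))
    rows = []
    for _, row in tables["biochem"].iterrows():
        budget = energy_budget(
            carb_mg=float(row["carb_mg"]), protein_mg=float(row["protein_mg"]),
            lipid_mg=float(row["lipid_mg"]),
            delta_a490_per_min=float(row["ets_da490_per_min"]),
            cells=float(row["ets_cells"]), constants=consts)
        rows.append({"dose_ug_per_l": float(row["dose_ug_per_l"]),
                     "replicate": str(row["replicate"]),
                     "ea_mj_per_1e6": budget.ea_mj,
                     "ec_mj_per_1e6_per_h": budget.ec_mj_per_h,
                     "cea_h": budget.cea_h,
                     "cea_undefined": budget.undefined_cea})
    return pd.DataFrame(rows), {"epsilon_unit": consts.epsilon_unit}


def _stage_stats(stage_outputs, config):
    """Kruskal-Wallis letters and Spearman dose correlations per endpoint."""
    alpha = config.switches["alpha"]
    rows = []
    for stage, endpoints in (
        ("growth", ["mu_per_day", "inhibition_pct"]),
        ("pigments", ["chl_a", "chl_c", "pheophytin_a", "beta_carotene",
                      "fucoxanthin", "diadinoxanthin", "diatoxanthin"]),
        ("fa", ["sfa_pct", "mufa_pct", "pufa_pct", "dbi"]),
        ("assays", ["mda_um", "cat_activity", "apx_activity", "sod_activity"]),
        ("energy", ["ea_mj_per_1e6", "ec_mj_per_1e6_per_h", "cea_h"]),
        ("jip", ["phi_P0", "abs_cs", "tr_cs", "et_cs", "di_cs", "rc_cs",
                 "S_M", "N", "aoec"]),
    ):
        df = stage_outputs.get(stage)
        if df is None:
            continue
        doses = df["dose_ug_per_l"].to_numpy(dtype=float)
        for col in endpoints:
            if col not in df.columns:
                continue
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                continue
            kw = kruskal_wallis_letters(vals, doses, alpha=alpha)
            sp = spearman_dose(vals, doses)
            rows.append({"stage": stage, "endpoint": col,
                         "kw_H": kw.H, "kw_p": kw.p,
                         "letters": json.dumps(
                             {str(k): v for k, v in kw.letters.items()}),
                         "spearman_rho": sp.rho,
                         "spearman_signed_rho2": sp.signed_rho2,
                         "spearman_p": sp.p})
    return pd.DataFrame(rows), {}


def _feature_matrix_optical(tables):
    transients = transients_from_table(tables["ojip"])
    grid = None
    feats, groups = [], []
    for (dose, rid), tr in sorted(transients.items()):
        if grid is None:
            grid = tr.times
        feats.append(np.interp(np.log10(grid), np.log10(tr.times),
                               tr.fluorescence))
        groups.append(dose)
    return np.array(feats), np.array(groups)


def _feature_matrix_fa(fa_df):
    wide = fa_df.set_index(["dose_ug_per_l", "replicate"])
    cols = [c for c in wide.columns if c.startswith("pct_")]
    wide = wide[cols].sort_index()
    return wide.to_numpy(dtype=float), wide.index.get_level_values(0).to_numpy()


def _stage_cap(tables, stage_outputs, config):
    sw = config.switches
    results = {}
    x_opt, g_opt = _feature_matrix_optical(tables)
    x_fa, g_fa = _feature_matrix_fa(stage_outputs["fa"])
    for name, (x, g) in (("optical", (x_opt, g_opt)),
                         ("fatty_acids", (x_fa, g_fa))):
        res = cap(x, g, m_rule=sw["cap_m_rule"], m=sw["cap_m"],
                  n_perm=sw["n_perm"], seed=config.seed)
        results[name] = res
    rows = [{"features": name, "m": r.m, "accuracy_pct": r.accuracy,
             "trace_stat": r.trace_stat, "p_permutation": r.p_permutation,
             "n_permutations": r.n_permutations, "seed": r.seed,
             "confusion": json.dumps(r.confusion.tolist()),
             "groups": json.dumps([float(g) for g in r.group_labels])}
            for name, r in results.items()]
    return pd.DataFrame(rows), {name: r.accuracy for name, r in results.items()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the summary dict (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    sep, dec = config.csv.get("sep", ","), config.csv.get("decimal", ".")
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "switches": config.switches,
        "stages": {},
    }
    try:
        try:
            tables = _load_tables(config, outdir)
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
        summary["input_hashes"] = {
            kind: hashlib.sha256(
                df.to_csv(index=False).encode()).hexdigest()[:16]
            for kind, df in tables.items()}

        stage_outputs: dict[str, pd.DataFrame] = {}
        stages = [
            ("growth", lambda: _stage_growth(tables, config)),
            ("jip", lambda: _stage_jip(tables, config)),
            ("pigments", lambda: _stage_pigments(tables, config)),
            ("fa", lambda: _stage_fa(tables, config)),
            ("assays", lambda: _stage_assays(tables, config)),
            ("energy", lambda: _stage_energy(tables, config)),
            ("stats", lambda: _stage_stats(stage_outputs, config)),
            ("cap", lambda: _stage_cap(tables, stage_outputs, config)),
        ]
        for name, fn in stages:
            log.info("running stage %s", name)
            try:
                df, meta = fn()
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
            stage_outputs[name] = df
            write_table(df.round(10), outdir / f"{name}.csv", sep, dec)
            summary["stages"][name] = {
                "rows": len(df), "meta": meta,
                "output_hash": _sha256(outdir / f"{name}.csv")}
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=str)
        log.info("pipeline complete")
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()
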