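"""CSV readers/writers, run configuration and table schemas.

All instrument-facing I/O is CSV (UTF-8).  The default dialect is
comma-delimited with dot decimals; a dialect switch supports
semicolon-delimited, comma-decimal exports common from European
instrument software.  Readers are schema-checked: required columns must
be present, numeric fields are validated row by row, and in permissive
mode corrupted rows are reported with their line numbers while the
remaining rows load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from phaeotox.growth import GrowthSeries
from phaeotox.ojip import FluorescenceTransient
from phaeotox.pigments import AbsorbanceSpectrum

__all__ = [
    "SCHEMAS",
    "RowError",
    "TableReadError",
    "read_table",
    "write_table",
    "RunConfig",
    "bundle_to_tables",
    "growth_from_table",
    "transients_from_table",
    "spectra_from_table",
]

# column name -> required dtype ("float" or "str") per input table kind
SCHEMAS: dict[str, dict[str, str]] = {
    "growth": {"time_h": "float", "density_cells_per_ml": "float",
               "dose_ug_per_l": "float", "replicate": "str"},
    "ojip": {"time_s": "float", "fluorescence": "float",
             "dose_ug_per_l": "float", "replicate": "str"},
    "spectra": {"wavelength_nm": "float", "absorbance": "float",
                "dose_ug_per_l": "float", "replicate": "str"},
    "fa": {"fa_id": "str", "peak_area": "float",
           "dose_ug_per_l": "float", "replicate": "str"},
    "assay_endpoints": {"a532": "float", "a600": "float",
                        "protein_mg": "float",
                        "dose_ug_per_l": "float", "replicate": "str"},
    "assay_kinetics": {"time_s": "float", "absorbance": "float",
                       "assay": "str", "dose_ug_per_l": "float",
                       "replicate": "str"},
    "biochem": {"carb_mg": "float", "protein_mg": "float", "lipid_mg": "float",
                "ets_da490_per_min": "float", "cells": "float",
                "ets_cells": "float", "dose_ug_per_l": "float",
                "replicate": "str"},
}


@dataclass
class RowError:
    line: int          # 1-based file line (header is line 1)
    message: str


class TableReadError(ValueError):
    """Raised on schema violations (strict mode) or missing columns."""


def read_table(
    path,
    schema: str | dict,
    permissive: bool = True,
    sep: str = ",",
    decimal: str = ".",
) -> tuple[pd.DataFrame, list[RowError]]:
    """Read and validate a CSV against a named or explicit schema.

    Returns the typed table and the list of row-level errors.  Rows
    failing numeric conversion are dropped in permissive mode (and
    reported with their file line numbers) or raise in strict mode.
    Extra columns are preserved.
    """
    spec = SCHEMAS[schema] if isinstance(schema, str) else schema
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep=sep, decimal=decimal, dtype=str,
                     comment="#", skip_blank_lines=True)
    missing = set(spec) - set(df.columns)
    if missing:
        raise TableReadError(
            f"{path.name}: missing required columns {sorted(missing)}")
    errors: list[RowError] = []
    bad = np.zeros(len(df), dtype=bool)
    for col, kind in spec.items():
        if kind != "float":
            continue
        converted = pd.to_numeric(
            df[col].str.replace(",", ".", regex=False) if decimal == ","
            else df[col], errors="coerce")
        for i in np.flatnonzero(converted.isna() & df[col].notna()):
            errors.append(RowError(line=int(i) + 2,
                                   message=f"column {col!r}: unparseable "
                                           f"value {df[col].iloc[i]!r}"))
        bad |= converted.isna().to_numpy()
        df[col] = converted
    if errors and not permissive:
        raise TableReadError(
            "; ".join(f"line {e.line}: {e.message}" for e in errors))
    return df[~bad].reset_index(drop=True), errors


def write_table(df: pd.DataFrame, path, sep: str = ",",
                decimal: str = ".") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, sep=sep, decimal=decimal)


# ---------------------------------------------------------------------------
# run configuration


_DEFAULT_SWITCHES = {
    "abs_cs_proxy": "F0",
    "formazan_epsilon_unit": "mM",
    "ic50_method": "log-logistic",
    "cap_m_rule": "max_loo",
    "cap_m": None,
    "n_perm": 999,
    "alpha": 0.05,
    "growth_window_h": [48.0, 96.0],
}


@dataclass
class RunConfig:
    """Structured run configuration (YAML with sections).

    Sections: ``output_dir``, ``seed``, ``simulate`` (bool),
    ``synthetic`` (ExperimentConfig overrides), ``inputs`` (paths per
    table kind when not simulating), ``constants`` (``assay`` and
    ``energy`` overrides), ``switches`` (analysis options) and ``csv``
    (dialect).
    """

    output_dir: str = "phaeotox_run"
    seed: int = 0
    simulate: bool = True
    synthetic: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    constants: dict = field(default_factory=dict)
    switches: dict = field(default_factory=dict)
    csv: dict = field(default_factory=lambda: {"sep": ",", "decimal": "."})

    def __post_init__(self) -> None:
        sw = dict(_DEFAULT_SWITCHES)
        sw.update(self.switches)
        unknown = set(sw) - set(_DEFAULT_SWITCHES)
        if unknown:
            raise ValueError(f"unknown switches: {sorted(unknown)}")
        if sw["abs_cs_proxy"] not in ("F0", "FM"):
            raise ValueError("abs_cs_proxy must be 'F0' or 'FM'")
        if sw["formazan_epsilon_unit"] not in ("mM", "M"):
            raise ValueError("formazan_epsilon_unit must be 'mM' or 'M'")
        if sw["ic50_method"] not in ("log-logistic", "interpolation"):
            raise ValueError("ic50_method must be 'log-logistic' or "
                             "'interpolation'")
        if sw["cap_m_rule"] not in ("max_loo", "fixed"):
            raise ValueError("cap_m_rule must be 'max_loo' or 'fixed'")
        self.switches = sw
        if not self.simulate:
            missing = [k for k, p in self.inputs.items() if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(
                    f"input paths do not exist: "
                    f"{[(k, str(self.inputs[k])) for k in missing]}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        """Stable hash of the configuration, for output provenance."""
        blob = json.dumps(
            {k: getattr(self, k) for k in
             ("output_dir", "seed", "simulate", "synthetic", "inputs",
              "constants", "switches", "csv")},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# bundle <-> long tables


def bundle_to_tables(bundle) -> dict[str, pd.DataFrame]:
    """Flatten a synthetic bundle into the long CSV dialects read back
    by the analysis stages."""
    growth_rows, ojip_rows, spec_rows, fa_rows = [], [], [], []
    end_rows, kin_rows, bio_rows = [], [], []
    for key, series in bundle.growth.items():
        dose, _ = key
        rid = series.replicate_id
        for t, n in zip(series.times, series.densities):
            growth_rows.append({"time_h": t, "density_cells_per_ml": n,
                                "dose_ug_per_l": dose, "replicate": rid})
        tr = bundle.transients[key]
        for t, f in zip(tr.times, tr.fluorescence):
            ojip_rows.append({"time_s": t, "fluorescence": f,
                              "dose_ug_per_l": dose, "replicate": rid})
        sp = bundle.spectra[key]
        for wl, ab in zip(sp.wavelengths, sp.absorbance):
            spec_rows.append({"wavelength_nm": wl, "absorbance": ab,
                              "dose_ug_per_l": dose, "replicate": rid})
        fa = bundle.fa_tables[key]
        for _, row in fa.iterrows():
            fa_rows.append({"fa_id": row["fa_id"],
                            "peak_area": row["peak_area"],
                            "dose_ug_per_l": dose, "replicate": rid})
        asy = bundle.assays[key]
        end_rows.append({"a532": asy["a532"], "a600": asy["a600"],
                         "protein_mg": asy["protein_mg"],
                         "dose_ug_per_l": dose, "replicate": rid})
        for name, trace in asy["traces"].items():
            for _, row in trace.iterrows():
                kin_rows.append({"time_s": row["time_s"],
                                 "absorbance": row["absorbance"],
                                 "assay": name, "dose_ug_per_l": dose,
                                 "replicate": rid})
        bio = bundle.biochem[key]
        bio_rows.append({**{k: bio[k] for k in SCHEMAS["biochem"]
                            if k in bio},
                         "dose_ug_per_l": dose, "replicate": rid})
    return {
        "growth": pd.DataFrame(growth_rows),
        "ojip": pd.DataFrame(ojip_rows),
        "spectra": pd.DataFrame(spec_rows),
        "fa": pd.DataFrame(fa_rows),
        "assay_endpoints": pd.DataFrame(end_rows),
        "assay_kinetics": pd.DataFrame(kin_rows),
        "biochem": pd.DataFrame(bio_rows),
    }


def _per_replicate(df: pd.DataFrame):
    for (dose, rid), grp in df.groupby(["dose_ug_per_l", "replicate"],
                                       sort=True):
        yield float(dose), str(rid), grp


def growth_from_table(df: pd.DataFrame) -> dict:
    out = {}
    for dose, rid, grp in _per_replicate(df):
        grp = grp.sort_values("time_h")
        out[(dose, rid)] = GrowthSeries(
            times=grp["time_h"].to_numpy(),
            densities=grp["density_cells_per_ml"].to_numpy(),
            treatment=dose, replicate_id=rid)
    return out


def transients_from_table(df: pd.DataFrame) -> dict:
    out = {}
    for dose, rid, grp in _per_replicate(df):
        grp = grp.sort_values("time_s")
        out[(dose, rid)] = FluorescenceTransient(
            times=grp["time_s"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(),
            treatment=dose, replicate_id=rid)
    return out


def spectra_from_table(df: pd.DataFrame) -> dict:
    out = {}
    for dose, rid, grp in _per_replicate(df):
        grp = grp.sort_values("wavelength_nm")
        out[(dose, rid)] = AbsorbanceSpectrum(
            wavelengths=grp["wavelength_nm"].to_numpy(),
            absorbance=grp["absorbance"].to_numpy(),
            treatment=dose, replicate_id=rid)
    return out
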