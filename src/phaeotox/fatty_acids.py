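"""FAME peak-table quantification and fatty-acid saturation statistics.

Gas-chromatography FAME peak areas are converted to masses against a
pentadecanoic-acid (C15:0) internal standard, then to relative percent
profiles (internal standard excluded).  Saturation classes (SFA, MUFA,
PUFA) follow the double-bond count parsed from the shorthand identifier
``Cx:y`` (optionally with an n-position suffix, e.g. ``C16:2n-7``),
and membrane saturation is summarised by the double-bond index

    DBI = 2 * (%monoenes + 2*%dienes + 3*%trienes
               + 4*%tetraenes + 5*%pentaenes) / 100.

Fatty acids with more than five double bonds extend the pattern
(coefficient = bond count) with a warning.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "FattyAcidProfile",
    "SaturationSummary",
    "parse_fa_id",
    "quantify",
    "saturation_summary",
    "INTERNAL_STANDARD",
]

INTERNAL_STANDARD = "C15:0"

_FA_RE = re.compile(r"^C(\d{1,2}):(\d{1,2})(?:n-?(\d{1,2}))?$", re.IGNORECASE)


def parse_fa_id(fa_id: str) -> tuple[int, int, int | None]:
    """Parse ``Cx:y`` / ``Cx:yn-z`` into (chain length, double bonds, n-position)."""
    m = _FA_RE.match(fa_id.strip())
    if not m:
        raise ValueError(f"unparseable fatty-acid identifier {fa_id!r}")
    chain, bonds = int(m.group(1)), int(m.group(2))
    npos = int(m.group(3)) if m.group(3) else None
    return chain, bonds, npos


@dataclass
class FattyAcidProfile:
    """Quantified FAME profile of one replicate.

    ``table`` has one row per identified fatty acid (internal standard
    excluded) with columns fa_id, chain_length, double_bonds, peak_area,
    mass (same unit as the internal-standard mass) and relative_pct
    (sums to 100 over the table).
    """

    table: pd.DataFrame
    is_area: float
    is_mass: float
    replicate_id: str = ""
    treatment: float = 0.0
    cells: float | None = None  # cells in the extracted pellet, for per-cell totals

    @property
    def relative_pct(self) -> pd.Series:
        return self.table.set_index("fa_id")["relative_pct"]

    @property
    def total_mass(self) -> float:
        return float(self.table["mass"].sum())

    def mass_per_million_cells(self) -> float:
        if self.cells is None or self.cells <= 0:
            raise ValueError("cell count not available for per-cell totals")
        return self.total_mass * 1e6 / self.cells


@dataclass
class SaturationSummary:
    """Saturation classes, ratios, and the double-bond index."""

    sfa_pct: float
    mufa_pct: float
    pufa_pct: float
    ufa_pct: float
    sfa_ufa: float
    pufa_sfa: float
    dbi: float


def quantify(
    peak_table: pd.DataFrame,
    is_mass: float,
    is_id: str = INTERNAL_STANDARD,
    replicate_id: str = "",
    treatment: float = 0.0,
    cells: float | None = None,
) -> FattyAcidProfile:
    """Convert a FAME peak table into a quantified relative profile.

    Parameters
    ----------
    peak_table : DataFrame
        Columns ``fa_id`` and ``peak_area``; must include the internal
        standard row.
    is_mass : float
        Mass of internal standard added to the sample (any mass unit;
        output masses share it).

    Masses follow the peak-surface method,
    ``mass_i = area_i / area_IS * mass_IS``; relative percentages are
    over all identified fatty acids excluding the internal standard.
    """
    if is_mass <= 0:
        raise ValueError("internal standard mass must be positive")
    tbl = peak_table.copy()
    if "fa_id" not in tbl.columns or "peak_area" not in tbl.columns:
        raise ValueError("peak table needs columns fa_id and peak_area")
    is_rows = tbl[tbl["fa_id"].str.strip().str.upper() == is_id.upper()]
    if is_rows.empty:
        raise ValueError(f"internal standard {is_id} missing from peak table")
    is_area = float(is_rows["peak_area"].iloc[0])
    if is_area <= 0:
        raise ValueError("internal standard peak area must be positive")

    fa = tbl[tbl["fa_id"].str.strip().str.upper() != is_id.upper()].copy()
    parsed = fa["fa_id"].map(parse_fa_id)
    fa["chain_length"] = [p[0] for p in parsed]
    fa["double_bonds"] = [p[1] for p in parsed]
    fa["mass"] = fa["peak_area"] / is_area * is_mass
    total = fa["mass"].sum()
    if total <= 0:
        raise ValueError("no positive fatty-acid peaks besides the standard")
    fa["relative_pct"] = fa["mass"] / total * 100.0
    fa = fa[["fa_id", "chain_length", "double_bonds", "peak_area",
             "mass", "relative_pct"]].reset_index(drop=True)
    return FattyAcidProfile(table=fa, is_area=is_area, is_mass=float(is_mass),
                            replicate_id=replicate_id, treatment=treatment,
                            cells=cells)


def saturation_summary(profile: FattyAcidProfile) -> SaturationSummary:
    """Saturation classes and double-bond index of a relative profile.

    Classes by double-bond count: 0 -> SFA, 1 -> MUFA, >=2 -> PUFA;
    UFA = MUFA + PUFA.  DBI per the weighted unsaturation-class formula
    (module docstring), linear in class percentages.
    """
    tbl = profile.table
    bonds = tbl["double_bonds"]
    pct = tbl["relative_pct"]
    sfa = float(pct[bonds == 0].sum())
    mufa = float(pct[bonds == 1].sum())
    pufa = float(pct[bonds >= 2].sum())
    ufa = mufa + pufa
    if (bonds > 5).any():
        warnings.warn(
            "fatty acids with >5 double bonds present; DBI extends the "
            "class-weight pattern with coefficient = bond count"
        )
    dbi = 2.0 * float((bonds * pct).sum()) / 100.0
    return SaturationSummary(
        sfa_pct=sfa,
        mufa_pct=mufa,
        pufa_pct=pufa,
        ufa_pct=ufa,
        sfa_ufa=sfa / ufa if ufa > 0 else float("inf"),
        pufa_sfa=pufa / sfa if sfa > 0 else float("inf"),
        dbi=dbi,
    )
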