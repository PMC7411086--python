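"""Gauss-peak deconvolution of whole-cell pigment absorbance spectra.

Each pigment's absorbance spectrum in the extraction solvent (100%
acetone) is represented as a fixed sum of Gaussian bands; an extract
spectrum is then a non-negative linear combination of pigment templates
plus a smooth baseline.  Unmixing is a bounded linear least-squares
problem (non-negative pigment scales, unconstrained constant + linear
baseline), the linear Gauss-Peak-Spectra variant with fixed band
positions.

The shipped template table (``data/gps_library_synthetic.csv``) is a
constructed stand-in with literature-plausible band positions per
pigment; concentrations are reported in template units.  All round-trip
guarantees of :func:`fit_pigments` hold for any internally consistent
library supplied in its place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

__all__ = [
    "STANDARD_WAVELENGTHS",
    "AbsorbanceSpectrum",
    "PigmentTemplateLibrary",
    "PigmentConcentrations",
    "default_library",
    "model_spectrum",
    "fit_pigments",
]

# measurement grid: 350-750 nm at 0.5 nm, 801 points
STANDARD_WAVELENGTHS = np.arange(350.0, 750.5, 0.5)


@dataclass(frozen=True)
class AbsorbanceSpectrum:
    """Whole-cell extract absorbance on the standard 350-750 nm grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    replicate_id: str = ""
    treatment: float = 0.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.shape != ab.shape or wl.ndim != 1:
            raise ValueError("wavelengths and absorbance must be matched 1-D")
        if not np.all(np.isfinite(ab)):
            raise ValueError("absorbance must be finite")
        if wl.size != STANDARD_WAVELENGTHS.size or not np.allclose(
            wl, STANDARD_WAVELENGTHS
        ):
            raise ValueError(
                "spectrum must be on the 350-750 nm grid at 0.5 nm steps "
                "(801 points); resample before constructing"
            )
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)


class PigmentTemplateLibrary:
    """Per-pigment Gaussian band sets for spectral unmixing.

    Parameters
    ----------
    components : mapping
        pigment name -> list of (center_nm, sigma_nm, amplitude) bands.
    """

    def __init__(self, components: dict[str, list[tuple[float, float, float]]]):
        if not components:
            raise ValueError("library must contain at least one pigment")
        for name, bands in components.items():
            if len(bands) < 1:
                raise ValueError(f"pigment {name!r} has no Gaussian bands")
            for c, s, a in bands:
                if s <= 0:
                    raise ValueError(f"pigment {name!r}: band width must be > 0")
                if a < 0:
                    raise ValueError(f"pigment {name!r}: band amplitude must be >= 0")
        self.components = {k: [tuple(map(float, b)) for b in v]
                           for k, v in components.items()}

    @property
    def pigments(self) -> list[str]:
        return list(self.components)

    def template(self, pigment: str,
                 wavelengths: np.ndarray | None = None) -> np.ndarray:
        """Unit-concentration absorbance template of one pigment."""
        if pigment not in self.components:
            raise KeyError(f"pigment {pigment!r} not in library")
        wl = STANDARD_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths)
        out = np.zeros_like(wl, dtype=float)
        for center, sigma, amp in self.components[pigment]:
            out += amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        return out

    def design_matrix(self, wavelengths: np.ndarray | None = None) -> np.ndarray:
        """Columns = pigment templates on the grid, in ``self.pigments`` order."""
        wl = STANDARD_WAVELENGTHS if wavelengths is None else np.asarray(wavelengths)
        return np.column_stack([self.template(p, wl) for p in self.pigments])

    def condition_number(self) -> float:
        """Condition number of the template Gram matrix (collinearity diagnostic)."""
        a = self.design_matrix()
        return float(np.linalg.cond(a.T @ a))

    @classmethod
    def from_csv(cls, path) -> "PigmentTemplateLibrary":
        df = pd.read_csv(path, comment="#")
        comps: dict[str, list[tuple[float, float, float]]] = {}
        for _, row in df.iterrows():
            comps.setdefault(str(row["pigment"]), []).append(
                (float(row["center_nm"]), float(row["sigma_nm"]),
                 float(row["amplitude"]))
            )
        return cls(comps)


def default_library() -> PigmentTemplateLibrary:
    """The shipped acetone template library (synthetic stand-in, see module doc)."""
    ref = resources.files("phaeotox") / "data" / "gps_library_synthetic.csv"
    with resources.as_file(ref) as path:
        return PigmentTemplateLibrary.from_csv(path)


@dataclass
class PigmentConcentrations:
    """Unmixing result: per-pigment concentrations in template units."""

    concentrations: dict[str, float]
    baseline: tuple[float, float]  # constant, linear slope (per normalised nm)
    residual_norm: float
    converged: bool
    condition_number: float = field(default=float("nan"))

    def __getitem__(self, pigment: str) -> float:
        return self.concentrations[pigment]


def _baseline_columns(wl: np.ndarray) -> np.ndarray:
    # centred/scaled linear term keeps the baseline block well-conditioned
    return np.column_stack([np.ones_like(wl), (wl - 550.0) / 200.0])


def model_spectrum(
    concentrations: dict[str, float],
    library: PigmentTemplateLibrary,
    baseline_params: tuple[float, float] = (0.0, 0.0),
) -> AbsorbanceSpectrum:
    """Forward model: sum of scaled templates plus a constant + linear baseline."""
    unknown = set(concentrations) - set(library.pigments)
    if unknown:
        raise KeyError(f"pigments not in library: {sorted(unknown)}")
    wl = STANDARD_WAVELENGTHS
    ab = np.zeros_like(wl)
    for pigment, c in concentrations.items():
        if c < 0:
            raise ValueError(f"concentration of {pigment!r} must be >= 0")
        ab += c * library.template(pigment, wl)
    ab += _baseline_columns(wl) @ np.asarray(baseline_params, dtype=float)
    return AbsorbanceSpectrum(wavelengths=wl, absorbance=ab)


def fit_pigments(
    spectrum: AbsorbanceSpectrum,
    library: PigmentTemplateLibrary | None = None,
) -> PigmentConcentrations:
    """Unmix a spectrum into non-negative pigment concentrations.

    Bounded linear least squares: pigment scales constrained >= 0, the
    constant and linear baseline terms unconstrained.  Returns the
    concentrations, fitted baseline, residual 2-norm, a convergence
    flag (best iterate is returned regardless) and the library's Gram
    condition number.
    """
    lib = library if library is not None else default_library()
    wl = spectrum.wavelengths
    a = lib.design_matrix(wl)
    x = np.hstack([a, _baseline_columns(wl)])
    n_pig = a.shape[1]
    lower = np.r_[np.zeros(n_pig), -np.inf, -np.inf]
    res = lsq_linear(x, spectrum.absorbance, bounds=(lower, np.inf),
                     tol=1e-12, max_iter=200)
    conc = dict(zip(lib.pigments, (float(v) for v in res.x[:n_pig])))
    return PigmentConcentrations(
        concentrations=conc,
        baseline=(float(res.x[n_pig]), float(res.x[n_pig + 1])),
        residual_norm=float(np.linalg.norm(x @ res.x - spectrum.absorbance)),
        converged=bool(res.status > 0),
        condition_number=lib.condition_number(),
    )
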