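"""JIP-test analysis of OJIP chlorophyll-a fluorescence transients.

A dark-adapted photosynthetic cell illuminated with saturating light
shows a polyphasic fluorescence rise (the Kautsky curve) with cardinal
steps O (origin, F0 at 50 us), J (~2 ms), I (~30 ms) and P (peak, FM).
The JIP-test partitions the absorbed light energy into trapping,
electron transport and dissipation from these cardinal points.  The
parameter definitions follow the standard JIP-test conventions
(Strasser school); each formula is stated next to its computation.

Cross-section fluxes need a proxy for the absorption per cross-section
ABS/CS; the common conventions are ABS/CS ~ F0 ("CS0", default) or
ABS/CS ~ FM ("CSM"), selectable and recorded in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FluorescenceTransient",
    "CardinalPoints",
    "JipParameters",
    "extract_cardinal_points",
    "compute_jip",
    "aoec_fraction",
    "grouping_probability",
]

# Cardinal times of the JIP-test, seconds
T_O = 50e-6     # O step, operational F0
T_K = 300e-6    # K band (F300), also the M0 initial-slope point
T_J = 2e-3      # J step
T_I = 30e-3     # I step


@dataclass(frozen=True)
class FluorescenceTransient:
    """One OJIP fluorescence induction curve.

    ``times`` in seconds (log-spaced, covering 50 us through the P
    plateau), ``fluorescence`` in relative instrument units.
    """

    times: np.ndarray
    fluorescence: np.ndarray
    replicate_id: str = ""
    treatment: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        if t.ndim != 1 or t.size < 4:
            raise ValueError("transient needs at least 4 samples")
        if f.shape != t.shape:
            raise ValueError("times and fluorescence must match")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(f > 0):
            raise ValueError("fluorescence must be positive")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fluorescence", f)

    def at(self, time_s: float) -> float:
        """Fluorescence at an arbitrary time by log-time linear interpolation."""
        t, f = self.times, self.fluorescence
        if time_s < t[0] or time_s > t[-1]:
            raise ValueError(f"requested time {time_s} s outside sampled range "
                             f"[{t[0]}, {t[-1]}]")
        return float(np.interp(np.log10(time_s), np.log10(t), f))


@dataclass(frozen=True)
class CardinalPoints:
    """Fluorescence at the O, K, J, I steps and the P maximum."""

    F0: float     # 50 us
    F300: float   # 300 us (K band)
    FJ: float     # 2 ms
    FI: float     # 30 ms
    FM: float     # maximum over the transient
    degenerate: bool = False


_UNDEFINED = float("nan")


@dataclass
class JipParameters:
    """Derived JIP-test quantities for one transient.

    Relative variable fluorescences VJ, VI; initial slope M0 (per ms);
    complementary area above the curve and its normalisations S_M
    (ms) and turnover number N; quantum-yield ratios; phenomenological
    fluxes per cross-section; and flux ratios.  ``abs_cs_proxy``
    records which convention was used for ABS/CS.
    """

    F0: float
    FM: float
    VJ: float
    VI: float
    VK: float
    M0: float                # per ms
    area: float              # r.u. * s, above the curve up to t(FM)
    S_M: float               # ms
    N: float
    phi_P0: float            # 1 - F0/FM  (= Fv/FM)
    psi_E0: float            # 1 - VJ
    delta_R0: float          # (1 - VI) / (1 - VJ)
    abs_cs: float
    tr_cs: float
    et_cs: float
    di_cs: float
    rc_cs: float
    rc_abs: float
    tr0_di0: float           # phi_P0 / (1 - phi_P0)
    psi_ratio: float         # psi_E0 / (1 - psi_E0)
    delta_ratio: float       # delta_R0 / (1 - delta_R0)
    re0_rc: float            # (M0 / VJ) * (1 - VI)
    p_g: float = _UNDEFINED  # grouping probability (needs control reference)
    aoec: float = _UNDEFINED # active OEC fraction vs control
    abs_cs_proxy: str = "F0"
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def extract_cardinal_points(transient: FluorescenceTransient) -> CardinalPoints:
    """Read F0, F300, FJ, FI off the transient and FM as its maximum.

    Values at the cardinal times are obtained by linear interpolation in
    log time between the neighbouring samples; FM is the maximum over
    the whole transient.  A flat transient (FM == F0) is returned with
    ``degenerate=True``.
    """
    f0 = transient.at(T_O)
    f300 = transient.at(T_K)
    fj = transient.at(T_J)
    fi = transient.at(T_I)
    fm = float(np.max(transient.fluorescence))
    return CardinalPoints(F0=f0, F300=f300, FJ=fj, FI=fi, FM=fm,
                          degenerate=not fm > f0)


def compute_jip(
    cardinals: CardinalPoints,
    transient: FluorescenceTransient,
    abs_cs_proxy: str = "F0",
) -> JipParameters:
    """Derive the JIP-test parameters from cardinal points and transient.

    Standard definitions:

    * VJ = (FJ - F0)/(FM - F0); VI = (FI - F0)/(FM - F0); VK likewise at 300 us
    * M0 = 4 * (F300 - F0)/(FM - F0)          [per ms; 4 = 1/(0.25 ms)]
    * Area = integral of (FM - F(t)) dt from the first sample to t(FM)
    * S_M = Area/(FM - F0)                    [reported in ms]
    * N = S_M * M0 * (1/VJ)                   [QA turnover number]
    * phi_P0 = 1 - F0/FM = Fv/FM; psi_E0 = 1 - VJ; delta_R0 = (1-VI)/(1-VJ)
    * ABS/CS proxied by F0 (or FM); TR/CS = phi_P0*ABS/CS;
      ET/CS = phi_P0*psi_E0*ABS/CS; DI/CS = ABS/CS - TR/CS;
      RC/ABS = phi_P0*(VJ/M0); RC/CS = RC/ABS * ABS/CS
    * TR0/DI0 = phi_P0/(1-phi_P0); RE0/RC = (M0/VJ)*(1-VI)

    A degenerate transient (FM <= F0) yields NaN for every derived field
    with ``degenerate=True``.
    """
    if abs_cs_proxy not in ("F0", "FM"):
        raise ValueError("abs_cs_proxy must be 'F0' or 'FM'")
    f0, f300, fj, fi, fm = (cardinals.F0, cardinals.F300, cardinals.FJ,
                            cardinals.FI, cardinals.FM)
    if not fm > f0:
        nan = _UNDEFINED
        return JipParameters(
            F0=f0, FM=fm, VJ=nan, VI=nan, VK=nan, M0=nan, area=nan, S_M=nan,
            N=nan, phi_P0=nan, psi_E0=nan, delta_R0=nan, abs_cs=nan, tr_cs=nan,
            et_cs=nan, di_cs=nan, rc_cs=nan, rc_abs=nan, tr0_di0=nan,
            psi_ratio=nan, delta_ratio=nan, re0_rc=nan,
            abs_cs_proxy=abs_cs_proxy, degenerate=True,
        )
    fv = fm - f0
    vj = (fj - f0) / fv
    vi = (fi - f0) / fv
    vk = (f300 - f0) / fv
    m0 = 4.0 * (f300 - f0) / fv  # per ms

    # complementary area above the curve, trapezoids on the raw time grid
    t, f = transient.times, np.minimum(transient.fluorescence, fm)
    i_fm = int(np.argmax(transient.fluorescence))
    area = float(np.trapezoid(fm - f[: i_fm + 1], t[: i_fm + 1]))  # r.u. * s

    s_m = area / fv * 1e3  # ms
    n = s_m * m0 / vj if vj > 0 else _UNDEFINED

    phi_p0 = 1.0 - f0 / fm
    psi_e0 = 1.0 - vj
    delta_r0 = (1.0 - vi) / (1.0 - vj) if vj < 1.0 else _UNDEFINED

    abs_cs = f0 if abs_cs_proxy == "F0" else fm
    tr_cs = phi_p0 * abs_cs
    et_cs = phi_p0 * psi_e0 * abs_cs
    di_cs = abs_cs - tr_cs
    rc_abs = phi_p0 * (vj / m0) if m0 > 0 else _UNDEFINED
    rc_cs = rc_abs * abs_cs if np.isfinite(rc_abs) else _UNDEFINED

    tr0_di0 = phi_p0 / (1.0 - phi_p0) if phi_p0 < 1.0 else _UNDEFINED
    psi_ratio = psi_e0 / (1.0 - psi_e0) if psi_e0 < 1.0 else _UNDEFINED
    delta_ratio = (delta_r0 / (1.0 - delta_r0)
                   if np.isfinite(delta_r0) and delta_r0 < 1.0 else _UNDEFINED)
    re0_rc = (m0 / vj) * (1.0 - vi) if vj > 0 else _UNDEFINED

    return JipParameters(
        F0=f0, FM=fm, VJ=vj, VI=vi, VK=vk, M0=m0, area=area, S_M=s_m, N=n,
        phi_P0=phi_p0, psi_E0=psi_e0, delta_R0=delta_r0, abs_cs=abs_cs,
        tr_cs=tr_cs, et_cs=et_cs, di_cs=di_cs, rc_cs=rc_cs, rc_abs=rc_abs,
        tr0_di0=tr0_di0, psi_ratio=psi_ratio, delta_ratio=delta_ratio,
        re0_rc=re0_rc, abs_cs_proxy=abs_cs_proxy,
    )


def aoec_fraction(sample: JipParameters, control: JipParameters) -> float:
    """Fraction of active oxygen-evolving complexes relative to a control.

    AOEC = [1 - VK/VJ]_sample / [1 - VK/VJ]_control, where VK is the
    relative variable fluorescence at 300 us (the K band).  A rise of
    the K band toward the J step (VK/VJ -> 1) marks OEC inactivation.
    """
    denom = 1.0 - control.VK / control.VJ
    if not denom > 0:
        raise ValueError("control 1 - VK/VJ must be positive")
    return float((1.0 - sample.VK / sample.VJ) / denom)


def grouping_probability(
    sample: FluorescenceTransient,
    control: FluorescenceTransient,
    t_band: float = 150e-6,
) -> float:
    """Connectivity (grouping) of PSII antenna units, experimental.

    Estimated from the L band: the 100-300 us difference of relative
    variable fluorescence W = (F - F0)/(FJ - F0) between a sample and a
    reference (control) transient, normalised per the standard
    connectivity treatment,

        P_G = (W_ref - W_sample) / (V_J,sample * W_ref * (1 - W_sample))

    evaluated at ``t_band`` (default 150 us).  Positive values indicate
    reduced antenna connectivity relative to the reference; a sample
    identical to the reference gives 0.  The underlying instrument
    protocol is not standardised, so this estimate is flagged
    experimental and should be interpreted only comparatively.
    """
    if not 100e-6 <= t_band <= 300e-6:
        warnings.warn("t_band outside the 100-300 us L-band window")

    def _w(tr: FluorescenceTransient) -> tuple[float, float]:
        f0, fj = tr.at(T_O), tr.at(T_J)
        fm = float(np.max(tr.fluorescence))
        w = (tr.at(t_band) - f0) / (fj - f0)
        vj = (fj - f0) / (fm - f0)
        return w, vj

    w_s, vj_s = _w(sample)
    w_r, _ = _w(control)
    denom = vj_s * w_r * (1.0 - w_s)
    if denom == 0:
        return _UNDEFINED
    return float((w_r - w_s) / denom)
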