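"""DOSY hydrodynamics: diffusion fitting, hydrodynamic radius, scale law.

Pulsed-field-gradient spin-echo intensities decay with gradient strength g as

    I(g) = I0 exp(−D γ² g² δ² (Δ − δ/3))

(the Stejskal–Tanner law), where δ is the gradient length, Δ the diffusion
delay and γ the ¹H gyromagnetic ratio.  The fitted translational diffusion
coefficient D converts to a hydrodynamic radius by ratio against an internal
reference of known Rh (dioxane, 2.12 Å), since Stokes–Einstein gives
Rh ∝ 1/D at fixed temperature and viscosity.  An independent expectation for
a monomeric random-coil chain of the same molecular weight comes from the
empirical scale law Rh = 0.027 · MW^0.50 (nm); comparing the two radii
classifies the peptide as monomeric-disordered versus compact/oligomeric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import lmfit
import numpy as np

GAMMA_1H = 26752.0  # rad s⁻¹ G⁻¹

DIOXANE_RH_A = 2.12  # Å, internal reference

# random-coil scale law Rh = coeff · MW^exponent, result in nm
SCALE_LAW_COEFF_NM = 0.027
SCALE_LAW_EXPONENT = 0.50


class OligomericVerdict(str, Enum):
    MONOMERIC_DISORDERED = "monomeric_disordered"
    COMPACT_OR_OLIGOMERIC = "compact_or_oligomeric"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class DiffusionSeries:
    """One PFG decay: integrated intensity versus gradient fraction."""

    gradient_fraction: np.ndarray  # of max_gradient, in [0, 1]
    intensity: np.ndarray
    max_gradient: float  # G cm⁻¹
    delta_ms: float = 2.5  # gradient length
    Delta_ms: float = 250.0  # diffusion delay

    def __post_init__(self) -> None:
        g = np.asarray(self.gradient_fraction, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        if np.any(i <= 0):
            raise ValueError("intensities must be positive")
        if np.any(g < 0) or np.any(g > 1) or np.any(np.diff(g) <= 0):
            raise ValueError("gradient fractions must increase within [0, 1]")
        if self.max_gradient <= 0:
            raise ValueError("max_gradient must be > 0")


def stejskal_tanner_factor(series: DiffusionSeries) -> np.ndarray:
    """γ² g² δ² (Δ − δ/3) per point, in s cm⁻²  (so that D·factor is unitless)."""
    g = np.asarray(series.gradient_fraction, dtype=float) * series.max_gradient
    delta = series.delta_ms * 1e-3
    Delta = series.Delta_ms * 1e-3
    return (GAMMA_1H * g * delta) ** 2 * (Delta - delta / 3.0)


@dataclass
class DiffusionFit:
    D: float  # cm² s⁻¹
    D_se: float | None
    I0: float
    converged: bool
    no_decay: bool = False
    message: str = ""

    def summary(self) -> str:
        se = f" ± {self.D_se:.2g}" if self.D_se is not None else ""
        return (
            "Stejskal–Tanner diffusion fit\n"
            "=============================\n"
            f"D (cm² s⁻¹): {self.D:.4g}{se}\n"
            f"I0         : {self.I0:.4g}\n"
            f"converged: {self.converged}   no_decay: {self.no_decay}"
        )


class StejskalTanner:
    """Exponential-decay diffusion model for a PFG intensity series."""

    def __init__(self, series: DiffusionSeries):
        if len(np.asarray(series.gradient_fraction)) < 6:
            raise ValueError("need at least 6 gradient points")
        self.series = series
        self.x = stejskal_tanner_factor(series)
        self.y = np.asarray(series.intensity, dtype=float)

    def fit(self) -> DiffusionFit:
        x, y = self.x, self.y
        rel_span = float(np.ptp(y)) / float(np.max(y))
        if rel_span < 1e-9:
            return DiffusionFit(
                D=0.0, D_se=None, I0=float(np.mean(y)), converged=False,
                no_decay=True, message="no attenuation across the gradient ramp",
            )
        # log-linear regression seeds the nonlinear fit
        slope, logI0 = np.polyfit(x, np.log(y), 1)
        params = lmfit.Parameters()
        params.add("I0", value=float(np.exp(logI0)), min=0.0)
        params.add("D", value=max(-slope, 1e-12), min=0.0)

        def resid(p):
            return p["I0"].value * np.exp(-p["D"].value * x) - y

        out = lmfit.minimize(resid, params, method="leastsq")
        p = out.params
        return DiffusionFit(
            D=p["D"].value, D_se=p["D"].stderr, I0=p["I0"].value,
            converged=bool(out.success),
            no_decay=p["D"].value <= 0.0,
            message="" if out.success else str(out.message),
        )


def fit_diffusion_decay(series: DiffusionSeries) -> DiffusionFit:
    """Fit the Stejskal–Tanner decay; returns D in cm² s⁻¹."""
    return StejskalTanner(series).fit()


def rh_from_reference(
    D_analyte: float, D_reference: float, Rh_reference: float = DIOXANE_RH_A
) -> float:
    """Hydrodynamic radius (Å) by Stokes–Einstein ratio to an internal reference."""
    if D_analyte <= 0 or D_reference <= 0:
        raise ValueError("diffusion coefficients must be > 0")
    return Rh_reference * D_reference / D_analyte


def rh_scale_law(
    mw: float,
    coeff_nm: float = SCALE_LAW_COEFF_NM,
    exponent: float = SCALE_LAW_EXPONENT,
) -> float:
    """Random-coil Rh (Å) expected for a chain of molecular weight ``mw`` (Da).

    The empirical coefficient is in nm; the result is converted to Å.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be > 0")
    return 10.0 * coeff_nm * mw ** exponent


def classify_oligomeric_state(
    rh_measured: float,
    rh_measured_se: float | None,
    rh_random_coil: float,
    rh_random_coil_se: float | None,
    window: float = 2.0,
) -> OligomericVerdict:
    """Compare measured Rh with the random-coil expectation.

    Radii within ``window`` × the combined (quadrature) uncertainty count as
    comparable ⇒ monomeric and disordered; a larger gap flags a compact or
    oligomeric species; missing uncertainties give an indeterminate verdict
    unless the radii agree exactly.
    """
    if rh_measured == rh_random_coil:
        return OligomericVerdict.MONOMERIC_DISORDERED
    if rh_measured_se is None or rh_random_coil_se is None:
        return OligomericVerdict.INDETERMINATE
    combined = math.hypot(rh_measured_se, rh_random_coil_se)
    if combined == 0:
        return OligomericVerdict.COMPACT_OR_OLIGOMERIC
    if abs(rh_measured - rh_random_coil) <= window * combined:
        return OligomericVerdict.MONOMERIC_DISORDERED
    return OligomericVerdict.COMPACT_OR_OLIGOMERIC


@dataclass
class HydroResult:
    """Full hydrodynamic characterization of one peptide."""

    D: float
    D_se: float | None
    Rh_ref: float  # Å, via internal reference
    Rh_scale: float  # Å, via the random-coil scale law
    verdict: OligomericVerdict

    def summary(self) -> str:
        se = f" ± {self.D_se:.2g}" if self.D_se is not None else ""
        return (
            "Hydrodynamic analysis\n"
            "=====================\n"
            f"D (cm² s⁻¹)        : {self.D:.4g}{se}\n"
            f"Rh, reference (Å)  : {self.Rh_ref:.3g}\n"
            f"Rh, random coil (Å): {self.Rh_scale:.3g}\n"
            f"verdict            : {self.verdict.value}"
        )


def analyze_hydrodynamics(
    analyte: DiffusionSeries,
    reference: DiffusionSeries,
    mw: float,
    rh_reference: float = DIOXANE_RH_A,
    rh_measured_se: float | None = None,
    rh_coil_se: float | None = None,
    window: float = 2.0,
) -> HydroResult:
    """Fit both decays, form both radii, and classify the oligomeric state."""
    fa = fit_diffusion_decay(analyte)
    fr = fit_diffusion_decay(reference)
    rh_ref = rh_from_reference(fa.D, fr.D, rh_reference)
    rh_scale = rh_scale_law(mw)
    if rh_measured_se is None and fa.D_se is not None and fa.D > 0:
        rh_measured_se = rh_ref * fa.D_se / fa.D
    verdict = classify_oligomeric_state(
        rh_ref, rh_measured_se, rh_scale, rh_coil_se, window=window
    )
    return HydroResult(D=fa.D, D_se=fa.D_se, Rh_ref=rh_ref,
                       Rh_scale=rh_scale, verdict=verdict)
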