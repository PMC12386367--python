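"""Isothermal titration calorimetry: single set of identical binding sites.

Ligand (peptide) is injected stepwise from a syringe into a perfusion cell of
volume V0 containing the macromolecule (importin α).  Each injection of
volume dV displaces cell content, so both cell species are diluted by
(1 − dV/V0) per injection while injected ligand accumulates.  With n
identical sites per protomer, site occupancy Θ after injection i follows the
1:1 mass-balance quadratic, cumulative heat is

    Q_i = n Θ_i [M]_i ΔH V0

and the measured per-injection heat includes the displaced-volume correction

    q_i = Q_i − Q_{i−1} + (dV_i/V0) (Q_i + Q_{i−1}) / 2.

Fitting q_i over (n, Kd, ΔH) by nonlinear least squares yields the binding
thermodynamics; ΔG = RT ln Kd (Kd in molar) and −TΔS = ΔG − ΔH follow
exactly.  Kd is log-transformed during optimization to stay positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np

R_KCAL = 1.9872e-3  # kcal mol⁻¹ K⁻¹


class ITCError(ValueError):
    pass


@dataclass(frozen=True)
class ITCExperiment:
    cell_volume_ml: float = 1.4
    cell_conc: float = 15.0  # μM macromolecule, protomer units
    syringe_conc: float = 175.0  # μM ligand
    injection_volumes_ul: tuple[float, ...] = tuple([10.0] * 28)
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if self.cell_volume_ml <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ITCError("concentrations and volumes must be > 0")
        if any(v <= 0 for v in self.injection_volumes_ul):
            raise ITCError("injection volumes must be > 0")

    @property
    def temperature_K(self) -> float:
        return self.temperature_C + 273.15


@dataclass(frozen=True)
class ITCIsotherm:
    experiment: ITCExperiment
    heats: tuple[float, ...]  # μcal per injection
    dilution_heats: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        n_inj = len(self.experiment.injection_volumes_ul)
        if len(self.heats) != n_inj:
            raise ITCError("heats must match the injection schedule length")
        if self.dilution_heats is not None and len(self.dilution_heats) != n_inj:
            raise ITCError("dilution_heats must match the injection schedule length")


def predict_injection_heats(
    n: float, Kd: float, dH: float, exp: ITCExperiment
) -> np.ndarray:
    """Forward model: per-injection heats (μcal) for given (n, Kd μM, ΔH kcal/mol)."""
    v0_ul = exp.cell_volume_ml * 1000.0
    m = exp.cell_conc  # μM, diluted stepwise
    x = 0.0  # μM ligand in cell
    q_prev = 0.0
    out = []
    for dv in exp.injection_volumes_ul:
        f = dv / v0_ul
        m *= 1.0 - f
        x = x * (1.0 - f) + exp.syringe_conc * f
        sites = n * m
        b = sites + x + Kd
        bound = 0.5 * (b - math.sqrt(max(b * b - 4.0 * sites * x, 0.0)))
        # μM · kcal/mol · mL  ==  μcal
        q_cum = bound * dH * exp.cell_volume_ml
        out.append(q_cum - q_prev + f * (q_cum + q_prev) / 2.0)
        q_prev = q_cum
    return np.array(out)


def subtract_dilution(
    iso: ITCIsotherm,
    mode: str = "blank",
    constant: float | None = None,
    tail: int = 3,
) -> np.ndarray:
    """Dilution-heat correction.

    mode="blank"    — element-wise subtraction of the blank-run heats;
    mode="constant" — subtract ``constant`` or, if None, the mean of the
                      final ``tail`` injections (near-saturation heats).
    """
    heats = np.asarray(iso.heats, dtype=float)
    if mode == "blank":
        if iso.dilution_heats is None:
            raise ITCError("no dilution blank available; use mode='constant'")
        return heats - np.asarray(iso.dilution_heats, dtype=float)
    if mode == "constant":
        offset = float(np.mean(heats[-tail:])) if constant is None else constant
        return heats - offset
    raise ITCError(f"unknown dilution mode {mode!r}")


@dataclass
class ITCFit:
    """Single-site ITC fit results and derived thermodynamics."""

    n: float
    Kd: float  # μM
    dH: float  # kcal mol⁻¹
    n_se: float | None
    Kd_se: float | None
    dH_se: float | None
    dG: float  # kcal mol⁻¹
    minus_TdS: float  # kcal mol⁻¹
    converged: bool
    low_confidence: bool
    c_value: float
    temperature_K: float
    residuals: np.ndarray | None = field(default=None, repr=False)
    message: str = ""

    def summary(self) -> str:
        def fmt(v, se):
            return f"{v:.4g}" + (f" ± {se:.2g}" if se is not None else "")

        return "\n".join([
            "Single-site ITC fit",
            "===================",
            f"n (sites/protomer): {fmt(self.n, self.n_se)}",
            f"Kd (μM)           : {fmt(self.Kd, self.Kd_se)}",
            f"ΔH  (kcal/mol)    : {fmt(self.dH, self.dH_se)}",
            f"ΔG  (kcal/mol)    : {self.dG:.3f}",
            f"−TΔS (kcal/mol)   : {self.minus_TdS:.3f}",
            f"c = [M]/Kd        : {self.c_value:.3g}",
            f"converged: {self.converged}   low_confidence: {self.low_confidence}",
        ])


class SingleSiteITC:
    """Model: single set of identical sites fitted to per-injection heats.

    Parameters
    ----------
    iso : ITCIsotherm
    dilution : {"blank", "constant", None}
        Heat correction applied before fitting; None fits raw heats.
    discard_first : bool
        Drop the first injection (a common vendor practice for the small
        pre-injection diffusion artifact).  Retained by default.
    """

    def __init__(
        self,
        iso: ITCIsotherm,
        dilution: str | None = None,
        discard_first: bool = False,
    ):
        self.iso = iso
        self.exp = iso.experiment
        if dilution is None:
            heats = np.asarray(iso.heats, dtype=float)
        else:
            heats = subtract_dilution(iso, mode=dilution)
        self.discard_first = discard_first
        self.heats = heats
        n_used = len(heats) - (1 if discard_first else 0)
        if n_used < 8:
            raise ITCError("need at least 8 injections to fit 3 parameters")

    def fit(self) -> ITCFit:
        exp = self.exp
        heats = self.heats
        mask = np.ones(len(heats), dtype=bool)
        if self.discard_first:
            mask[0] = False
        T = exp.temperature_K

        span = float(np.ptp(heats[mask]))
        if span < 1e-9 and float(np.max(np.abs(heats[mask]))) < 1e-9:
            return ITCFit(
                n=np.nan, Kd=np.nan, dH=0.0, n_se=None, Kd_se=None, dH_se=None,
                dG=np.nan, minus_TdS=np.nan, converged=False,
                low_confidence=True, c_value=np.nan, temperature_K=T,
                message="no heat signal: Kd unidentifiable",
            )

        total_q = float(np.sum(heats[mask]))
        dh0 = total_q / (exp.cell_conc * exp.cell_volume_ml) or -1.0
        params = lmfit.Parameters()
        params.add("n", value=1.0, min=0.05, max=20.0)
        params.add("log10_kd", value=math.log10(max(exp.cell_conc / 5.0, 1e-3)),
                   min=-4.0, max=5.0)
        params.add("dH", value=dh0)

        def resid(p):
            pred = predict_injection_heats(
                p["n"].value, 10.0 ** p["log10_kd"].value, p["dH"].value, exp
            )
            return pred[mask] - heats[mask]

        out = lmfit.minimize(resid, params, method="leastsq")
        p = out.params
        kd = 10.0 ** p["log10_kd"].value
        kd_se = None
        if p["log10_kd"].stderr is not None:
            kd_se = kd * math.log(10.0) * p["log10_kd"].stderr
        dg = R_KCAL * T * math.log(kd * 1e-6)
        c = exp.cell_conc / kd
        return ITCFit(
            n=p["n"].value, Kd=kd, dH=p["dH"].value,
            n_se=p["n"].stderr, Kd_se=kd_se, dH_se=p["dH"].stderr,
            dG=dg, minus_TdS=dg - p["dH"].value,
            converged=bool(out.success),
            low_confidence=not (0.01 <= c <= 1e4) or not out.success,
            c_value=c, temperature_K=T,
            residuals=np.asarray(out.residual),
            message="" if out.success else str(out.message),
        )


def fit_itc(
    iso: ITCIsotherm,
    dilution: str | None = None,
    discard_first: bool = False,
) -> ITCFit:
    """Fit the single-set-of-sites model to an ITC isotherm."""
    return SingleSiteITC(iso, dilution=dilution, discard_first=discard_first).fit()
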