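"""Fluorescence titration analysis with explicit ligand depletion.

A receptor (importin α, a few μM, concentration fixed) is titrated with
increasing peptide, and the quench (or gain) of intrinsic fluorescence is
fitted to the exact 1:1 binding isotherm.  Because receptor and ligand
concentrations are comparable to the dissociation constant, the free-ligand
approximation fails; the model solves the mass-balance quadratic for the
complex concentration instead:

    F = F0 + (ΔFmax / 2 R_T) [ (R_T + L_T + Kd) − sqrt((R_T + L_T + Kd)² − 4 R_T L_T) ]

where the bracket equals twice the complex concentration.  Blank subtraction
and the multiplicative inner-filter correction 10^((A_ex + A_em)/2) happen
before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd


class Reliability(str, Enum):
    RELIABLE = "reliable"
    OUT_OF_RANGE = "out_of_range"
    UNIDENTIFIABLE = "unidentifiable"


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class TitrationPoint:
    ligand_total: float  # μM
    intensity_raw: float
    intensity_blank: float = 0.0
    absorbance_ex: float | None = None
    absorbance_em: float | None = None

    def __post_init__(self) -> None:
        if self.ligand_total < 0:
            raise ValueError("ligand_total must be >= 0")
        for a in (self.absorbance_ex, self.absorbance_em):
            if a is not None and a < 0:
                raise ValueError("absorbances must be >= 0")


@dataclass(frozen=True)
class TitrationCurve:
    """One titration: fixed receptor, increasing ligand."""

    receptor_total: float  # μM, protomer units
    points: tuple[TitrationPoint, ...]
    excitation_nm: int = 280
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be > 0")
        lig = [p.ligand_total for p in self.points]
        if lig and lig[0] != 0:
            raise ValueError("first titration point must have ligand_total = 0")
        if any(b >= a for a, b in zip(lig[1:], lig[:-1])):
            raise ValueError("ligand_total must be strictly increasing")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        receptor_total: float,
        excitation_nm: int = 280,
        temperature_C: float = 25.0,
    ) -> "TitrationCurve":
        """Build from columns ligand_total_uM, intensity, blank[, A_ex, A_em]."""
        points = []
        for _, row in df.iterrows():
            points.append(
                TitrationPoint(
                    ligand_total=float(row["ligand_total_uM"]),
                    intensity_raw=float(row["intensity"]),
                    intensity_blank=float(row.get("blank", 0.0)),
                    absorbance_ex=float(row["A_ex"]) if "A_ex" in row and pd.notna(row["A_ex"]) else None,
                    absorbance_em=float(row["A_em"]) if "A_em" in row and pd.notna(row["A_em"]) else None,
                )
            )
        return cls(receptor_total, tuple(points), excitation_nm, temperature_C)

    @classmethod
    def read_csv(cls, path: str | Path, receptor_total: float, **kw) -> "TitrationCurve":
        return cls.from_dataframe(pd.read_csv(path, comment="#"), receptor_total, **kw)

    @property
    def ligand_totals(self) -> np.ndarray:
        return np.array([p.ligand_total for p in self.points])


def inner_filter_correct(
    intensity: float | np.ndarray,
    absorbance_ex: float | np.ndarray,
    absorbance_em: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Multiplicative inner-filter correction 10^((A_ex + A_em)/2)."""
    a_ex = np.asarray(absorbance_ex, dtype=float)
    a_em = np.asarray(absorbance_em, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValueError("absorbances must be >= 0")
    out = np.asarray(intensity, dtype=float) * 10.0 ** ((a_ex + a_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def complex_concentration(
    receptor_total: float | np.ndarray,
    ligand_total: float | np.ndarray,
    kd: float | np.ndarray,
) -> float | np.ndarray:
    """Equilibrium 1:1 complex concentration from the mass-balance quadratic."""
    r = np.asarray(receptor_total, dtype=float)
    l = np.asarray(ligand_total, dtype=float)
    b = r + l + np.asarray(kd, dtype=float)
    disc = b * b - 4.0 * r * l
    # round-off can push the discriminant slightly negative at Kd = 0
    c = 0.5 * (b - np.sqrt(np.maximum(disc, 0.0)))
    return float(c) if c.ndim == 0 else c


def eval_binding_isotherm(
    F0: float,
    dFmax: float,
    Kd: float,
    receptor_total: float,
    ligand_total: float | np.ndarray,
) -> float | np.ndarray:
    """Predicted fluorescence at a total ligand concentration (Kd, conc in μM)."""
    if receptor_total <= 0:
        raise ValueError("receptor_total must be > 0")
    if Kd < 0:
        raise ValueError("Kd must be >= 0")
    c = complex_concentration(receptor_total, ligand_total, Kd)
    out = F0 + dFmax * np.asarray(c) / receptor_total
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class BindingFit:
    """Results of a ligand-depletion titration fit."""

    F0: float
    dFmax: float
    Kd: float  # μM
    F0_se: float | None
    dFmax_se: float | None
    Kd_se: float | None
    converged: bool
    reliability: Reliability
    curve: TitrationCurve | None = None
    residuals: np.ndarray | None = field(default=None, repr=False)
    message: str = ""

    def summary(self) -> str:
        def fmt(v, se):
            if v is None:
                return "n.d."
            return f"{v:.4g}" + (f" ± {se:.2g}" if se is not None else "")

        lines = [
            "Ligand-depletion titration fit",
            "==============================",
            f"F0      : {fmt(self.F0, self.F0_se)}",
            f"dFmax   : {fmt(self.dFmax, self.dFmax_se)}",
            f"Kd (μM) : {fmt(self.Kd, self.Kd_se)}",
            f"converged  : {self.converged}",
            f"reliability: {self.reliability.value}",
        ]
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: corrected data with the fitted isotherm."""
        import matplotlib.pyplot as plt

        if self.curve is None:
            raise ValueError("no curve attached to this fit")
        if ax is None:
            _, ax = plt.subplots()
        lig = self.curve.ligand_totals
        y = [p.intensity_raw - p.intensity_blank for p in self.curve.points]
        ax.plot(lig, y, "o", label="data")
        if self.converged:
            grid = np.linspace(0.0, lig.max(), 200)
            ax.plot(grid, eval_binding_isotherm(
                self.F0, self.dFmax, self.Kd, self.curve.receptor_total, grid),
                "-", label=f"fit (Kd = {self.Kd:.3g} μM)")
        ax.set_xlabel("total ligand (μM)")
        ax.set_ylabel("fluorescence intensity")
        ax.legend()
        return ax


class LigandDepletionTitration:
    """Model for a fluorescence titration curve under ligand depletion.

    Parameters
    ----------
    curve : TitrationCurve
    inner_filter : bool
        Apply the 10^((A_ex+A_em)/2) correction where absorbances are present.
    kd_max_rel_se : float
        Reliability threshold: relative standard error of Kd above which the
        fit is flagged out-of-range.
    """

    def __init__(
        self,
        curve: TitrationCurve,
        inner_filter: bool = False,
        kd_max_rel_se: float = 1.0,
    ):
        if len(curve.points) < 5:
            raise FitError("need at least 5 titration points to fit 3 parameters")
        if curve.ligand_totals.max() <= 0:
            raise FitError("titration must span a nonzero ligand range")
        self.curve = curve
        self.inner_filter = inner_filter
        self.kd_max_rel_se = kd_max_rel_se
        self.ligand = curve.ligand_totals
        self.signal = self._prepare_signal()

    def _prepare_signal(self) -> np.ndarray:
        y = []
        for p in self.curve.points:
            v = p.intensity_raw - p.intensity_blank
            if self.inner_filter and p.absorbance_ex is not None:
                v = inner_filter_correct(v, p.absorbance_ex, p.absorbance_em or 0.0)
            y.append(v)
        return np.array(y)

    def fit(self) -> BindingFit:
        y = self.signal
        lig = self.ligand
        r = self.curve.receptor_total
        span = float(np.max(np.abs(y - y[0])))
        scale = max(abs(y[0]), 1.0)
        if span < 1e-9 * scale:
            return BindingFit(
                F0=float(y[0]), dFmax=0.0, Kd=np.nan,
                F0_se=None, dFmax_se=None, Kd_se=None,
                converged=False, reliability=Reliability.UNIDENTIFIABLE,
                curve=self.curve, message="no signal change across the titration",
            )

        params = lmfit.Parameters()
        params.add("F0", value=float(y[0]))
        params.add("dFmax", value=float(y[-1] - y[0]))
        params.add("Kd", value=float(np.median(lig[lig > 0])), min=1e-9)

        def resid(p):
            return eval_binding_isotherm(
                p["F0"].value, p["dFmax"].value, p["Kd"].value, r, lig
            ) - y

        out = lmfit.minimize(resid, params, method="leastsq")
        p = out.params
        kd, kd_se = p["Kd"].value, p["Kd"].stderr
        fit = BindingFit(
            F0=p["F0"].value, dFmax=p["dFmax"].value, Kd=kd,
            F0_se=p["F0"].stderr, dFmax_se=p["dFmax"].stderr, Kd_se=kd_se,
            converged=bool(out.success), reliability=Reliability.RELIABLE,
            curve=self.curve, residuals=np.asarray(out.residual),
            message="" if out.success else str(out.message),
        )
        if not out.success:
            fit.reliability = Reliability.UNIDENTIFIABLE
            return fit
        dfm, dfm_se = p["dFmax"].value, p["dFmax"].stderr
        if kd > lig.max() or (kd_se is not None and kd_se / kd > self.kd_max_rel_se):
            fit.reliability = Reliability.OUT_OF_RANGE
        elif abs(dfm) < 1e-9 * scale or (dfm_se is not None and abs(dfm) <= dfm_se):
            fit.reliability = Reliability.UNIDENTIFIABLE
        return fit


def fit_titration(
    curve: TitrationCurve,
    inner_filter: bool = False,
    kd_max_rel_se: float = 1.0,
) -> BindingFit:
    """Fit the ligand-depletion isotherm to a titration curve."""
    return LigandDepletionTitration(curve, inner_filter, kd_max_rel_se).fit()
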