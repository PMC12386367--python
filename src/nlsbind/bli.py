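"""Biolayer-interferometry (BLI) kinetic analysis.

A sensorgram records the optical response R(t) (response units, RU) of a
fiber tip carrying immobilized receptor as ligand associates and then
dissociates.  For a 1:1 interaction at pseudo-first-order conditions the
association phase approaches steady state as

    R(t) = Req (1 − e^{−kobs (t − t0)}) − R'eq (t − t0)

with kobs = kon [L] + koff, and the dissociation phase decays as

    R(t) = R1 e^{−koff (t − t0)} − R''eq (t − t0).

The linear drift terms absorb slow baseline wander at long times.  Per-curve
kobs values are regressed against ligand concentration (the pseudo-first-order
plot): the slope is kon, the intercept koff, and Kd = koff/kon with standard
error propagated in quadrature.  A non-positive intercept means koff (hence
Kd) cannot be reported from the plot.

The two-step procedure (per-curve exponential fits, then linear regression)
is the implemented method; no global ODE fit is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import statsmodels.api as sm


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class PhaseSchedule:
    """Durations of the five BLI steps, in seconds."""

    baseline1_s: float = 30.0
    loading_s: float = 120.0
    baseline2_s: float = 30.0
    association_s: float = 120.0
    dissociation_s: float = 120.0

    def __post_init__(self) -> None:
        for name in ("baseline1_s", "loading_s", "baseline2_s",
                     "association_s", "dissociation_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def association_start(self) -> float:
        return self.baseline1_s + self.loading_s + self.baseline2_s

    @property
    def dissociation_start(self) -> float:
        return self.association_start + self.association_s

    @property
    def total(self) -> float:
        return self.dissociation_start + self.dissociation_s


@dataclass(frozen=True)
class Sensorgram:
    time: np.ndarray  # s
    response: np.ndarray  # RU
    ligand_conc: float  # μM
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if len(t) != len(self.response):
            raise ValueError("time and response must have equal length")


@dataclass(frozen=True)
class Segment:
    time: np.ndarray
    response: np.ndarray
    t0: float  # phase start, s


def segment_sensorgram(s: Sensorgram) -> tuple[Segment, Segment]:
    """Split a sensorgram into association and dissociation segments.

    Boundaries are computed from the schedule; association covers
    [t_assoc, t_dissoc), dissociation [t_dissoc, end of schedule].
    """
    sched = s.schedule
    t = np.asarray(s.time, dtype=float)
    r = np.asarray(s.response, dtype=float)
    if t[-1] < sched.total - 1e-9:
        raise SegmentationError(
            f"sensorgram ends at {t[-1]:.1f} s but the schedule requires "
            f"{sched.total:.1f} s"
        )
    ta, td = sched.association_start, sched.dissociation_start
    m_assoc = (t >= ta) & (t < td)
    m_dissoc = (t >= td) & (t <= sched.total + 1e-9)
    if m_assoc.sum() < 2 or m_dissoc.sum() < 2:
        raise SegmentationError("too few samples in a kinetic phase")
    return (
        Segment(t[m_assoc], r[m_assoc], ta),
        Segment(t[m_dissoc], r[m_dissoc], td),
    )


@dataclass
class AssocFit:
    Req: float
    kobs: float  # s⁻¹
    drift: float  # RU/s
    t0: float
    Req_se: float | None
    kobs_se: float | None
    drift_se: float | None
    converged: bool
    message: str = ""


@dataclass
class DissocFit:
    R1: float
    koff: float  # s⁻¹
    drift: float  # RU/s
    t0: float
    R1_se: float | None
    koff_se: float | None
    drift_se: float | None
    converged: bool
    no_decay: bool = False
    message: str = ""


def _assoc_model(tau, req, kobs, drift):
    return req * (1.0 - np.exp(-kobs * tau)) - drift * tau


def fit_association(segment: Segment, ligand_conc: float | None = None) -> AssocFit:
    """Fit the drifting single-exponential association model to one phase."""
    tau = segment.time - segment.t0
    y = segment.response
    if len(y) < 10:
        raise ValueError("need at least 10 samples in the association phase")
    span = float(np.ptp(y))
    if span < 1e-12:
        return AssocFit(
            Req=float(np.mean(y)), kobs=np.nan, drift=0.0, t0=segment.t0,
            Req_se=None, kobs_se=None, drift_se=None, converged=False,
            message="flat trace: kobs unidentifiable",
        )
    params = lmfit.Parameters()
    params.add("req", value=float(y[-1]) or span)
    # crude rate guess: time to reach ~63% of the final level
    i63 = int(np.searchsorted(np.maximum.accumulate(np.abs(y)), 0.63 * abs(y[-1])))
    t63 = tau[min(max(i63, 1), len(tau) - 1)]
    params.add("kobs", value=1.0 / max(t63, tau[1] if len(tau) > 1 else 1.0), min=1e-6)
    params.add("drift", value=0.0)

    def resid(p):
        return _assoc_model(tau, p["req"].value, p["kobs"].value, p["drift"].value) - y

    out = lmfit.minimize(resid, params, method="leastsq")
    p = out.params
    converged = bool(out.success) and p["kobs"].value > 1e-6
    return AssocFit(
        Req=p["req"].value, kobs=p["kobs"].value, drift=p["drift"].value,
        t0=segment.t0, Req_se=p["req"].stderr, kobs_se=p["kobs"].stderr,
        drift_se=p["drift"].stderr, converged=converged,
        message="" if out.success else str(out.message),
    )


def _dissoc_model(tau, r1, koff, drift):
    return r1 * np.exp(-koff * tau) - drift * tau


def fit_dissociation(segment: Segment) -> DissocFit:
    """Fit the drifting single-exponential dissociation model to one phase."""
    tau = segment.time - segment.t0
    y = segment.response
    if len(y) < 10:
        raise ValueError("need at least 10 samples in the dissociation phase")
    span = float(np.ptp(y))
    if span < 1e-12 * max(1.0, abs(float(y[0]))):
        return DissocFit(
            R1=float(y[0]), koff=0.0, drift=0.0, t0=segment.t0,
            R1_se=None, koff_se=None, drift_se=None,
            converged=False, no_decay=True,
            message="constant response: no dissociation observed",
        )
    params = lmfit.Parameters()
    params.add("r1", value=float(y[0]))
    half = float(y[0]) / 2.0
    below = np.nonzero(y <= half)[0] if y[0] > 0 else np.array([])
    t_half = tau[below[0]] if below.size else tau[-1] / 2.0
    params.add("koff", value=math.log(2.0) / max(t_half, tau[1] if len(tau) > 1 else 1.0),
               min=1e-8)
    params.add("drift", value=0.0)

    def resid(p):
        return _dissoc_model(tau, p["r1"].value, p["koff"].value, p["drift"].value) - y

    out = lmfit.minimize(resid, params, method="leastsq")
    p = out.params
    return DissocFit(
        R1=p["r1"].value, koff=p["koff"].value, drift=p["drift"].value,
        t0=segment.t0, R1_se=p["r1"].stderr, koff_se=p["koff"].stderr,
        drift_se=p["drift"].stderr, converged=bool(out.success),
        no_decay=p["koff"].value < 1e-6,
        message="" if out.success else str(out.message),
    )


def propagate_kd(
    kon: float, kon_se: float, koff: float, koff_se: float
) -> tuple[float, float]:
    """Kd = koff/kon with the standard error propagated in quadrature."""
    if kon <= 0 or koff <= 0:
        raise ValueError("rate constants must be positive")
    kd = koff / kon
    kd_se = kd * math.sqrt((kon_se / kon) ** 2 + (koff_se / koff) ** 2)
    return kd, kd_se


@dataclass
class KineticsResult:
    """Rate constants from the pseudo-first-order plot."""

    kon: float  # μM⁻¹ s⁻¹
    kon_se: float
    koff: float | None  # s⁻¹; None when the intercept is non-positive
    koff_se: float | None
    Kd: float | None  # μM
    Kd_se: float | None
    intercept_valid: bool
    kobs_by_conc: list[tuple[float, float, float | None]]  # (conc, kobs, se)
    no_association: bool = False

    def summary(self) -> str:
        lines = [
            "BLI pseudo-first-order kinetics",
            "===============================",
            f"kon  (μM⁻¹s⁻¹): {self.kon:.4g} ± {self.kon_se:.2g}",
        ]
        if self.intercept_valid:
            lines.append(f"koff (s⁻¹)    : {self.koff:.4g} ± {self.koff_se:.2g}")
            lines.append(f"Kd   (μM)     : {self.Kd:.4g} ± {self.Kd_se:.2g}")
        else:
            lines.append("koff (s⁻¹)    : n.d. (non-positive intercept)")
            lines.append("Kd   (μM)     : n.d.")
        lines.append("  [L] μM    kobs s⁻¹")
        for conc, kobs, se in self.kobs_by_conc:
            se_s = f" ± {se:.2g}" if se is not None else ""
            lines.append(f"  {conc:8.3g}  {kobs:.4g}{se_s}")
        return "\n".join(lines)


def pseudo_first_order(
    kobs_by_conc: list[tuple[float, float] | tuple[float, float, float | None]],
) -> KineticsResult:
    """Regress kobs = kon·[L] + koff over ligand concentrations.

    Weighted by 1/SE(kobs)² when every point carries a positive standard
    error, unweighted otherwise.  A non-positive intercept invalidates koff
    and Kd (they are reported as None) while kon is still taken from the
    slope.
    """
    rows = []
    for item in kobs_by_conc:
        conc, kobs = item[0], item[1]
        se = item[2] if len(item) > 2 else None
        rows.append((float(conc), float(kobs), se))
    concs = np.array([r[0] for r in rows])
    kobs = np.array([r[1] for r in rows])
    if len(set(concs)) < 3:
        raise ValueError("need kobs at >= 3 distinct ligand concentrations")

    X = sm.add_constant(concs)
    ses = [r[2] for r in rows]
    if all(s is not None and s > 0 for s in ses):
        w = 1.0 / np.array(ses, dtype=float) ** 2
        res = sm.WLS(kobs, X, weights=w).fit()
    else:
        res = sm.OLS(kobs, X).fit()
    intercept, slope = res.params
    intercept_se, slope_se = res.bse

    no_association = abs(slope) <= 1e-12 or (
        not np.isnan(slope_se) and abs(slope) <= 2 * slope_se and abs(slope) < 1e-6
    )
    intercept_valid = intercept > 0
    if intercept_valid and slope > 0:
        kd, kd_se = propagate_kd(slope, slope_se, intercept, intercept_se)
    else:
        kd = kd_se = None
    return KineticsResult(
        kon=float(slope), kon_se=float(slope_se),
        koff=float(intercept) if intercept_valid else None,
        koff_se=float(intercept_se) if intercept_valid else None,
        Kd=kd, Kd_se=kd_se,
        intercept_valid=bool(intercept_valid),
        kobs_by_conc=rows,
        no_association=bool(no_association),
    )


class SensorgramKinetics:
    """Two-step kinetic model over a set of sensorgrams.

    `fit()` segments every sensorgram, fits the association and dissociation
    exponentials, and regresses the per-concentration kobs values on ligand
    concentration.
    """

    def __init__(self, sensorgrams: list[Sensorgram]):
        if not sensorgrams:
            raise ValueError("need at least one sensorgram")
        self.sensorgrams = list(sensorgrams)
        self.assoc_fits: list[AssocFit] = []
        self.dissoc_fits: list[DissocFit] = []

    def fit(self) -> KineticsResult:
        kobs_rows = []
        for s in self.sensorgrams:
            assoc_seg, dissoc_seg = segment_sensorgram(s)
            a = fit_association(assoc_seg, s.ligand_conc)
            d = fit_dissociation(dissoc_seg)
            self.assoc_fits.append(a)
            self.dissoc_fits.append(d)
            if a.converged:
                kobs_rows.append((s.ligand_conc, a.kobs, a.kobs_se))
        self.result = pseudo_first_order(kobs_rows)
        return self.result

    def plot(self, ax=None):
        """Diagnostic pseudo-first-order plot: kobs vs [L] with the fit line."""
        import matplotlib.pyplot as plt

        res = getattr(self, "result", None)
        if res is None:
            raise ValueError("call fit() before plot()")
        if ax is None:
            _, ax = plt.subplots()
        concs = np.array([c for c, _, _ in res.kobs_by_conc])
        kobs = np.array([k for _, k, _ in res.kobs_by_conc])
        ses = [s for _, _, s in res.kobs_by_conc]
        yerr = ses if all(s is not None for s in ses) else None
        ax.errorbar(concs, kobs, yerr=yerr, fmt="o", label="kobs")
        grid = np.linspace(0.0, concs.max(), 50)
        intercept = res.koff if res.intercept_valid else 0.0
        ax.plot(grid, res.kon * grid + intercept, "-",
                label=f"kon = {res.kon:.3g} μM⁻¹s⁻¹")
        ax.set_xlabel("peptide concentration (μM)")
        ax.set_ylabel("kobs (s⁻¹)")
        ax.legend()
        return ax
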