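"""Synthetic-data generators for every technique in the pipeline.

Each generator evaluates the technique's forward model (the same code used in
the fitters' oracles) and adds Gaussian noise from an explicitly seeded
stream, so each call is a pure function of (parameters, seed).  Defaults
reproduce the study designs: fluorescence titrations with 3 μM receptor over
0–35 μM ligand; a 30/120/30/120/120 s BLI schedule with peptide at
{1, 2, 3, 5, 10} μM; a 1.4 mL ITC cell at 15 μM titrated with 28 × 10 μL
injections of ~175 μM peptide; 16 gradient steps spanning 2–95% of coil
power for DOSY.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bli import PhaseSchedule, Sensorgram
from .fluorescence import TitrationCurve, TitrationPoint, eval_binding_isotherm
from .hydro import DiffusionSeries, stejskal_tanner_factor
from .itc import ITCExperiment, ITCIsotherm, predict_injection_heats

DEFAULT_BLI_CONCS = (1.0, 2.0, 3.0, 5.0, 10.0)  # μM
DEFAULT_DOSY_MAX_GRADIENT = 40.0  # G cm⁻¹


@dataclass(frozen=True)
class NoiseSpec:
    sigma: float
    seed: int = 0
    model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.model != "gaussian":
            raise ValueError(f"unsupported noise model {self.model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


NOISELESS = NoiseSpec(sigma=0.0, seed=0)


def gen_titration(
    F0: float,
    dFmax: float,
    Kd: float,
    receptor_total: float = 3.0,
    ligand_grid: np.ndarray | None = None,
    noise: NoiseSpec = NOISELESS,
) -> TitrationCurve:
    """Synthetic fluorescence titration on the ligand-depletion isotherm."""
    if ligand_grid is None:
        ligand_grid = np.linspace(0.0, 35.0, 15)
    lig = np.asarray(ligand_grid, dtype=float)
    f = eval_binding_isotherm(F0, dFmax, Kd, receptor_total, lig)
    f = np.atleast_1d(f) + noise.rng().normal(0.0, noise.sigma, size=lig.shape)
    points = tuple(
        TitrationPoint(ligand_total=float(l), intensity_raw=float(v), intensity_blank=0.0)
        for l, v in zip(lig, f)
    )
    return TitrationCurve(receptor_total=receptor_total, points=points)


def sensorgram_trace(
    kon: float,
    koff: float,
    rmax: float,
    ligand_conc: float,
    schedule: PhaseSchedule,
    sample_rate: float = 5.0,
    assoc_drift: float = 0.0,
    dissoc_drift: float = 0.0,
    loading_level: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free sensorgram over the full schedule.

    Phases are emitted re-referenced to zero at each phase start (per-step
    baseline alignment), so the association phase is exactly
    Req (1 − e^{−kobs τ}) − drift·τ and the dissociation phase
    R1 e^{−koff τ} − drift·τ with R1 the drift-free association endpoint.
    """
    dt = 1.0 / sample_rate
    t = np.arange(0.0, schedule.total + dt / 2.0, dt)
    r = np.zeros_like(t)

    t_load0 = schedule.baseline1_s
    t_base2 = t_load0 + schedule.loading_s
    t_assoc = schedule.association_start
    t_dissoc = schedule.dissociation_start

    kd = koff / kon if kon > 0 else np.inf
    req = rmax * ligand_conc / (ligand_conc + kd) if np.isfinite(kd) else 0.0
    kobs = kon * ligand_conc + koff

    m = (t >= t_load0) & (t < t_base2)  # loading ramp (not analyzed)
    r[m] = loading_level * (t[m] - t_load0) / schedule.loading_s

    m = (t >= t_assoc) & (t < t_dissoc)
    tau = t[m] - t_assoc
    r[m] = req * (1.0 - np.exp(-kobs * tau)) - assoc_drift * tau

    r1 = req * (1.0 - np.exp(-kobs * schedule.association_s))
    m = t >= t_dissoc
    tau = t[m] - t_dissoc
    r[m] = r1 * np.exp(-koff * tau) - dissoc_drift * tau
    return t, r


def gen_sensorgram_set(
    kon: float,
    koff: float,
    rmax: float = 1.0,
    drifts: tuple[float, float] = (0.0, 0.0),
    conc_list: tuple[float, ...] = DEFAULT_BLI_CONCS,
    schedule: PhaseSchedule | None = None,
    sample_rate: float = 5.0,
    noise: NoiseSpec = NOISELESS,
) -> list[Sensorgram]:
    """Synthetic sensorgrams for a concentration series of one peptide."""
    schedule = schedule or PhaseSchedule()
    rng = noise.rng()
    out = []
    for conc in conc_list:
        t, r = sensorgram_trace(
            kon, koff, rmax, conc, schedule, sample_rate,
            assoc_drift=drifts[0], dissoc_drift=drifts[1],
        )
        r = r + rng.normal(0.0, noise.sigma, size=r.shape)
        out.append(Sensorgram(time=t, response=r, ligand_conc=conc, schedule=schedule))
    return out


def gen_itc(
    n: float,
    Kd: float,
    dH: float,
    exp: ITCExperiment | None = None,
    noise: NoiseSpec = NOISELESS,
    dilution_heat: float = 0.0,
) -> ITCIsotherm:
    """Synthetic ITC isotherm; a constant per-injection dilution heat is
    added to the signal and recorded in ``dilution_heats``."""
    exp = exp or ITCExperiment()
    q = predict_injection_heats(n, Kd, dH, exp)
    q = q + dilution_heat + noise.rng().normal(0.0, noise.sigma, size=q.shape)
    blanks = None
    if dilution_heat != 0.0:
        blanks = tuple([dilution_heat] * len(q))
    return ITCIsotherm(experiment=exp, heats=tuple(float(v) for v in q),
                       dilution_heats=blanks)


def gen_dosy(
    D: float,
    I0: float = 1000.0,
    n_steps: int = 16,
    frac_range: tuple[float, float] = (0.02, 0.95),
    max_gradient: float = DEFAULT_DOSY_MAX_GRADIENT,
    delta_ms: float = 2.5,
    Delta_ms: float = 250.0,
    noise: NoiseSpec = NOISELESS,
) -> DiffusionSeries:
    """Synthetic PFG decay on the Stejskal–Tanner law."""
    if D < 0:
        raise ValueError("D must be >= 0")
    fracs = np.linspace(frac_range[0], frac_range[1], n_steps)
    series = DiffusionSeries(
        gradient_fraction=fracs,
        intensity=np.full(n_steps, I0),
        max_gradient=max_gradient,
        delta_ms=delta_ms,
        Delta_ms=Delta_ms,
    )
    x = stejskal_tanner_factor(series)
    intens = I0 * np.exp(-D * x)
    intens = intens + noise.rng().normal(0.0, noise.sigma, size=intens.shape)
    intens = np.maximum(intens, 1e-9 * I0)  # intensities must stay positive
    return DiffusionSeries(
        gradient_fraction=fracs, intensity=intens,
        max_gradient=max_gradient, delta_ms=delta_ms, Delta_ms=Delta_ms,
    )
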