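"""Study orchestration: run every technique from a manifest, compare D vs L.

A study manifest (YAML) lists the peptides, per-technique data files for each
(peptide, importin species) pair, and optional L-isomer reference Kd values.
``run_study`` executes every dataset independently — a failure in one is
recorded and does not abort the rest — and assembles a tidy results table
with one row per (peptide, species).  ``compare_enantiomers`` adds fold
differences Kd(D)/Kd(L) and a concordance flag (same order of magnitude,
fold within [0.1, 10] by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bli, disorder, fluorescence, hydro, itc

TECHNIQUES = ("fluorescence", "bli", "itc", "dosy", "disorder")

CONCORDANCE_WINDOW = (0.1, 10.0)


class ManifestError(ValueError):
    pass


@dataclass
class StudyManifest:
    peptides: dict[str, dict]
    datasets: list[dict]
    l_reference: dict[tuple[str, str], float] = field(default_factory=dict)
    base_dir: Path = Path(".")

    def validate(self) -> None:
        if not self.datasets:
            raise ManifestError("manifest lists no datasets")
        seen = set()
        for d in self.datasets:
            tech = d.get("technique")
            if tech not in TECHNIQUES:
                raise ManifestError(f"unknown technique {tech!r}")
            key = (d.get("peptide"), d.get("species"), tech)
            if key in seen:
                raise ManifestError(f"duplicate dataset {key}")
            seen.add(key)
            for pk in ("path", "shifts_path", "noes_path", "reference_path"):
                if pk in d and not (self.base_dir / d[pk]).exists():
                    raise ManifestError(f"missing file {d[pk]!r}")
            for f in d.get("files", []):
                if not (self.base_dir / f["path"]).exists():
                    raise ManifestError(f"missing file {f['path']!r}")


def load_manifest(path: str | Path) -> StudyManifest:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    peptides = {p["id"]: p for p in raw.get("peptides", [])}
    l_ref = {}
    for entry in raw.get("l_reference", []):
        l_ref[(entry["peptide"], entry["species"])] = float(entry["kd"])
    m = StudyManifest(
        peptides=peptides,
        datasets=raw.get("datasets", []),
        l_reference=l_ref,
        base_dir=path.parent,
    )
    m.validate()
    return m


def _run_fluorescence(d: dict, base: Path) -> dict:
    curve = fluorescence.TitrationCurve.read_csv(
        base / d["path"],
        receptor_total=float(d["receptor_total_uM"]),
    )
    fit = fluorescence.fit_titration(curve, inner_filter=bool(d.get("inner_filter", False)))
    return {
        "kd_fluor": fit.Kd, "kd_fluor_se": fit.Kd_se,
        "fluor_reliability": fit.reliability.value,
    }


def _run_bli(d: dict, base: Path) -> dict:
    sched = bli.PhaseSchedule(**d.get("schedule", {}))
    sensorgrams = []
    for f in d["files"]:
        df = pd.read_csv(base / f["path"], comment="#")
        sensorgrams.append(
            bli.Sensorgram(
                time=df["time_s"].to_numpy(),
                response=df["response_RU"].to_numpy(),
                ligand_conc=float(f["ligand_conc_uM"]),
                schedule=sched,
            )
        )
    res = bli.SensorgramKinetics(sensorgrams).fit()
    return {
        "kon": res.kon, "kon_se": res.kon_se,
        "koff": res.koff, "koff_se": res.koff_se,
        "kd_bli": res.Kd, "kd_bli_se": res.Kd_se,
        "intercept_valid": res.intercept_valid,
    }


def _run_itc(d: dict, base: Path) -> dict:
    df = pd.read_csv(base / d["path"], comment="#")
    exp_kw = d.get("experiment", {})
    exp = itc.ITCExperiment(
        cell_volume_ml=float(exp_kw.get("cell_volume_ml", 1.4)),
        cell_conc=float(exp_kw.get("cell_conc_uM", 15.0)),
        syringe_conc=float(exp_kw.get("syringe_conc_uM", 175.0)),
        injection_volumes_ul=tuple(df["volume_uL"].astype(float)),
        temperature_C=float(exp_kw.get("temperature_C", 25.0)),
    )
    blanks = None
    if "dilution_ucal" in df.columns:
        blanks = tuple(df["dilution_ucal"].astype(float))
    iso = itc.ITCIsotherm(
        experiment=exp,
        heats=tuple(df["heat_ucal"].astype(float)),
        dilution_heats=blanks,
    )
    fit = itc.fit_itc(iso, dilution="blank" if blanks is not None else None)
    return {
        "kd_itc": fit.Kd, "kd_itc_se": fit.Kd_se,
        "itc_n": fit.n, "itc_dh": fit.dH, "itc_dg": fit.dG,
        "itc_minus_tds": fit.minus_TdS,
    }


def _run_dosy(d: dict, base: Path) -> dict:
    def read_series(p):
        df = pd.read_csv(base / p, comment="#")
        return hydro.DiffusionSeries(
            gradient_fraction=df["gradient_fraction"].to_numpy(),
            intensity=df["intensity"].to_numpy(),
            max_gradient=float(d["max_gradient"]),
            delta_ms=float(d.get("delta_ms", 2.5)),
            Delta_ms=float(d.get("Delta_ms", 250.0)),
        )

    res = hydro.analyze_hydrodynamics(
        read_series(d["path"]),
        read_series(d["reference_path"]),
        mw=float(d["mw_da"]),
        rh_coil_se=float(d["rh_coil_se_A"]) if "rh_coil_se_A" in d else None,
    )
    return {
        "diffusion_D": res.D, "rh_ref_A": res.Rh_ref,
        "rh_coil_A": res.Rh_scale, "oligomeric_verdict": res.verdict.value,
    }


def _run_disorder(d: dict, base: Path, sequence: str, offset: int) -> dict:
    shifts = pd.read_csv(base / d["shifts_path"], comment="#")
    table = disorder.conformational_shifts(shifts, sequence, numbering_offset=offset)
    contacts = []
    noes = pd.read_csv(base / d["noes_path"], comment="#")
    for _, row in noes.iterrows():
        contacts.append(
            disorder.NOEContact(
                i=int(row["i"]), j=int(row["j"]),
                contact_class=str(row["class"]),
                intensity=str(row.get("intensity", "medium")),
                unambiguous=bool(row.get("unambiguous", True)),
            )
        )
    verdict = disorder.classify_disorder(table, contacts, sequence_length=len(sequence))
    return {
        "shift_verdict": verdict.by_shifts.value,
        "noe_verdict": verdict.by_noes.value,
        "assignment_coverage": verdict.coverage,
    }


_RUNNERS = {
    "fluorescence": _run_fluorescence,
    "bli": _run_bli,
    "itc": _run_itc,
    "dosy": _run_dosy,
}


@dataclass
class StudyResult:
    table: pd.DataFrame
    failures: list[dict]

    def to_dir(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "results.csv", index=False)
        meta = {
            "n_datasets_ok": int(len(self.table)),
            "failures": self.failures,
        }
        with open(out / "results.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)


def run_study(manifest: StudyManifest, out_dir: str | Path | None = None) -> StudyResult:
    """Execute every dataset in the manifest; per-dataset faults are isolated."""
    manifest.validate()
    rows: dict[tuple[str, str], dict] = {}
    failures: list[dict] = []
    for d in manifest.datasets:
        peptide, species, tech = d.get("peptide", ""), d.get("species", ""), d["technique"]
        key = (peptide, species)
        try:
            if tech == "disorder":
                pep = manifest.peptides.get(peptide, {})
                res = _run_disorder(
                    d, manifest.base_dir,
                    sequence=pep.get("sequence", ""),
                    offset=int(pep.get("numbering_offset", 1)),
                )
            else:
                res = _RUNNERS[tech](d, manifest.base_dir)
        except Exception as err:  # fault isolation: record, keep going
            failures.append(
                {"peptide": peptide, "species": species, "technique": tech,
                 "error": f"{type(err).__name__}: {err}"}
            )
            continue
        rows.setdefault(key, {"peptide": peptide, "species": species}).update(res)
    table = pd.DataFrame(list(rows.values()))
    result = StudyResult(table=table, failures=failures)
    if out_dir is not None:
        result.to_dir(out_dir)
    return result


def compare_enantiomers(
    d_results: pd.DataFrame,
    l_reference: dict[tuple[str, str], float],
    window: tuple[float, float] = CONCORDANCE_WINDOW,
) -> pd.DataFrame:
    """Fold differences Kd(D)/Kd(L) per (peptide, species).

    The D-side Kd is the first available of BLI, ITC, fluorescence.  Rows
    without an L reference keep empty comparison columns.
    """
    out = []
    for _, row in d_results.iterrows():
        kd_d = None
        for col in ("kd_bli", "kd_itc", "kd_fluor"):
            v = row.get(col)
            if v is not None and not pd.isna(v):
                kd_d = float(v)
                break
        kd_l = l_reference.get((row["peptide"], row["species"]))
        fold = concordant = None
        if kd_d is not None and kd_l is not None and kd_d > 0 and kd_l > 0:
            fold = kd_d / kd_l
            concordant = window[0] <= fold <= window[1]
        out.append(
            {
                "peptide": row["peptide"], "species": row["species"],
                "kd_d": kd_d, "kd_l": kd_l,
                "fold_difference": fold, "concordant": concordant,
            }
        )
    return pd.DataFrame(out)
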