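"""NMR disorder metrics for short peptides.

Two orthogonal classifiers of chain disorder from assigned homonuclear
spectra:

* **Conformational shifts.**  Δδ = observed Hα shift − random-coil reference,
  the reference being a tabulated per-residue value with a nearest-neighbor
  correction (the residue preceding a proline shifts downfield by ~0.29 ppm).
  |Δδ| ≤ 0.1 ppm across the chain is the accepted random-coil signature; a
  run of same-sign outliers marks locally structured regions (negative runs
  are helical-like, positive extended-like).

* **NOE pattern.**  A disordered chain shows only sequential (i, i+1)
  NOESY contacts (αN, βN, and αδ at prolines); any medium- (|j−i| of 2–4) or
  long-range (≥5) contact is evidence of persistent structure.

D-peptides are scored against the same (L-residue) reference table: chemical
shifts are insensitive to a global mirror inversion of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
import pandas as pd

HALPHA_THRESHOLD_PPM = 0.1
PRE_PROLINE_HALPHA_PPM = 0.29  # downfield correction for residue i when i+1 is Pro


class ShiftVerdict(str, Enum):
    RANDOM_COIL = "random_coil"
    STRUCTURED_REGIONS = "structured_regions"
    INSUFFICIENT = "insufficient"


class NOEVerdict(str, Enum):
    DISORDERED = "disordered"
    MEDIUM_OR_LONG_RANGE_PRESENT = "medium_or_long_range_present"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class NOEContact:
    i: int
    j: int
    contact_class: str  # αN, βN, αδ, NN, other
    intensity: str = "medium"  # strong / medium / weak
    unambiguous: bool = True

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("inter-residue contact requires i != j")

    @property
    def range(self) -> int:
        return abs(self.j - self.i)


@dataclass
class DisorderVerdict:
    by_shifts: ShiftVerdict
    by_noes: NOEVerdict
    flagged_residues: list[int]
    coverage: float | None = None  # fraction of sequence with assignments

    def summary(self) -> str:
        cov = f"{self.coverage:.0%}" if self.coverage is not None else "n/a"
        return (
            "Disorder classification\n"
            "=======================\n"
            f"by Hα shifts: {self.by_shifts.value}\n"
            f"by NOEs     : {self.by_noes.value}\n"
            f"flagged residues: {self.flagged_residues or 'none'}\n"
            f"assignment coverage: {cov}"
        )


def random_coil_table() -> dict[str, float]:
    """Bundled random-coil Hα reference shifts (ppm) per residue type."""
    with resources.files("nlsbind.data").joinpath("random_coil_halpha.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["residue"], df["halpha_ppm"]))


def conformational_shifts(
    observed: pd.DataFrame,
    sequence: str,
    numbering_offset: int = 1,
) -> pd.DataFrame:
    """Sequence-corrected Hα conformational shifts.

    ``observed`` needs columns position, residue, halpha_ppm, with positions
    in the parent-protein numbering starting at ``numbering_offset``.
    Returns a table with the corrected random-coil reference and
    Δδ = observed − reference per assigned residue.
    """
    ref = random_coil_table()
    rows = []
    for _, rec in observed.iterrows():
        pos = int(rec["position"])
        idx = pos - numbering_offset  # 0-based into sequence
        if not 0 <= idx < len(sequence):
            raise ValueError(f"position {pos} outside the peptide sequence")
        res = str(rec["residue"]).upper()
        if sequence[idx] != res:
            raise ValueError(
                f"residue mismatch at position {pos}: table says {res}, "
                f"sequence has {sequence[idx]}"
            )
        rc = ref[res]
        if idx + 1 < len(sequence) and sequence[idx + 1] == "P":
            rc += PRE_PROLINE_HALPHA_PPM
        rows.append(
            {
                "position": pos,
                "residue": res,
                "halpha_ppm": float(rec["halpha_ppm"]),
                "random_coil_ppm": rc,
                "delta_ppm": float(rec["halpha_ppm"]) - rc,
            }
        )
    return pd.DataFrame(rows).sort_values("position").reset_index(drop=True)


def classify_disorder_from_shifts(
    table: pd.DataFrame,
    threshold: float = HALPHA_THRESHOLD_PPM,
    min_run: int = 3,
) -> tuple[ShiftVerdict, list[int]]:
    """Random-coil test on a conformational-shift table.

    All |Δδ| ≤ threshold ⇒ random coil.  A run of ≥ ``min_run`` consecutive
    assigned residues exceeding the threshold with a common sign ⇒ structured
    regions.  Isolated outliers are flagged but do not change the verdict.
    Fewer than 5 assigned residues ⇒ insufficient.
    """
    if len(table) < 5:
        return ShiftVerdict.INSUFFICIENT, []
    t = table.sort_values("position")
    positions = t["position"].to_numpy()
    dd = t["delta_ppm"].to_numpy()
    outlier = np.abs(dd) > threshold
    flagged = [int(p) for p in positions[outlier]]
    if not outlier.any():
        return ShiftVerdict.RANDOM_COIL, []
    run = 0
    run_sign = 0
    prev_pos = None
    for pos, d, out in zip(positions, dd, outlier):
        consecutive = prev_pos is not None and pos == prev_pos + 1
        if out:
            sign = 1 if d > 0 else -1
            if consecutive and sign == run_sign:
                run += 1
            else:
                run, run_sign = 1, sign
            if run >= min_run:
                return ShiftVerdict.STRUCTURED_REGIONS, flagged
        else:
            run, run_sign = 0, 0
        prev_pos = pos
    return ShiftVerdict.RANDOM_COIL, flagged


def classify_noe_pattern(
    contacts: list[NOEContact],
    include_ambiguous: bool = False,
) -> NOEVerdict:
    """Sequential-only NOE test: any |j−i| ≥ 2 contact indicates structure."""
    usable = [c for c in contacts if include_ambiguous or c.unambiguous]
    if not usable:
        return NOEVerdict.INDETERMINATE
    if any(c.range >= 2 for c in usable):
        return NOEVerdict.MEDIUM_OR_LONG_RANGE_PRESENT
    return NOEVerdict.DISORDERED


def classify_disorder(
    shift_table: pd.DataFrame,
    contacts: list[NOEContact],
    sequence_length: int | None = None,
    threshold: float = HALPHA_THRESHOLD_PPM,
    min_run: int = 3,
) -> DisorderVerdict:
    """Combined verdict from shifts and NOEs, with assignment coverage."""
    by_shifts, flagged = classify_disorder_from_shifts(shift_table, threshold, min_run)
    by_noes = classify_noe_pattern(contacts)
    coverage = None
    if sequence_length:
        coverage = len(shift_table) / sequence_length
    return DisorderVerdict(by_shifts=by_shifts, by_noes=by_noes,
                           flagged_residues=flagged, coverage=coverage)
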