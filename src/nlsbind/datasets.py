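"""Reported study parameters for D-enantiomeric NLS peptides and importin α3.

These tables collect the published binding and hydrodynamic parameters for
four all-D NLS peptides against full-length importin α3 ("full") and the
IBB-truncated species ("ibb_truncated"): BLI rate constants with fitting
errors, the dissociation constants available from ITC or fluorescence, the
ITC binding enthalpies, and the peptide sequences with molecular weights.
They serve as inputs for simulation studies and as regression surfaces for
the analysis chain; None marks quantities that could not be determined (the
BLI koff of the unmodified NUPR1 peptide has a negative pseudo-first-order
intercept, and most fluorescence/ITC cells showed no fittable isotherm).

The koff error printed for the NUPR1L peptide against the truncated importin
(0.038 ± 0.05 s⁻¹) is reproduced verbatim even though it is inconsistent
with the quadrature-propagated Kd error (0.7 ± 0.2 μM); only the Kd point
value should be relied on for that row.

The molecular weight listed for the phosphopeptide (2541.78 Da) is likewise
reproduced verbatim; it sits only +30.00 Da above the unmodified peptide,
whereas a phosphate adds 79.98 Da.
"""

from __future__ import annotations

import pandas as pd

from .peptides import Chirality, PeptideRecord, TerminalCap, parse_peptide

PEPTIDES: dict[str, PeptideRecord] = {
    "D-NLS-NUPR1": parse_peptide(
        "YTNRPSPGGHERKLVTKLQNSE", id="D-NLS-NUPR1",
        chirality=Chirality.D, n_terminal_cap=TerminalCap.ACETYL,
        c_terminal_cap=TerminalCap.AMIDE, numbering_offset=53,
    ),
    "D-NLS-NUPR1phospho": parse_peptide(
        "YTNRPSPGGHERKLV{pT}KLQNSE", id="D-NLS-NUPR1phospho",
        chirality=Chirality.D, n_terminal_cap=TerminalCap.ACETYL,
        c_terminal_cap=TerminalCap.AMIDE, numbering_offset=53,
    ),
    "D-NLS-NUPR1L": parse_peptide(
        "RTRREQALRTNWPAPGGHERKVAQ", id="D-NLS-NUPR1L",
        chirality=Chirality.D, n_terminal_cap=TerminalCap.ACETYL,
        c_terminal_cap=TerminalCap.AMIDE, numbering_offset=51,
    ),
    "D-NLS-PADI": parse_peptide(
        "KLFQEQQNEGHGEALLFEGIKKKKQQKI", id="D-NLS-PADI",
        chirality=Chirality.D, n_terminal_cap=TerminalCap.ACETYL,
        c_terminal_cap=TerminalCap.AMIDE, numbering_offset=499,
    ),
}

# reported molecular weights (Da, average, uncapped) and random-coil Rh (Å)
HYDRO_REFERENCE = pd.DataFrame(
    [
        ("D-NLS-NUPR1", 2511.78, 13.0, 3.0),
        ("D-NLS-NUPR1phospho", 2541.78, 13.0, 3.0),
        ("D-NLS-NUPR1L", 2815.15, 14.0, 2.0),
        ("D-NLS-PADI", 3297.80, 15.0, 2.0),
    ],
    columns=["peptide", "mw_da", "rh_coil_A", "rh_coil_se_A"],
)

# BLI rate constants (μM⁻¹ s⁻¹, s⁻¹) and derived Kd (μM); None = not determined
BLI_REFERENCE = pd.DataFrame(
    [
        ("D-NLS-NUPR1", "full", 0.05, 0.01, None, None, None, None),
        ("D-NLS-NUPR1phospho", "full", 0.010, 0.003, 0.13, 0.02, 13.0, 4.0),
        ("D-NLS-NUPR1L", "full", 0.068, 0.007, 0.069, 0.04, 1.0, 0.6),
        ("D-NLS-PADI", "full", 0.045, 0.02, 0.6, 0.1, 15.0, 3.0),
        ("D-NLS-NUPR1", "ibb_truncated", 0.11, 0.02, None, None, None, None),
        ("D-NLS-NUPR1phospho", "ibb_truncated", 0.006, 0.001, 0.05, 0.01, 8.0, 2.0),
        ("D-NLS-NUPR1L", "ibb_truncated", 0.0512, 0.0007, 0.038, 0.05, 0.7, 0.2),
        ("D-NLS-PADI", "ibb_truncated", 0.06, 0.01, 0.37, 0.05, 6.0, 1.0),
    ],
    columns=["peptide", "species", "kon", "kon_se", "koff", "koff_se", "kd", "kd_se"],
)

# equilibrium Kd (μM) by ITC or fluorescence where an isotherm was fittable
EQUILIBRIUM_REFERENCE = pd.DataFrame(
    [
        ("D-NLS-NUPR1L", "full", "itc", 2.7, 0.6),
        ("D-NLS-NUPR1L", "ibb_truncated", "itc", 5.0, 1.0),
        ("D-NLS-PADI", "full", "fluorescence", 12.0, 5.0),
        ("D-NLS-PADI", "ibb_truncated", "fluorescence", 16.0, 11.0),
    ],
    columns=["peptide", "species", "technique", "kd", "kd_se"],
)

# ITC enthalpies (kcal mol⁻¹) for the one peptide with measurable isotherms
ITC_ENTHALPY_REFERENCE = pd.DataFrame(
    [
        ("D-NLS-NUPR1L", "full", -2.5, 0.2),
        ("D-NLS-NUPR1L", "ibb_truncated", -4.5, 0.7),
    ],
    columns=["peptide", "species", "dh_kcal_mol", "dh_se"],
)

# L-isomer reference Kd values (μM) for enantiomer comparisons
L_REFERENCE_KD = pd.DataFrame(
    [
        ("D-NLS-NUPR1", "full", 1.7),
        ("D-NLS-NUPR1phospho", "full", 27.0),
        ("D-NLS-NUPR1L", "full", 3.0),
        ("D-NLS-PADI", "full", 4.0),
        ("D-NLS-NUPR1", "ibb_truncated", 0.95),
        ("D-NLS-NUPR1phospho", "ibb_truncated", 29.0),
        ("D-NLS-NUPR1L", "ibb_truncated", 5.0),
        ("D-NLS-PADI", "ibb_truncated", 4.0),
    ],
    columns=["peptide", "species", "kd_l"],
)


def bli_rates(peptide: str, species: str) -> tuple[float, float]:
    """(kon, koff) for one peptide/importin pair; raises if koff undetermined."""
    row = BLI_REFERENCE[
        (BLI_REFERENCE.peptide == peptide) & (BLI_REFERENCE.species == species)
    ]
    if row.empty:
        raise KeyError(f"no BLI reference for {peptide}/{species}")
    kon, koff = float(row.iloc[0].kon), row.iloc[0].koff
    if koff is None or pd.isna(koff):
        raise ValueError(f"koff not determined for {peptide}/{species}")
    return kon, float(koff)
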