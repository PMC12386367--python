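"""Peptide records, modification handling and molecular weight.

Peptides are short (20–30 residue) nuclear-localization-signal (NLS)
sequences, synthesized either from L- or D-amino acids and usually capped
(N-terminal acetyl, C-terminal amide) to suppress charge fraying.  The
molecular weight computed here feeds the random-coil hydrodynamic scale law
in :mod:`nlsbind.hydro`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from Bio.SeqUtils import molecular_weight as _bio_mw

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

WATER_MASS = 18.0153  # average, Da

# average mass deltas for supported modification tags, Da
MODIFICATION_MASSES = {
    "p": 79.9799,  # phosphorylation (HPO3)
}

ACETYL_MASS = 42.0367  # N-terminal acetyl cap (replaces one amine H)
AMIDE_MASS = -0.9847   # C-terminal amide cap (OH -> NH2)


class Chirality(str, Enum):
    L = "L"
    D = "D"


class TerminalCap(str, Enum):
    FREE = "free"
    ACETYL = "acetyl"
    AMIDE = "amide"


class PeptideParseError(ValueError):
    pass


@dataclass(frozen=True)
class Modification:
    """A covalent modification at a 1-based sequence position."""

    position: int
    tag: str
    mass_delta: float


@dataclass(frozen=True)
class MolecularWeight:
    value: float  # Da, average isotopic
    includes_caps: bool


@dataclass(frozen=True)
class PeptideRecord:
    id: str
    sequence: str
    chirality: Chirality = Chirality.L
    modifications: tuple[Modification, ...] = field(default_factory=tuple)
    n_terminal_cap: TerminalCap = TerminalCap.FREE
    c_terminal_cap: TerminalCap = TerminalCap.FREE
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideParseError("empty peptide sequence")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in AMINO_ACIDS:
                raise PeptideParseError(
                    f"unknown residue {ch!r} at position {i}"
                )
        for m in self.modifications:
            if not 1 <= m.position <= len(self.sequence):
                raise PeptideParseError(
                    f"modification position {m.position} outside sequence "
                    f"of length {len(self.sequence)}"
                )
            if m.tag == "p" and m.mass_delta <= 0:
                raise PeptideParseError("phospho mass delta must be positive")

    def __len__(self) -> int:
        return len(self.sequence)


# numbering annotations like "T^54^" or markdown bold markers are stripped
_ANNOTATION = re.compile(r"\^[0-9]+\^|\*\*|\s+|[0-9]")
_MOD_GROUP = re.compile(r"\{([a-z])([A-Z])\}")


def parse_peptide(
    text: str,
    id: str = "",
    chirality: Chirality | str = Chirality.L,
    n_terminal_cap: TerminalCap | str = TerminalCap.FREE,
    c_terminal_cap: TerminalCap | str = TerminalCap.FREE,
    numbering_offset: int = 1,
) -> PeptideRecord:
    """Parse a one-letter sequence with optional ``{pT}``-style inline tags.

    Residue-numbering superscripts (``T^54^``), digits, whitespace and
    markdown bold markers are stripped before parsing.  Inline tags are a
    lowercase modification letter plus the residue, in braces; the only tag
    understood out of the box is ``p`` (phospho, +79.98 Da).
    """
    if isinstance(chirality, str):
        chirality = Chirality(chirality)
    if isinstance(n_terminal_cap, str):
        n_terminal_cap = TerminalCap(n_terminal_cap)
    if isinstance(c_terminal_cap, str):
        c_terminal_cap = TerminalCap(c_terminal_cap)

    cleaned = _ANNOTATION.sub("", text)
    if not cleaned:
        raise PeptideParseError("empty peptide sequence")

    sequence: list[str] = []
    modifications: list[Modification] = []
    i = 0
    while i < len(cleaned):
        m = _MOD_GROUP.match(cleaned, i)
        if m:
            tag, residue = m.group(1), m.group(2)
            if tag not in MODIFICATION_MASSES:
                raise PeptideParseError(f"unknown modification tag {tag!r}")
            sequence.append(residue)
            modifications.append(
                Modification(len(sequence), tag, MODIFICATION_MASSES[tag])
            )
            i = m.end()
            continue
        ch = cleaned[i]
        if ch not in AMINO_ACIDS:
            raise PeptideParseError(
                f"unknown residue {ch!r} at position {len(sequence) + 1}"
            )
        sequence.append(ch)
        i += 1

    return PeptideRecord(
        id=id or cleaned,
        sequence="".join(sequence),
        chirality=chirality,
        modifications=tuple(modifications),
        n_terminal_cap=n_terminal_cap,
        c_terminal_cap=c_terminal_cap,
        numbering_offset=numbering_offset,
    )


def molecular_weight(p: PeptideRecord, include_caps: bool = False) -> MolecularWeight:
    """Average molecular weight: residue masses + one water + mod deltas.

    Terminal caps contribute only when ``include_caps`` is set; D- and
    L-residues are isobaric, so chirality never enters.
    """
    mw = _bio_mw(p.sequence, seq_type="protein", monoisotopic=False)
    mw += sum(m.mass_delta for m in p.modifications)
    if include_caps:
        if p.n_terminal_cap is TerminalCap.ACETYL:
            mw += ACETYL_MASS
        if p.c_terminal_cap is TerminalCap.AMIDE:
            mw += AMIDE_MASS
    return MolecularWeight(value=mw, includes_caps=include_caps)
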