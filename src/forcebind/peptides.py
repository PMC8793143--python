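"""Peptide library utilities.

The package analyses the hydroxyapatite-binding dodecapeptide SVSVGMKPSPRP
and its variants: the SVSV / GMKPSPRP subdomains and the single-residue
alanine-scan derivatives named ``XNA`` (native residue X at 1-based position N
replaced by alanine).  This module builds that library and supplies the
molecular-weight and net-charge bookkeeping the adsorption analysis needs.

Charges use an integer model at neutral pH: +1 per Lys/Arg, -1 per Asp/Glu,
+1/-1 for free N-/C-termini, His neutral.  Masses are average (not
monoisotopic) residue masses, since surface-concentration accounting divides
areal mass density by bulk molecular weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The native hydroxyapatite-binding peptide (phage-display dodecamer).
NATIVE_SEQUENCE = "SVSVGMKPSPRP"

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Average residue masses (Da); a residue is the amino acid minus one water.
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MASS = 18.0153

# Side-chain / termini pKa values (EMBOSS set) for the optional fractional
# charge mode.  positive: proton-bound form charged; negative: deprotonated
# form charged.
_PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
_PKA_NTERM = 8.6
_PKA_CTERM = 3.6


def validate_sequence(sequence: str) -> str:
    """Return ``sequence`` upper-cased, or raise naming the offending residue."""
    if not isinstance(sequence, str) or len(sequence) == 0:
        raise ValueError("peptide sequence must be a non-empty string")
    seq = sequence.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACIDS:
            raise ValueError(
                f"invalid residue {ch!r} at position {i} in sequence {sequence!r}"
            )
    return seq


@dataclass(frozen=True)
class Peptide:
    """A named peptide sequence with derived mass and charge.

    ``name`` is a short label ("native", "K7A", "SVSV", ...); ``sequence`` is
    one-letter code.  Positions in names are 1-based, matching the XNA
    alanine-scan convention.
    """

    name: str
    sequence: str = field(default="")

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", validate_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mw(self) -> float:
        """Average molecular mass, Da."""
        return average_mass(self.sequence)

    @property
    def net_charge(self) -> int:
        """Integer net charge at neutral pH with free termini."""
        return net_charge(self.sequence)


def average_mass(sequence: str) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    seq = validate_sequence(sequence)
    return sum(AVERAGE_RESIDUE_MASS[ch] for ch in seq) + WATER_MASS


def net_charge(sequence: str, free_termini: bool = True) -> int:
    """Integer net charge at neutral pH.

    +1 per Lys/Arg, -1 per Asp/Glu; His neutral; free termini contribute
    +1 (N) and -1 (C), which cancel, so they matter only when blocked
    asymmetrically or for bookkeeping clarity.
    """
    seq = validate_sequence(sequence)
    charge = sum(ch in ("K", "R") for ch in seq) - sum(ch in ("D", "E") for ch in seq)
    if free_termini:
        charge += 1 - 1
    return charge


def fractional_charge(sequence: str, ph: float = 7.2, free_termini: bool = True) -> float:
    """Henderson-Hasselbalch fractional net charge (non-default mode).

    Provided for sensitivity checks; the integer model is what the analysis
    and tests use.
    """
    seq = validate_sequence(sequence)

    def pos(pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))

    def neg(pka: float) -> float:
        return -1.0 / (1.0 + 10.0 ** (pka - ph))

    q = 0.0
    for ch in seq:
        if ch in _PKA_POSITIVE:
            q += pos(_PKA_POSITIVE[ch])
        elif ch in _PKA_NEGATIVE:
            q += neg(_PKA_NEGATIVE[ch])
    if free_termini:
        q += pos(_PKA_NTERM) + neg(_PKA_CTERM)
    return q


def make_alanine_scan(native: "Peptide | str") -> list[Peptide]:
    """One derivative per non-alanine position, named XNA, ordered by position.

    Positions already holding alanine are skipped, so the native dodecamer
    (which contains no alanine) yields exactly 12 derivatives.
    """
    pep = native if isinstance(native, Peptide) else Peptide("native", native)
    derivatives = []
    for i, residue in enumerate(pep.sequence, start=1):
        if residue == "A":
            continue
        mutated = pep.sequence[: i - 1] + "A" + pep.sequence[i:]
        derivatives.append(Peptide(f"{residue}{i}A", mutated))
    return derivatives


def subdomains(peptide: "Peptide | str", split: int) -> tuple[Peptide, Peptide]:
    """Split into prefix (1..split) and suffix (split+1..end) subdomains."""
    pep = peptide if isinstance(peptide, Peptide) else Peptide("peptide", peptide)
    if not 1 <= split < len(pep.sequence):
        raise ValueError(
            f"split position {split} out of range for length {len(pep.sequence)}"
        )
    prefix = Peptide(f"{pep.name}[1-{split}]", pep.sequence[:split])
    suffix = Peptide(f"{pep.name}[{split + 1}-{len(pep)}]", pep.sequence[split:])
    return prefix, suffix


def standard_library(native_sequence: str = NATIVE_SEQUENCE) -> list[Peptide]:
    """Native peptide, its two subdomains, and the full alanine scan.

    For the native dodecamer the subdomains are SVSV (positions 1-4) and the
    SVSV-deleted remainder GMKPSPRP.
    """
    native = Peptide("native", native_sequence)
    prefix, suffix = subdomains(native, 4)
    library = [
        native,
        Peptide("SVSV", prefix.sequence),
        Peptide("dSVSV", suffix.sequence),
    ]
    library.extend(make_alanine_scan(native))
    return library


def library_table(peptides: Sequence[Peptide], free_termini: bool = True) -> pd.DataFrame:
    """Delimited-table view: name, sequence, mw (Da), net_charge (e)."""
    return pd.DataFrame(
        {
            "name": [p.name for p in peptides],
            "sequence": [p.sequence for p in peptides],
            "mw": [round(p.mw, 4) for p in peptides],
            "net_charge": [net_charge(p.sequence, free_termini) for p in peptides],
        }
    )


def write_fasta(peptides: Iterable[Peptide], path: "str | Path") -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.name, description="") for p in peptides
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: "str | Path") -> list[Peptide]:
    return [Peptide(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def lookup(name: str, native_sequence: str = NATIVE_SEQUENCE) -> Peptide:
    """Find a library peptide by label (e.g. "native", "K7A")."""
    for pep in standard_library(native_sequence):
        if pep.name == name:
            return pep
    raise KeyError(f"unknown peptide label {name!r}")
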