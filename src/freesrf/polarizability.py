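"""Dry (solute) polarizabilities by strict additivity.

Proteins: sum of per-residue contributions over the sequence.
Small molecules and ions: sum of per-atom contributions over the elemental
composition — no bond-order or conjugation corrections, so aromatic systems
are mildly underestimated; the solvation shell dominates the observable in
every regime of interest.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

from Bio import SeqIO

from .errors import EmptyInputError, LookupMissError, ValidationError
from .reference_data import (
    NONSTANDARD_CODES,
    PolarizabilityTable,
    with_mean_substitution,
)

WATER_MASS = 18.015  # g/mol, added back for N-1 peptide bonds

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation formula string (e.g. ``"C6H7NO2S"``) into element counts.

    No installed library exposes a bare formula parser (RDKit wants SMILES/mol
    blocks), so this is done here.  Parenthesised groups are not supported.
    """
    formula = formula.strip()
    if not formula:
        raise EmptyInputError("empty formula")
    pos = 0
    counts: Counter[str] = Counter()
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r} at position {pos}")
        element, digits = match.groups()
        counts[element] += int(digits) if digits else 1
        pos = match.end()
    if pos != len(formula):
        raise ValidationError(f"cannot parse formula {formula!r} at position {pos}")
    return dict(counts)


def protein_polarizability(
    sequence: str,
    table: PolarizabilityTable,
    on_nonstandard: Literal["raise", "mean"] = "raise",
) -> float:
    """Polarizability (A^3) of a protein: sum of per-residue contributions.

    Strictly additive, hence permutation-invariant and linear under
    concatenation.  Nonstandard codes (X/B/Z/U...) raise unless
    ``on_nonstandard="mean"`` maps them to the mean residue contribution.
    """
    if not sequence:
        raise EmptyInputError("empty protein sequence")
    if on_nonstandard == "mean":
        table = with_mean_substitution(table)
    total = 0.0
    for residue in sequence.upper():
        try:
            total += table.residue_alpha[residue]
        except KeyError:
            hint = " (pass on_nonstandard='mean' to substitute)" \
                if residue in NONSTANDARD_CODES else ""
            raise LookupMissError(f"unknown residue {residue!r}{hint}") from None
    return total


def protein_molar_mass(
    sequence: str,
    table: PolarizabilityTable,
    on_nonstandard: Literal["raise", "mean"] = "raise",
) -> float:
    """Average molar mass (g/mol) of the chain: residue masses plus one water."""
    if not sequence:
        raise EmptyInputError("empty protein sequence")
    if on_nonstandard == "mean":
        table = with_mean_substitution(table)
    try:
        return sum(table.residue_mass[r] for r in sequence.upper()) + WATER_MASS
    except KeyError as exc:
        raise LookupMissError(f"unknown residue {exc.args[0]!r}") from None


def molecule_polarizability(
    composition: Mapping[str, int], table: PolarizabilityTable
) -> float:
    """Polarizability (A^3) of a small molecule: sum of per-atom contributions."""
    if not composition:
        raise EmptyInputError("empty composition")
    total = 0.0
    for element, count in composition.items():
        if not (isinstance(count, (int,)) and count > 0):
            raise ValidationError(f"count for {element!r} must be a positive integer, got {count}")
        try:
            total += count * table.atom_alpha[element]
        except KeyError:
            raise LookupMissError(f"unknown element {element!r}") from None
    return total


def molecule_molar_mass(composition: Mapping[str, int], table: PolarizabilityTable) -> float:
    if not composition:
        raise EmptyInputError("empty composition")
    try:
        return sum(n * table.atom_mass[e] for e, n in composition.items())
    except KeyError as exc:
        raise LookupMissError(f"unknown element {exc.args[0]!r}") from None


def ion_polarizability(symbol: str, table: PolarizabilityTable) -> float:
    """Literature polarizability (A^3) of a monatomic ion stored in the atom table."""
    try:
        return table.atom_alpha[symbol]
    except KeyError:
        raise LookupMissError(f"unknown ion {symbol!r}") from None


_CHARGE_SUFFIX = re.compile(r"(\d*)([+-])$")


@dataclass(frozen=True)
class MolecularSpecies:
    """A receptor or ligand with its dry polarizability and molar mass.

    ``composition`` is the sequence string for proteins, an element->count map
    for small molecules, and the ion symbol for ions.
    """

    label: str
    kind: Literal["protein", "small_molecule", "ion"]
    composition: object
    molar_mass: float
    alpha_solute: float
    charge: int = 0

    def __post_init__(self) -> None:
        if not self.alpha_solute > 0:
            raise ValidationError(f"alpha_solute must be > 0, got {self.alpha_solute}")
        if not self.molar_mass > 0:
            raise ValidationError(f"molar_mass must be > 0, got {self.molar_mass}")

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        table: PolarizabilityTable,
        label: str = "protein",
        on_nonstandard: Literal["raise", "mean"] = "raise",
    ) -> "MolecularSpecies":
        return cls(
            label=label,
            kind="protein",
            composition=sequence.upper(),
            molar_mass=protein_molar_mass(sequence, table, on_nonstandard),
            alpha_solute=protein_polarizability(sequence, table, on_nonstandard),
        )

    @classmethod
    def from_fasta(
        cls,
        path,
        table: PolarizabilityTable,
        on_nonstandard: Literal["raise", "mean"] = "raise",
    ) -> "MolecularSpecies":
        """Build from a FASTA file; multiple records are treated as chains and summed."""
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise EmptyInputError(f"no sequences in {path}")
        sequence = "".join(str(r.seq) for r in records)
        species = cls.from_sequence(
            sequence, table, label=Path(str(path)).stem, on_nonstandard=on_nonstandard
        )
        # multi-chain mass: one water terminus per chain
        if len(records) > 1:
            extra = WATER_MASS * (len(records) - 1)
            species = cls(
                label=species.label, kind="protein", composition=species.composition,
                molar_mass=species.molar_mass + extra, alpha_solute=species.alpha_solute,
            )
        return species

    @classmethod
    def from_formula(
        cls, formula: str, table: PolarizabilityTable, label: str | None = None
    ) -> "MolecularSpecies":
        composition = parse_formula(formula)
        return cls(
            label=label or formula,
            kind="small_molecule",
            composition=composition,
            molar_mass=molecule_molar_mass(composition, table),
            alpha_solute=molecule_polarizability(composition, table),
        )

    @classmethod
    def from_ion(
        cls, symbol: str, table: PolarizabilityTable, label: str | None = None
    ) -> "MolecularSpecies":
        match = _CHARGE_SUFFIX.search(symbol)
        charge = 0
        if match:
            magnitude = int(match.group(1) or 1)
            charge = magnitude if match.group(2) == "+" else -magnitude
        return cls(
            label=label or symbol,
            kind="ion",
            composition=symbol,
            molar_mass=table.atom_mass.get(symbol) or _missing_ion(symbol),
            alpha_solute=ion_polarizability(symbol, table),
            charge=charge,
        )


def _missing_ion(symbol: str) -> float:
    raise LookupMissError(f"unknown ion {symbol!r}")
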