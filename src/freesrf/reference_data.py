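"""Reference tables: residue/atom polarizabilities, water constants, sequence fixtures.

Every other module consumes these tables; they are shipped as plain TSV under
``freesrf/data`` and validated on load.  Values are static (frequency-independent)
electronic polarizabilities in the CGS volume convention (A^3).

The two bundled protein fixtures are SYNTHETIC stand-ins: sequences with the
lengths and molar masses of the proteins they emulate (recoverin, carbonic
anhydrase II) but a generic vertebrate-average composition.  They exist so the
worked examples run offline; they are not database sequences.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

from .errors import ConfigurationError, ValidationError

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue codes that are rejected unless mean-substitution is requested
NONSTANDARD_CODES = frozenset("XBZUJO")
REQUIRED_ELEMENTS = ("H", "C", "N", "O", "S")

_FIXTURES = {
    "recoverin": "recoverin_synthetic.fasta",
    "caii": "caii_synthetic.fasta",
}


@dataclass(frozen=True)
class PolarizabilityTable:
    """Additive polarizability contributions (A^3) for residues, atoms and ions.

    ``atom_alpha`` also holds monatomic-ion entries (e.g. ``"Ca2+"``); their
    ionic radii (A) live in ``ion_radius``.  Masses are g/mol; residue masses
    are in-chain (water-condensed) masses.
    """

    residue_alpha: Mapping[str, float]
    atom_alpha: Mapping[str, float]
    residue_mass: Mapping[str, float] = field(default_factory=dict)
    atom_mass: Mapping[str, float] = field(default_factory=dict)
    ion_radius: Mapping[str, float] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        missing = [a for a in STANDARD_AMINO_ACIDS if a not in self.residue_alpha]
        if missing:
            raise ValidationError(f"residue table missing standard amino acids: {missing}")
        missing = [e for e in REQUIRED_ELEMENTS if e not in self.atom_alpha]
        if missing:
            raise ValidationError(f"atom table missing required elements: {missing}")
        for name, table in (("residue_alpha", self.residue_alpha),
                            ("atom_alpha", self.atom_alpha)):
            for key, value in table.items():
                if not value > 0:
                    raise ValidationError(f"{name}[{key!r}] must be > 0, got {value}")

    @property
    def mean_residue_alpha(self) -> float:
        """Mean contribution over the 20 standard residues (used for X/B/Z/U substitution)."""
        vals = [self.residue_alpha[a] for a in STANDARD_AMINO_ACIDS]
        return sum(vals) / len(vals)

    @property
    def mean_residue_mass(self) -> float:
        vals = [self.residue_mass[a] for a in STANDARD_AMINO_ACIDS]
        return sum(vals) / len(vals)


@dataclass(frozen=True)
class WaterConstants:
    """Solvation-shell water: per-molecule polarizability and volume.

    The defaults (1.5 A^3 per shell water of volume 25 A^3) give the shell a
    polarizability-per-volume ratio of 0.06 — roughly an order of magnitude
    above a dry protein interior, which is why the shell dominates the signal.
    """

    alpha_shell_water: float = 1.5
    v_water: float = 25.0

    def __post_init__(self) -> None:
        if not self.alpha_shell_water > 0:
            raise ValidationError(f"alpha_shell_water must be > 0, got {self.alpha_shell_water}")
        if not self.v_water > 0:
            raise ValidationError(f"v_water must be > 0, got {self.v_water}")

    @property
    def alpha_ratio(self) -> float:
        return self.alpha_shell_water / self.v_water


@dataclass(frozen=True)
class SequenceFixture:
    name: str
    accession: str
    sequence: str


def _data_text(filename: str) -> str:
    return resources.files("freesrf.data").joinpath(filename).read_text()


def _parse_residues(text: str) -> tuple[dict, dict]:
    alpha, mass = {}, {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        code, a, m, _source = line.split("\t")
        alpha[code] = float(a)
        mass[code] = float(m)
    return alpha, mass


def _parse_atoms(text: str) -> tuple[dict, dict, dict]:
    alpha, mass, radius = {}, {}, {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, a, m, r, _source = line.split("\t")
        alpha[symbol] = float(a)
        mass[symbol] = float(m)
        if r != "-":
            radius[symbol] = float(r)
    return alpha, mass, radius


def _parse_water(text: str) -> dict:
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, value, _source = line.split("\t")
        out[key] = float(value)
    return out


def load_tables(
    overrides: Mapping | None = None,
) -> tuple[PolarizabilityTable, WaterConstants]:
    """Load the shipped reference tables, optionally replacing known entries.

    Parameters
    ----------
    overrides:
        Optional mapping with any of the keys ``"residue_alpha"`` (dict of
        one-letter code -> A^3), ``"atom_alpha"`` (dict of symbol -> A^3),
        ``"alpha_shell_water"`` and ``"v_water"`` (floats).  Override keys must
        name residues/atoms already present; values must be positive.  The
        shipped files are never mutated.

    Returns
    -------
    (PolarizabilityTable, WaterConstants)
    """
    residue_alpha, residue_mass = _parse_residues(_data_text("residues.tsv"))
    atom_alpha, atom_mass, ion_radius = _parse_atoms(_data_text("atoms.tsv"))
    water = _parse_water(_data_text("water.tsv"))
    source = "freesrf bundled tables v1 (atom-additive residues; refraction-derived atoms)"

    if overrides:
        known_top = {"residue_alpha", "atom_alpha", "alpha_shell_water", "v_water"}
        unknown = set(overrides) - known_top
        if unknown:
            raise ConfigurationError(f"unknown override keys: {sorted(unknown)}")
        for sub, table in (("residue_alpha", residue_alpha), ("atom_alpha", atom_alpha)):
            for key, value in dict(overrides.get(sub, {})).items():
                if key not in table:
                    raise ConfigurationError(f"unknown {sub} override key: {key!r}")
                table[key] = float(value)
        for key in ("alpha_shell_water", "v_water"):
            if key in overrides:
                water[key] = float(overrides[key])

    table = PolarizabilityTable(
        residue_alpha=residue_alpha,
        atom_alpha=atom_alpha,
        residue_mass=residue_mass,
        atom_mass=atom_mass,
        ion_radius=ion_radius,
        source=source,
    )
    constants = WaterConstants(
        alpha_shell_water=water["alpha_shell_water"], v_water=water["v_water"]
    )
    return table, constants


def write_tables(table: PolarizabilityTable, constants: WaterConstants, directory) -> None:
    """Serialize tables to TSV files (residues.tsv / atoms.tsv / water.tsv) in *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "residues.tsv", "w") as fh:
        fh.write("# code\talpha_A3\tmass_gmol\tsource\n")
        for code in sorted(table.residue_alpha):
            fh.write(f"{code}\t{table.residue_alpha[code]!r}\t"
                     f"{table.residue_mass.get(code, 0.0)!r}\t{table.source}\n")
    with open(directory / "atoms.tsv", "w") as fh:
        fh.write("# symbol\talpha_A3\tmass_gmol\tradius_A\tsource\n")
        for sym in sorted(table.atom_alpha):
            r = table.ion_radius.get(sym)
            fh.write(f"{sym}\t{table.atom_alpha[sym]!r}\t{table.atom_mass.get(sym, 0.0)!r}\t"
                     f"{'-' if r is None else repr(r)}\t{table.source}\n")
    with open(directory / "water.tsv", "w") as fh:
        fh.write("# key\tvalue\tsource\n")
        fh.write(f"alpha_shell_water\t{constants.alpha_shell_water!r}\tserialized\n")
        fh.write(f"v_water\t{constants.v_water!r}\tserialized\n")


def read_tables(directory) -> tuple[PolarizabilityTable, WaterConstants]:
    """Inverse of :func:`write_tables` (round trip is the identity)."""
    directory = Path(directory)
    residue_alpha, residue_mass = _parse_residues((directory / "residues.tsv").read_text())
    atom_alpha, atom_mass, ion_radius = _parse_atoms((directory / "atoms.tsv").read_text())
    water = _parse_water((directory / "water.tsv").read_text())
    table = PolarizabilityTable(
        residue_alpha=residue_alpha, atom_alpha=atom_alpha,
        residue_mass=residue_mass, atom_mass=atom_mass,
        ion_radius=ion_radius, source="reloaded",
    )
    return table, WaterConstants(water["alpha_shell_water"], water["v_water"])


def list_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str) -> SequenceFixture:
    """Load a bundled synthetic sequence fixture by short name (``recoverin`` / ``caii``)."""
    try:
        filename = _FIXTURES[name.lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {list_fixtures()}"
        ) from None
    record = next(SeqIO.parse(io.StringIO(_data_text(filename)), "fasta"))
    return SequenceFixture(name=name.lower(), accession=record.id, sequence=str(record.seq))


def with_mean_substitution(table: PolarizabilityTable) -> PolarizabilityTable:
    """Return a table in which nonstandard codes (X, B, Z, U...) map to the mean residue.

    Off by default because silent substitution biases the receptor polarizability;
    opt in when sequences carry ambiguity codes.
    """
    extra_alpha = {c: table.mean_residue_alpha for c in NONSTANDARD_CODES}
    extra_mass = {c: table.mean_residue_mass for c in NONSTANDARD_CODES}
    return replace(
        table,
        residue_alpha={**table.residue_alpha, **extra_alpha},
        residue_mass={**table.residue_mass, **extra_mass},
    )
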