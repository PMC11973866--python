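"""Assembly of solvated species and binding systems.

Bridges the dry-polarizability and shell-geometry layers: a solvated species
carries its dry polarizability plus the polarizability of its hydration layer,
and a binding system pairs a solvated receptor and ligand with the product
concentration and the binding-induced polarizability ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import ValidationError
from .polarizability import MolecularSpecies
from .reference_data import PolarizabilityTable, WaterConstants
from .solvation import (
    DEFAULT_PSV,
    ShellConvention,
    SolvationShell,
    SpeciesGeometry,
    build_shell,
    geometry_for_species,
)

GammaScope = Literal["solvated", "dry"]


@dataclass(frozen=True)
class SolvatedSpecies:
    """A species together with its geometry and solvation shell."""

    species: MolecularSpecies
    geometry: SpeciesGeometry
    shell: SolvationShell

    @property
    def alpha_total(self) -> float:
        return self.species.alpha_solute + self.shell.alpha_shell


def solvate(
    species: MolecularSpecies,
    shell_size: float,
    table: PolarizabilityTable,
    constants: WaterConstants,
    partial_specific_volume: float = DEFAULT_PSV,
    convention: ShellConvention = "thickness",
) -> SolvatedSpecies:
    """Attach a spherical solvation shell of the given size to a species."""
    geometry = geometry_for_species(species, table, partial_specific_volume)
    shell = build_shell(geometry.effective_radius, shell_size, constants, convention)
    return SolvatedSpecies(species=species, geometry=geometry, shell=shell)


@dataclass(frozen=True)
class SolvatedSystem:
    """Solvated receptor + ligand, ready to enter the forward prediction.

    ``gamma_scope`` selects what the polarizability ratio multiplies:
    ``"solvated"`` (default) applies it to the solvated totals, i.e. the
    product's polarizability is compared against receptor+shell plus
    ligand(+shell); ``"dry"`` applies it to the dry polarizabilities only,
    with the shells assumed to cancel.  ``include_ligand_shell=False`` drops
    the ligand's shell from the unbound side (shell-ejection scenarios).
    """

    receptor: SolvatedSpecies
    ligand: SolvatedSpecies
    include_ligand_shell: bool = True
    gamma_scope: GammaScope = "solvated"

    @property
    def alpha_R_total(self) -> float:
        if self.gamma_scope == "dry":
            return self.receptor.species.alpha_solute
        return self.receptor.alpha_total

    @property
    def alpha_L_total(self) -> float:
        if self.gamma_scope == "dry":
            return self.ligand.species.alpha_solute
        if self.include_ligand_shell:
            return self.ligand.alpha_total
        return self.ligand.species.alpha_solute


def build_system(
    receptor: MolecularSpecies,
    ligand: MolecularSpecies,
    receptor_shell: float,
    ligand_shell: float | None = None,
    *,
    table: PolarizabilityTable,
    constants: WaterConstants,
    partial_specific_volume: float = DEFAULT_PSV,
    include_ligand_shell: bool = True,
    gamma_scope: GammaScope = "solvated",
    convention: ShellConvention = "thickness",
) -> SolvatedSystem:
    """Solvate both partners (ligand shell defaults to the receptor's size)."""
    if receptor_shell < 0 or (ligand_shell is not None and ligand_shell < 0):
        raise ValidationError("shell sizes must be >= 0")
    if ligand_shell is None:
        ligand_shell = receptor_shell
    return SolvatedSystem(
        receptor=solvate(receptor, receptor_shell, table, constants,
                         partial_specific_volume, convention),
        ligand=solvate(ligand, ligand_shell, table, constants,
                       partial_specific_volume, convention),
        include_ligand_shell=include_ligand_shell,
        gamma_scope=gamma_scope,
    )
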