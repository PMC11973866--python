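"""Clausius-Mossotti algebra for free-solution binding signals.

The Clausius-Mossotti relation

    (n^2 - 1) / (n^2 + 2) = (4*pi/3) * sum_i N_i * alpha_i

links a medium's refractive index n to the number densities N_i (per A^3) and
polarizabilities alpha_i (A^3) of its constituents.  Linearizing about the
solvent index n0 gives the binding signal

    dn = k * N * d(alpha),    k = (2*pi/9) * (n0^2 + 2)^2 / n0

(k ~ 7.47 for water), where N is the number density of binding events and
d(alpha) the polarizability change per event.  Parameterizing the product's
polarizability as a ratio Gamma of the unbound total turns this into a forward
predictor in molar units,

    dn = k * C * N_A * 1e-27 * (alpha_R + alpha_L) * (Gamma - 1),

which is linear in both C and (Gamma - 1), hence trivially invertible for
Gamma from a measured dn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInversionError, DomainError, NonPhysicalDensityError, ValidationError
from .polarizability import MolecularSpecies
from .reference_data import PolarizabilityTable, WaterConstants
from .solvation import AVOGADRO, DEFAULT_PSV, ShellConvention
from .systems import GammaScope, SolvatedSystem, build_system

#: L per A^3 — converts mol/L * N_A into a per-A^3 number density
LITERS_PER_CUBIC_ANGSTROM = 1e-27


@dataclass(frozen=True)
class Medium:
    """The unperturbed solution, characterized by its refractive index."""

    n0: float = 1.333

    def __post_init__(self) -> None:
        if not self.n0 > 1:
            raise DomainError(f"medium refractive index must exceed 1, got {self.n0}")


@dataclass(frozen=True)
class InteractionSystem:
    """Inputs to the forward prediction: solvated totals, Gamma, concentration.

    ``alpha_R_total``/``alpha_L_total`` are the receptor's and ligand's
    polarizabilities including whatever shells the caller decided to count.
    ``gamma`` may be None for systems destined for inversion.
    """

    alpha_R_total: float
    alpha_L_total: float
    concentration: float
    gamma: float | None = None

    def __post_init__(self) -> None:
        if not self.alpha_R_total > 0 or not self.alpha_L_total > 0:
            raise ValidationError("alpha totals must be > 0")
        if self.concentration < 0:
            raise ValidationError(f"concentration must be >= 0, got {self.concentration}")
        if self.gamma is not None and not self.gamma > 0:
            raise ValidationError(f"gamma must be > 0, got {self.gamma}")

    @classmethod
    def from_solvated(
        cls, system: SolvatedSystem, concentration: float, gamma: float | None = None
    ) -> "InteractionSystem":
        return cls(
            alpha_R_total=system.alpha_R_total,
            alpha_L_total=system.alpha_L_total,
            concentration=concentration,
            gamma=gamma,
        )


@dataclass(frozen=True)
class Prediction:
    """A forward result: the RI change, the polarizability change behind it, and k."""

    delta_n: float
    delta_alpha: float
    k_const: float


def cm_k(medium: Medium | float = Medium()) -> float:
    """Linearization constant k = (2*pi/9) * (n0^2 + 2)^2 / n0.

    Equals the derivative dn/d(sum N*alpha) of the exact Clausius-Mossotti
    solution at the operating point n0 (~7.47 for water at 1.333; 2*pi at 1).
    """
    n0 = medium.n0 if isinstance(medium, Medium) else float(medium)
    if not n0 >= 1:
        raise DomainError(f"refractive index must be >= 1, got {n0}")
    return (2.0 * math.pi / 9.0) * (n0**2 + 2.0) ** 2 / n0


def cm_refractive_index(
    number_densities_and_alphas: Iterable[tuple[float, float]]
) -> float:
    """Exact refractive index from the Clausius-Mossotti relation.

    Each item is (number density per A^3, polarizability A^3).  Solves
    (n^2-1)/(n^2+2) = (4*pi/3) * sum(N*alpha) for n; the empty sum is vacuum
    (n = 1).  Sums >= 1 have no real solution and raise.
    """
    s = (4.0 * math.pi / 3.0) * sum(n * a for n, a in number_densities_and_alphas)
    if s >= 1.0:
        raise NonPhysicalDensityError(
            f"Clausius-Mossotti sum {s:.4g} >= 1 has no physical refractive index"
        )
    if s < 0.0:
        raise DomainError(f"Clausius-Mossotti sum must be >= 0, got {s:.4g}")
    return math.sqrt((1.0 + 2.0 * s) / (1.0 - s))


def delta_n_from_delta_alpha(
    number_density: float, delta_alpha: float, medium: Medium = Medium()
) -> float:
    """Linearized RI change dn = k * N * d(alpha); N in per-A^3, alpha in A^3."""
    if number_density < 0:
        raise DomainError(f"number density must be >= 0, got {number_density}")
    return cm_k(medium) * number_density * delta_alpha


def delta_n_prediction(system: InteractionSystem, medium: Medium = Medium()) -> Prediction:
    """Forward prediction of the binding-induced RI change.

    dn = k * C * N_A * 1e-27 * (alpha_R_total + alpha_L_total) * (Gamma - 1).
    The recorded ``delta_alpha`` is the product's polarizability change,
    (alpha_R_total + alpha_L_total) * (Gamma - 1); sign(dn) = sign(Gamma - 1).
    """
    if system.gamma is None:
        raise ValidationError("forward prediction requires gamma")
    k = cm_k(medium)
    delta_alpha = (system.alpha_R_total + system.alpha_L_total) * (system.gamma - 1.0)
    number_density = system.concentration * AVOGADRO * LITERS_PER_CUBIC_ANGSTROM
    return Prediction(delta_n=k * number_density * delta_alpha,
                      delta_alpha=delta_alpha, k_const=k)


def gamma_from_measured_dn(
    measured_delta_n: float,
    system: InteractionSystem,
    medium: Medium = Medium(),
) -> float:
    """Closed-form inversion: the Gamma that reproduces a measured dn.

    The forward map is linear in (Gamma - 1), so
    Gamma = 1 + dn / (k * C * N_A * 1e-27 * (alpha_R_total + alpha_L_total)).
    """
    if system.concentration <= 0:
        raise DegenerateInversionError("cannot invert at zero product concentration")
    denom = (
        cm_k(medium)
        * system.concentration
        * AVOGADRO
        * LITERS_PER_CUBIC_ANGSTROM
        * (system.alpha_R_total + system.alpha_L_total)
    )
    return 1.0 + measured_delta_n / denom


def gamma_from_dndc_ratio(dndc_a: float, dndc_b: float) -> float:
    """Gamma implied by a pair of refractive-index increments: dndc_b / dndc_a.

    Lets solvent-dependent dn/dc spreads for one protein bound the plausible
    range of the binding-induced polarizability ratio.
    """
    if not dndc_a > 0 or not dndc_b > 0:
        raise DomainError("dn/dc values must be > 0")
    return dndc_b / dndc_a


def molar_refractometry(delta_alpha: float, medium: Medium = Medium()) -> float:
    """Molar refractometry chi (RIU per mol/L) for a per-event polarizability change."""
    return cm_k(medium) * AVOGADRO * LITERS_PER_CUBIC_ANGSTROM * delta_alpha


def freesrf_exp_signal(chi: float, beta: float, concentration: float) -> float:
    """Empirical instrument signal rho = beta * chi * C.

    chi is the molar refractometry (RIU per mol/L) and beta the instrument
    response (signal units per RIU); with beta = 1 and chi built from the same
    system via :func:`molar_refractometry`, rho equals the predicted dn.
    """
    if concentration < 0:
        raise DomainError(f"concentration must be >= 0, got {concentration}")
    return beta * chi * concentration


def product_concentration(
    total_receptor: float, total_ligand: float, kd: float
) -> float:
    """Equilibrium 1:1 complex concentration from totals and a dissociation constant.

    Convenience for assembling inputs when only totals are known: solves the
    standard quadratic [RL]^2 - (R_t + L_t + Kd)[RL] + R_t L_t = 0 and returns
    the physical root.  All quantities in mol/L.
    """
    if total_receptor < 0 or total_ligand < 0 or kd < 0:
        raise DomainError("concentrations and Kd must be >= 0")
    b = total_receptor + total_ligand + kd
    disc = b * b - 4.0 * total_receptor * total_ligand
    return 0.5 * (b - math.sqrt(max(disc, 0.0)))


@dataclass(frozen=True)
class SweepGrid:
    """dn evaluated over a (Gamma, shell size) lattice; rows follow gamma_axis."""

    gamma_axis: tuple[float, ...]
    shell_axis: tuple[float, ...]
    delta_n_grid: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected = (len(self.gamma_axis), len(self.shell_axis))
        if self.delta_n_grid.shape != expected:
            raise ValidationError(
                f"grid shape {self.delta_n_grid.shape} does not match axes {expected}"
            )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns gamma, shell_A, delta_n_RIU."""
        rows = [
            (g, s, float(self.delta_n_grid[i, j]))
            for i, g in enumerate(self.gamma_axis)
            for j, s in enumerate(self.shell_axis)
        ]
        return pd.DataFrame(rows, columns=["gamma", "shell_A", "delta_n_RIU"])


def sweep_gamma_shell(
    receptor: MolecularSpecies,
    ligand: MolecularSpecies,
    concentration: float,
    gamma_axis: Sequence[float],
    shell_axis: Sequence[float],
    medium: Medium = Medium(),
    *,
    table: PolarizabilityTable,
    constants: WaterConstants,
    partial_specific_volume: float = DEFAULT_PSV,
    include_ligand_shell: bool = True,
    gamma_scope: GammaScope = "solvated",
    convention: ShellConvention = "thickness",
) -> SweepGrid:
    """Forward prediction over a (Gamma, shell size) lattice.

    Both partners' shells are rebuilt at every shell size; each cell equals
    the standalone :func:`delta_n_prediction` at that (Gamma, shell) point.
    """
    if len(gamma_axis) == 0 or len(shell_axis) == 0:
        raise ValidationError("sweep axes must be non-empty")
    grid = np.empty((len(gamma_axis), len(shell_axis)))
    for j, shell in enumerate(shell_axis):
        solvated = build_system(
            receptor, ligand, shell,
            table=table, constants=constants,
            partial_specific_volume=partial_specific_volume,
            include_ligand_shell=include_ligand_shell,
            gamma_scope=gamma_scope, convention=convention,
        )
        for i, gamma in enumerate(gamma_axis):
            sys_ = InteractionSystem.from_solvated(solvated, concentration, gamma)
            grid[i, j] = delta_n_prediction(sys_, medium).delta_n
    return SweepGrid(
        gamma_axis=tuple(float(g) for g in gamma_axis),
        shell_axis=tuple(float(s) for s in shell_axis),
        delta_n_grid=grid,
    )
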